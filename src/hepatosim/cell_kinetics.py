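"""Kinetic hepatocyte model of acetaminophen (APAP) metabolism and oxidative stress.

The cell model tracks APAP uptake, Phase I oxidation to the reactive quinone
imine NAPQI (CYP3A4 / CYP2E1 / a lumped minor-CYP pool), Phase II conjugation
(glucuronidation, sulfation, glutathione conjugation), glutathione (GSH)
turnover, NAPQI protein binding, and the downstream reactive-oxygen cascade
(superoxide -> H2O2 -> GSH peroxidase) that drives necrosis at overdose.

The right-hand side of the cell ODE is ``dc/dt = N @ v(c, p)`` with ``N`` the
integer stoichiometric matrix and ``v`` the vector of reaction rates. All
enzymatic reactions use irreversible Michaelis-Menten kinetics (multiplicative
saturation terms for the two bi-substrate reactions, GST and GPX), membrane
transport uses a saturable carrier plus linear passive permeation, and
non-specific binding is first-order mass action.

Canonical internal units: concentrations in uM (intracellular entries are
umol per litre of cell volume), time in minutes, rates in uM/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "N_INTRACELLULAR",
    "IDX",
    "EnzymeProfile",
    "StoichiometricModel",
    "ActivityConversionSpec",
    "CellTrajectory",
    "build_network",
    "reaction_rates",
    "cell_rhs",
    "convert_specific_activity",
    "simulate_cell",
    "basal_state",
]

# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------

#: Ordered species list. The first ``N_INTRACELLULAR`` entries are
#: intracellular pools (umol/L_cell); the trailing ``*_ext`` entries are the
#: adjacent extracellular bulk slots (uM). Suffix ``_B`` marks non-specific
#: binding to protein/lipid, ``_P`` protein-bound NAPQI.
SPECIES: tuple[str, ...] = (
    "APAP_cyt",
    "APAP_B",
    "NAPQI",
    "NAPQI_P",
    "APAPG",
    "APAPS",
    "APAPS_B",
    "APAPGS",
    "GSH",
    "GSSG",
    "H2O2",
    "ROS",
    "APAP_ext",
    "APAPG_ext",
    "APAPS_ext",
    "APAPGS_ext",
    "NAPQI_ext",
)

N_INTRACELLULAR = 12

#: name -> index lookup
IDX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

#: Species carrying the APAP moiety (parent + all metabolites/bound forms,
#: intracellular and extracellular). GSH-derived atoms are not counted.
APAP_MOIETY_SPECIES: tuple[str, ...] = (
    "APAP_cyt",
    "APAP_B",
    "NAPQI",
    "NAPQI_P",
    "APAPG",
    "APAPS",
    "APAPS_B",
    "APAPGS",
    "APAP_ext",
    "APAPG_ext",
    "APAPS_ext",
    "APAPGS_ext",
    "NAPQI_ext",
)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class EnzymeProfile:
    """Per-individual hepatocyte parameter set.

    Vmax values are umol/L_cell/min, Km values uM, permeabilities and rate
    constants 1/min (volume-normalized). CYP3A4/CYP2E1 defaults are the
    reference individual (0.95 and 1.0 umol/L_cell/min); the remaining
    constants are package defaults at literature-typical magnitudes,
    calibrated against the in-vitro LC50 (see `hepatosim.experiments`).
    """

    # Phase I oxidation APAP -> NAPQI (Km at the mM scale typical for the
    # low-affinity oxidation of APAP, keeping NAPQI formation
    # concentration-sensitive across the overdose range)
    vmax_cyp3a4: float = 0.95
    km_cyp3a4: float = 10000.0
    vmax_cyp2e1: float = 1.0
    km_cyp2e1: float = 10000.0
    # lumped CYP2A6 + CYP1A2 + CYP2D6
    vmax_cyp_minor: float = 0.5
    km_cyp_minor: float = 10000.0
    # Phase II conjugation
    vmax_ugt: float = 30.0
    km_ugt: float = 7000.0
    vmax_sult: float = 8.0
    km_sult: float = 300.0
    vmax_gst: float = 400.0
    km_gst_napqi: float = 50.0
    km_gst_gsh: float = 300.0
    # NAPQI reduction back to APAP
    vmax_nqo1: float = 0.05
    km_nqo1: float = 200.0
    # glutathione turnover; basal_gsh is the resting level at which GGT
    # degradation balances GSS synthesis
    vmax_gss: float = 0.1          # zero-order synthesis
    vmax_ggt: float = 0.26
    km_ggt: float = 800.0
    basal_gsh: float = 500.0
    # oxidative-stress pathway
    k_ros: float = 1.0             # ROS synthesis gain, 1/min per uM NAPQI_P
    vmax_sod: float = 6.5
    km_sod: float = 10.0
    vmax_gpx: float = 50.0
    km_gpx_h2o2: float = 100.0
    km_gpx_gsh: float = 200.0
    vmax_gsr: float = 0.3          # recycling saturates under oxidative load
    km_gsr: float = 20.0
    k_h2o2_clear: float = 0.0001    # basal catalase-like first-order clearance
    # membrane transport
    vmax_uptake: float = 10.0      # saturable basolateral APAP carrier
    km_uptake: float = 500.0
    p_apap: float = 2.0            # passive permeability, 1/min (cell-volume basis)
    p_napqi: float = 0.005
    vmax_mrp2: float = 50.0        # apical (bile) conjugate export
    km_mrp2: float = 500.0
    vmax_mrp34: float = 25.0       # basolateral (blood) conjugate export
    km_mrp34: float = 500.0
    # non-specific binding (mass action)
    kon_apap: float = 0.1
    koff_apap: float = 0.1
    kon_apaps: float = 0.2
    koff_apaps: float = 0.05
    kon_napqi: float = 0.05
    koff_napqi: float = 0.05

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value < 0:
                raise ValueError(f"EnzymeProfile.{f.name} must be >= 0, got {value}")
        for vmax_name, km_names in _VMAX_KM_PAIRS.items():
            if getattr(self, vmax_name) > 0:
                for km_name in km_names:
                    if getattr(self, km_name) <= 0:
                        raise ValueError(
                            f"{km_name} must be > 0 when {vmax_name} > 0"
                        )

    def as_array(self) -> np.ndarray:
        """Flatten to the canonical float64 vector used by the fast kernels."""
        return np.array([getattr(self, f.name) for f in fields(self)], float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "EnzymeProfile":
        names = [f.name for f in fields(cls)]
        if len(arr) != len(names):
            raise ValueError("parameter vector length mismatch")
        return cls(**dict(zip(names, map(float, arr))))

    def with_updates(self, **kwargs: float) -> "EnzymeProfile":
        return replace(self, **kwargs)


_VMAX_KM_PAIRS: dict[str, tuple[str, ...]] = {
    "vmax_cyp3a4": ("km_cyp3a4",),
    "vmax_cyp2e1": ("km_cyp2e1",),
    "vmax_cyp_minor": ("km_cyp_minor",),
    "vmax_ugt": ("km_ugt",),
    "vmax_sult": ("km_sult",),
    "vmax_gst": ("km_gst_napqi", "km_gst_gsh"),
    "vmax_nqo1": ("km_nqo1",),
    "vmax_ggt": ("km_ggt",),
    "vmax_sod": ("km_sod",),
    "vmax_gpx": ("km_gpx_h2o2", "km_gpx_gsh"),
    "vmax_gsr": ("km_gsr",),
    "vmax_uptake": ("km_uptake",),
    "vmax_mrp2": ("km_mrp2",),
    "vmax_mrp34": ("km_mrp34",),
}

#: index of each EnzymeProfile field in the flattened parameter vector
PARAM_INDEX: dict[str, int] = {
    f.name: i for i, f in enumerate(fields(EnzymeProfile))
}


@dataclass(frozen=True)
class ActivityConversionSpec:
    """Bookkeeping constants for converting recombinant-enzyme specific
    activities (nmol/nmol_enzyme/min) to cell-volume activities.

    total_cell_protein is g protein per litre of cells; microsomal_ratio is
    the microsomal-to-total-protein mass ratio.
    """

    total_cell_protein: float = 30.0   # g/L_cell
    microsomal_ratio: float = 0.22

    def __post_init__(self) -> None:
        if self.total_cell_protein <= 0 or self.microsomal_ratio <= 0:
            raise ValueError("conversion constants must be > 0")


def convert_specific_activity(
    a_spec: float,
    content: float,
    spec: ActivityConversionSpec = ActivityConversionSpec(),
) -> float:
    """Convert a specific activity to a cell-volume Vmax (umol/L_cell/min).

    Parameters
    ----------
    a_spec
        Specific activity on the recombinant enzyme, nmol substrate per nmol
        enzyme per min.
    content
        Microsomal enzyme content, nmol enzyme per g microsomal protein.
    spec
        Protein bookkeeping constants.

    The enzyme concentration per cell volume is
    ``content * microsomal_ratio * total_cell_protein`` (nmol/L_cell); the
    activity in umol/L_cell/min follows after the nmol -> umol conversion.
    """
    if a_spec < 0 or content < 0:
        raise ValueError("specific activity and enzyme content must be >= 0")
    enzyme_nmol_per_l_cell = (
        content * spec.microsomal_ratio * spec.total_cell_protein
    )
    return a_spec * enzyme_nmol_per_l_cell * 1e-3


# ---------------------------------------------------------------------------
# Reaction network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    name: str
    stoich: dict[str, int]
    law: str               # "mm", "mm2", "passive", "binding", "zero_order", "linear"
    enzyme: str            # parameter stem, e.g. "cyp3a4", or "" for none
    substrates: tuple[str, ...]
    transform: bool        # True: chemical transformation; False: transport


def _reactions() -> tuple[Reaction, ...]:
    r = [
        Reaction("uptake_active", {"APAP_ext": -1, "APAP_cyt": +1},
                 "mm", "uptake", ("APAP_ext",), False),
        Reaction("uptake_passive", {"APAP_ext": -1, "APAP_cyt": +1},
                 "passive", "p_apap", ("APAP_ext", "APAP_cyt"), False),
        Reaction("ugt", {"APAP_cyt": -1, "APAPG": +1},
                 "mm", "ugt", ("APAP_cyt",), True),
        Reaction("sult", {"APAP_cyt": -1, "APAPS": +1},
                 "mm", "sult", ("APAP_cyt",), True),
        Reaction("cyp3a4", {"APAP_cyt": -1, "NAPQI": +1},
                 "mm", "cyp3a4", ("APAP_cyt",), True),
        Reaction("cyp2e1", {"APAP_cyt": -1, "NAPQI": +1},
                 "mm", "cyp2e1", ("APAP_cyt",), True),
        Reaction("cyp_minor", {"APAP_cyt": -1, "NAPQI": +1},
                 "mm", "cyp_minor", ("APAP_cyt",), True),
        Reaction("nqo1", {"NAPQI": -1, "APAP_cyt": +1},
                 "mm", "nqo1", ("NAPQI",), True),
        Reaction("gst", {"NAPQI": -1, "GSH": -1, "APAPGS": +1},
                 "mm2", "gst", ("NAPQI", "GSH"), True),
        Reaction("bind_apap", {"APAP_cyt": -1, "APAP_B": +1},
                 "binding", "apap", ("APAP_cyt", "APAP_B"), True),
        Reaction("bind_apaps", {"APAPS": -1, "APAPS_B": +1},
                 "binding", "apaps", ("APAPS", "APAPS_B"), True),
        Reaction("bind_napqi", {"NAPQI": -1, "NAPQI_P": +1},
                 "binding", "napqi", ("NAPQI", "NAPQI_P"), True),
        Reaction("mrp2_apapg", {"APAPG": -1},
                 "mm", "mrp2", ("APAPG",), False),
        Reaction("mrp2_apaps", {"APAPS": -1},
                 "mm", "mrp2", ("APAPS",), False),
        Reaction("mrp2_apapgs", {"APAPGS": -1},
                 "mm", "mrp2", ("APAPGS",), False),
        Reaction("mrp34_apapg", {"APAPG": -1, "APAPG_ext": +1},
                 "mm", "mrp34", ("APAPG",), False),
        Reaction("mrp34_apaps", {"APAPS": -1, "APAPS_ext": +1},
                 "mm", "mrp34", ("APAPS",), False),
        Reaction("mrp34_apapgs", {"APAPGS": -1, "APAPGS_ext": +1},
                 "mm", "mrp34", ("APAPGS",), False),
        Reaction("napqi_passive", {"NAPQI_ext": -1, "NAPQI": +1},
                 "passive", "p_napqi", ("NAPQI_ext", "NAPQI"), False),
        Reaction("gss", {"GSH": +1},
                 "zero_order", "gss", (), True),
        Reaction("ggt", {"GSH": -1},
                 "mm", "ggt", ("GSH",), True),
        Reaction("ros_synthesis", {"ROS": +1},
                 "linear", "k_ros", ("NAPQI_P",), True),
        Reaction("sod", {"ROS": -1, "H2O2": +1},
                 "mm", "sod", ("ROS",), True),
        Reaction("gpx", {"H2O2": -1, "GSH": -2, "GSSG": +1},
                 "mm2", "gpx", ("H2O2", "GSH"), True),
        Reaction("gsr", {"GSSG": -1, "GSH": +2},
                 "mm", "gsr", ("GSSG",), True),
        Reaction("h2o2_clearance", {"H2O2": -1},
                 "linear", "k_h2o2_clear", ("H2O2",), True),
    ]
    return tuple(r)


@dataclass(frozen=True)
class StoichiometricModel:
    """Fixed reaction network: species order, reactions, and integer N."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    N: np.ndarray                 # (m species, r reactions), int
    transform_mask: np.ndarray    # (r,), bool; True = chemical transformation

    @property
    def moiety_vector(self) -> np.ndarray:
        """Indicator row of the APAP-carrying species (conserved moiety)."""
        w = np.zeros(len(self.species))
        for name in APAP_MOIETY_SPECIES:
            w[self.species.index(name)] = 1.0
        return w

    def reaction_index(self, name: str) -> int:
        for i, rxn in enumerate(self.reactions):
            if rxn.name == name:
                return i
        raise KeyError(name)


def build_network() -> StoichiometricModel:
    """Build the fixed APAP metabolism / oxidative-stress reaction network."""
    reactions = _reactions()
    m, r = len(SPECIES), len(reactions)
    N = np.zeros((m, r), dtype=int)
    for j, rxn in enumerate(reactions):
        for sp, coeff in rxn.stoich.items():
            N[IDX[sp], j] = coeff
    transform = np.array([rxn.transform for rxn in reactions])
    return StoichiometricModel(SPECIES, reactions, N, transform)


#: module-level singleton; the network topology is fixed
NETWORK = build_network()


# ---------------------------------------------------------------------------
# Rate laws and RHS
# ---------------------------------------------------------------------------


def reaction_rates(
    c: np.ndarray,
    e: EnzymeProfile,
    zone_factor: float = 1.0,
    network: StoichiometricModel = NETWORK,
) -> np.ndarray:
    """Evaluate the reaction-rate vector v(c, p) in uM/min.

    ``zone_factor`` multiplies the CYP3A4 Vmax only (pericentral zonation).
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (len(network.species),):
        raise ValueError(f"expected {len(network.species)} species, got {c.shape}")
    if np.any(c < 0):
        raise ValueError("negative concentration")
    if zone_factor <= 0:
        raise ValueError("zone_factor must be > 0")

    v = np.zeros(len(network.reactions))
    for j, rxn in enumerate(network.reactions):
        if rxn.law == "mm":
            vmax = getattr(e, f"vmax_{rxn.enzyme}")
            km = getattr(e, f"km_{rxn.enzyme}")
            if rxn.enzyme == "cyp3a4":
                vmax = vmax * zone_factor
            s = c[IDX[rxn.substrates[0]]]
            v[j] = vmax * s / (km + s) if vmax > 0 else 0.0
        elif rxn.law == "mm2":
            vmax = getattr(e, f"vmax_{rxn.enzyme}")
            if vmax == 0:
                continue
            s1 = c[IDX[rxn.substrates[0]]]
            s2 = c[IDX[rxn.substrates[1]]]
            km1 = getattr(e, f"km_{rxn.enzyme}_{rxn.substrates[0].lower()}")
            km2 = getattr(e, f"km_{rxn.enzyme}_{rxn.substrates[1].lower()}")
            v[j] = vmax * (s1 / (km1 + s1)) * (s2 / (km2 + s2))
        elif rxn.law == "passive":
            p = getattr(e, rxn.enzyme)
            v[j] = p * (c[IDX[rxn.substrates[0]]] - c[IDX[rxn.substrates[1]]])
        elif rxn.law == "binding":
            kon = getattr(e, f"kon_{rxn.enzyme}")
            koff = getattr(e, f"koff_{rxn.enzyme}")
            v[j] = kon * c[IDX[rxn.substrates[0]]] - koff * c[IDX[rxn.substrates[1]]]
        elif rxn.law == "zero_order":
            v[j] = getattr(e, f"vmax_{rxn.enzyme}")
        elif rxn.law == "linear":
            k = getattr(e, rxn.enzyme)
            v[j] = k * c[IDX[rxn.substrates[0]]]
        else:  # pragma: no cover
            raise ValueError(f"unknown rate law {rxn.law}")
    return v


def cell_rhs(
    c: np.ndarray,
    e: EnzymeProfile,
    zone_factor: float = 1.0,
    alive: bool = True,
    vol_ratio: float = 1.0,
    clamp_ext: bool = False,
    network: StoichiometricModel = NETWORK,
) -> np.ndarray:
    """Cell ODE right-hand side dc/dt = N @ v.

    Parameters
    ----------
    vol_ratio
        Ratio of total cell volume to extracellular bulk volume; derivatives
        of the ``*_ext`` slots are scaled by it so amounts, not
        concentrations, are conserved across the membrane.
    alive
        Dead cells are frozen: all intracellular derivatives are zero and no
        exchange with the bulk occurs.
    clamp_ext
        Hold extracellular slots fixed (infinite-reservoir in-vitro mode).
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (len(network.species),):
        raise ValueError("dimension mismatch with the stoichiometric model")
    if not alive:
        return np.zeros_like(c)
    # rate laws are evaluated on the non-negative part; tiny negative solver
    # excursions are treated as zero substrate
    v = reaction_rates(np.maximum(c, 0.0), e, zone_factor, network)
    dcdt = network.N @ v
    dcdt[N_INTRACELLULAR:] *= vol_ratio
    if clamp_ext:
        dcdt[N_INTRACELLULAR:] = 0.0
    return dcdt


def basal_state(e: EnzymeProfile) -> np.ndarray:
    """Drug-free resting state: GSH at its basal level, all else zero.

    The default profile satisfies GGT(basal_gsh) == vmax_gss so this is a
    fixed point of the kinetics in the absence of APAP.
    """
    c0 = np.zeros(len(SPECIES))
    c0[IDX["GSH"]] = e.basal_gsh
    return c0


# ---------------------------------------------------------------------------
# Single-cell simulation (reference stiff-ODE path)
# ---------------------------------------------------------------------------


@dataclass
class CellTrajectory:
    """Solution of a single-cell simulation on the requested output grid."""

    times: np.ndarray                 # (n_t,), min
    concentrations: np.ndarray        # (n_t, m), uM
    success: bool
    message: str = ""

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[:, IDX[species]]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.concentrations, columns=list(SPECIES))
        df.insert(0, "time_min", self.times)
        return df


def simulate_cell(
    c0: np.ndarray,
    e: EnzymeProfile,
    exposure: float | Callable[[float], float],
    duration: float,
    zone_factor: float = 1.0,
    n_out: int = 200,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "LSODA",
) -> CellTrajectory:
    """Simulate one hepatocyte under a clamped extracellular APAP schedule.

    ``exposure`` is either a constant concentration (uM) or a function of
    time (min) giving the well concentration; the medium is treated as an
    infinite reservoir (in-vitro mode), so extracellular slots are clamped.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    expo = exposure if callable(exposure) else (lambda t, _c=float(exposure): _c)

    def rhs(t: float, c: np.ndarray) -> np.ndarray:
        c = c.copy()
        c[IDX["APAP_ext"]] = max(expo(t), 0.0)
        return cell_rhs(c, e, zone_factor=zone_factor, clamp_ext=True)

    c0 = np.asarray(c0, dtype=float).copy()
    c0[IDX["APAP_ext"]] = max(expo(0.0), 0.0)
    t_eval = np.linspace(0.0, duration, n_out)
    sol = solve_ivp(
        rhs, (0.0, duration), c0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol,
    )
    conc = sol.y.T if sol.success else sol.y.T
    times = sol.t
    if sol.success:
        conc = conc.copy()
        conc[:, IDX["APAP_ext"]] = [max(expo(t), 0.0) for t in times]
    msg = "" if sol.success else f"{sol.message} (reached t = {times[-1]:.3f} min)"
    return CellTrajectory(times=times, concentrations=conc,
                          success=bool(sol.success), message=msg)
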
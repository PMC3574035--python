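"""Core model definition: species, parameters, rate laws and the coupled ODE system.

The model tracks whole-body cholesterol through six physiological blocks:
dietary intake, the intestinal pool (with enterohepatic bile-salt cycling),
faecal excretion, the hepatic free/ester pools, the plasma lipoprotein cascade
(VLDL -> IDL -> LDL, plus HDL-mediated reverse transport), and the peripheral
free/ester pools.  Tissue pools are in mg, plasma lipoprotein species in mg/dL,
receptor counts and enzyme activities are dimensionless indices with a nominal
"normal" value of 100.  The two unit families are deliberately not reconciled
by a plasma-volume factor; the model reproduces its source parameterisation
as printed, so it is not globally mass-conserving across compartments (see
docs/methods.md).

Synthesis fluxes are Hill-type: negative feedback of each free-cholesterol
pool on its own synthesis (intestinal, hepatic, peripheral), and feed-forward
stimulation of biliary cholesterol release by the hepatic pool.  LDL-receptor
synthesis is reciprocally inhibited by the local free-cholesterol pool
(khrs * HRS / HFC hepatically, kprs * PRS / PFC peripherally, with HRS/PRS
constant source terms), so the steady-state receptor count falls as the pool
grows -- the down-regulation through which absorption and receptor-synthesis
changes move plasma LDL-C.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SPECIES",
    "SPECIES_NAMES",
    "SINK_SPECIES",
    "BOUNDARY_NAMES",
    "PARAMETER_NAMES",
    "StateVector",
    "ParameterSet",
    "BoundarySet",
    "ModelOptions",
    "Model",
    "Reaction",
    "REACTIONS",
    "intestinal_synthesis_rate",
    "hepatic_synthesis_rate",
    "peripheral_synthesis_rate",
    "biliary_release_rate",
    "bile_salt_synthesis_rate",
    "hldlr_synthesis_rate",
    "pldlr_synthesis_rate",
    "rhs",
    "rhs_array",
    "reaction_rates",
]


class DomainError(ValueError):
    """Raised when an operation is evaluated outside its biological domain."""


# ---------------------------------------------------------------------------
# Species / boundary / parameter registries
# ---------------------------------------------------------------------------

#: (name, unit, role) for every dynamic and sink species, in state-vector order.
SPECIES: tuple[tuple[str, str, str], ...] = (
    ("IC", "mg", "dynamic"),          # intestinal cholesterol
    ("IBS", "mg", "dynamic"),         # intestinal bile salts
    ("EC", "mg", "sink"),             # excreted (faecal) cholesterol
    ("EBS", "mg", "sink"),            # excreted bile salts
    ("HBS", "mg", "dynamic"),         # hepatic bile-salt pool
    ("HFC", "mg", "dynamic"),         # hepatic free cholesterol
    ("HCE", "mg", "dynamic"),         # hepatic cholesteryl esters
    ("HLDLR", "receptor", "dynamic"),  # hepatic LDL receptors (index, ~100)
    ("HLDLRD", "receptor", "sink"),   # degraded hepatic receptors
    ("VLDLC", "mg/dL", "dynamic"),
    ("IDLC", "mg/dL", "dynamic"),
    ("LDLC", "mg/dL", "dynamic"),
    ("HDLC", "mg/dL", "dynamic"),
    ("NHDL", "particle", "dynamic"),  # nascent HDL particle count (index)
    ("PLDLR", "receptor", "dynamic"),
    ("PLDLRD", "receptor", "sink"),
    ("PFC", "mg", "dynamic"),         # peripheral free cholesterol
    ("PCE", "mg", "dynamic"),         # peripheral cholesteryl esters
    ("PSS", "mg", "sink"),            # cholesterol lost to steroidogenesis
)

SPECIES_NAMES: tuple[str, ...] = tuple(s[0] for s in SPECIES)
SPECIES_UNITS: dict[str, str] = {s[0]: s[1] for s in SPECIES}
SPECIES_ROLES: dict[str, str] = {s[0]: s[2] for s in SPECIES}
SINK_SPECIES: tuple[str, ...] = tuple(s[0] for s in SPECIES if s[2] == "sink")
_IDX: dict[str, int] = {name: i for i, name in enumerate(SPECIES_NAMES)}

#: Fixed boundary species: seven enzyme/receptor activities plus dietary intake.
BOUNDARY_NAMES: tuple[str, ...] = (
    "DC", "ACAT", "CEH", "LPL", "HSL", "LCAT", "CETP", "SRB1",
)
_BIDX: dict[str, int] = {name: i for i, name in enumerate(BOUNDARY_NAMES)}

#: Pools whose appearance in a rate-law denominator makes zero a singularity.
SINGULAR_DENOMINATORS: tuple[str, ...] = ("HBS", "HFC", "PFC")

_RATE_CONSTANTS = tuple(f"k{i}" for i in range(1, 30)) + ("khrs", "kprs")
#: constant source terms of the receptor-synthesis rate laws (khrs*HRS/HFC,
#: kprs*PRS/PFC) -- receptor production is reciprocally inhibited by the local
#: free-cholesterol pool but does not depend on the receptor count itself
_SOURCE_CONSTANTS = ("HRS", "PRS")
_HILL_CONSTANTS = (
    "ICSmax", "ICt", "IS",
    "BCRmax", "BCRt", "BS",
    "HCSmax", "HCSt", "HS",
    "PCSmax", "PPCt", "PCSS",
)
PARAMETER_NAMES: tuple[str, ...] = (
    _RATE_CONSTANTS + _SOURCE_CONSTANTS + _HILL_CONSTANTS
)
_PIDX: dict[str, int] = {name: i for i, name in enumerate(PARAMETER_NAMES)}

#: Printed default rate constants (per day unless noted in the source table).
_DEFAULT_PARAMS: dict[str, float] = {
    "k1": 1.0,            # cholesterol intake
    "k2": 6.0,            # bile-salt release into the intestine
    "k3": 4.29,           # hepatic return of bile salts
    "k4": 8.56e-1,        # bile-salt excretion
    "k5": 2.66,           # bile-salt synthesis
    "k6": 5.29e-4,        # cholesterol absorption
    "k7": 5.29e-4,        # cholesterol excretion
    "k8": 5e-4,           # intestinal nascent-HDL synthesis
    "k9": 1.0,            # hepatic esterification (ACAT)
    "k10": 5.998,         # hepatic ester hydrolysis (CEH)
    "k11": 5e-2,          # hepatic nascent-HDL synthesis
    "k12": 1.6e-2,        # VLDL-C secretion
    "k13": 1e-3,          # hepatic LDL-receptor degradation
    "k14": 4.96e-3,       # VLDL-C hepatic receptor uptake
    "k15": 4.3e-1,        # VLDL -> IDL lipolysis (LPL)
    "k16": 5.4e-2,        # IDL-C hepatic receptor uptake
    "k17": 3.8e-1,        # IDL -> LDL conversion (HSL)
    "k18": 6.80e-2,       # LDL-C hepatic receptor uptake
    "k19": 5.0e-3,        # LDL-C receptor-independent hepatic uptake
    "k20": 6.75e-3,       # LDL-C peripheral receptor uptake
    "k21": 5.0e-6,        # LDL-C receptor-independent peripheral uptake
    "k22": 1e-2,          # peripheral LDL-receptor degradation
    "k23": 1.75e-2,       # peripheral esterification (ACAT)
    "k24": 1.07e-1,       # peripheral ester hydrolysis (CEH)
    "k25": 5e-4,          # steroid-hormone production
    "k26": 1.5e-5,        # HDL-C formation (LCAT scavenging)
    "k27": 10e-3,         # CETP transfer HDL -> VLDL
    "k28": 1e-3,          # CETP transfer HDL -> LDL
    "k29": 5.0e-2,        # SR-BI hepatic HDL uptake (reverse transport)
    "khrs": 100.0,        # hepatic LDL-receptor synthesis
    "kprs": 100.0,        # peripheral LDL-receptor synthesis
    "HRS": 60.0,          # hepatic receptor-synthesis source -- see note below
    "PRS": 575.16,        # peripheral receptor-synthesis source
    "ICSmax": 1e2,        # mg/day
    "ICt": 3120.0,        # mg -- see note below
    "IS": 5.0,
    "BCRmax": 2e3,        # mg/day
    "BCRt": 5.55e4,       # mg
    "BS": 5.0,
    "HCSmax": 5e2,        # mg/day
    "HCSt": 9.39e4,       # mg
    "HS": 5.0,
    "PCSmax": 5e2,        # mg/day
    "PPCt": 8.0342e4,     # mg
    "PCSS": 5.0,
}

# ICt: the source table prints 3.120e2, but with the documented intestinal pool
# of 3150 mg that yields ~1e-3 mg/day of synthesis, contradicting the same
# source's 49 mg/day intestinal-synthesis budget.  3120 mg reproduces the
# budget (ICSmax/(1+(3150/3120)^5) ~ 48.8 mg/day) and is used as the default;
# the printed value is retained as metadata.
#
# HRS/PRS: the documented receptor-synthesis source values are 600 (hepatic)
# and 575.16 (peripheral).  Peripherally, kprs*575.16/PFC0 = 1.0/day equals
# the degradation flux k22*PLDLR0 exactly -- the source value is the constant
# that balances receptor turnover at the documented state.  The same
# construction hepatically requires HFC0*k13*HLDLR0/khrs = 60; the documented
# 600 contradicts k13 by exactly one order of magnitude and is kept as
# metadata while 60 (the self-consistent value) is the default.
PRINTED_VALUES: dict[str, float] = {"ICt": 3.120e2, "HRS": 600.0}

#: printed unit strings of the source parameter table (reproduced verbatim,
#: including its idiosyncrasies, e.g. "mg/day/day" for k20)
PARAMETER_UNITS: dict[str, str] = {
    **{k: "mg/day" for k in ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8",
                             "k9", "k10", "k11", "k23", "k24", "k25")},
    **{k: "mg/dL/day" for k in ("k12", "k14", "k15", "k16", "k17", "k18",
                                "k19", "k21", "k26", "k27", "k28", "k29")},
    "k13": "number/day", "k22": "number/day",
    "khrs": "number/day", "kprs": "number/day",
    "k20": "mg/day/day",
    "HRS": "dimensionless", "PRS": "dimensionless",
    "ICSmax": "mg/day", "ICt": "mg", "IS": "dimensionless",
    "BCRmax": "mg/day", "BCRt": "mg", "BS": "dimensionless",
    "HCSmax": "mg/day", "HCSt": "mg", "HS": "dimensionless",
    "PCSmax": "mg/day", "PPCt": "mg", "PCSS": "dimensionless",
}

_DEFAULT_STATE: dict[str, float] = {
    "IC": 3150.0,
    "IBS": 467.0,
    "EC": 0.0,
    "EBS": 0.0,
    "HBS": 400.0,
    "HFC": 60000.0,
    "HCE": 10000.0,
    "HLDLR": 100.0,
    "HLDLRD": 0.0,
    "VLDLC": 20.0,
    "IDLC": 20.0,
    "LDLC": 100.0,
    "HDLC": 45.0,
    "NHDL": 100.0,
    "PLDLR": 100.0,
    "PLDLRD": 0.0,
    "PFC": 57516.0,
    "PCE": 9363.0,
    "PSS": 0.0,
}

_DEFAULT_BOUNDARIES: dict[str, float] = {
    "DC": 304.0,
    "ACAT": 100.0, "CEH": 100.0, "LPL": 100.0, "HSL": 100.0,
    "LCAT": 100.0, "CETP": 100.0, "SRB1": 100.0,
}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


def _make_float_dataclass_body(names: Iterable[str], defaults: Mapping[str, float]):
    return {name: defaults[name] for name in names}


@dataclass
class StateVector:
    """All dynamic and sink species at one time point (see SPECIES for units)."""

    IC: float = 3150.0
    IBS: float = 467.0
    EC: float = 0.0
    EBS: float = 0.0
    HBS: float = 400.0
    HFC: float = 60000.0
    HCE: float = 10000.0
    HLDLR: float = 100.0
    HLDLRD: float = 0.0
    VLDLC: float = 20.0
    IDLC: float = 20.0
    LDLC: float = 100.0
    HDLC: float = 45.0
    NHDL: float = 100.0
    PLDLR: float = 100.0
    PLDLRD: float = 0.0
    PFC: float = 57516.0
    PCE: float = 9363.0
    PSS: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SPECIES_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "StateVector":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(SPECIES_NAMES),):
            raise ValueError(f"expected {len(SPECIES_NAMES)} species, got shape {y.shape}")
        return cls(**dict(zip(SPECIES_NAMES, y.tolist())))

    @classmethod
    def default(cls) -> "StateVector":
        return cls(**_DEFAULT_STATE)

    def replace(self, **kwargs: float) -> "StateVector":
        return replace(self, **kwargs)

    def asdict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in SPECIES_NAMES}


@dataclass
class BoundarySet:
    """Fixed species: dietary cholesterol plus seven enzyme/receptor activities.

    Activities are dimensionless multipliers with 100 = normal; DC is mg/day of
    dietary cholesterol entering the intake compartment.  Constant during
    integration unless a Schedule overrides one of them.
    """

    DC: float = 304.0
    ACAT: float = 100.0
    CEH: float = 100.0
    LPL: float = 100.0
    HSL: float = 100.0
    LCAT: float = 100.0
    CETP: float = 100.0
    SRB1: float = 100.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in BOUNDARY_NAMES], dtype=float)

    @classmethod
    def from_array(cls, b: Sequence[float]) -> "BoundarySet":
        return cls(**dict(zip(BOUNDARY_NAMES, np.asarray(b, dtype=float).tolist())))

    def replace(self, **kwargs: float) -> "BoundarySet":
        return replace(self, **kwargs)

    def asdict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in BOUNDARY_NAMES}


@dataclass
class ParameterSet:
    """Rate constants k1..k29, receptor-synthesis rates, and Hill-law constants.

    ``provenance`` tags every parameter as printed (source table), calibrated
    (adjusted to hit steady-state targets) or user (explicit override).
    ``printed_values`` records source-table values that the defaults override.
    """

    k1: float = _DEFAULT_PARAMS["k1"]
    k2: float = _DEFAULT_PARAMS["k2"]
    k3: float = _DEFAULT_PARAMS["k3"]
    k4: float = _DEFAULT_PARAMS["k4"]
    k5: float = _DEFAULT_PARAMS["k5"]
    k6: float = _DEFAULT_PARAMS["k6"]
    k7: float = _DEFAULT_PARAMS["k7"]
    k8: float = _DEFAULT_PARAMS["k8"]
    k9: float = _DEFAULT_PARAMS["k9"]
    k10: float = _DEFAULT_PARAMS["k10"]
    k11: float = _DEFAULT_PARAMS["k11"]
    k12: float = _DEFAULT_PARAMS["k12"]
    k13: float = _DEFAULT_PARAMS["k13"]
    k14: float = _DEFAULT_PARAMS["k14"]
    k15: float = _DEFAULT_PARAMS["k15"]
    k16: float = _DEFAULT_PARAMS["k16"]
    k17: float = _DEFAULT_PARAMS["k17"]
    k18: float = _DEFAULT_PARAMS["k18"]
    k19: float = _DEFAULT_PARAMS["k19"]
    k20: float = _DEFAULT_PARAMS["k20"]
    k21: float = _DEFAULT_PARAMS["k21"]
    k22: float = _DEFAULT_PARAMS["k22"]
    k23: float = _DEFAULT_PARAMS["k23"]
    k24: float = _DEFAULT_PARAMS["k24"]
    k25: float = _DEFAULT_PARAMS["k25"]
    k26: float = _DEFAULT_PARAMS["k26"]
    k27: float = _DEFAULT_PARAMS["k27"]
    k28: float = _DEFAULT_PARAMS["k28"]
    k29: float = _DEFAULT_PARAMS["k29"]
    khrs: float = _DEFAULT_PARAMS["khrs"]
    kprs: float = _DEFAULT_PARAMS["kprs"]
    HRS: float = _DEFAULT_PARAMS["HRS"]
    PRS: float = _DEFAULT_PARAMS["PRS"]
    ICSmax: float = _DEFAULT_PARAMS["ICSmax"]
    ICt: float = _DEFAULT_PARAMS["ICt"]
    IS: float = _DEFAULT_PARAMS["IS"]
    BCRmax: float = _DEFAULT_PARAMS["BCRmax"]
    BCRt: float = _DEFAULT_PARAMS["BCRt"]
    BS: float = _DEFAULT_PARAMS["BS"]
    HCSmax: float = _DEFAULT_PARAMS["HCSmax"]
    HCSt: float = _DEFAULT_PARAMS["HCSt"]
    HS: float = _DEFAULT_PARAMS["HS"]
    PCSmax: float = _DEFAULT_PARAMS["PCSmax"]
    PPCt: float = _DEFAULT_PARAMS["PPCt"]
    PCSS: float = _DEFAULT_PARAMS["PCSS"]
    provenance: dict[str, str] = field(default_factory=dict, compare=False)
    printed_values: dict[str, float] = field(
        default_factory=lambda: dict(PRINTED_VALUES), compare=False
    )

    def __post_init__(self) -> None:
        for name in _RATE_CONSTANTS:
            if getattr(self, name) < 0:
                raise DomainError(f"rate constant {name} must be >= 0")
        for name in ("ICSmax", "BCRmax", "HCSmax", "PCSmax", "HRS", "PRS"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        for name in ("IS", "BS", "HS", "PCSS"):
            if getattr(self, name) < 1:
                raise DomainError(f"Hill exponent {name} must be >= 1")
        for name in ("ICt", "BCRt", "HCSt", "PPCt"):
            if getattr(self, name) <= 0:
                raise DomainError(f"threshold {name} must be > 0")
        if not self.provenance:
            self.provenance = {n: "printed" for n in PARAMETER_NAMES}

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES], dtype=float)

    @classmethod
    def from_array(
        cls, k: Sequence[float], provenance: Mapping[str, str] | None = None
    ) -> "ParameterSet":
        values = dict(zip(PARAMETER_NAMES, np.asarray(k, dtype=float).tolist()))
        ps = cls(**values)
        if provenance is not None:
            ps.provenance = dict(provenance)
        return ps

    @classmethod
    def default(cls) -> "ParameterSet":
        return cls()

    def replace(self, _provenance: str = "user", **kwargs: float) -> "ParameterSet":
        """Return a copy with ``kwargs`` overridden and retagged."""
        new = replace(self, **kwargs)
        new.provenance = dict(self.provenance)
        for name in kwargs:
            new.provenance[name] = _provenance
        new.printed_values = dict(self.printed_values)
        return new

    def asdict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAMETER_NAMES}


@dataclass(frozen=True)
class ModelOptions:
    """Mode flags resolving ambiguities in the printed equation set.

    strict_paper_cetp
        If True, the CETP transfer fluxes k27*CETP*HDLC and k28*CETP*HDLC
        remove cholesterol from HDL without crediting VLDL/LDL, exactly as
        printed.  The default (False) adds the matching gain terms so CETP
        transfer conserves plasma cholesterol.
    bilinear_bile_return
        If True, hepatic bile-salt return is k3*IBS*IC as the printed strings
        suggest; the default k3*IBS is the only reading that balances the
        documented enterohepatic fluxes (~2400 release, ~2000 return,
        ~400 excretion mg/day).
    """

    strict_paper_cetp: bool = False
    bilinear_bile_return: bool = False


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------


def intestinal_synthesis_rate(IC: float, p: ParameterSet) -> float:
    """Intestinal cholesterol synthesis, mg/day.

    Hill-type negative feedback of the intestinal pool on its own synthesis:
    ICSmax / (1 + (IC/ICt)**IS).  Strictly decreasing in IC, bounded in
    (0, ICSmax].
    """
    if IC < 0:
        raise DomainError("IC must be >= 0")
    return p.ICSmax / (1.0 + (IC / p.ICt) ** p.IS)


def hepatic_synthesis_rate(HFC: float, p: ParameterSet) -> float:
    """Hepatic cholesterol synthesis, mg/day: HCSmax / (1 + (HFC/HCSt)**HS)."""
    if HFC < 0:
        raise DomainError("HFC must be >= 0")
    return p.HCSmax / (1.0 + (HFC / p.HCSt) ** p.HS)


def peripheral_synthesis_rate(PFC: float, p: ParameterSet) -> float:
    """Peripheral cholesterol synthesis, mg/day: PCSmax / (1 + (PFC/PPCt)**PCSS)."""
    if PFC < 0:
        raise DomainError("PFC must be >= 0")
    return p.PCSmax / (1.0 + (PFC / p.PPCt) ** p.PCSS)


def biliary_release_rate(HFC: float, p: ParameterSet) -> float:
    """Biliary cholesterol release, mg/day (feed-forward in the hepatic pool).

    BCRmax / (1 + (BCRt/HFC)**BS): strictly increasing in HFC, saturating at
    BCRmax, half-maximal at HFC = BCRt.  The HFC -> 0 limit (zero release) is
    returned at HFC = 0.
    """
    if HFC < 0:
        raise DomainError("HFC must be >= 0")
    if HFC == 0.0:
        return 0.0
    return p.BCRmax / (1.0 + (p.BCRt / HFC) ** p.BS)


def bile_salt_synthesis_rate(HFC: float, HBS: float, p: ParameterSet) -> float:
    """Hepatic bile-salt production, mg/day: k5 * HFC / HBS.

    Reciprocal inhibition by the hepatic bile-salt pool -- production halves
    when HBS doubles at fixed HFC.
    """
    if HFC < 0:
        raise DomainError("HFC must be >= 0")
    if HBS <= 0:
        raise DomainError("HBS must be > 0 (singular denominator)")
    return p.k5 * HFC / HBS


def hldlr_synthesis_rate(HFC: float, p: ParameterSet) -> float:
    """Hepatic LDL-receptor synthesis, receptor units/day: khrs * HRS / HFC.

    Receptor production is reciprocally inhibited by hepatic free cholesterol:
    a constant source HRS divided by the free-cholesterol pool.  At steady
    state the receptor count is khrs*HRS/(k13*HFC), so receptor expression
    falls as the hepatic pool grows -- the classical down-regulation of LDL
    receptors by intracellular cholesterol.
    """
    if HFC <= 0:
        raise DomainError("HFC must be > 0 (singular denominator)")
    return p.khrs * p.HRS / HFC


def pldlr_synthesis_rate(PFC: float, p: ParameterSet) -> float:
    """Peripheral LDL-receptor synthesis: kprs * PRS / PFC (mirrors hepatic)."""
    if PFC <= 0:
        raise DomainError("PFC must be > 0 (singular denominator)")
    return p.kprs * p.PRS / PFC


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

# Fast array core.  Index constants mirror SPECIES_NAMES / BOUNDARY_NAMES /
# PARAMETER_NAMES ordering; the friendly rhs() wrapper below validates and
# converts.  Kept free of Python containers so numba can compile it.

(_iIC, _iIBS, _iEC, _iEBS, _iHBS, _iHFC, _iHCE, _iHLDLR, _iHLDLRD, _iVLDLC,
 _iIDLC, _iLDLC, _iHDLC, _iNHDL, _iPLDLR, _iPLDLRD, _iPFC, _iPCE, _iPSS) = range(19)

(_bDC, _bACAT, _bCEH, _bLPL, _bHSL, _bLCAT, _bCETP, _bSRB1) = range(8)


def _rhs_core(y, b, k, strict_cetp, bilinear_bile):
    (k1, k2, k3, k4, k5, k6, k7, k8, k9, k10, k11, k12, k13, k14, k15, k16,
     k17, k18, k19, k20, k21, k22, k23, k24, k25, k26, k27, k28, k29,
     khrs, kprs, HRS, PRS, ICSmax, ICt, IS, BCRmax, BCRt, BS,
     HCSmax, HCSt, HS, PCSmax, PPCt, PCSS) = (
        k[0], k[1], k[2], k[3], k[4], k[5], k[6], k[7], k[8], k[9], k[10],
        k[11], k[12], k[13], k[14], k[15], k[16], k[17], k[18], k[19], k[20],
        k[21], k[22], k[23], k[24], k[25], k[26], k[27], k[28], k[29], k[30],
        k[31], k[32], k[33], k[34], k[35], k[36], k[37], k[38], k[39], k[40],
        k[41], k[42], k[43], k[44])

    IC = y[_iIC]; IBS = y[_iIBS]; HBS = y[_iHBS]; HFC = y[_iHFC]
    HCE = y[_iHCE]; HLDLR = y[_iHLDLR]; VLDLC = y[_iVLDLC]; IDLC = y[_iIDLC]
    LDLC = y[_iLDLC]; HDLC = y[_iHDLC]; NHDL = y[_iNHDL]; PLDLR = y[_iPLDLR]
    PFC = y[_iPFC]; PCE = y[_iPCE]

    DC = b[_bDC]; ACAT = b[_bACAT]; CEH = b[_bCEH]; LPL = b[_bLPL]
    HSL = b[_bHSL]; LCAT = b[_bLCAT]; CETP = b[_bCETP]; SRB1 = b[_bSRB1]

    ics = ICSmax / (1.0 + (IC / ICt) ** IS)
    hcs = HCSmax / (1.0 + (HFC / HCSt) ** HS)
    pcs = PCSmax / (1.0 + (PFC / PPCt) ** PCSS)
    bcr = BCRmax / (1.0 + (BCRt / HFC) ** BS)
    bile_syn = k5 * HFC / HBS
    bile_ret = k3 * IBS * IC if bilinear_bile else k3 * IBS

    absorb = k6 * IBS * IC
    excrete = k7 * IBS * IC
    hest = k9 * ACAT * HFC
    hhyd = k10 * HCE * CEH
    pest = k23 * ACAT * PFC
    phyd = k24 * PCE * CEH
    vsec = k12 * HFC
    vup = k14 * HLDLR * VLDLC
    lipo = k15 * LPL * VLDLC
    iup = k16 * HLDLR * IDLC
    iconv = k17 * HSL * IDLC
    lup_h = k18 * LDLC * HLDLR
    lup_hi = k19 * LDLC
    lup_p = k20 * LDLC * PLDLR
    scav = k26 * LCAT * NHDL * PFC
    cetp_v = k27 * CETP * HDLC
    cetp_l = k28 * CETP * HDLC
    srb1 = k29 * HDLC * SRB1
    hrs = khrs * HRS / HFC
    prs = kprs * PRS / PFC

    dy = np.zeros(19)
    dy[_iIC] = k1 * DC + bcr + ics - absorb - excrete
    dy[_iIBS] = k2 * HBS - bile_ret - k4 * IBS
    dy[_iEC] = excrete
    dy[_iEBS] = k4 * IBS
    dy[_iHBS] = bile_syn + bile_ret - k2 * HBS
    dy[_iHFC] = (lup_hi + hhyd - bcr + hcs + absorb + iup + lup_h + srb1 + vup
                 - vsec - bile_syn - hest)
    dy[_iHCE] = hest - hhyd
    dy[_iHLDLR] = hrs - k13 * HLDLR
    dy[_iHLDLRD] = k13 * HLDLR
    dy[_iVLDLC] = vsec - vup - lipo
    dy[_iIDLC] = lipo - iup - iconv
    dy[_iLDLC] = iconv - lup_h - lup_hi - lup_p - k21
    dy[_iHDLC] = scav - cetp_v - cetp_l - srb1
    dy[_iNHDL] = k8 + k11
    dy[_iPLDLR] = prs - k22 * PLDLR
    dy[_iPLDLRD] = k22 * PLDLR
    dy[_iPFC] = k21 - k25 + phyd - scav - pest + pcs + lup_p
    dy[_iPCE] = pest - phyd
    dy[_iPSS] = k25
    if not strict_cetp:
        dy[_iVLDLC] += cetp_v
        dy[_iLDLC] += cetp_l
    return dy


try:  # optional JIT; the pure-Python core is the reference either way
    from numba import njit as _njit

    _rhs_fast = _njit(cache=False)(_rhs_core)
except Exception:  # pragma: no cover - numba always present in target env
    _rhs_fast = _rhs_core


def rhs_array(
    y: np.ndarray,
    b: np.ndarray,
    k: np.ndarray,
    options: ModelOptions = ModelOptions(),
) -> np.ndarray:
    """Array-level right-hand side (no validation); see rhs() for the checked API."""
    return _rhs_fast(y, b, k, options.strict_paper_cetp, options.bilinear_bile_return)


def rhs(
    t: float,
    s: StateVector,
    p: ParameterSet,
    b: BoundarySet,
    options: ModelOptions = ModelOptions(),
) -> StateVector:
    """Time derivative of every species, as a StateVector (units per day).

    ``t`` is accepted for signature compatibility with time-varying protocols;
    the autonomous system does not depend on it.  Raises DomainError naming the
    species if a singular denominator (HBS, HFC or PFC at zero) is hit.
    """
    del t
    for name in SINGULAR_DENOMINATORS:
        if getattr(s, name) <= 0:
            raise DomainError(
                f"{name} = {getattr(s, name)} is non-positive: rate laws divide by it"
            )
    dy = rhs_array(s.to_array(), b.to_array(), p.to_array(), options)
    return StateVector.from_array(dy)


# ---------------------------------------------------------------------------
# Reaction table (drives SBML export, flux audits and the config round trip)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One elementary flux: a rate-law expression plus its stoichiometry.

    ``rate`` is a plain arithmetic expression over species, boundary and
    parameter identifiers (Python/sympy syntax).  ``stoich`` maps species name
    to the signed stoichiometric coefficient the flux contributes.
    """

    id: str
    name: str
    rate: str
    stoich: Mapping[str, float]


REACTIONS: tuple[Reaction, ...] = (
    Reaction("R01_intake", "Cholesterol intake", "k1*DC", {"IC": +1}),
    Reaction("R02_biliary_release", "Biliary cholesterol release",
             "BCRmax/(1 + (BCRt/HFC)**BS)", {"HFC": -1, "IC": +1}),
    Reaction("R03_intestinal_synthesis", "Intestinal cholesterol synthesis",
             "ICSmax/(1 + (IC/ICt)**IS)", {"IC": +1}),
    Reaction("R04_absorption", "Cholesterol absorption",
             "k6*IBS*IC", {"IC": -1, "HFC": +1}),
    Reaction("R05_excretion", "Cholesterol excretion",
             "k7*IBS*IC", {"IC": -1, "EC": +1}),
    Reaction("R06_bile_release", "Bile-salt release", "k2*HBS",
             {"HBS": -1, "IBS": +1}),
    Reaction("R07_bile_return", "Hepatic return of bile salts", "k3*IBS",
             {"IBS": -1, "HBS": +1}),
    Reaction("R08_bile_excretion", "Bile-salt excretion", "k4*IBS",
             {"IBS": -1, "EBS": +1}),
    Reaction("R09_bile_synthesis", "Bile-salt synthesis", "k5*HFC/HBS",
             {"HFC": -1, "HBS": +1}),
    Reaction("R10_hepatic_synthesis", "Hepatic cholesterol synthesis",
             "HCSmax/(1 + (HFC/HCSt)**HS)", {"HFC": +1}),
    Reaction("R11_hepatic_esterification", "Hepatic cholesterol storage",
             "k9*ACAT*HFC", {"HFC": -1, "HCE": +1}),
    Reaction("R12_hepatic_hydrolysis", "Release of stored hepatic cholesterol",
             "k10*HCE*CEH", {"HCE": -1, "HFC": +1}),
    Reaction("R13_vldl_secretion", "VLDL-cholesterol formation", "k12*HFC",
             {"HFC": -1, "VLDLC": +1}),
    Reaction("R14_vldl_uptake", "VLDL-cholesterol hepatic reuptake",
             "k14*HLDLR*VLDLC", {"VLDLC": -1, "HFC": +1}),
    Reaction("R15_lipolysis", "IDL-cholesterol formation", "k15*LPL*VLDLC",
             {"VLDLC": -1, "IDLC": +1}),
    Reaction("R16_idl_uptake", "IDL-cholesterol hepatic reuptake",
             "k16*HLDLR*IDLC", {"IDLC": -1, "HFC": +1}),
    Reaction("R17_ldl_formation", "LDL-cholesterol formation", "k17*HSL*IDLC",
             {"IDLC": -1, "LDLC": +1}),
    Reaction("R18_ldl_hepatic_uptake", "Hepatic receptor uptake of LDL-C",
             "k18*LDLC*HLDLR", {"LDLC": -1, "HFC": +1}),
    Reaction("R19_ldl_hepatic_independent",
             "Hepatic receptor-independent uptake of LDL-C", "k19*LDLC",
             {"LDLC": -1, "HFC": +1}),
    Reaction("R20_ldl_peripheral_uptake", "Peripheral receptor uptake of LDL-C",
             "k20*LDLC*PLDLR", {"LDLC": -1, "PFC": +1}),
    Reaction("R21_ldl_peripheral_independent",
             "Peripheral receptor-independent uptake of LDL-C", "k21",
             {"LDLC": -1, "PFC": +1}),
    Reaction("R22_hldlr_synthesis", "Synthesis of hepatic LDL receptors",
             "khrs*HRS/HFC", {"HLDLR": +1}),
    Reaction("R23_hldlr_degradation", "Hepatic LDL-receptor degradation",
             "k13*HLDLR", {"HLDLR": -1, "HLDLRD": +1}),
    Reaction("R24_pldlr_synthesis", "Synthesis of peripheral LDL receptors",
             "kprs*PRS/PFC", {"PLDLR": +1}),
    Reaction("R25_pldlr_degradation", "Peripheral LDL-receptor degradation",
             "k22*PLDLR", {"PLDLR": -1, "PLDLRD": +1}),
    Reaction("R26_peripheral_synthesis", "Peripheral cholesterol synthesis",
             "PCSmax/(1 + (PFC/PPCt)**PCSS)", {"PFC": +1}),
    Reaction("R27_peripheral_esterification", "Peripheral cholesterol storage",
             "k23*ACAT*PFC", {"PFC": -1, "PCE": +1}),
    Reaction("R28_peripheral_hydrolysis", "Release of stored peripheral cholesterol",
             "k24*PCE*CEH", {"PCE": -1, "PFC": +1}),
    Reaction("R29_steroidogenesis", "Peripheral steroid production", "k25",
             {"PFC": -1, "PSS": +1}),
    Reaction("R30_nhdl_intestinal", "Intestinal nascent-HDL synthesis", "k8",
             {"NHDL": +1}),
    Reaction("R31_nhdl_hepatic", "Hepatic nascent-HDL synthesis", "k11",
             {"NHDL": +1}),
    Reaction("R32_hdl_scavenging", "HDL-cholesterol formation",
             "k26*LCAT*NHDL*PFC", {"PFC": -1, "HDLC": +1}),
    Reaction("R33_cetp_to_vldl", "CETP transfer of cholesterol HDL to VLDL",
             "k27*CETP*HDLC", {"HDLC": -1, "VLDLC": +1}),
    Reaction("R34_cetp_to_ldl", "CETP transfer of cholesterol HDL to LDL",
             "k28*CETP*HDLC", {"HDLC": -1, "LDLC": +1}),
    Reaction("R35_srb1_uptake", "Reverse cholesterol transport (SR-BI)",
             "k29*HDLC*SRB1", {"HDLC": -1, "HFC": +1}),
)


def reactions_for(options: ModelOptions = ModelOptions()) -> tuple[Reaction, ...]:
    """The reaction table with the mode flags applied.

    In strict-paper CETP mode the two CETP transfers drain HDL-C without
    crediting VLDL/LDL; with bilinear bile return R07's rate is k3*IBS*IC.
    """
    out = []
    for r in REACTIONS:
        if options.strict_paper_cetp and r.id == "R33_cetp_to_vldl":
            r = Reaction(r.id, r.name, r.rate, {"HDLC": -1})
        elif options.strict_paper_cetp and r.id == "R34_cetp_to_ldl":
            r = Reaction(r.id, r.name, r.rate, {"HDLC": -1})
        elif options.bilinear_bile_return and r.id == "R07_bile_return":
            r = Reaction(r.id, r.name, "k3*IBS*IC", r.stoich)
        out.append(r)
    return tuple(out)


def reaction_rates(
    s: StateVector, p: ParameterSet, b: BoundarySet,
    options: ModelOptions = ModelOptions(),
) -> dict[str, float]:
    """Evaluate every reaction's rate (mg/day or mg/dL/day) at a state."""
    env: dict[str, float] = {}
    env.update(s.asdict())
    env.update(b.asdict())
    env.update(p.asdict())
    rates = {}
    for r in reactions_for(options):
        rates[r.id] = float(eval(r.rate, {"__builtins__": {}}, env))  # noqa: S307
    return rates


def absorption_fraction(p: ParameterSet) -> float:
    """Fraction of intestinal cholesterol absorbed rather than excreted: k6/(k6+k7)."""
    return p.k6 / (p.k6 + p.k7)


# ---------------------------------------------------------------------------
# Facade
# ---------------------------------------------------------------------------


@dataclass
class Model:
    """Bundle of parameters, boundaries, initial state and mode flags.

    The lightweight object every simulation- and scenario-level function
    accepts.  ``Model.default()`` is the printed parameterisation;
    ``Model.calibrated()`` runs the plasma-species calibration (deterministic)
    and caches the result for the process.
    """

    params: ParameterSet = field(default_factory=ParameterSet.default)
    boundaries: BoundarySet = field(default_factory=BoundarySet)
    state: StateVector = field(default_factory=StateVector.default)
    options: ModelOptions = field(default_factory=ModelOptions)

    @classmethod
    def default(cls, **option_kwargs: bool) -> "Model":
        return cls(options=ModelOptions(**option_kwargs))

    @classmethod
    def calibrated(cls, **option_kwargs: bool) -> "Model":
        from .simulate import calibrated_baseline

        return calibrated_baseline(cls.default(**option_kwargs))

    def replace(self, **kwargs) -> "Model":
        return replace(self, **kwargs)

    def rhs(self, s: StateVector | None = None) -> StateVector:
        return rhs(0.0, s if s is not None else self.state,
                   self.params, self.boundaries, self.options)

    # Convenience delegates (implemented in cholsim.simulate)
    def integrate(self, t_span, **kwargs):
        from .simulate import integrate

        return integrate(self.params, self.boundaries, self.state, t_span,
                         options=self.options, **kwargs)

    def steady_state(self, **kwargs):
        from .simulate import steady_state

        return steady_state(self.params, self.boundaries, self.state,
                            options=self.options, **kwargs)
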
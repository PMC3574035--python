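"""Parameter-derivation worksheets.

The model's steady-state pool sizes and fluxes are not free fits: each one is
derived from a handful of physiological inputs (body mass, tissue cholesterol
densities, synthesis rates per kg, absorption efficiency).  This module
reproduces those worksheets as small pure functions so every derived number is
testable, and exposes the absorption-fraction <-> rate-constant mapping used
by the sensitivity and ageing protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import DomainError

__all__ = [
    "SynthesisPartition",
    "FluxAudit",
    "synthesis_partition",
    "intestinal_pool",
    "hepatic_pool",
    "peripheral_pool",
    "intestinal_flux_audit",
    "absorption_fraction_to_k6",
    "k6_to_absorption_fraction",
    "worksheet_tables",
]

CHOLESTEROL_MW = 386.66  # g/mol


@dataclass(frozen=True)
class SynthesisPartition:
    """Whole-body cholesterol synthesis split across compartments, mg/day."""

    whole_body: float
    peripheral_excl_intestine: float
    intestine: float
    liver: float

    def __post_init__(self) -> None:
        parts = (self.whole_body, self.peripheral_excl_intestine,
                 self.intestine, self.liver)
        if any(v < 0 for v in parts):
            raise DomainError("synthesis rates must be >= 0")
        total = self.peripheral_excl_intestine + self.intestine + self.liver
        if abs(total - self.whole_body) > 1e-9 * max(1.0, self.whole_body):
            raise DomainError("partition does not sum to whole-body synthesis")


@dataclass(frozen=True)
class FluxAudit:
    """Daily cholesterol flux through the small intestine, mg/day."""

    diet: float
    biliary: float
    intestinal_synthesis: float
    total: float
    absorbed: float
    excreted: float

    def __post_init__(self) -> None:
        if abs(self.total - (self.diet + self.biliary + self.intestinal_synthesis)) \
                > 1e-9 * max(1.0, self.total):
            raise DomainError("total flux does not equal the sum of its inputs")
        if abs(self.absorbed + self.excreted - self.total) \
                > 1e-9 * max(1.0, self.total):
            raise DomainError("absorbed + excreted must equal total")


def synthesis_partition(
    mg_per_kg: float,
    body_mass: float,
    peripheral_fraction: float,
    intestinal_fraction_of_peripheral: float,
) -> SynthesisPartition:
    """Partition whole-body synthesis into liver, intestine and other periphery.

    Whole-body synthesis is mg_per_kg * body_mass; a fraction of it is
    peripheral (default physiology ~70%), and a fraction of the peripheral
    share is intestinal (~10%).  The liver gets the remainder.
    """
    if body_mass < 0:
        raise DomainError("body mass must be >= 0")
    for frac in (peripheral_fraction, intestinal_fraction_of_peripheral):
        if not 0.0 <= frac <= 1.0:
            raise DomainError("fractions must lie in [0, 1]")
    whole = mg_per_kg * body_mass
    peripheral_total = peripheral_fraction * whole
    intestine = intestinal_fraction_of_peripheral * peripheral_total
    return SynthesisPartition(
        whole_body=whole,
        peripheral_excl_intestine=peripheral_total - intestine,
        intestine=intestine,
        liver=whole - peripheral_total,
    )


def intestinal_pool(
    body_mass: float, intestine_g_per_kg: float, chol_mg_per_100g: float
) -> float:
    """Steady-state intestinal cholesterol pool, mg.

    body_mass [kg] * intestine_g_per_kg [g/kg] gives the intestinal tissue
    mass; at chol_mg_per_100g of cholesterol per 100 g of tissue the pool is
    mass/100 * density.  Mammalian tissue density is 100-200 mg/100 g.
    """
    if body_mass <= 0 or intestine_g_per_kg <= 0 or chol_mg_per_100g <= 0:
        raise DomainError("all inputs must be > 0")
    return body_mass * intestine_g_per_kg / 100.0 * chol_mg_per_100g


def hepatic_pool(
    total_nmol_per_mg: float,
    ester_nmol_per_mg: float,
    mw: float = CHOLESTEROL_MW,
    liver_mass: float = 1.5e6,
) -> dict[str, float]:
    """Hepatic cholesterol pools, mg, from tissue concentrations.

    nmol of cholesterol per mg of liver tissue converts to mg/mg via the
    molecular weight (1 nmol = mw * 1e-6 mg) and scales by the liver mass
    (default 1.5 kg = 1.5e6 mg).  Returns total, esterified and free pools.
    """
    if total_nmol_per_mg <= 0 or ester_nmol_per_mg < 0 or mw <= 0 or liver_mass <= 0:
        raise DomainError("inputs must be positive (ester may be zero)")
    if ester_nmol_per_mg > total_nmol_per_mg:
        raise DomainError("esterified cholesterol cannot exceed total")
    total = total_nmol_per_mg * mw * 1e-6 * liver_mass
    esters = ester_nmol_per_mg * mw * 1e-6 * liver_mass
    return {"total": total, "esters": esters, "free": total - esters}


def peripheral_pool(
    whole_body_chol: float,
    liver_chol: float,
    intestine_chol: float,
    stored_fraction: float,
) -> dict[str, float]:
    """Peripheral cholesterol pools, mg: whole body minus liver and intestine.

    A fraction of the remaining peripheral cholesterol (the same ~14% share
    observed hepatically) is stored as esters; the rest is the free pool.
    """
    if liver_chol + intestine_chol > whole_body_chol:
        raise DomainError("liver + intestine cannot exceed whole-body cholesterol")
    if not 0.0 <= stored_fraction <= 1.0:
        raise DomainError("stored fraction must lie in [0, 1]")
    remaining = whole_body_chol - liver_chol - intestine_chol
    stored = stored_fraction * remaining
    return {"remaining": remaining, "stored": stored, "free": remaining - stored}


def intestinal_flux_audit(
    diet: float, biliary: float, synthesis: float, absorbed_fraction: float
) -> FluxAudit:
    """Daily intestinal cholesterol balance: inputs, absorbed and excreted shares."""
    if not 0.0 <= absorbed_fraction <= 1.0:
        raise DomainError("absorbed fraction must lie in [0, 1]")
    total = diet + biliary + synthesis
    absorbed = absorbed_fraction * total
    return FluxAudit(
        diet=diet, biliary=biliary, intestinal_synthesis=synthesis,
        total=total, absorbed=absorbed, excreted=total - absorbed,
    )


def absorption_fraction_to_k6(fraction: float, k7: float) -> float:
    """Absorption rate constant giving a target absorption fraction at fixed k7.

    Absorption and excretion compete for the same intestinal pool with rates
    k6*IBS*IC and k7*IBS*IC, so the absorbed fraction is k6/(k6+k7)
    independent of the pool sizes.  Inverting: k6 = k7 * f / (1 - f).
    """
    if not 0.0 < fraction < 1.0:
        raise DomainError("fraction must lie strictly in (0, 1)")
    if k7 <= 0:
        raise DomainError("k7 must be > 0")
    return k7 * fraction / (1.0 - fraction)


def k6_to_absorption_fraction(k6: float, k7: float) -> float:
    """Inverse of absorption_fraction_to_k6: f = k6/(k6+k7)."""
    if k6 < 0 or k7 <= 0:
        raise DomainError("require k6 >= 0 and k7 > 0")
    return k6 / (k6 + k7)


# ---------------------------------------------------------------------------
# Worksheet emission (CLI `cholsim derive`)
# ---------------------------------------------------------------------------


def worksheet_tables() -> dict[str, pd.DataFrame]:
    """All derivation worksheets at their default physiological inputs.

    Returns tidy DataFrames keyed by worksheet name, each with a provenance
    column distinguishing inputs from derived values.  These are the numbers
    the default ParameterSet and StateVector are built from.
    """
    tables: dict[str, pd.DataFrame] = {}

    part = synthesis_partition(10.0, 70.0, 0.7, 0.1)
    tables["synthesis_partition"] = pd.DataFrame(
        [
            ("whole_body", part.whole_body, "mg/day", "derived"),
            ("peripheral_excl_intestine", part.peripheral_excl_intestine,
             "mg/day", "derived"),
            ("intestine", part.intestine, "mg/day", "derived"),
            ("liver", part.liver, "mg/day", "derived"),
        ],
        columns=["quantity", "value", "unit", "provenance"],
    )

    pool = intestinal_pool(70.0, 30.0, 150.0)
    tables["intestinal_pool"] = pd.DataFrame(
        [
            ("body_mass", 70.0, "kg", "input"),
            ("intestine_per_kg", 30.0, "g/kg", "input"),
            ("cholesterol_density", 150.0, "mg/100g", "input"),
            ("intestinal_cholesterol", pool, "mg", "derived"),
        ],
        columns=["quantity", "value", "unit", "provenance"],
    )

    audit = intestinal_flux_audit(304.0, 1200.0, 49.0, 0.5)
    tables["intestinal_flux_audit"] = pd.DataFrame(
        [
            ("diet", audit.diet, "mg/day", "input"),
            ("biliary", audit.biliary, "mg/day", "input"),
            ("intestinal_synthesis", audit.intestinal_synthesis, "mg/day", "input"),
            ("total", audit.total, "mg/day", "derived"),
            ("absorbed", audit.absorbed, "mg/day", "derived"),
            ("excreted", audit.excreted, "mg/day", "derived"),
        ],
        columns=["quantity", "value", "unit", "provenance"],
    )

    hep = hepatic_pool(115.6, 18.5)
    tables["hepatic_pool"] = pd.DataFrame(
        [
            ("total_concentration", 115.6, "nmol/mg", "input"),
            ("ester_concentration", 18.5, "nmol/mg", "input"),
            ("molecular_weight", CHOLESTEROL_MW, "g/mol", "input"),
            ("liver_mass", 1.5e6, "mg", "input"),
            ("total", hep["total"], "mg", "derived"),
            ("esters", hep["esters"], "mg", "derived"),
            ("free", hep["free"], "mg", "derived"),
        ],
        columns=["quantity", "value", "unit", "provenance"],
    )

    per = peripheral_pool(140000.0, 70000.0, 3120.0, 0.14)
    tables["peripheral_pool"] = pd.DataFrame(
        [
            ("whole_body", 140000.0, "mg", "input"),
            ("liver", 70000.0, "mg", "input"),
            ("intestine", 3120.0, "mg", "input"),
            ("stored_fraction", 0.14, "dimensionless", "input"),
            ("remaining", per["remaining"], "mg", "derived"),
            ("stored", per["stored"], "mg", "derived"),
            ("free", per["free"], "mg", "derived"),
        ],
        columns=["quantity", "value", "unit", "provenance"],
    )

    return tables
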
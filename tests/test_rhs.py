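"""The full right-hand side against an independently coded flux-table oracle,
plus its structural invariants (flux pairing, ester antisymmetry, sinks)."""

import numpy as np
import pytest

from cholsim import BoundarySet, Model, ParameterSet, StateVector
from cholsim.model import (
    DomainError,
    ModelOptions,
    PARAMETER_NAMES,
    SPECIES_NAMES,
    reaction_rates,
    rhs,
    rhs_array,
)


def oracle_rhs(s: dict, b: dict, p: dict, *, strict_cetp=False,
               bilinear_bile=False) -> dict:
    """Naive per-flux oracle: every flux written out once, summed per species.

    Deliberately independent of the package's vectorised implementation and
    of its reaction table.
    """
    ics = p["ICSmax"] / (1 + (s["IC"] / p["ICt"]) ** p["IS"])
    hcs = p["HCSmax"] / (1 + (s["HFC"] / p["HCSt"]) ** p["HS"])
    pcs = p["PCSmax"] / (1 + (s["PFC"] / p["PPCt"]) ** p["PCSS"])
    bcr = p["BCRmax"] / (1 + (p["BCRt"] / s["HFC"]) ** p["BS"])
    flux = {
        "intake": p["k1"] * b["DC"],
        "biliary": bcr,
        "ics": ics,
        "absorb": p["k6"] * s["IBS"] * s["IC"],
        "excrete": p["k7"] * s["IBS"] * s["IC"],
        "bile_release": p["k2"] * s["HBS"],
        "bile_return": (p["k3"] * s["IBS"] * s["IC"] if bilinear_bile
                        else p["k3"] * s["IBS"]),
        "bile_excrete": p["k4"] * s["IBS"],
        "bile_synth": p["k5"] * s["HFC"] / s["HBS"],
        "hcs": hcs,
        "h_ester": p["k9"] * b["ACAT"] * s["HFC"],
        "h_hydro": p["k10"] * s["HCE"] * b["CEH"],
        "vldl_sec": p["k12"] * s["HFC"],
        "vldl_up": p["k14"] * s["HLDLR"] * s["VLDLC"],
        "lipolysis": p["k15"] * b["LPL"] * s["VLDLC"],
        "idl_up": p["k16"] * s["HLDLR"] * s["IDLC"],
        "ldl_form": p["k17"] * b["HSL"] * s["IDLC"],
        "ldl_h_up": p["k18"] * s["LDLC"] * s["HLDLR"],
        "ldl_h_ind": p["k19"] * s["LDLC"],
        "ldl_p_up": p["k20"] * s["LDLC"] * s["PLDLR"],
        "ldl_p_ind": p["k21"],
        "hrs": p["khrs"] * p["HRS"] / s["HFC"],
        "hdeg": p["k13"] * s["HLDLR"],
        "prs": p["kprs"] * p["PRS"] / s["PFC"],
        "pdeg": p["k22"] * s["PLDLR"],
        "pcs": pcs,
        "p_ester": p["k23"] * b["ACAT"] * s["PFC"],
        "p_hydro": p["k24"] * s["PCE"] * b["CEH"],
        "steroid": p["k25"],
        "nhdl_i": p["k8"],
        "nhdl_h": p["k11"],
        "scav": p["k26"] * b["LCAT"] * s["NHDL"] * s["PFC"],
        "cetp_v": p["k27"] * b["CETP"] * s["HDLC"],
        "cetp_l": p["k28"] * b["CETP"] * s["HDLC"],
        "srb1": p["k29"] * s["HDLC"] * b["SRB1"],
    }
    f = flux
    dy = {
        "IC": f["intake"] + f["biliary"] + f["ics"] - f["absorb"] - f["excrete"],
        "IBS": f["bile_release"] - f["bile_return"] - f["bile_excrete"],
        "EC": f["excrete"],
        "EBS": f["bile_excrete"],
        "HBS": f["bile_synth"] + f["bile_return"] - f["bile_release"],
        "HFC": (f["ldl_h_ind"] + f["h_hydro"] - f["biliary"] + f["hcs"]
                + f["absorb"] + f["idl_up"] + f["ldl_h_up"] + f["srb1"]
                + f["vldl_up"] - f["vldl_sec"] - f["bile_synth"] - f["h_ester"]),
        "HCE": f["h_ester"] - f["h_hydro"],
        "HLDLR": f["hrs"] - f["hdeg"],
        "HLDLRD": f["hdeg"],
        "VLDLC": f["vldl_sec"] - f["vldl_up"] - f["lipolysis"]
                 + (0.0 if strict_cetp else f["cetp_v"]),
        "IDLC": f["lipolysis"] - f["idl_up"] - f["ldl_form"],
        "LDLC": (f["ldl_form"] - f["ldl_h_up"] - f["ldl_h_ind"]
                 - f["ldl_p_up"] - f["ldl_p_ind"]
                 + (0.0 if strict_cetp else f["cetp_l"])),
        "HDLC": f["scav"] - f["cetp_v"] - f["cetp_l"] - f["srb1"],
        "NHDL": f["nhdl_i"] + f["nhdl_h"],
        "PLDLR": f["prs"] - f["pdeg"],
        "PLDLRD": f["pdeg"],
        "PFC": (f["ldl_p_ind"] - f["steroid"] + f["p_hydro"] - f["scav"]
                - f["p_ester"] + f["pcs"] + f["ldl_p_up"]),
        "PCE": f["p_ester"] - f["p_hydro"],
        "PSS": f["steroid"],
    }
    return dy


def random_state(rng) -> StateVector:
    base = StateVector.default().to_array()
    return StateVector.from_array(base * rng.uniform(0.2, 3.0, base.size))


@pytest.mark.parametrize("strict_cetp,bilinear", [
    (False, False), (True, False), (False, True), (True, True)])
def test_rhs_matches_flux_table_oracle(rng, strict_cetp, bilinear):
    """rhs agrees flux-by-flux with the naive oracle on 100 random states."""
    p = ParameterSet.default()
    b = BoundarySet()
    opts = ModelOptions(strict_paper_cetp=strict_cetp,
                        bilinear_bile_return=bilinear)
    pd_, bd = p.asdict(), b.asdict()
    for _ in range(100):
        s = random_state(rng)
        got = rhs(0.0, s, p, b, opts).asdict()
        want = oracle_rhs(s.asdict(), bd, pd_, strict_cetp=strict_cetp,
                          bilinear_bile=bilinear)
        for name in SPECIES_NAMES:
            assert got[name] == pytest.approx(
                want[name], rel=1e-12, abs=1e-9), name


def test_rhs_documented_initial_state():
    """Key derivative components at the documented initial state."""
    m = Model.default()
    d = m.rhs()
    # faecal cholesterol excretion flux k7*IBS*IC
    assert d.EC == pytest.approx(5.29e-4 * 467 * 3150, rel=1e-12)
    assert d.EC == pytest.approx(778.2, abs=0.05)
    # bile-salt excretion ~400 mg/day
    assert d.EBS == pytest.approx(0.856 * 467, rel=1e-12)
    assert d.EBS == pytest.approx(399.8, abs=0.05)
    # nascent HDL production is state-independent
    assert d.NHDL == pytest.approx(5e-4 + 5e-2, rel=1e-12)
    # receptor turnover balances exactly at the documented state
    assert d.HLDLR == pytest.approx(0.0, abs=1e-12)
    assert d.PLDLR == pytest.approx(0.0, abs=1e-12)


def test_zero_rates_give_zero_vector():
    zeros = {n: 0.0 for n in PARAMETER_NAMES
             if n.startswith("k") or n in ("khrs", "kprs", "HRS", "PRS")}
    zeros.update({n: 0.0 for n in ("ICSmax", "BCRmax", "HCSmax", "PCSmax")})
    p = ParameterSet.default().replace(**zeros)
    d = rhs(0.0, StateVector.default(), p, BoundarySet())
    assert all(v == 0.0 for v in d.asdict().values())


def test_flux_pairing_absorption_vs_excretion(rng):
    """Absorbed and excreted fluxes out of IC are in the exact ratio k6:k7."""
    p = ParameterSet.default().replace(k6=3.7e-4, k7=9.1e-4)
    b = BoundarySet()
    for _ in range(20):
        s = random_state(rng)
        rates = reaction_rates(s, p, b)
        assert rates["R04_absorption"] * p.k7 == pytest.approx(
            rates["R05_excretion"] * p.k6, rel=1e-12)


def test_ester_cycle_antisymmetry(rng):
    """Esterification/hydrolysis contribute with opposite signs to the free
    and ester pools: d(HCE) is exactly minus the ester-cycle part of d(HFC)."""
    p, b = ParameterSet.default(), BoundarySet()
    # switch off everything except the two ester cycles
    quiet = {n: 0.0 for n in PARAMETER_NAMES if n.startswith("k")}
    quiet.update(dict(k9=p.k9, k10=p.k10, k23=p.k23, k24=p.k24,
                      khrs=0.0, kprs=0.0, HRS=0.0, PRS=0.0,
                      ICSmax=0.0, BCRmax=0.0, HCSmax=0.0, PCSmax=0.0))
    p2 = p.replace(**quiet)
    for _ in range(20):
        s = random_state(rng)
        d = rhs(0.0, s, p2, b)
        assert d.HCE == pytest.approx(-d.HFC, rel=1e-12)
        assert d.PCE == pytest.approx(-d.PFC, rel=1e-12)


def test_strict_cetp_mode_drops_transfer_gains():
    """Strict printed equations omit the CETP gains on VLDL-C and LDL-C."""
    m = Model.default()
    d_default = m.rhs()
    d_strict = rhs(0.0, m.state, m.params, m.boundaries,
                   ModelOptions(strict_paper_cetp=True))
    cetp_v = m.params.k27 * m.boundaries.CETP * m.state.HDLC
    cetp_l = m.params.k28 * m.boundaries.CETP * m.state.HDLC
    assert d_default.VLDLC - d_strict.VLDLC == pytest.approx(cetp_v, rel=1e-12)
    assert d_default.LDLC - d_strict.LDLC == pytest.approx(cetp_l, rel=1e-12)
    assert d_default.HDLC == pytest.approx(d_strict.HDLC, rel=1e-12)


def test_singular_pool_raises_named_error():
    s = StateVector.default().replace(HBS=0.0)
    with pytest.raises(DomainError, match="HBS"):
        rhs(0.0, s, ParameterSet.default(), BoundarySet())


def test_rhs_array_matches_wrapper(rng):
    p, b = ParameterSet.default(), BoundarySet()
    s = random_state(rng)
    via_array = rhs_array(s.to_array(), b.to_array(), p.to_array())
    via_wrapper = rhs(0.0, s, p, b).to_array()
    np.testing.assert_allclose(via_array, via_wrapper, rtol=0, atol=0)
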
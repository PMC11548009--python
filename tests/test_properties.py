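"""Property-engine tests, including an independent brute-force oracle.

The oracle below recomputes every quantity with its own atomic-mass
arithmetic and plain per-term loops; it shares no code with the engine.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from famefuel.profiles import FameProfile, ProfileError
from famefuel.properties import (
    cetane_number,
    class_percents,
    cold_filter_plugging_point,
    compute_all,
    degree_of_unsaturation,
    iodine_value,
    long_chain_saturation_factor,
    oxidative_stability,
    saponification_value,
)
from famefuel.registry import FattyAcid, parse_shorthand
from famefuel.simulate import ProfileGeneratorSpec, generate_fame_profile


# --- independent oracle ----------------------------------------------------

def oracle(rows):
    """Brute-force property suite from (n, d, pct) rows."""
    def mass(n, d):
        return 12.011 * n + 1.008 * (2 * n - 2 * d) + 15.999 * 2

    sv = iv = sfa = mufa = pufa = lcsf = x = 0.0
    weights = {16: 0.1, 18: 0.5, 20: 1.0, 22: 1.5, 24: 2.0}
    for n, d, pct in rows:
        sv += 560 * pct / mass(n, d)
        iv += 254 * d * pct / mass(n, d)
        if d == 0:
            sfa += pct
            lcsf += weights.get(n, 0.0) * pct
        elif d == 1:
            mufa += pct
        else:
            pufa += pct
        if (n, d) in ((18, 2), (18, 3)):
            x += pct
    return {
        "sv": sv, "iv": iv, "sfa": sfa, "mufa": mufa, "pufa": pufa,
        "du": mufa + 2 * pufa, "lcsf": lcsf,
        "cfpp": 3.1417 * lcsf - 16.477,
        "cn": 46.3 + 5458 / sv - 0.225 * iv,
        "os": (117.9295 / x + 2.5905) if x > 0 else None,
    }


def make_profile(rows):
    pool = {}
    for n, d, pct in rows:
        pool[(n, d)] = pool.get((n, d), 0.0) + pct
    return FameProfile([(FattyAcid(n, d), pct) for (n, d), pct in pool.items()])


# --- golden worked example -------------------------------------------------

def test_published_profile_reproduces_published_properties(aqys21_profile):
    """The five-component profile reproduces the published property row."""
    props = compute_all(aqys21_profile)
    assert props.sv == pytest.approx(205.11, abs=0.05)
    assert props.iv == pytest.approx(171.65, abs=0.05)
    assert props.du == pytest.approx(134.04, abs=1e-9)
    assert props.mufa_percent == pytest.approx(13.3, abs=1e-9)
    assert props.pufa_percent == pytest.approx(60.37, abs=1e-9)
    assert props.sfa_percent == pytest.approx(26.37, abs=1e-9)
    assert round(props.lcsf, 2) == pytest.approx(2.99, abs=0.01)
    assert props.cfpp_cascade == pytest.approx(-7.08, abs=0.03)
    assert props.cn == pytest.approx(34.29, abs=0.05)
    assert props.os_hours == pytest.approx(4.54, abs=0.02)


def test_rounding_cascade_documented_difference(aqys21_profile):
    """Full-precision CFPP (-7.10) and 2-dp-cascade CFPP (-7.08) both carried."""
    props = compute_all(aqys21_profile)
    assert props.cfpp == pytest.approx(-7.099, abs=0.001)
    assert props.cfpp_cascade == pytest.approx(-7.083, abs=0.001)


# --- single-operation checks ----------------------------------------------

def test_sv_pure_linolenic():
    prof = FameProfile([(parse_shorthand("C18:3 n-3"), 100.0)])
    assert saponification_value(prof) == pytest.approx(560 * 100 / 278.43, abs=0.05)


def test_iv_pure_oleic_and_saturated_zero():
    oleic = FameProfile([(parse_shorthand("C18:1 n-9"), 100.0)])
    assert iodine_value(oleic) == pytest.approx(89.92, abs=0.05)
    sat = FameProfile([(parse_shorthand("C16:0"), 60.0),
                       (parse_shorthand("C18:0"), 40.0)])
    assert iodine_value(sat) == 0.0


def test_class_percents_definition():
    prof = FameProfile([(parse_shorthand("C18:1 n-9"), 50.0),
                        (parse_shorthand("C18:2 n-6"), 50.0)])
    assert class_percents(prof) == (0.0, 50.0, 50.0)
    pure = FameProfile([(parse_shorthand("C16:0"), 100.0)])
    assert class_percents(pure) == (100.0, 0.0, 0.0)


@pytest.mark.parametrize(("mufa", "pufa", "du"),
                         [(13.3, 60.37, 134.04), (0, 0, 0), (100, 0, 100)])
def test_degree_of_unsaturation(mufa, pufa, du):
    assert degree_of_unsaturation(mufa, pufa) == pytest.approx(du)


def test_lcsf_term_weights():
    none_heavy = FameProfile([(parse_shorthand("C14:0"), 50.0),
                              (parse_shorthand("C18:1 n-9"), 50.0)])
    assert long_chain_saturation_factor(none_heavy) == 0.0
    c24 = FameProfile([(parse_shorthand("C24:0"), 10.0)])
    assert long_chain_saturation_factor(c24) == pytest.approx(20.0)  # 2 * 10


def test_cfpp_intercept_and_published_rows():
    assert cold_filter_plugging_point(0.0) == pytest.approx(-16.477)
    # high-saturate vegetable-oil row: LCSF 11.65 -> CFPP 20.12
    assert cold_filter_plugging_point(11.65) == pytest.approx(20.12, abs=0.05)


def test_cetane_number_published_palm_row():
    assert cetane_number(194.82, 48.05) == pytest.approx(63.5, abs=0.1)
    assert cetane_number(200.0, 0.0) == pytest.approx(46.3 + 5458 / 200.0)
    with pytest.raises(ValueError):
        cetane_number(0.0, 10.0)


def test_oxidative_stability_contract():
    sat = FameProfile([(parse_shorthand("C16:0"), 100.0)])
    assert oxidative_stability(sat) is None
    prof = FameProfile([(parse_shorthand("C18:2 n-6"), 58.96475),
                        (parse_shorthand("C16:0"), 41.0)])
    assert oxidative_stability(prof) == pytest.approx(117.9295 / 58.96475 + 2.5905)


def test_gamma_linolenic_counts_toward_x():
    """OS is positional-isomer-blind: C18:3 n-6 adds to X like n-3."""
    a = FameProfile([(parse_shorthand("C18:3 n-3"), 30.0),
                     (parse_shorthand("C16:0"), 70.0)])
    b = FameProfile([(parse_shorthand("C18:3 n-6"), 30.0),
                     (parse_shorthand("C16:0"), 70.0)])
    assert oxidative_stability(a) == oxidative_stability(b)


def test_empty_profile_rejected():
    empty = FameProfile([])
    for fn in (saponification_value, iodine_value,
               long_chain_saturation_factor, compute_all):
        with pytest.raises(ProfileError):
            fn(empty)


def test_all_saturated_compute_all():
    prof = FameProfile([(parse_shorthand("C16:0"), 100.0)])
    props = compute_all(prof)
    assert props.sv == pytest.approx(218.36, abs=0.05)
    assert props.iv == 0.0 and props.du == 0.0
    assert props.lcsf == pytest.approx(10.0)
    assert props.cfpp == pytest.approx(14.94, abs=0.01)
    assert props.os_hours is None


# --- invariants over random profiles ---------------------------------------

rows_strategy = st.lists(
    st.tuples(
        st.sampled_from([14, 16, 18, 20, 22, 24]),
        st.integers(min_value=0, max_value=4),
        st.floats(min_value=0.01, max_value=30.0, allow_nan=False),
    ),
    min_size=1,
    max_size=6,
)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(rows=rows_strategy)
def test_engine_matches_bruteforce_oracle(rows):
    rows = [(n, min(d, (n - 2) // 2), pct) for n, d, pct in rows]
    if sum(p for _, _, p in rows) > 100.5:
        return
    prof = make_profile(rows)
    props = compute_all(prof)
    exp = oracle([(fa.n_carbons, fa.n_double_bonds, pct)
                  for fa, pct in prof.components])
    assert props.sv == pytest.approx(exp["sv"], abs=1e-12)
    assert props.iv == pytest.approx(exp["iv"], abs=1e-12)
    assert props.du == pytest.approx(exp["du"], abs=1e-12)
    assert props.lcsf == pytest.approx(exp["lcsf"], abs=1e-12)
    assert props.cfpp == pytest.approx(exp["cfpp"], abs=1e-12)
    assert props.cn == pytest.approx(exp["cn"], abs=1e-12)
    if exp["os"] is None:
        assert props.os_hours is None
    else:
        assert props.os_hours == pytest.approx(exp["os"], abs=1e-12)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_algebraic_identities_on_random_compositions(seed):
    prof = generate_fame_profile(ProfileGeneratorSpec(seed=seed))
    p = compute_all(prof)
    assert abs(p.cn + 0.225 * p.iv - 5458.0 / p.sv - 46.3) < 1e-9
    assert p.du == p.mufa_percent + 2.0 * p.pufa_percent
    assert math.isclose(p.sfa_percent + p.mufa_percent + p.pufa_percent,
                        prof.total_percent, abs_tol=1e-9)


def test_monotonicity_in_composition():
    """More ≥C16 saturate never lowers LCSF/CFPP; more unsaturate never lowers IV."""
    base = [(parse_shorthand("C16:0"), 20.0), (parse_shorthand("C18:3 n-3"), 40.0)]
    prof = FameProfile(list(base))
    more_sat = FameProfile([(parse_shorthand("C16:0"), 30.0), base[1]])
    more_unsat = FameProfile([base[0], (parse_shorthand("C18:3 n-3"), 50.0)])
    assert long_chain_saturation_factor(more_sat) >= long_chain_saturation_factor(prof)
    assert compute_all(more_sat).cfpp >= compute_all(prof).cfpp
    assert iodine_value(more_unsat) >= iodine_value(prof)
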
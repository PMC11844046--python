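import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psidrift import (
    CountTableError,
    InterpretationPolicy,
    drift_matrix,
    interpret_psi,
    js_distance,
    kl_divergence,
    psi,
    psi_from_counts,
    to_proportions,
)
from psidrift.count_table import ProportionVector
from psidrift.psi import PsiDomainError

# ---------------------------------------------------------------- helpers

def pvec(shares, scale="proportion", sample="s"):
    return ProportionVector(
        variable_name="x", sample_id=sample,
        categories=tuple(f"c{i}" for i in range(len(shares))),
        shares=tuple(shares), scale=scale,
    )


positive_shares = (
    st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=20)
    .map(lambda xs: tuple(x / math.fsum(xs) for x in xs))
)


def pair_of_shares():
    return st.integers(min_value=2, max_value=20).flatmap(
        lambda k: st.tuples(
            st.lists(st.floats(1e-6, 1.0), min_size=k, max_size=k),
            st.lists(st.floats(1e-6, 1.0), min_size=k, max_size=k),
        )
    ).map(lambda ab: (
        tuple(x / math.fsum(ab[0]) for x in ab[0]),
        tuple(x / math.fsum(ab[1]) for x in ab[1]),
    ))


# ------------------------------------------------------- worked examples

def test_two_category_hand_computation():
    """0.1*ln(1.2) + (-0.1)*ln(0.8) computed by hand = 0.040546."""
    bd = psi(pvec([0.5, 0.5], sample="E"), pvec([0.6, 0.4], sample="O"),
             convention="proportion")
    assert bd.total == pytest.approx(
        0.1 * math.log(1.2) - 0.1 * math.log(0.8), abs=1e-12)
    assert bd.total == pytest.approx(0.1 * math.log(1.5), abs=1e-12)
    assert bd.total == pytest.approx(0.040546, abs=1e-6)


def test_age_2000_vs_2016_breakdown_matches_published_cells(age_by_year):
    bd = psi_from_counts(age_by_year["2000"], age_by_year["2016"],
                         convention="percent")
    assert round(bd.total, 2) == 2.96
    contrib = {r.category: r.contribution for r in bd.rows}
    for cat, printed in {"75-79": 0.83, "65-69": 0.60, "60-64": 0.49,
                         "80-84": 0.32, "40-44": 0.22, "55-59": 0.19,
                         "45-49": 0.13}.items():
        assert contrib[cat] == pytest.approx(printed, abs=5e-3)
    # sign convention of the printed table: difference = reference - scoring
    row60 = next(r for r in bd.rows if r.category == "60-64")
    assert round(row60.difference, 1) == -2.5
    assert round(row60.log_ratio, 1) == -0.2
    assert bd.band == "significant" and bd.stars == "**"


def test_self_comparison_is_exactly_zero(age_by_year):
    v = to_proportions(age_by_year["2000"], scale="percent")
    bd = psi(v, v, convention="percent")
    assert bd.total == 0.0
    assert all(r.contribution == 0.0 for r in bd.rows)
    assert bd.band == "none"


@pytest.mark.parametrize(
    "total, band",
    [(2.96, "significant"), (0.25, "significant"), (0.1, "moderate"),
     (0.2499, "moderate"), (0.099, "none"), (0.0, "none")],
)
def test_interpretation_boundaries_belong_to_higher_band(total, band):
    assert interpret_psi(total) == band


def test_negative_total_is_a_domain_error():
    with pytest.raises(PsiDomainError):
        interpret_psi(-0.01)


def test_zero_share_requires_smoothing():
    with pytest.raises(PsiDomainError, match="smoothing"):
        psi(pvec([0.0, 1.0]), pvec([0.5, 0.5]), convention="proportion")


def test_convention_and_scale_must_agree():
    with pytest.raises(CountTableError, match="scale"):
        psi(pvec([0.5, 0.5]), pvec([0.5, 0.5]), convention="percent")


# ------------------------------------------------------------ properties

@given(pair_of_shares())
@settings(deadline=None)
def test_psi_is_symmetric_nonnegative_and_scales_by_100(pq):
    p, q = pq
    a = psi(pvec(p, sample="a"), pvec(q, sample="b"), convention="proportion")
    b = psi(pvec(q, sample="b"), pvec(p, sample="a"), convention="proportion")
    assert a.total >= 0
    assert a.total == pytest.approx(b.total, abs=1e-12)
    assert all(r.contribution >= 0 for r in a.rows)
    pct = psi(pvec([x * 100 for x in p], scale="percent", sample="a"),
              pvec([x * 100 for x in q], scale="percent", sample="b"),
              convention="percent")
    assert pct.total == pytest.approx(100 * a.total, rel=1e-9)


@given(pair_of_shares(), st.randoms(use_true_random=False))
@settings(deadline=None)
def test_psi_is_invariant_under_joint_category_permutation(pq, rnd):
    p, q = pq
    order = list(range(len(p)))
    rnd.shuffle(order)
    base = psi(pvec(p, sample="a"), pvec(q, sample="b"),
               convention="proportion").total
    perm = psi(pvec([p[i] for i in order], sample="a"),
               pvec([q[i] for i in order], sample="b"),
               convention="proportion").total
    assert perm == pytest.approx(base, abs=1e-12)


@given(pair_of_shares())
@settings(deadline=None)
def test_jeffreys_identity_links_psi_and_kl(pq):
    p, q = pq
    vp, vq = pvec(p, sample="a"), pvec(q, sample="b")
    total = psi(vp, vq, convention="proportion").total
    assert total == pytest.approx(
        kl_divergence(vp, vq) + kl_divergence(vq, vp), abs=1e-12)


def test_loop_oracle_agrees_on_random_pairs():
    """Naive per-category loop vs production path on 1,000 random pairs."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        k = int(rng.integers(2, 21))
        p = rng.dirichlet(np.ones(k) * 2)
        q = rng.dirichlet(np.ones(k) * 2)
        p, q = np.maximum(p, 1e-9), np.maximum(q, 1e-9)
        p, q = p / p.sum(), q / q.sum()
        naive = sum((o - e) * math.log(o / e) for o, e in zip(q, p))
        got = psi(pvec(p), pvec(q), convention="proportion").total
        assert got == pytest.approx(naive, abs=1e-12)


# ------------------------------------------------------------ KL and JS

def test_kl_hand_values_and_asymmetry():
    o, e = pvec([0.6, 0.4], sample="O"), pvec([0.5, 0.5], sample="E")
    assert kl_divergence(o, e) == pytest.approx(
        0.6 * math.log(1.2) + 0.4 * math.log(0.8), abs=1e-12)
    assert kl_divergence(e, o) == pytest.approx(
        0.5 * math.log(25 / 24), abs=1e-12)  # = 0.0204110
    assert kl_divergence(o, e) == pytest.approx(0.020136, abs=1e-6)
    assert kl_divergence(e, o) == pytest.approx(0.020411, abs=1e-6)


def test_divergences_vanish_on_identical_inputs():
    v = pvec([0.2, 0.3, 0.5])
    assert kl_divergence(v, v) == 0.0
    assert js_distance(v, v) == 0.0


def test_js_distance_stays_below_sqrt_ln2_even_near_disjoint():
    eps = 1e-6
    a = pvec([1 - eps, eps], sample="a")
    b = pvec([eps, 1 - eps], sample="b")
    assert 0 < js_distance(a, b) < math.sqrt(math.log(2))


def test_divergences_reject_percent_scale():
    v = pvec([50.0, 50.0], scale="percent")
    with pytest.raises(PsiDomainError, match="proportion"):
        kl_divergence(v, v)


# ---------------------------------------------------------- drift matrix

def test_drift_matrix_enumerates_all_pairs(by_variable):
    mat = drift_matrix(by_variable["age_group"], convention="percent")
    assert len(list(mat.iter_pairs())) == 21
    assert mat.pair_value("2000", "2016") == pytest.approx(2.9635, abs=5e-4)
    assert np.allclose(mat.values, mat.values.T)
    assert np.all(np.diag(mat.values) == 0)


def test_drift_matrix_of_identical_samples_is_zero(vec):
    a = vec([5, 5], sample="a")
    b = vec([5, 5], sample="b")
    mat = drift_matrix([a, b])
    assert list(mat.iter_pairs()) == [("a", "b", 0.0, "")]


def test_drift_matrix_pair_count_matches_binomial(vec):
    samples = [vec([i + 1, 10 - i], sample=f"s{i}") for i in range(4)]
    mat = drift_matrix(samples, convention="proportion")
    assert len(list(mat.iter_pairs())) == 6  # C(4,2)


def test_drift_matrix_needs_two_samples(vec):
    with pytest.raises(CountTableError):
        drift_matrix([vec([1, 1])])


def test_policy_validation():
    with pytest.raises(ValueError):
        InterpretationPolicy(psi_none_below=0.3, psi_significant_at=0.25)
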
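import numpy as np
import pytest

from ventromech import synthetic
from ventromech.cohort_stats import (
    CohortFieldStack,
    anova_eta2,
    burden_bin_summary,
    hemispheric_difference_test,
    hemispheric_map,
    kl_divergence,
    nodewise_test,
    pearson,
    variance_field,
    welch_t,
)
from ventromech.wmh import bin_burden


def welch_oracle(a, b):
    """Closed-form Welch statistic and Welch-Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def test_welch_t_basics():
    t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0
    t, p = welch_t([1.0, 2.0, 3.0], [1001.0, 1002.0, 1003.0])
    assert p < 1e-4
    t1, _ = welch_t([1.0, 2.0, 4.0], [3.0, 5.0, 6.0])
    t2, _ = welch_t([3.0, 5.0, 6.0], [1.0, 2.0, 4.0])
    assert t1 == pytest.approx(-t2)


def test_welch_t_matches_closed_form(rng):
    a = rng.normal(0, 1, 12)
    b = rng.normal(0.5, 2, 9)
    t, p = welch_t(a, b)
    t_ref, df = welch_oracle(a, b)
    assert t == pytest.approx(t_ref, abs=1e-12)
    from scipy import stats
    assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), df), abs=1e-12)


def test_welch_t_zero_variance_convention():
    assert welch_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
    t, p = welch_t([3.0, 3.0], [2.0, 2.0])
    assert p == 0.0 and t > 0


def test_nodewise_null_calibration():
    rng = np.random.default_rng(7)
    stack = CohortFieldStack(rng.normal(size=(50, 200)),
                             np.array(["F"] * 25 + ["M"] * 25))
    res = nodewise_test(stack)
    frac = (res.p_raw < 0.05).mean()
    # 3 binomial SDs around 5% with 200 vertices
    assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 200)
    assert res.significant.sum() <= 1


def test_nodewise_planted_effect_detected():
    rng = np.random.default_rng(8)
    vals = rng.normal(size=(50, 200))
    vals[25:, 17] += 3.0  # 3-SD effect at one vertex
    stack = CohortFieldStack(vals, np.array(["F"] * 25 + ["M"] * 25))
    res = nodewise_test(stack)
    assert res.significant[17]


def test_nodewise_constant_fields_give_p1():
    vals = np.ones((10, 5))
    stack = CohortFieldStack(vals, np.array(["F"] * 5 + ["M"] * 5))
    res = nodewise_test(stack)
    assert np.all(res.p_raw == 1.0) and np.all(res.statistic == 0.0)


def test_bh_monotone_in_rank(rng):
    vals = rng.normal(size=(20, 100))
    stack = CohortFieldStack(vals, np.array(["A"] * 10 + ["B"] * 10))
    res = nodewise_test(stack)
    order = np.argsort(res.p_raw)
    assert np.all(np.diff(res.p_adjusted[order]) >= -1e-15)
    assert np.all(res.p_adjusted >= res.p_raw - 1e-15)


def test_hemispheric_map_symmetric_mesh():
    sph = synthetic.make_icosphere(5.0, 3)  # icosphere is mirror-symmetric in x
    pairing = hemispheric_map(sph)
    assert pairing.distance.max() < 1e-9
    # involution: partner of partner is self
    assert np.array_equal(pairing.partner[pairing.partner], np.arange(sph.n_vertices))
    # translating the mesh with its plane leaves the pairing unchanged
    moved = sph.with_vertices(sph.vertices + [3.0, -1.0, 2.0])
    pairing2 = hemispheric_map(moved)
    assert np.array_equal(pairing.partner, pairing2.partner)


def test_hemispheric_map_localizes_asymmetry():
    sph = synthetic.make_icosphere(5.0, 3)
    bump = synthetic.RadialBump(center=(5.0, 0.0, 0.0), amplitude=0.8, width=1.5)
    bumped = sph.with_vertices(bump.map(sph.vertices))
    pairing = hemispheric_map(bumped, plane_point=(0.0, 0.0, 0.0))
    near_bump = np.linalg.norm(sph.vertices - [5.0, 0.0, 0.0], axis=1) < 2.0
    far = np.linalg.norm(np.abs(sph.vertices) - [5.0, 0.0, 0.0], axis=1) > 4.0
    assert pairing.distance[near_bump].mean() > 5 * pairing.distance[far].mean()


def test_hemispheric_difference_test_null_and_effect():
    sph = synthetic.make_icosphere(5.0, 2)
    pairing = hemispheric_map(sph)
    rng = np.random.default_rng(11)
    # symmetric null: vertex-paired values drawn iid
    vals = rng.normal(size=(20, sph.n_vertices))
    stack = CohortFieldStack(vals, np.array(["F"] * 10 + ["M"] * 10))
    res = nodewise_test(stack)  # sanity on shapes only
    hres = hemispheric_difference_test(stack, pairing)
    assert abs((hres.p_raw < 0.05).mean() - 0.05) <= 3 * np.sqrt(
        0.05 * 0.95 / len(hres.p_raw))
    # one-sided inflation: add a consistent offset on the +x side
    vals2 = vals.copy()
    left = pairing.side > 0
    vals2[:, left] += 5.0
    stack2 = CohortFieldStack(vals2, stack.groups)
    hres2 = hemispheric_difference_test(stack2, pairing)
    assert hres2.significant.mean() > 0.95
    # identical left/right values -> p = 1
    sym = np.zeros((4, sph.n_vertices))
    hres3 = hemispheric_difference_test(
        CohortFieldStack(sym, np.array(["F", "F", "M", "M"])), pairing)
    assert np.all(hres3.p_raw == 1.0)


def test_variance_field():
    vals = np.array([[0.0, 1.0], [1.0, 0.0]])
    stack = CohortFieldStack(vals, np.array(["F", "M"]))
    assert np.allclose(variance_field(stack), 0.5)
    same = CohortFieldStack(np.tile([0.0, 2.0, 1.0], (5, 1)),
                            np.array(["F"] * 5))
    assert np.allclose(variance_field(same), 0.0)
    # subject order invariance
    rng = np.random.default_rng(3)
    v = rng.normal(size=(6, 30))
    s1 = CohortFieldStack(v, np.array(["F"] * 6))
    s2 = CohortFieldStack(v[::-1], np.array(["F"] * 6))
    assert np.allclose(variance_field(s1), variance_field(s2))
    with pytest.warns(UserWarning, match="constant"):
        variance_field(CohortFieldStack(
            np.vstack([np.ones(5), rng.normal(size=(2, 5))]),
            np.array(["F"] * 3)))


def test_kl_divergence():
    rng = np.random.default_rng(4)
    a = rng.normal(size=500)
    assert kl_divergence(a, a) <= 1e-12
    b = rng.normal(1.0, 2.0, size=500)
    assert kl_divergence(a, b) >= 0.0
    # hand case: 4 points in 2 bins -> p=(0.75, 0.25), q=(0.5, 0.5)
    x = [0.0, 0.0, 0.0, 1.0]
    y = [0.0, 0.0, 1.0, 1.0]
    expected = 0.75 * np.log(1.5) + 0.25 * np.log(0.5)
    assert kl_divergence(x, y, bins=2) == pytest.approx(expected, abs=1e-6)
    # documented asymmetry
    assert kl_divergence(x, y, bins=2) != pytest.approx(kl_divergence(y, x, bins=2))


def test_anova_eta2_cases(rng):
    res = anova_eta2([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert res["F"] == pytest.approx(0.0) and res["eta2"] == pytest.approx(0.0)
    # brute-force oracle: SS_b = 13.5, SS_t = 17.5
    res = anova_eta2([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    assert res["eta2"] == pytest.approx(13.5 / 17.5, abs=1e-12)
    # eta2 matches explicit SS decomposition on random data
    groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(4)]
    res = anova_eta2(groups)
    pooled = np.concatenate(groups)
    ss_t = np.sum((pooled - pooled.mean()) ** 2)
    ss_b = sum(len(g) * (g.mean() - pooled.mean()) ** 2 for g in groups)
    assert res["eta2"] == pytest.approx(ss_b / ss_t, abs=1e-12)
    assert 0.0 <= res["eta2"] <= 1.0


def test_anova_posthoc_when_significant():
    res = anova_eta2([[1.0, 1.1, 0.9], [5.0, 5.1, 4.9], [9.0, 9.1, 8.9]])
    assert res["p"] < 0.05 and res["posthoc"] is not None
    assert len(res["posthoc"]) == 3
    assert all(ph["p_adjusted"] >= ph["p_raw"] - 1e-15 for ph in res["posthoc"])


def test_pearson():
    x = np.arange(10.0)
    assert pearson(x, x)[0] == pytest.approx(1.0)
    assert pearson(x, -x)[0] == pytest.approx(-1.0)
    rng = np.random.default_rng(5)
    rs = [pearson(rng.normal(size=30), rng.normal(size=30))[0] for _ in range(50)]
    assert abs(np.mean(rs)) < 0.1
    with pytest.raises(ValueError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_burden_bin_summary_recovers_construction(rng):
    # 3 subjects, 90 vertices; construct bins and a marker with a bin effect
    p = np.concatenate([np.zeros(30), np.full(30, 0.2), np.full(30, 0.9)])
    bins = bin_burden(p)
    base = rng.normal(0, 0.01, size=(3, 90))
    base[:, 60:] += 2.0  # high-burden vertices carry larger marker values
    stack = CohortFieldStack(base, np.array(["F", "M", "F"]))
    out = burden_bin_summary(stack, bins)
    assert out["missing_bins"] == ["intermediate"]
    means = out["summary"]["mean"]
    assert means["high"] > means["low"] + 1.5
    assert means["high"] > means["noWMH"] + 1.5
    # single-bin sanity: all vertices in one bin -> bin mean = field mean
    all_zero = bin_burden(np.zeros(90))
    out2 = burden_bin_summary(stack, all_zero)
    assert out2["per_subject"]["noWMH"] == pytest.approx(base.mean(axis=1))
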
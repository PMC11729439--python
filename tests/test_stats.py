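import itertools

import numpy as np
import pandas as pd
import pytest

from mggf.stats import (StatsError, feature_distance_matrix,
                        label_distance_matrix, logistic_panel_weights,
                        mantel_test, pearson_matrix, significance_band,
                        ttest_by_label)


def _frame(values0, values1, feature="x"):
    return pd.DataFrame({
        "pneumonia": 0,
        "hypoalbuminemia": [0] * len(values0) + [1] * len(values1),
        feature: list(values0) + list(values1),
    })


def test_identical_groups_give_null_result():
    r = ttest_by_label(_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), "x")
    assert r.t_stat == pytest.approx(0.0)
    assert r.smd == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)
    assert r.band == "ns"


def test_pooled_t_matches_closed_form_oracle():
    # independent textbook evaluation of the pooled two-sample t statistic
    g0, g1 = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
    n0, n1 = 3, 3
    sp2 = ((n0 - 1) * g0.var(ddof=1) + (n1 - 1) * g1.var(ddof=1)) / (n0 + n1 - 2)
    t_oracle = (g1.mean() - g0.mean()) / np.sqrt(sp2 * (1 / n0 + 1 / n1))
    from scipy.stats import t as tdist
    p_oracle = 2 * tdist.sf(abs(t_oracle), n0 + n1 - 2)
    r = ttest_by_label(_frame(g0, g1), "x")
    assert r.t_stat == pytest.approx(t_oracle, abs=1e-12)
    assert r.p_value == pytest.approx(p_oracle, abs=1e-12)
    assert r.smd == pytest.approx((g1.mean() - g0.mean()) / np.sqrt(sp2),
                                  abs=1e-12)


def test_smd_sign_follows_hypo_minus_nonhypo():
    lo_hi = ttest_by_label(_frame([1.0, 2.0], [5.0, 6.0]), "x")
    hi_lo = ttest_by_label(_frame([5.0, 6.0], [1.0, 2.0]), "x")
    assert lo_hi.smd > 0 > hi_lo.smd
    assert lo_hi.smd == pytest.approx(-hi_lo.smd)


def test_insufficient_group_raises():
    with pytest.raises(StatsError, match="insufficient"):
        ttest_by_label(_frame([1.0, 2.0], [3.0]), "x")


@pytest.mark.parametrize("p,band", [
    (0.0005, "***"), (0.005, "**"), (0.04, "*"), (0.2, "ns")])
def test_significance_bands(p, band):
    assert significance_band(p) == band


def test_logistic_weights_rank_constructed_signal(panel_spec):
    # label driven by a single URE feature -> URE panel weight largest
    rng = np.random.default_rng(0)
    n = 2000
    t = pd.DataFrame({f: rng.normal(size=n) for f in panel_spec.features()})
    t["pneumonia"] = 0
    t["hypoalbuminemia"] = (t["USG"] > 0).astype(int)
    w = logistic_panel_weights(t, "all", panel_spec)
    assert max(w.panel_weights, key=w.panel_weights.get) == "URE"


def test_logistic_weights_null_near_zero(panel_spec):
    rng = np.random.default_rng(1)
    n = 4000
    t = pd.DataFrame({f: rng.normal(size=n) for f in panel_spec.features()})
    t["pneumonia"] = 0
    t["hypoalbuminemia"] = rng.integers(0, 2, size=n)
    w = logistic_panel_weights(t, "all", panel_spec)
    assert all(v < 0.1 for v in w.panel_weights.values())


def test_pearson_matrix_basic_identities():
    rng = np.random.default_rng(2)
    t = pd.DataFrame({"x": rng.normal(size=50)})
    t["negx"] = -t["x"]
    m = pearson_matrix(t, ["x", "negx"])
    assert m.loc["x", "x"] == pytest.approx(1.0)
    assert m.loc["x", "negx"] == pytest.approx(-1.0)


def test_pearson_independent_columns_near_zero():
    rng = np.random.default_rng(3)
    t = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list("abcd"))
    m = pearson_matrix(t, list("abcd")).to_numpy()
    off = m[~np.eye(4, dtype=bool)]
    assert (np.abs(off) < 0.1).all()


def test_pearson_flags_zero_variance():
    t = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
    with pytest.warns(RuntimeWarning, match="zero-variance"):
        m = pearson_matrix(t, ["x", "c"])
    assert np.isnan(m.loc["x", "c"])


def _random_distance(rng, n):
    x = rng.normal(size=(n, 2))
    d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    return d


def test_mantel_identity():
    d = _random_distance(np.random.default_rng(4), 8)
    r, p = mantel_test(d, d, n_perm=99, seed=0)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(1 / 100)


def test_mantel_exhaustive_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    a, b = _random_distance(rng, 4), _random_distance(rng, 4)
    r, p = mantel_test(a, b, exhaustive=True)
    iu = np.triu_indices(4, 1)
    r_oracle = np.corrcoef(a[iu], b[iu])[0, 1]
    count = 0
    for perm in itertools.permutations(range(4)):
        bp = b[np.ix_(perm, perm)]
        count += np.corrcoef(a[iu], bp[iu])[0, 1] >= r_oracle - 1e-12
    assert r == pytest.approx(r_oracle)
    assert p == pytest.approx(count / 24)


def test_mantel_invariant_to_joint_relabeling():
    rng = np.random.default_rng(6)
    a, b = _random_distance(rng, 7), _random_distance(rng, 7)
    perm = rng.permutation(7)
    r1, p1 = mantel_test(a, b, n_perm=199, seed=1)
    r2, p2 = mantel_test(a[np.ix_(perm, perm)], b[np.ix_(perm, perm)],
                         n_perm=199, seed=1)
    assert r1 == pytest.approx(r2)
    assert abs(p1 - p2) < 0.05


def test_mantel_agrees_with_skbio():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix, mantel
    rng = np.random.default_rng(7)
    a, b = _random_distance(rng, 12), _random_distance(rng, 12)
    r_sk, _, _ = mantel(DistanceMatrix(a), DistanceMatrix(b),
                        permutations=0)
    r, _ = mantel_test(a, b, n_perm=9, seed=0)
    assert r == pytest.approx(float(r_sk), abs=1e-12)


def test_mantel_input_validation():
    d = _random_distance(np.random.default_rng(8), 5)
    with pytest.raises(StatsError, match="symmetric"):
        mantel_test(d, d + np.triu(np.ones((5, 5)), 1))
    with pytest.raises(StatsError, match="size"):
        mantel_test(d, d[:4, :4])


def test_label_and_feature_distances():
    d = label_distance_matrix(np.array([0, 1, 1]))
    assert d.tolist() == [[0, 1, 1], [1, 0, 0], [1, 0, 0]]
    t = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0]})
    f = feature_distance_matrix(t, ["x"])
    assert f.shape == (3, 3) and f[0, 2] > f[0, 1]
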
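import numpy as np
import pytest

from entrainmeg import stats


# ------------------------------------------------------------------- ANOVA

def test_anova_matches_statsmodels_repeated_measures():
    """Cross-check F and p against an independent RM-ANOVA implementation
    on a random balanced table."""
    import pandas as pd
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(7)
    y = rng.standard_normal((12, 4, 2, 2))
    table = stats.rm_anova_3way(y).set_index("effect")
    rows = [(s, e, a, b, y[s, e, a, b])
            for s in range(12) for e in range(4)
            for a in range(2) for b in range(2)]
    df = pd.DataFrame(rows, columns=["subj", "entrainer", "what", "when",
                                     "y"])
    ref = AnovaRM(df, "y", "subj",
                  within=["entrainer", "what", "when"]).fit().anova_table
    mapping = {"entrainer": "entrainer", "what": "what", "when": "when",
               "entrainer:what": "entrainer * what",
               "entrainer:when": "entrainer * when",
               "what:when": "what * when",
               "entrainer:what:when": "entrainer * what * when"}
    for ref_name, name in mapping.items():
        assert table.loc[name, "F"] == pytest.approx(
            ref.loc[ref_name, "F Value"], rel=1e-8)
        assert table.loc[name, "p"] == pytest.approx(
            ref.loc[ref_name, "Pr > F"], rel=1e-8)


def test_anova_null_calibration():
    """Participant constants plus noise: every effect's F has expectation
    near 1 and rejects at roughly the nominal rate."""
    rng = np.random.default_rng(0)
    n_rep = 200
    fs, rejections = [], 0
    for _ in range(n_rep):
        y = (rng.standard_normal((8, 1, 1, 1))
             + 0.5 * rng.standard_normal((8, 4, 2, 2)))
        tab = stats.rm_anova_3way(y).set_index("effect")
        fs.append(tab.loc["entrainer", "F"])
        rejections += tab.loc["entrainer", "p"] < 0.05
    assert abs(np.mean(fs) - 1.0) < 0.25
    assert rejections / n_rep < 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)


def test_anova_detects_injected_entrainer_effect():
    rng = np.random.default_rng(1)
    base = rng.standard_normal((10, 4, 2, 2))
    effect = np.linspace(0, 3, 4)[None, :, None, None]
    f_null = stats.rm_anova_3way(base).set_index("effect")
    f_eff = stats.rm_anova_3way(base + effect).set_index("effect")
    assert f_eff.loc["entrainer", "F"] > 5 * f_null.loc["entrainer", "F"]
    # the other effects are untouched by a pure entrainer effect
    for other in ("what", "when", "what * when"):
        assert f_eff.loc[other, "F"] == pytest.approx(
            f_null.loc[other, "F"], rel=1e-8)


def test_anova_rejects_missing_cells():
    y = np.zeros((6, 4, 2, 2))
    y[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        stats.rm_anova_3way(y)


# ------------------------------------------------------------------- t-map

def test_paired_t_hand_computation():
    a = np.array([[2.0], [3.0], [4.0]])
    b = np.array([[1.0], [1.0], [1.0]])
    t = stats.paired_t_map(a, b)
    assert t[0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-4)
    assert t[0] == pytest.approx(3.4641, abs=1e-4)


def test_paired_t_participant_constant_invariance(rng):
    a = rng.standard_normal((6, 3, 10))
    b = rng.standard_normal((6, 3, 10))
    shift = rng.standard_normal((6, 1, 1)) * 10
    np.testing.assert_allclose(stats.paired_t_map(a, b),
                               stats.paired_t_map(a + shift, b + shift),
                               rtol=1e-9)
    np.testing.assert_allclose(stats.paired_t_map(a, a), 0.0)


def test_paired_t_zero_variance_warns():
    a = np.ones((4, 2))
    b = np.zeros((4, 2))
    with pytest.warns(RuntimeWarning):
        t = stats.paired_t_map(a, b)
    assert np.all(np.isinf(t)) and np.all(t > 0)


# -------------------------------------------------------------- clustering

def test_form_clusters_hand_enumeration():
    """Three mutually adjacent sensors above threshold at two adjacent
    samples, t = 4 each: one cluster of six members, mass 24."""
    t_map = np.zeros((3, 20))
    t_map[:, 10:12] = 4.0
    adj = ~np.eye(3, dtype=bool)
    clusters = stats.form_clusters(t_map, 3.0, adj, min_neighbors=2)
    assert len(clusters) == 1
    assert clusters[0].mass == pytest.approx(24.0)
    assert len(clusters[0].members) == 6


def test_isolated_sensor_is_pruned(chain_adjacency):
    t_map = np.zeros((4, 10))
    t_map[0, 5] = 10.0     # isolated supra-threshold sensor
    clusters = stats.form_clusters(t_map, 3.0, chain_adjacency(4),
                                   min_neighbors=2)
    assert clusters == []
    # with the neighbour rule disabled it survives
    assert len(stats.form_clusters(t_map, 3.0, chain_adjacency(4),
                                   min_neighbors=0)) == 1


def test_form_clusters_empty_and_negative_tail(chain_adjacency):
    assert stats.form_clusters(np.zeros((3, 5)), 2.0,
                               chain_adjacency(3)) == []
    t_map = np.zeros((3, 10))
    t_map[:, 3:5] = -4.0
    neg = stats.form_clusters(t_map, 3.0, ~np.eye(3, dtype=bool),
                              min_neighbors=2, tail="two")
    assert len(neg) == 1 and neg[0].mass == pytest.approx(-24.0)
    assert stats.form_clusters(t_map, 3.0, ~np.eye(3, dtype=bool),
                               min_neighbors=2, tail="pos") == []


# ---------------------------------------------------- permutation tests

def _effect_data(rng, n=8, s=4, t=20, effect=1.5):
    a = rng.standard_normal((n, s, t))
    b = rng.standard_normal((n, s, t))
    b[:, 1:3, 8:14] -= effect
    return a, b


def test_cluster_test_identical_conditions_empty(chain_adjacency, rng):
    a = rng.standard_normal((6, 4, 15))
    res = stats.cluster_permutation_test(a, a.copy(),
                                         adjacency=chain_adjacency(4),
                                         n_perm=200, seed=0)
    assert res.clusters == []


def test_cluster_test_monte_carlo_agrees_with_exhaustive(chain_adjacency):
    rng = np.random.default_rng(3)
    a, b = _effect_data(rng, effect=1.0)
    kwargs = dict(adjacency=chain_adjacency(4), threshold_alpha=0.05,
                  min_neighbors=1)
    mc = stats.cluster_permutation_test(a, b, n_perm=1000, seed=1, **kwargs)
    ex = stats.cluster_permutation_test(a, b, method="exhaustive", **kwargs)
    assert len(mc.clusters) == len(ex.clusters)
    for p_mc, p_ex in zip(mc.p_values(), ex.p_values()):
        se = np.sqrt(max(p_ex * (1 - p_ex), 1e-4) / 1000)
        assert abs(p_mc - p_ex) < 4 * se + 2e-3


def test_cluster_test_p_invariant_to_rescaling(chain_adjacency):
    rng = np.random.default_rng(4)
    a, b = _effect_data(rng)
    kwargs = dict(adjacency=chain_adjacency(4), threshold_alpha=0.05,
                  min_neighbors=1, n_perm=300, seed=5)
    p1 = stats.cluster_permutation_test(a, b, **kwargs).p_values()
    p2 = stats.cluster_permutation_test(5.0 * a, 5.0 * b,
                                        **kwargs).p_values()
    np.testing.assert_array_equal(p1, p2)


def test_cluster_test_power_monotone_in_effect_size(chain_adjacency):
    """Detection rate grows with the injected suppression effect."""
    adj = chain_adjacency(4)
    rates = []
    for effect in (0.0, 0.8, 2.0):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(12):
            a, b = _effect_data(rng, effect=effect)
            res = stats.cluster_permutation_test(
                a, b, adjacency=adj, threshold_alpha=0.05,
                min_neighbors=1, n_perm=200, seed=0)
            hits += any(p < 0.05 for p in res.p_values())
        rates.append(hits / 12)
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] > rates[0]


def test_sign_permutation_contracts(rng):
    # all participants exactly at chance
    res = stats.sign_permutation_test(np.zeros((6, 25)), n_perm=200, seed=0)
    assert res.clusters == []
    # strong constant positive effect: one full-window cluster at the floor
    x = 0.10 + 0.001 * rng.standard_normal((8, 25))
    res = stats.sign_permutation_test(x, n_perm=1000, seed=0)
    assert len(res.clusters) == 1
    assert len(res.clusters[0].members) == 25
    # permutation floor: only the (rare) all-positive sign draws tie the
    # observed mass, so p stays within a few counts of 1/(N+1)
    assert res.clusters[0].p < 0.01
    # below-chance effects never cluster in the one-tailed test
    res = stats.sign_permutation_test(-x, n_perm=200, seed=0)
    assert res.clusters == []


def test_sign_permutation_exhaustive_matches_monte_carlo(rng):
    x = rng.normal(0.04, 0.05, size=(8, 20))
    mc = stats.sign_permutation_test(x, n_perm=2000, seed=2)
    ex = stats.sign_permutation_test(x, method="exhaustive")
    assert len(mc.clusters) == len(ex.clusters)
    for p_mc, p_ex in zip(mc.p_values(), ex.p_values()):
        se = np.sqrt(max(p_ex * (1 - p_ex), 1e-4) / 2000)
        assert abs(p_mc - p_ex) < 4 * se + 1e-3
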
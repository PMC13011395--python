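import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tests.conftest import make_catalog, make_matrix
from virome_ap import synthetic_data as sd
from virome_ap.differential import (
    amg_occurrence_test,
    bh_adjust,
    covariate_validate,
    fisher_exact_two_sided,
    fold_change,
    host_family_summary,
    select_differential,
    wilcoxon_rank_sum,
)
from virome_ap.profiling import AbundanceMatrix


def enumeration_wilcoxon_p(x, y):
    """Independent oracle: exact two-sided p over all label assignments."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2
    hits = total = 0
    for combo in itertools.combinations(range(n), nx):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_exact_small_case(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            nx_, ny = rng.integers(2, 6, size=2)
            x = rng.normal(size=nx_)
            y = rng.normal(size=ny)
            _, p = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_approximation_close_to_exact(self, monkeypatch):
        # fuzzed tie-free n=12 cases: normal approx within 0.05 of enumeration
        import virome_ap.differential as dmod

        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(200):
            x = rng.normal(size=6)
            y = rng.normal(size=6) + rng.normal() * 0.5
            exact = enumeration_wilcoxon_p(x, y)
            _, p_exact = wilcoxon_rank_sum(x, y)
            assert p_exact == pytest.approx(exact, abs=1e-12)
            with monkeypatch.context() as mp:
                mp.setattr(dmod, "EXACT_N_MAX", 0)  # force approximation path
                _, p_approx = wilcoxon_rank_sum(x, y)
            worst = max(worst, abs(p_approx - exact))
        assert worst < 0.05

    def test_large_sample_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(2)
        x = np.round(rng.normal(size=30), 1)
        y = np.round(rng.normal(0.8, size=30), 1)
        _, p = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-6)


def brute_force_bh(p):
    """Step-up oracle: q_i = min over j>=rank(i) of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_hand_computed_example(self):
        q = bh_adjust([0.01, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(q, [0.04, 0.05, 0.05, 0.05])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_single_p(self):
        assert bh_adjust([0.7])[0] == 0.7

    def test_matches_brute_force_fuzzed(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            p = rng.random(rng.integers(1, 25))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_and_idempotent(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.random(15))
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-12)  # order-preserving
        np.testing.assert_allclose(bh_adjust(q), q, atol=1e-12)
        assert np.all(q >= p - 1e-15)


class TestFoldChange:
    def test_simple_ratio(self):
        assert fold_change(0.02, 0.01) == pytest.approx(2.0, rel=1e-5)

    def test_equal_means(self):
        assert fold_change(0.01, 0.01) == pytest.approx(1.0)

    def test_zero_denominator_finite(self):
        fc = fold_change(0.01, 0.0)
        assert np.isfinite(fc) and fc > 1e5


class TestSelectDifferential:
    def test_ground_truth_recovery(self):
        sens, fdr = [], []
        for seed in range(5):
            cfg = sd.SyntheticConfig(seed=seed, n_votus=200, n_ap=50, n_hc=50,
                                     sparsity=0.0, planted_log2fc=2.0)
            cat = sd.generate_catalog(cfg)
            viral, _, meta, truth = sd.generate_cohort(cfg, cat)
            tab = select_differential(viral, meta)
            sel = set(tab.loc[tab["direction"] != "ns", "feature_id"])
            tset = set(truth.differential_votus)
            tp = len(sel & tset)
            sens.append(tp / len(tset))
            fdr.append((len(sel) - tp) / max(len(sel), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdr) <= 0.1

    def test_null_cohort_few_discoveries(self):
        zero_seeds = 0
        for seed in range(10):
            cfg = sd.SyntheticConfig(seed=100 + seed, n_votus=100, n_ap=25, n_hc=25,
                                     frac_differential=0.0, frac_monotone=0.0)
            cat = sd.generate_catalog(cfg)
            viral, _, meta, _ = sd.generate_cohort(cfg, cat)
            tab = select_differential(viral, meta)
            if (tab["direction"] != "ns").sum() == 0:
                zero_seeds += 1
        assert zero_seeds >= 8

    def test_abundance_filter_precedence(self):
        rng = np.random.default_rng(5)
        n = 20
        base = rng.dirichlet(np.ones(3) * 50, size=2 * n) * (1 - 2e-6)
        tiny = np.where(np.arange(2 * n) < n, 2e-6, 1e-12)  # huge FC, tiny abundance
        vals = np.column_stack([base * (1 - tiny)[:, None], tiny])
        m = make_matrix(vals)
        meta = pd.DataFrame(
            {"group": ["AP"] * n + ["HC"] * n},
            index=pd.Index(m.sample_ids, name="sample_id"),
        )
        tab = select_differential(m, meta).set_index("feature_id")
        assert tab.loc["f4", "fold_change"] > 100
        assert tab.loc["f4", "direction"] == "ns"

    def test_direction_flips_with_labels(self, small_cohort):
        viral, _, meta, _ = small_cohort
        tab1 = select_differential(viral, meta)
        flipped = meta.copy()
        flipped["group"] = np.where(flipped["group"] == "AP", "HC", "AP")
        tab2 = select_differential(viral, flipped)
        d1 = tab1.set_index("feature_id")["direction"]
        d2 = tab2.set_index("feature_id")["direction"]
        swap = {"AP-enriched": "HC-enriched", "HC-enriched": "AP-enriched", "ns": "ns"}
        assert (d1.map(swap) == d2).all()

    def test_q_at_least_p(self, small_cohort):
        viral, _, meta, _ = small_cohort
        tab = select_differential(viral, meta)
        assert (tab["q_bh"] >= tab["p_raw"] - 1e-12).all()


class TestCovariateValidate:
    def test_majority_of_selected_validated(self):
        cfg = sd.SyntheticConfig(seed=21, n_votus=200, n_ap=50, n_hc=50, sparsity=0.0)
        cat = sd.generate_catalog(cfg)
        viral, _, meta, _ = sd.generate_cohort(cfg, cat)
        tab = select_differential(viral, meta)
        flags = covariate_validate(viral, meta, tab)
        sel = tab.loc[tab["direction"] != "ns", "feature_id"]
        assert len(sel) > 0
        assert flags[sel].mean() >= 0.79

    def test_confounded_effect_not_validated(self):
        # effect driven entirely by a covariate correlated with group
        rng = np.random.default_rng(6)
        n = 60
        age = np.concatenate([rng.normal(70, 2, n // 2), rng.normal(30, 2, n // 2)])
        raw = np.exp(rng.normal(size=(n, 30)))
        raw[:, 0] *= np.exp(0.15 * (age - 50))  # feature follows age, not group
        vals = raw / raw.sum(axis=1, keepdims=True)
        m = make_matrix(vals)
        meta = pd.DataFrame(
            {
                "group": ["AP"] * (n // 2) + ["HC"] * (n // 2),
                "age": age,
                "sex": rng.choice(["F", "M"], n),
                "bmi": rng.normal(24, 3, n),
            },
            index=pd.Index(m.sample_ids, name="sample_id"),
        )
        tab = select_differential(m, meta)
        flags = covariate_validate(m, meta, tab)
        assert not flags["f1"]

    def test_zero_variance_feature_not_validated(self):
        rng = np.random.default_rng(7)
        n = 40
        vals = rng.dirichlet(np.ones(5), size=n)
        vals[:, 0] = 0.0
        m = make_matrix(vals)
        meta = pd.DataFrame(
            {
                "group": ["AP"] * 20 + ["HC"] * 20,
                "age": rng.normal(50, 10, n),
                "sex": rng.choice(["F", "M"], n),
                "bmi": rng.normal(24, 3, n),
            },
            index=pd.Index(m.sample_ids, name="sample_id"),
        )
        tab = select_differential(m, meta)
        flags = covariate_validate(m, meta, tab)
        assert not flags["f1"]

    def test_collinear_covariate_dropped(self, caplog):
        rng = np.random.default_rng(8)
        n = 30
        m = make_matrix(rng.dirichlet(np.ones(4), size=n))
        age = rng.normal(50, 10, n)
        meta = pd.DataFrame(
            {
                "group": ["AP"] * 15 + ["HC"] * 15,
                "age": age,
                "sex": rng.choice(["F", "M"], n),
                "bmi": age * 2.0,  # exactly collinear with age
            },
            index=pd.Index(m.sample_ids, name="sample_id"),
        )
        tab = select_differential(m, meta)
        with caplog.at_level("WARNING"):
            covariate_validate(m, meta, tab)
        assert "collinear" in caplog.text


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_two_sided(3, 0, 0, 3) == pytest.approx(0.1)

    def test_balanced_table_p_one(self):
        assert fisher_exact_two_sided(2, 2, 2, 2) == pytest.approx(1.0)

    def test_matches_scipy_fuzzed(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 8, size=4)
            if a + b == 0 or c + d == 0:
                continue
            ours = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            ref = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(ref, abs=1e-12)


class TestAmgOccurrence:
    @pytest.fixture()
    def ko_catalog(self):
        # K1 carried by all of set A, none of set B; K2 balanced
        ko = [frozenset({"K1", "K2"}), frozenset({"K1"}), frozenset({"K1", "K2"}),
              frozenset({"K2"}), frozenset({"K2"}), frozenset()]
        return make_catalog(
            {f"v{i}": 1000 for i in range(6)}, ko_set=ko
        )

    def test_separating_ko_detected(self, ko_catalog):
        # K1: 3/3 vs 0/3 -> Fisher p = 0.1, BH over {K1, K2} -> q = 0.2
        out = amg_occurrence_test(
            {"v0", "v1", "v2"}, {"v3", "v4", "v5"}, ko_catalog, min_rate=0.05, q_max=0.25
        )
        assert "K1" in set(out["ko_id"])
        row = out.set_index("ko_id").loc["K1"]
        assert row["count_a"] == 3 and row["count_b"] == 0
        assert row["enriched_in"] == "A"

    def test_empty_set_raises(self, ko_catalog):
        with pytest.raises(ValueError):
            amg_occurrence_test(set(), {"v1"}, ko_catalog)

    def test_overlapping_sets_raise(self, ko_catalog):
        with pytest.raises(ValueError):
            amg_occurrence_test({"v1"}, {"v1", "v2"}, ko_catalog)

    def test_counts_bounded_by_denominators(self, small_catalog):
        ids = small_catalog.votu_ids
        out = amg_occurrence_test(set(ids[:30]), set(ids[30:60]), small_catalog,
                                  min_rate=0.0, q_max=1.01)
        assert (out["count_a"] <= out["n_a"]).all()
        assert (out["count_b"] <= out["n_b"]).all()


class TestHostFamilySummary:
    def test_counts_and_conservation(self):
        cat = make_catalog(
            {f"v{i}": 1000 for i in range(4)},
            host_genus=["Escherichia", "Escherichia", None, "Blautia_A"],
            family=["Peduoviridae", "unassigned", "unassigned", "Microviridae"],
            lifestyle=["lytic", "temperate", "unknown", "lytic"],
        )
        tab = pd.DataFrame(
            {
                "feature_id": ["v0", "v1", "v2", "v3"],
                "direction": ["AP-enriched", "AP-enriched", "HC-enriched", "ns"],
            }
        )
        out = host_family_summary(tab, cat)
        assert out["host_genus"].loc["Escherichia", "AP-enriched"] == 2
        assert out["host_genus"].loc["unknown", "HC-enriched"] == 1
        n_selected = (tab["direction"] != "ns").sum()
        for key in ("host_genus", "family", "lifestyle"):
            assert out[key].to_numpy().sum() == n_selected
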
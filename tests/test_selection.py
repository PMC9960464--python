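"""Feature-ranking behavior: signal recovery, redundancy penalties,
invariances and determinism for CFS, RReliefF and MRMR."""

import numpy as np
import pandas as pd
import pytest

from ppgbp.selection import cfs_rank, mrmr_rank, rrelieff_rank, selection_report


def planted_table(n=500, n_features=50, noise=0.05, seed=0):
    """One feature carries the label (up to small noise), the rest are noise."""
    rng = np.random.default_rng(seed)
    y = rng.normal(120, 15, n)
    data = {"sbp": y, "dbp": y - 40}
    data["signal"] = y + rng.normal(0, noise * y.std(), n)
    for j in range(n_features - 1):
        data[f"noise{j:02d}"] = rng.normal(size=n)
    return pd.DataFrame(data)


class TestCfs:
    def test_label_copy_selected_first_with_unit_merit(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        t = pd.DataFrame({"sbp": y, "dbp": y - 1, "copy": y,
                          "junk": rng.normal(size=200)})
        res = cfs_rank(t, "sbp")
        assert res.ranking[0] == "copy"
        assert res.scores["copy"] == pytest.approx(1.0)

    def test_redundancy_penalty_matches_closed_form_merit(self):
        """Two noisy label copies: the pair's merit equals the closed-form
        arithmetic from the measured correlations, and the redundancy term
        keeps it far below the merit an equally-relevant but uncorrelated
        partner would have given (2 * r_cf / sqrt(2))."""
        rng = np.random.default_rng(2)
        y = rng.normal(size=400)
        c1 = y + rng.normal(0, 0.1, 400)
        c2 = y + rng.normal(0, 0.1, 400)
        t = pd.DataFrame({"sbp": y, "dbp": y, "copyA": c1, "copyB": c2,
                          "junk": rng.normal(size=400)})
        res = cfs_rank(t, "sbp")
        first, second = res.ranking[0], res.ranking[1]
        assert {first, second} == {"copyA", "copyB"}
        r_cf = {f: abs(np.corrcoef(t[f], y)[0, 1]) for f in ("copyA", "copyB")}
        r_ff = abs(np.corrcoef(c1, c2)[0, 1])
        mean_cf = (r_cf["copyA"] + r_cf["copyB"]) / 2
        merit2 = 2 * mean_cf / np.sqrt(2 + 2 * r_ff)
        no_redundancy = 2 * mean_cf / np.sqrt(2)
        assert res.scores[second] == pytest.approx(merit2, rel=1e-9)
        assert res.scores[second] < 0.75 * no_redundancy

    def test_constant_feature_gets_zero_correlation(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=100)
        t = pd.DataFrame({"sbp": y, "dbp": y, "const": np.ones(100),
                          "sig": y + rng.normal(0, 0.2, 100)})
        res = cfs_rank(t, "sbp")
        assert res.ranking[0] == "sig"
        assert res.ranking[-1] == "const" or res.scores["const"] <= min(
            res.scores[f] for f in res.ranking[:1])


class TestRrelieff:
    def test_planted_signal_gets_highest_weight(self):
        res = rrelieff_rank(planted_table(n=300, n_features=20, seed=4), "sbp")
        assert res.ranking[0] == "signal"
        assert -1.0 <= min(res.scores.values()) <= max(res.scores.values()) <= 1.0

    def test_independent_feature_weight_shrinks_with_n(self):
        res = rrelieff_rank(planted_table(n=2000, n_features=5, seed=5), "sbp")
        for f, w in res.scores.items():
            if f.startswith("noise"):
                assert abs(w) < 0.05

    def test_duplicating_every_row_preserves_ranking(self):
        t = planted_table(n=150, n_features=8, seed=6)
        t2 = pd.concat([t, t], ignore_index=True)
        r1 = rrelieff_rank(t, "sbp")
        r2 = rrelieff_rank(t2, "sbp")
        assert r1.ranking[0] == r2.ranking[0] == "signal"

    def test_needs_more_rows_than_neighbors(self):
        with pytest.raises(ValueError):
            rrelieff_rank(planted_table(n=8, n_features=3), "sbp", n_neighbors=10)

    def test_sampled_iteration_is_seed_deterministic(self):
        t = planted_table(n=400, n_features=10, seed=7)
        a = rrelieff_rank(t, "sbp", n_iterations=100, seed=42)
        b = rrelieff_rank(t, "sbp", n_iterations=100, seed=42)
        assert a.ranking == b.ranking and a.scores == b.scores


class TestMrmr:
    def test_duplicate_of_selected_copy_is_heavily_penalized(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=400)
        t = pd.DataFrame({"sbp": y, "dbp": y, "copy1": y, "copy2": y,
                          "junk": rng.normal(size=400)})
        res = mrmr_rank(t, "sbp")
        assert res.ranking[0] == "copy1"  # lexicographic tie-break
        # the duplicate's step objective = relevance - MI(copy,copy) << relevance
        assert res.scores["copy2"] < 0.25 * res.scores["copy1"]

    def test_all_noise_table_has_uniformly_low_scores(self):
        rng = np.random.default_rng(9)
        t = pd.DataFrame({f"n{j}": rng.normal(size=400) for j in range(8)})
        t["sbp"] = rng.normal(size=400)
        t["dbp"] = rng.normal(size=400)
        res = mrmr_rank(t, "sbp")
        assert res.scores[res.ranking[0]] < 0.2

    def test_column_order_does_not_change_selection(self):
        t = planted_table(n=200, n_features=10, seed=10)
        res1 = mrmr_rank(t, "sbp")
        res2 = mrmr_rank(t[list(t.columns[::-1])], "sbp")
        assert res1.ranking == res2.ranking

    def test_f_statistic_variant_also_finds_signal(self):
        res = mrmr_rank(planted_table(n=300, n_features=15, seed=11), "sbp",
                        relevance="f")
        assert res.ranking[0] == "signal"


class TestCrossMethod:
    @pytest.mark.parametrize("ranker", [cfs_rank, rrelieff_rank, mrmr_rank])
    def test_affine_feature_rescaling_leaves_ranking_unchanged(self, ranker):
        t = planted_table(n=250, n_features=12, seed=12)
        t2 = t.copy()
        for c in t2.columns:
            if c not in ("sbp", "dbp"):
                t2[c] = -3.0 * t2[c] + 11.0
        assert ranker(t, "sbp").ranking == ranker(t2, "sbp").ranking

    @pytest.mark.parametrize("ranker", [cfs_rank, rrelieff_rank, mrmr_rank])
    def test_planted_signal_recovered_across_seeds(self, ranker):
        hits = 0
        for seed in range(10):
            res = ranker(planted_table(n=300, n_features=25, seed=100 + seed), "sbp")
            hits += res.ranking[0] == "signal"
        assert hits >= 9

    def test_full_ranking_covers_all_features(self):
        t = planted_table(n=200, n_features=10, seed=13)
        nf = 10
        for ranker in (cfs_rank, rrelieff_rank, mrmr_rank):
            res = ranker(t, "sbp")
            assert len(res.ranking) == nf
            assert set(res.scores) == set(res.ranking)


class TestReport:
    def test_k_larger_than_feature_count_gives_full_ranking(self):
        t = planted_table(n=150, n_features=6, seed=14)
        res = cfs_rank(t, "sbp")
        rep = selection_report([res], k=100)
        assert len(rep["topk"]) == 6

    def test_identical_scores_give_full_agreement(self):
        t = planted_table(n=150, n_features=6, seed=15)
        a = cfs_rank(t, "sbp")
        b = cfs_rank(t, "sbp")
        b.method = "CFS-bis"
        rep = selection_report([a, b], k=3)
        assert rep["agreement"]["sbp"] == sorted(a.ranking[:3])

    def test_planted_feature_in_all_three_methods_topk(self):
        t = planted_table(n=300, n_features=20, seed=16)
        results = [cfs_rank(t, "sbp"), rrelieff_rank(t, "sbp"), mrmr_rank(t, "sbp")]
        rep = selection_report(results, k=5)
        assert "signal" in rep["agreement"]["sbp"]
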
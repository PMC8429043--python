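"""Size factors, NB Wald test, DE filter, ranking, signature rules."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_stats_table
from nanoliver import de, simulate


class TestSizeFactors:
    def test_doubled_sample_hand_computation(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        sf = de.size_factors(counts)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples_are_unit(self):
        counts = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2], "c": [5, 9, 2]})
        assert np.allclose(de.size_factors(counts), 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, (100, 4)), columns=list("abcd"))
        sf = de.size_factors(counts)
        sf_perm = de.size_factors(counts[["c", "a", "d", "b"]])
        assert np.allclose(sf_perm[["a", "b", "c", "d"]], sf)

    def test_no_common_gene_raises(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            de.size_factors(counts)


class TestNbWaldTest:
    def test_scale_invariance_of_log2fc(self, bulk_counts):
        counts, truth, _ = bulk_counts
        groups = ["A"] * 3 + ["B"] * 3
        sf = de.size_factors(counts)
        a = de.nb_wald_test(counts, groups, size_factors_=sf)
        b = de.nb_wald_test(counts * 2, groups, size_factors_=sf * 2)
        assert np.allclose(a["log2fc"], b["log2fc"], atol=1e-9)

    def test_planted_lfc_recovered(self, bulk_counts):
        counts, truth, _ = bulk_counts
        stats = de.nb_wald_test(counts, ["A"] * 3 + ["B"] * 3)
        up = truth.index[(truth["true_log2fc"] == 3.0) & (truth["base_mean"] > 100)]
        assert abs(stats.loc[up, "log2fc"].mean() - 3.0) < 0.3

    def test_null_type_one_error_calibrated(self):
        cfg = simulate.SimulationConfig(seed=21, n_genes=5000, de_fraction=0.0)
        counts, _, _ = simulate.simulate_counts_bulk(cfg)
        stats = de.nb_wald_test(counts, ["A"] * 3 + ["B"] * 3)
        rate = (stats["p"] < 0.05).mean()
        assert 0.03 < rate < 0.07

    def test_all_zero_genes_excluded_with_warning(self, bulk_counts):
        counts, _, _ = bulk_counts
        counts = counts.copy()
        counts.iloc[0] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            stats = de.nb_wald_test(counts, ["A"] * 3 + ["B"] * 3)
        assert counts.index[0] not in stats.index

    def test_padj_dominates_p_and_matches_bh_oracle(self, bulk_counts):
        counts, _, _ = bulk_counts
        stats = de.nb_wald_test(counts.iloc[:300], ["A"] * 3 + ["B"] * 3)
        p = stats["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        running_min = 1.0
        for rank_from_last, i in enumerate(order[::-1]):
            rank = m - rank_from_last
            running_min = min(running_min, p[i] * m / rank)
            brute[i] = running_min
        assert np.allclose(stats["padj"], brute, atol=1e-12)
        assert (stats["padj"] >= stats["p"] - 1e-15).all()


class TestFilterDe:
    @pytest.mark.parametrize(
        "base_mean,padj,l2fc,direction",
        [
            (50.0, 0.001, 3.0, None),  # baseMean not > 50
            (51.0, 0.01, 3.0, None),  # FDR not < 0.01
            (51.0, 0.001, 2.0, None),  # |l2fc| not > 2
            (51.0, 0.001, -2.5, "down"),
            (51.0, 0.001, 2.5, "up"),
        ],
    )
    def test_strict_inequalities(self, base_mean, padj, l2fc, direction):
        tab = pd.DataFrame(
            {"baseMean": [base_mean], "log2fc": [l2fc], "padj": [padj], "p": [padj / 2]},
            index=["g"],
        )
        up, down = de.filter_de(tab)
        expected_up = {"g"} if direction == "up" else set()
        expected_down = {"g"} if direction == "down" else set()
        assert (up, down) == (expected_up, expected_down)

    def test_anti_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        tab = random_stats_table(rng, 500)
        loose = set().union(*de.filter_de(tab, 10, 0.5, 0.5))
        tight = set().union(*de.filter_de(tab, 100, 0.05, 2.5))
        assert tight <= loose


class TestTopN:
    def test_returns_all_when_fewer_than_n(self):
        rng = np.random.default_rng(4)
        tab = random_stats_table(rng, 10)
        up = tab.index[tab["log2fc"] > 0]
        assert len(de.top_n(tab, "up", 500)) == len(up)

    def test_tie_break_prefers_larger_effect(self):
        tab = pd.DataFrame(
            {"baseMean": 100.0, "log2fc": [3.0, 4.0], "p": 0.001, "padj": [0.01, 0.01]},
            index=["gA", "gB"],
        )
        assert de.top_n(tab, "up", 2) == ["gB", "gA"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(5)
        tab = random_stats_table(rng, 50)
        got = de.top_n(tab, "up", 20)
        sub = tab[tab["log2fc"] > 0]
        brute = sorted(sub.index, key=lambda g: (sub.loc[g, "padj"], -abs(sub.loc[g, "log2fc"]), g))
        assert got == brute[:20]


def _stats_from_sets(up, down, filler=0):
    """A stats table where exactly `up`/`down` pass the DE filter."""
    genes = list(up) + list(down) + [f"null{i}" for i in range(filler)]
    n_pass = len(up) + len(down)
    return pd.DataFrame(
        {
            "baseMean": [100.0] * n_pass + [10.0] * filler,
            "log2fc": [3.0] * len(up) + [-3.0] * len(down) + [0.1] * filler,
            "p": 1e-6,
            "padj": [1e-4] * n_pass + [0.5] * filler,
        },
        index=genes,
    )


class TestSignatures:
    def test_hepatocyte_intersection_identity_and_disjoint(self):
        up = [f"u{i}" for i in range(40)]
        down = [f"d{i}" for i in range(30)]
        tab = _stats_from_sets(up, down, filler=20)
        sig = de.build_hepatocyte_signature(tab, tab, n=500)
        assert sig.up_genes == set(up) and sig.down_genes == set(down)
        other = _stats_from_sets([f"x{i}" for i in range(10)], [])
        assert de.build_hepatocyte_signature(tab, other).size == 0

    def test_hepatocyte_planted_overlap_size(self):
        shared_up = [f"su{i}" for i in range(120)]
        shared_down = [f"sd{i}" for i in range(80)]
        t1 = _stats_from_sets(shared_up + ["a1", "a2"], shared_down + ["a3"])
        t2 = _stats_from_sets(shared_up + ["b1"], shared_down + ["b2", "b3"])
        sig = de.build_hepatocyte_signature(t1, t2, n=500)
        assert sig.size == 200

    def test_hcc_asymmetric_cap(self):
        tab = _stats_from_sets([f"u{i}" for i in range(700)], [f"d{i}" for i in range(90)])
        sig = de.build_hcc_signature(tab)
        assert len(sig.up_genes) == 500
        assert len(sig.down_genes) == 90  # uncapped

    def test_hcc_empty_warns(self):
        tab = _stats_from_sets([], [], filler=5)
        with pytest.warns(UserWarning):
            sig = de.build_hcc_signature(tab)
        assert sig.size == 0

    def test_consensus_three_of_five(self):
        studies = [
            ({"a", "b"}, {"z"}),
            ({"a"}, {"z", "y"}),
            ({"a", "c"}, set()),
            (set(), {"z"}),
            ({"b"}, {"y"}),
        ]
        sig = de.consensus_signature(studies, k=3)
        assert sig.up_genes == {"a"} and sig.down_genes == {"z"}

    def test_consensus_conflict_excluded(self):
        studies = [({"g"}, set()), ({"g"}, set()), ({"g"}, {"g"}), (set(), {"g"}), (set(), {"g"})]
        sig = de.consensus_signature(studies, k=3)
        assert sig.size == 0 and sig.provenance["both_directions"] == ["g"]

    def test_consensus_degenerate_k_and_invalid_k(self):
        studies = [({"a"}, set()), ({"b"}, {"c"})]
        sig = de.consensus_signature(studies, k=1)
        assert sig.up_genes == {"a", "b"} and sig.down_genes == {"c"}
        with pytest.raises(ValueError):
            de.consensus_signature(studies, k=3)

    def test_signatures_order_invariant(self):
        rng = np.random.default_rng(6)
        tab = random_stats_table(rng, 100)
        shuffled = tab.sample(frac=1, random_state=1)
        a = de.build_hcc_signature(tab, min_base_mean=10, max_fdr=0.5, min_abs_l2fc=1)
        b = de.build_hcc_signature(shuffled, min_base_mean=10, max_fdr=0.5, min_abs_l2fc=1)
        assert a.up_genes == b.up_genes and a.down_genes == b.down_genes


class TestPipelineRecovery:
    def test_planted_de_recovered_and_nulls_excluded(self):
        """With 3v3 and |log2FC|=3 at high expression, nearly all planted
        genes pass the filter and nearly all nulls are excluded."""
        hits = []
        false = []
        for seed in range(10):
            cfg = simulate.SimulationConfig(
                seed=100 + seed, n_genes=800, de_fraction=0.1, lfc_scale=3.0
            )
            counts, truth, _ = simulate.simulate_counts_bulk(cfg)
            stats = de.nb_wald_test(counts, ["A"] * 3 + ["B"] * 3)
            up, down = de.filter_de(stats)
            passing = up | down
            planted = set(truth.index[truth["is_de"] & (truth["base_mean"] >= 300)])
            nulls = set(truth.index[~truth["is_de"]])
            hits.append(len(passing & planted) / max(len(planted), 1))
            false.append(len(passing & nulls) / max(len(nulls), 1))
        assert np.mean(hits) >= 0.90
        assert 1 - np.mean(false) >= 0.99
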
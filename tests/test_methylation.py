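"""Context classification, emission model, calling, filtering, smoothing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoliver import methylation as me
from nanoliver import simulate


def oracle_context(prev: str, nxt: str) -> str:
    """Lookup-table oracle over the 16 flank pairs."""
    table = {
        (True, True): "GCG",
        (True, False): "GCH",
        (False, True): "HCG",
        (False, False): "HCH",
    }
    return table[(prev == "G", nxt == "G")]


class TestClassifyContext:
    def test_plus_strand_examples(self):
        assert me.classify_context("AAGCAAA", 3, "+") == "GCH"
        assert me.classify_context("AAGCGAA", 3, "+") == "GCG"

    def test_minus_strand_reads_its_own_five_prime(self):
        # revcomp of AAGCAAA is TTTGCTT: the C at reference pos 2 has G
        # before and T after on the minus strand
        assert me.classify_context("AAGCAAA", 2, "-") == "GCH"

    def test_exhaustive_flanks_both_strands(self):
        for prev in "ACGT":
            for nxt in "ACGT":
                seq = f"A{prev}C{nxt}A"
                assert me.classify_context(seq, 2, "+") == oracle_context(prev, nxt)
                # same site on the minus strand of the reverse complement
                rc = me.revcomp(seq)
                pos_rc = len(seq) - 1 - 2
                assert me.classify_context(rc, pos_rc, "-") == oracle_context(prev, nxt)

    def test_non_cytosine_raises(self):
        with pytest.raises(ValueError):
            me.classify_context("AAGAAAA", 3, "+")

    def test_edge_position_is_no_context(self):
        assert me.classify_context("CAA", 0, "+") is None
        assert me.classify_context("AAC", 2, "+") is None

    @given(st.text(alphabet="ACGT", min_size=10, max_size=200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_strand_symmetric_site_catalog(self, seq):
        counts = me.catalog_sites(seq)["context"].value_counts()
        counts_rc = me.catalog_sites(me.revcomp(seq))["context"].value_counts()
        assert counts.to_dict() == counts_rc.to_dict()


class TestEmissionModel:
    def test_sample_moments(self):
        events = pd.DataFrame(
            {
                "kmer": ["AACGTT"] * 6,
                "signal": [99.0, 100.0, 101.0, 103.0, 104.0, 105.0],
                "label": ["unmeth"] * 3 + ["meth"] * 3,
            }
        )
        model = me.train_emission_model(events, min_events=3)
        row = model.table.loc["AACGTT"]
        assert row["mean_unmeth"] == pytest.approx(100.0)
        assert row["mean_meth"] == pytest.approx(104.0)

    def test_sparse_kmer_omitted_and_reported(self):
        events = pd.DataFrame(
            {"kmer": ["AACGTT"] * 10, "signal": np.arange(10.0), "label": ["meth", "unmeth"] * 5}
        )
        model = me.train_emission_model(events, min_events=20)
        assert "AACGTT" not in model
        assert model.omitted == ["AACGTT"]

    def test_parameter_recovery_within_clt_band(self):
        events = simulate.simulate_emission_events(
            ["AACGTA", "GGCGTT"], n_per_label=1000, shift=4.0, sd=2.0, seed=3
        )
        model = me.train_emission_model(events)
        for kmer, sub in events.groupby("kmer"):
            for label, col in (("unmeth", "mean_unmeth"), ("meth", "mean_meth")):
                truth = sub[sub["label"] == label]["true_mean"].iloc[0]
                sd = sub[sub["label"] == label]["true_sd"].iloc[0]
                assert abs(model.table.loc[kmer, col] - truth) < 3 * sd / math.sqrt(1000)


class TestScoreSite:
    @pytest.fixture()
    def toy_model(self):
        table = pd.DataFrame(
            {
                "mean_unmeth": [100.0],
                "sd_unmeth": [2.0],
                "mean_meth": [104.0],
                "sd_meth": [2.0],
                "n_unmeth": [100],
                "n_meth": [100],
            },
            index=pd.Index(["AACGTT"], name="kmer"),
        )
        return me.EmissionModel(table=table)

    def test_closed_form_gaussian_difference(self, toy_model):
        assert me.score_site([("AACGTT", 103.0)], toy_model) == pytest.approx(1.0)

    def test_midpoint_symmetry_and_additivity(self, toy_model):
        assert me.score_site([("AACGTT", 102.0)], toy_model) == pytest.approx(0.0)
        one = me.score_site([("AACGTT", 103.0)], toy_model)
        two = me.score_site([("AACGTT", 103.0)] * 2, toy_model)
        assert two == pytest.approx(2 * one)

    def test_missing_kmer_skipped_with_count(self, toy_model):
        llr, n_used, n_skipped = me.score_site_detailed(
            [("AACGTT", 103.0), ("TTTTTT", 50.0)], toy_model
        )
        assert (llr, n_used, n_skipped) == (pytest.approx(1.0), 1, 1)


class TestCallMethylation:
    @pytest.mark.parametrize(
        "llr,expected",
        [(3.1, "methylated"), (2.0, "methylated"), (-2.0, "unmethylated"), (1.9, "ambiguous"), (-1.9, "ambiguous")],
    )
    def test_threshold_with_inclusive_boundary(self, llr, expected):
        assert me.call_methylation(llr, 2.0) == expected

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            me.call_methylation(1.0, 0.0)


def _read_calls(read_id, n_gc, n_meth, offset=0):
    """A read with n_gc GC-context calls, the first n_meth methylated."""
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "strand": "+",
            "pos": np.arange(n_gc) * 10 + offset,
            "context": "GCH",
            "read_id": read_id,
            "llr": np.where(np.arange(n_gc) < n_meth, 5.0, -5.0),
            "call": np.where(np.arange(n_gc) < n_meth, "methylated", "unmethylated"),
        }
    )


class TestContaminantFilter:
    @pytest.mark.parametrize(
        "n_gc,n_meth,dropped",
        [
            (80, 60, True),  # exactly ceil(0.75*80) methylated -> dropped
            (80, 59, False),
            (79, 79, False),  # fewer than 80 GC sites: no qualifying window
            (200, 200, True),
        ],
    )
    def test_window_boundaries(self, n_gc, n_meth, dropped):
        calls = _read_calls("r0", n_gc, n_meth)
        kept, out = me.filter_contaminant_reads(calls)
        assert (len(out) == 1) == dropped

    def test_ambiguous_calls_do_not_occupy_window_slots(self):
        # 59 methylated + 21 ambiguous + 20 unmethylated GC calls: only 79
        # definite calls, so no 80-site window exists
        calls = _read_calls("r0", 100, 59)
        calls.loc[59:79, "call"] = "ambiguous"
        kept, out = me.filter_contaminant_reads(calls)
        assert out == []

    def test_filter_only_changes_read_membership(self, small_methylome):
        cfg = simulate.SimulationConfig(seed=8, coverage=8, contamination_fraction=0.2)
        calls, _ = simulate.simulate_call_table(small_methylome, cfg)
        called = me.call_table(calls)
        kept, dropped = me.filter_contaminant_reads(called)
        manual = called[~called["read_id"].isin(dropped)]
        agg_a = me.aggregate_sites(kept).set_index(["chrom", "pos", "strand"])
        agg_b = me.aggregate_sites(manual).set_index(["chrom", "pos", "strand"])
        pd.testing.assert_frame_equal(agg_a, agg_b)

    def test_truth_recovery_on_simulated_contamination(self, small_methylome):
        cfg = simulate.SimulationConfig(seed=8, coverage=10, contamination_fraction=0.2)
        calls, read_truth = simulate.simulate_call_table(small_methylome, cfg)
        kept, dropped = me.filter_contaminant_reads(me.call_table(calls))
        truth = set(read_truth[read_truth["contaminant"]]["read_id"])
        assert set(dropped) == truth


class TestAggregateSites:
    def test_proportion_and_coverage_rules(self):
        calls = pd.DataFrame(
            {
                "chrom": "chr1",
                "strand": "+",
                "pos": [10] * 4 + [20] * 3 + [30] * 5,
                "context": "GCH",
                "read_id": [f"r{i}" for i in range(12)],
                "call": ["methylated"] * 3
                + ["unmethylated"]
                + ["methylated"] * 2
                + ["unmethylated"]
                + ["methylated", "ambiguous", "unmethylated", "unmethylated", "methylated"],
            }
        )
        out = me.aggregate_sites(calls, min_coverage=4).set_index("pos")
        assert out.loc[10, "proportion"] == pytest.approx(0.75)
        assert 20 not in out.index  # coverage 3 < 4
        assert out.loc[30, "n_meth"] + out.loc[30, "n_unmeth"] == 4  # ambiguous dropped
        assert out.loc[30, "proportion"] == pytest.approx(0.5)


def smoothing_oracle(x, width=5):
    h = (width - 1) // 2
    w = np.array([h + 1 - abs(k) for k in range(-h, h + 1)], float)
    out = np.empty(len(x))
    for i in range(len(x)):
        num = den = 0.0
        for k in range(-h, h + 1):
            j = i + k
            if 0 <= j < len(x):
                num += w[k + h] * x[j]
                den += w[k + h]
        out[i] = num / den
    return out


class TestSmoothing:
    def test_impulse_response(self):
        out = me.smooth_levels([0, 0, 1, 0, 0])
        assert np.allclose(out, [1 / 6, 2 / 8, 3 / 9, 2 / 8, 1 / 6])

    def test_constant_and_singleton_fixed_points(self):
        assert np.allclose(me.smooth_levels([0.4] * 7), 0.4)
        assert np.allclose(me.smooth_levels([0.9]), [0.9])

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            me.smooth_levels([0.1, 0.2], width=4)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
        st.sampled_from([1, 3, 5, 7]),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_renormalized_convolution_oracle(self, x, width):
        out = me.smooth_levels(x, width)
        assert np.allclose(out, smoothing_oracle(x, width), atol=1e-12)
        assert out.min() >= min(x) - 1e-12 and out.max() <= max(x) + 1e-12


class TestPromoterProfile:
    def _summaries(self, positions, contexts, props):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "strand": "+",
                "context": contexts,
                "n_meth": 4,
                "n_unmeth": 4,
                "proportion": props,
            }
        )

    def test_inclusive_flank_boundary(self):
        summ = self._summaries([8499, 8500, 11500, 11501], ["GCH"] * 4, [1.0, 0.0, 0.0, 1.0])
        tss = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "tss": [10000]})
        prof = me.promoter_profile(summ, tss, flank=1500)
        assert prof.loc[0, "n_gch_sites"] == 2  # 8500 and 11500 only
        assert prof.loc[0, "mean_gch_level"] == pytest.approx(0.0)

    def test_context_means_and_missing_context(self):
        summ = self._summaries([100, 200, 300], ["GCH", "GCH", "GCG"], [0.2, 0.4, 0.9])
        tss = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "tss": [200]})
        prof = me.promoter_profile(summ, tss, flank=1500)
        assert prof.loc[0, "mean_gch_level"] == pytest.approx(0.3)
        assert np.isnan(prof.loc[0, "mean_hcg_level"])  # GCG excluded, no HCG sites

    def test_open_promoters_beat_background(self, small_genome, small_methylome):
        cfg = simulate.SimulationConfig(seed=4, coverage=15, contamination_fraction=0.0)
        calls, _ = simulate.simulate_call_table(small_methylome, cfg)
        summ = me.aggregate_sites(me.call_table(calls))
        gch = summ[summ["context"] == "GCH"]
        in_prom = np.zeros(len(gch), bool)
        for s, e in small_genome.promoters:
            in_prom |= (gch["pos"] >= s) & (gch["pos"] < e)
        assert gch[in_prom]["proportion"].mean() > gch[~in_prom]["proportion"].mean()
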
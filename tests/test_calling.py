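import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methyltsg.calling import (
    CALL_AMBIG,
    CALL_METH,
    CALL_UNMETH,
    aggregate_nanopore_frequency,
    bisulfite_frequency,
    call_reads,
    call_site,
    platform_spearman,
    score_site_llr,
)
from methyltsg.genome import generate_toy_genome
from methyltsg.simulate import assign_landscape, simulate_nanopore_events
from methyltsg.sixmer import SixMerModel, methylated_variant


def two_kmer_model(mu_c=8.0, mu_m=10.0, sd=1.0):
    """Minimal model with a single CpG 6-mer pair."""
    return SixMerModel({"AACGTT": (mu_c, sd), "AAMGTT": (mu_m, sd)})


class TestScoreSiteLlr:
    def test_identical_models_give_zero(self):
        m = two_kmer_model(mu_c=9.0, mu_m=9.0)
        assert score_site_llr([(0, 7.3), (0, 11.0)], m) == pytest.approx(0.0)

    def test_hand_computed_single_event(self):
        # x = mu_M = 10, mu_C = 8, sd = 1: llr = 0 - (-(10-8)^2/2) = 2.0
        m = two_kmer_model()
        assert score_site_llr([(0, 10.0)], m) == pytest.approx(2.0)

    def test_swapping_model_entries_negates_llr_exactly(self):
        m = two_kmer_model(mu_c=8.0, mu_m=11.5, sd=2.0)
        swapped = SixMerModel({"AACGTT": (11.5, 2.0), "AAMGTT": (8.0, 2.0)})
        for x in (-3.0, 0.0, 9.1, 20.0):
            events = [(0, x), (0, x + 1.0)]
            assert score_site_llr(events, m) == pytest.approx(
                -score_site_llr(events, swapped)
            )

    def test_empty_event_list_errors(self):
        with pytest.raises(ValueError, match="no events"):
            score_site_llr([], two_kmer_model())

    def test_matches_scipy_logpdf_sum(self):
        m = two_kmer_model(mu_c=100.0, mu_m=104.0, sd=2.0)
        xs = [98.0, 103.0, 101.5]
        expected = sum(
            stats.norm.logpdf(x, 104.0, 2.0) - stats.norm.logpdf(x, 100.0, 2.0) for x in xs
        )
        assert score_site_llr([(0, x) for x in xs], m) == pytest.approx(expected)


class TestCallSite:
    @pytest.mark.parametrize(
        "llr,expected",
        [
            (2.5, CALL_METH),  # boundary inclusive at the published threshold
            (-2.5, CALL_UNMETH),
            (-3.0, CALL_UNMETH),
            (0.4, CALL_AMBIG),
            (2.499, CALL_AMBIG),
            (7.0, CALL_METH),
        ],
    )
    def test_threeway_decision(self, llr, expected):
        assert call_site(llr, 2.5) == expected

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            call_site(1.0, 0.0)

    def test_raising_threshold_never_adds_methylated_calls(self):
        rng = np.random.default_rng(0)
        llrs = rng.normal(0, 4, 500)
        counts = [
            sum(call_site(l, t) == CALL_METH for l in llrs) for t in (1.0, 2.5, 4.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCallReads:
    def test_vectorised_matches_scalar_path(self, model):
        g = generate_toy_genome(1, 40_000, 2, 0.002, seed=1)
        land = assign_landscape(g, (0.5, 0.5, 0.0), seed=0)
        ev = simulate_nanopore_events(land, g, model, 3.0, seed=2)
        calls = call_reads(ev, model, 2.5)
        grouped = ev.groupby(["read_id", "chrom", "pos"])
        sample = calls.sample(20, random_state=0)
        for row in sample.itertuples():
            events = grouped.get_group((row.read_id, row.chrom, row.pos))
            scalar = score_site_llr(
                list(zip(events["kmer_index"], events["current"])), model
            )
            assert row.llr == pytest.approx(scalar, rel=1e-9, abs=1e-9)

    def test_unknown_kmer_index_errors(self, model):
        ev = pd.DataFrame(
            {"read_id": [0], "chrom": ["chr1"], "pos": [5], "kmer_index": [4096],
             "current": [100.0]}
        )
        with pytest.raises(KeyError, match="4096"):
            call_reads(ev, model)


class TestAggregation:
    @staticmethod
    def make_calls(n_meth, n_unmeth, n_ambig):
        rows = (
            [(i, "chr1", 10, 5.0, CALL_METH) for i in range(n_meth)]
            + [(100 + i, "chr1", 10, -5.0, CALL_UNMETH) for i in range(n_unmeth)]
            + [(200 + i, "chr1", 10, 0.0, CALL_AMBIG) for i in range(n_ambig)]
        )
        return pd.DataFrame(rows, columns=["read_id", "chrom", "pos", "llr", "call"])

    def test_ambiguous_calls_excluded_from_both_counts(self):
        rec = aggregate_nanopore_frequency(self.make_calls(10, 0, 3))
        assert rec.loc[0, "coverage"] == 10
        assert rec.loc[0, "methylated"] == 10
        assert rec.loc[0, "frequency"] == 1.0

    def test_half_and_half(self):
        rec = aggregate_nanopore_frequency(self.make_calls(2, 2, 0))
        assert rec.loc[0, "frequency"] == 0.5

    def test_all_ambiguous_site_kept_with_zero_coverage(self):
        rec = aggregate_nanopore_frequency(self.make_calls(0, 0, 4))
        assert rec.loc[0, "coverage"] == 0
        assert np.isnan(rec.loc[0, "frequency"])


class TestBisulfiteFrequency:
    @staticmethod
    def table(rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "methylated_count", "total_count",
                           "platform"]
        )

    def test_minimum_coverage_rule(self):
        t = self.table([("chr1", 5, "+", 2, 4, "wgbs"), ("chr1", 9, "+", 5, 5, "wgbs")])
        rec = bisulfite_frequency(t, min_coverage=5)
        assert list(rec["pos"]) == [9]  # 4-read site dropped: fewer than five reads
        assert rec.loc[0, "frequency"] == 1.0

    def test_frequency_arithmetic(self):
        t = self.table([("chr1", 5, "+", 2, 8, "wgbs")])
        rec = bisulfite_frequency(t, min_coverage=5)
        assert rec.loc[0, "frequency"] == 0.25

    def test_invalid_counts_rejected(self):
        t = self.table([("chr1", 5, "+", 9, 8, "wgbs")])
        with pytest.raises(ValueError, match="exceeds"):
            bisulfite_frequency(t)


def _records(freqs, coverage=10):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(len(freqs)),
            "strand": "+",
            "platform": "x",
            "coverage": coverage,
            "methylated": (np.asarray(freqs) * coverage).astype(int),
            "frequency": freqs,
        }
    )


class TestPlatformSpearman:
    def test_identity_and_reversal(self):
        a = _records([0.1, 0.3, 0.5, 0.7, 0.9])
        assert platform_spearman(a, a) == pytest.approx(1.0)
        b = _records([0.9, 0.7, 0.5, 0.3, 0.1])
        assert platform_spearman(a, b) == pytest.approx(-1.0)

    def test_matches_brute_force_rank_formula_with_ties(self):
        fa = [0.1, 0.4, 0.4, 0.7, 0.2, 0.9]
        fb = [0.2, 0.5, 0.3, 0.8, 0.8, 0.6]

        def avg_ranks(v):
            v = np.asarray(v)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), float)
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        ra, rb = avg_ranks(fa), avg_ranks(fb)
        expected = np.corrcoef(ra, rb)[0, 1]  # Pearson on average ranks
        assert platform_spearman(_records(fa), _records(fb)) == pytest.approx(expected)

    def test_too_few_shared_sites(self):
        a = _records([0.1, 0.2])
        with pytest.raises(ValueError, match="shared sites"):
            platform_spearman(a, a)

    def test_coverage_filter_applies_to_both_sides(self):
        a = _records([0.1, 0.2, 0.3, 0.4], coverage=10)
        b = _records([0.1, 0.2, 0.3, 0.4], coverage=4)
        with pytest.raises(ValueError):
            platform_spearman(a, b, min_coverage=5)


def test_llr_calibration_on_simulated_methylated_sites(model):
    """E[LLR | methylated] = sum over CpG events of (mu_M - mu_C)^2 / (2 sd^2);
    the Monte-Carlo mean must sit within 3 standard errors."""
    g = generate_toy_genome(1, 500_000, 0, 0.004, seed=3)
    land = assign_landscape(g, (0.0, 1.0, 0.0), p_out=0.0, p_background=1.0, seed=0)
    ev = simulate_nanopore_events(land, g, model, 2.0, seed=4)
    calls = call_reads(ev, model, 2.5)

    mu_c, sd_c, mu_m, _ = model.param_arrays()
    per_event = (mu_m - mu_c) ** 2 / (2 * sd_c**2)
    exp_by_site = (
        ev.assign(e=per_event[ev["kmer_index"].to_numpy()])
        .groupby(["read_id", "chrom", "pos"], sort=False)["e"]
        .sum()
        .reset_index(name="expected")
    )
    merged = calls.merge(exp_by_site, on=["read_id", "chrom", "pos"])
    resid = merged["llr"] - merged["expected"]
    se = resid.std() / np.sqrt(len(resid))
    assert len(resid) > 2000
    assert abs(resid.mean()) < 3 * se
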
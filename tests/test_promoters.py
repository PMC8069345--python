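import numpy as np
import pandas as pd
import pytest

from methyltsg.genome import PromoterRecord
from methyltsg.promoters import (
    HYPER,
    HYPO,
    PromoterProfile,
    assign_sites_to_promoters,
    build_profiles,
    collapse_to_genes,
    kmeans_classify,
    select_hypermethylated_sites,
    tss_metaplot,
)


def records(rows):
    """rows: (chrom, pos, frequency[, coverage])"""
    df = pd.DataFrame(
        [(r[0], r[1], "+", "nanopore", r[3] if len(r) > 3 else 10, 0, r[2]) for r in rows],
        columns=["chrom", "pos", "strand", "platform", "coverage", "methylated", "frequency"],
    )
    return df


PLUS = PromoterRecord("P1", "G1", "chr1", 10_000, "+", 1000, 500)
MINUS = PromoterRecord("P2", "G2", "chr1", 50_000, "-", 1000, 500)


class TestAssignment:
    def test_site_at_tss_assigned(self):
        m = assign_sites_to_promoters(records([("chr1", 10_000, 0.5)]), [PLUS])
        assert list(m["P1"]) == [0]

    def test_downstream_boundary_is_half_open(self):
        m = assign_sites_to_promoters(
            records([("chr1", 10_499, 0.5), ("chr1", 10_500, 0.5)]), [PLUS]
        )
        assert list(m["P1"]) == [0]

    def test_upstream_boundary_inclusive(self):
        m = assign_sites_to_promoters(
            records([("chr1", 9_000, 0.5), ("chr1", 8_999, 0.5)]), [PLUS]
        )
        assert list(m["P1"]) == [0]

    def test_minus_strand_mirror(self):
        # on the minus strand, downstream means smaller coordinates:
        # offset d = tss - pos, window -1000 <= d < 500
        m = assign_sites_to_promoters(
            records(
                [
                    ("chr1", 49_501, 0.5),  # d = 499: assigned
                    ("chr1", 49_500, 0.5),  # d = 500: excluded (half-open)
                    ("chr1", 51_000, 0.5),  # d = -1000: assigned (upstream edge)
                    ("chr1", 51_001, 0.5),  # d = -1001: excluded
                ]
            ),
            [MINUS],
        )
        assert list(m["P2"]) == [0, 2]

    def test_shared_site_belongs_to_both_overlapping_promoters(self):
        other = PromoterRecord("P3", "G3", "chr1", 10_200, "+", 1000, 500)
        m = assign_sites_to_promoters(records([("chr1", 10_100, 0.5)]), [PLUS, other])
        assert list(m["P1"]) == [0] and list(m["P3"]) == [0]

    def test_unknown_chromosome_warns_and_skips(self):
        with pytest.warns(UserWarning, match="unknown chromosome"):
            m = assign_sites_to_promoters(records([("chrZ", 10_000, 0.5)]), [PLUS])
        assert len(m["P1"]) == 0


class TestHypermethylatedSelection:
    def test_strictly_greater_than_fifty_percent(self):
        recs = records([("chr1", 1, 0.50), ("chr1", 2, 0.51), ("chr1", 3, 0.49)])
        assert list(select_hypermethylated_sites(recs)["pos"]) == [2]

    def test_empty_input(self):
        assert select_hypermethylated_sites(records([])).empty


class TestProfiles:
    def test_all_or_none_hypermethylated(self):
        recs = records([("chr1", 9_500 + 100 * i, 0.9) for i in range(10)])
        m = assign_sites_to_promoters(recs, [PLUS])
        (prof,) = build_profiles(m, recs, [PLUS])
        assert np.allclose(prof.feature, 1.0)
        low = records([("chr1", 9_500 + 100 * i, 0.1) for i in range(10)])
        (prof,) = build_profiles(assign_sites_to_promoters(low, [PLUS]), low, [PLUS])
        assert np.allclose(prof.feature, 0.0)

    def test_empty_bins_imputed_with_promoter_mean(self):
        # 4 sites in one 75-bp bin (window 1500/20 bins): half hypermethylated
        recs = records(
            [("chr1", 9_010, 0.9), ("chr1", 9_020, 0.9), ("chr1", 9_030, 0.1),
             ("chr1", 9_040, 0.1)]
        )
        m = assign_sites_to_promoters(recs, [PLUS])
        (prof,) = build_profiles(m, recs, [PLUS], n_bins=20, min_sites=3)
        assert np.allclose(prof.feature, 0.5)
        assert prof.n_sites == 4 and prof.classifiable

    def test_min_sites_marks_unclassifiable(self):
        recs = records([("chr1", 9_500, 0.9), ("chr1", 9_600, 0.9)])
        m = assign_sites_to_promoters(recs, [PLUS])
        (prof,) = build_profiles(m, recs, [PLUS], min_sites=3)
        assert not prof.classifiable

    def test_zero_coverage_sites_ignored(self):
        recs = records([("chr1", 9_500, np.nan, 0), ("chr1", 9_600, 0.9)])
        m = assign_sites_to_promoters(recs, [PLUS])
        (prof,) = build_profiles(m, recs, [PLUS], min_sites=1)
        assert prof.n_sites == 1
        assert prof.mean_frequency == pytest.approx(0.9)


def planted_profiles(n_hyper=30, n_hypo=30, seed=0, noise=0.03):
    rng = np.random.default_rng(seed)
    profs, truth = [], {}
    for i in range(n_hyper + n_hypo):
        hyper = i < n_hyper
        mean = 0.9 if hyper else 0.05
        feat = np.clip(rng.normal(mean, noise, 20), 0, 1)
        pid = f"P{i:03d}"
        profs.append(PromoterProfile(pid, f"G{i:03d}", 10, feat, mean, 10.0, True))
        truth[pid] = HYPER if hyper else HYPO
    return profs, truth


class TestKMeans:
    def test_planted_separation_recovered_exactly(self):
        profs, truth = planted_profiles()
        cls = kmeans_classify(profs, seed=1)
        assert cls.labels == truth
        assert cls.centroid_means[HYPER] > cls.centroid_means[HYPO]

    def test_deterministic_across_reruns(self):
        profs, _ = planted_profiles(seed=3)
        a = kmeans_classify(profs, seed=7)
        b = kmeans_classify(profs, seed=7)
        assert a.labels == b.labels

    def test_label_invariance_under_input_permutation(self):
        profs, _ = planted_profiles(seed=4)
        cls = kmeans_classify(profs, seed=2)
        rng = np.random.default_rng(0)
        shuffled = list(profs)
        rng.shuffle(shuffled)
        assert kmeans_classify(shuffled, seed=2).labels == cls.labels

    def test_duplicates_get_identical_labels(self):
        profs, _ = planted_profiles(n_hyper=5, n_hypo=5, seed=5)
        doubled = profs + [
            PromoterProfile(p.promoter_id + "d", p.gene, p.n_sites, p.feature,
                            p.mean_frequency, p.read_depth, True)
            for p in profs
        ]
        cls = kmeans_classify(doubled, seed=0)
        for p in profs:
            assert cls.labels[p.promoter_id] == cls.labels[p.promoter_id + "d"]

    def test_degenerate_identical_profiles(self):
        feat = np.full(20, 0.8)
        profs = [PromoterProfile(f"P{i}", f"G{i}", 5, feat, 0.8, 5.0, True) for i in range(4)]
        with pytest.warns(UserWarning, match="identical"):
            cls = kmeans_classify(profs)
        assert cls.degenerate and set(cls.labels.values()) == {HYPER}

    def test_too_few_profiles(self):
        profs, _ = planted_profiles(n_hyper=1, n_hypo=0)
        with pytest.raises(ValueError, match="at least 2"):
            kmeans_classify(profs)


class TestCollapse:
    def test_any_promoter_or_logic_and_counts(self):
        p1 = PromoterRecord("P1", "G1", "chr1", 10_000, "+")
        p2 = PromoterRecord("P2", "G1", "chr1", 20_000, "+")
        p3 = PromoterRecord("P3", "G2", "chr1", 30_000, "+")
        from methyltsg.promoters import PromoterClassification

        cls = PromoterClassification({"P1": HYPER, "P2": HYPO, "P3": HYPO}, {})
        genes, n_prom = collapse_to_genes(cls, [p1, p2, p3])
        assert genes == {"G1"} and n_prom == 1

    def test_no_hyper_promoters(self):
        from methyltsg.promoters import PromoterClassification

        p = PromoterRecord("P1", "G1", "chr1", 10_000, "+")
        genes, n = collapse_to_genes(PromoterClassification({"P1": HYPO}, {}), [p])
        assert genes == set() and n == 0

    def test_gene_count_never_exceeds_promoter_count(self, default_result):
        for platform in ("nanopore", "wgbs", "epic"):
            genes = default_result.cluster.gene_sets[platform]
            n_prom = default_result.cluster.promoter_counts[platform]
            assert len(genes) <= n_prom


class TestMetaplot:
    def test_uniform_landscape_is_flat(self):
        recs = records([("chr1", p, 0.7) for p in range(8_000, 12_000, 25)])
        meta = tss_metaplot(recs, [PLUS], span=2000, n_bins=40)
        filled = meta.dropna(subset=["mean_frequency"])
        assert np.allclose(filled["mean_frequency"], 0.7)

    def test_planted_dip_at_tss(self):
        rows = []
        for p in range(8_000, 12_000, 20):
            inside = -1000 <= p - PLUS.tss < 500
            rows.append(("chr1", p, 0.05 if inside else 0.9))
        meta = tss_metaplot(records(rows), [PLUS], span=2000, n_bins=80)
        center = meta[abs(meta["bin_center"]) <= 400]["mean_frequency"]
        flank = meta[abs(meta["bin_center"]) >= 1600]["mean_frequency"].dropna()
        assert center.max() < flank.min()

    def test_empty_records_all_undefined(self):
        meta = tss_metaplot(records([]), [PLUS])
        assert meta["mean_frequency"].isna().all()
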
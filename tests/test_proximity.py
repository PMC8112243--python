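import numpy as np
import pytest

from hervlink.annotations import AnnotationSet, GeneFeature, GenomicInterval, HervLocus
from hervlink.proximity import (
    ProximityConfig,
    ProximityRecord,
    classify_intersections,
    distance_null_test,
    find_nearest_gene,
    proximity_table,
)
from hervlink.simulate import SimulationConfig, simulate_annotation

from oracles import mannwhitney_exact_oracle


def gene(chrom, start, end, gid, biotype="protein_coding", exons=()):
    return GeneFeature(
        interval=GenomicInterval(chrom, start, end),
        gene_id=gid,
        biotype=biotype,
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exons),
    )


def herv(chrom, start, end, lid="ERV3_1q1.1"):
    return HervLocus(GenomicInterval(chrom, start, end), lid)


class TestFindNearestGene:
    def test_gene_in_first_window_reports_gap(self):
        ann = AnnotationSet(genes=[gene("chr1", 11_200, 12_000, "G1")])
        rec = find_nearest_gene(herv("chr1", 10_000, 11_000), ann)
        assert rec.nearest_gene_id == "G1"
        assert rec.distance_bp == 200
        assert rec.relation == "proximal"

    def test_intronic_when_inside_gene_without_exon_overlap(self):
        g = gene("chr1", 0, 50_000, "G1", exons=[(0, 1000), (40_000, 41_000)])
        ann = AnnotationSet(genes=[g])
        rec = find_nearest_gene(herv("chr1", 10_000, 11_000), ann)
        assert rec.relation == "intronic"
        assert rec.distance_bp == 0
        assert rec.intersected_elements == [("G1", "protein_coding", "intron")]

    def test_exonic_when_any_exon_touches(self):
        g = gene("chr1", 0, 50_000, "G1", exons=[(10_500, 12_000)])
        ann = AnnotationSet(genes=[g])
        rec = find_nearest_gene(herv("chr1", 10_000, 11_000), ann)
        assert rec.relation == "exonic"

    def test_nothing_within_limit(self):
        ann = AnnotationSet(genes=[gene("chr1", 100_000, 110_000, "G1")])
        rec = find_nearest_gene(herv("chr1", 10_000, 11_000), ann)
        assert rec.relation == "none_within_limit"
        assert rec.nearest_gene_id is None

    def test_limit_is_inclusive_of_max_window(self):
        # gap exactly 10 kb: gene starts at herv.end + 10_000
        ann = AnnotationSet(genes=[gene("chr1", 21_000, 22_000, "G1")])
        rec = find_nearest_gene(herv("chr1", 10_000, 11_000), ann)
        assert rec.relation == "proximal"
        assert rec.distance_bp == 10_000

    def test_multiple_intersected_elements_all_reported(self):
        lnc = gene("chr1", 9_000, 12_000, "LNC1", biotype="lncRNA", exons=[(10_200, 10_800)])
        pc = gene("chr1", 5_000, 30_000, "PC1", exons=[(5_000, 6_000)])
        ann = AnnotationSet(genes=[lnc, pc])
        rec = find_nearest_gene(herv("chr1", 10_000, 11_000), ann)
        assert rec.relation == "exonic"  # lncRNA exon overlaps
        assert set(rec.intersected_elements) == {
            ("LNC1", "lncRNA", "exon"),
            ("PC1", "protein_coding", "intron"),
        }

    def test_protein_coding_universe_skips_lncrna(self):
        lnc = gene("chr1", 11_100, 11_500, "LNC1", biotype="lncRNA")
        pc = gene("chr1", 13_000, 14_000, "PC1")
        ann = AnnotationSet(genes=[lnc, pc])
        cfg = ProximityConfig(gene_universe="protein_coding")
        rec = find_nearest_gene(herv("chr1", 10_000, 11_000), ann, cfg)
        assert rec.nearest_gene_id == "PC1"
        assert rec.distance_bp == 2_000

    def test_matches_brute_force_on_random_annotations(self):
        rng = np.random.default_rng(17)
        cfg = ProximityConfig()
        for _ in range(20):
            genes = []
            for i in range(30):
                s = int(rng.integers(0, 200_000))
                genes.append(gene("chr1", s, s + int(rng.integers(500, 5_000)), f"G{i}"))
            ann = AnnotationSet(genes=genes)
            hs = int(rng.integers(0, 200_000))
            h = herv("chr1", hs, hs + 1_000)
            rec = find_nearest_gene(h, ann, cfg)
            # brute force: min gap over all genes, found iff <= max_window
            gaps = sorted(
                (h.interval.gap_to(g.interval), g.interval.start, g.gene_id)
                for g in genes
            )
            best_gap = gaps[0][0]
            if best_gap > cfg.max_window_bp:
                assert rec.relation == "none_within_limit"
            else:
                assert rec.distance_bp == best_gap
                assert rec.nearest_gene_id == gaps[0][2]

    def test_invariant_to_gene_storage_order(self):
        genes = [gene("chr1", 13_000, 14_000, "A"), gene("chr1", 11_500, 12_000, "B")]
        r1 = find_nearest_gene(herv("chr1", 10_000, 11_000), AnnotationSet(genes=genes))
        r2 = find_nearest_gene(herv("chr1", 10_000, 11_000), AnnotationSet(genes=genes[::-1]))
        assert r1.nearest_gene_id == r2.nearest_gene_id == "B"

    def test_larger_max_window_never_changes_found_records(self):
        rng = np.random.default_rng(23)
        genes = [
            gene("chr1", int(s), int(s) + 800, f"G{i}")
            for i, s in enumerate(rng.integers(0, 300_000, size=40))
        ]
        ann = AnnotationSet(genes=genes)
        small = ProximityConfig(max_window_bp=10_000)
        large = ProximityConfig(max_window_bp=20_000)
        for i in range(25):
            s = int(rng.integers(0, 300_000))
            h = herv("chr1", s, s + 500, f"ERV3_1q{i}.1")
            r_small = find_nearest_gene(h, ann, small)
            if r_small.relation != "none_within_limit":
                r_large = find_nearest_gene(h, ann, large)
                assert (r_large.nearest_gene_id, r_large.distance_bp) == (
                    r_small.nearest_gene_id,
                    r_small.distance_bp,
                )


class TestDistanceNullTest:
    def test_complete_separation_is_significant(self):
        de = [
            ProximityRecord(f"H{i}", "G1", 0, "exonic") for i in range(20)
        ]
        nd = [
            ProximityRecord(f"N{i}", "G2", 10_001, "proximal") for i in range(20)
        ]
        res = distance_null_test(de, nd)
        assert res.p_value < 1e-6
        assert res.median_distance_de < res.median_distance_non_de

    def test_small_samples_match_exact_enumeration_oracle(self):
        de = [ProximityRecord(f"H{i}", "G", d, "proximal") for i, d in enumerate([10, 250, 900])]
        nd = [
            ProximityRecord(f"N{i}", "G", d, "proximal")
            for i, d in enumerate([3_000, 4_500, 7_000, 9_000])
        ]
        res = distance_null_test(de, nd)
        expected = mannwhitney_exact_oracle([10, 250, 900], [3_000, 4_500, 7_000, 9_000])
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_unfound_records_excluded_by_default_and_censorable(self):
        de = [ProximityRecord("H1", "G", 100, "proximal"), ProximityRecord("H2", None, None, "none_within_limit")]
        nd = [ProximityRecord(f"N{i}", "G", 200, "proximal") for i in range(3)]
        res = distance_null_test(de, nd)
        assert res.n_de == 1
        res_c = distance_null_test(de, nd, censor_unfound_at=10_001)
        assert res_c.n_de == 2

    def test_calibrated_under_identical_distributions(self):
        """When both groups draw distances from the same distribution, the
        rejection rate at 0.05 stays inside its binomial band."""
        rng = np.random.default_rng(31)
        n_rep = 400
        n_reject = 0
        for _ in range(n_rep):
            a = rng.integers(0, 10_000, size=15)
            b = rng.integers(0, 10_000, size=20)
            de = [ProximityRecord(f"H{i}", "G", int(d), "proximal") for i, d in enumerate(a)]
            nd = [ProximityRecord(f"N{i}", "G", int(d), "proximal") for i, d in enumerate(b)]
            if distance_null_test(de, nd).p_value < 0.05:
                n_reject += 1
        rate = n_reject / n_rep
        band = 4 * np.sqrt(0.05 * 0.95 / n_rep)  # ~4 sigma
        assert abs(rate - 0.05) < band

    def test_empty_group_is_hard_error(self):
        nd = [ProximityRecord("N1", "G", 5, "proximal")]
        with pytest.raises(ValueError):
            distance_null_test([], nd)


class TestLinkedPowerAndTallies:
    def test_planted_linkage_detected_against_unlinked_null(self):
        """DE HERVs placed near DE genes (link prob 0.9) sit closer to genes
        than non-DE HERVs; the rank test should reject decisively."""
        cfg = SimulationConfig(
            n_genes=800,
            n_hervs=1_200,
            frac_de_hervs=0.1,
            proximity_link_prob=0.9,
            set_size_range=(5, 10),
            n_enriched_sets=0,
            seed=77,
        )
        ann, truth = simulate_annotation(cfg)
        de_ids = set().union(*truth.de_herv_ids.values())
        cfg_prox = ProximityConfig()
        de_recs = proximity_table([h for h in ann.hervs if h.locus_id in de_ids], ann, cfg_prox)
        nd_recs = proximity_table(
            [h for h in ann.hervs if h.locus_id not in de_ids], ann, cfg_prox
        )
        assert len(de_recs) >= 100
        res = distance_null_test(de_recs, nd_recs, censor_unfound_at=10_001)
        assert res.p_value < 0.01
        assert res.median_distance_de <= res.median_distance_non_de

    def test_classify_counts_relations(self):
        records = [
            ProximityRecord("H1", "G1", 0, "exonic", [("G1", "protein_coding", "exon")]),
            ProximityRecord("H2", "G2", 0, "intronic", [("G2", "lncRNA", "intron")]),
            ProximityRecord("H3", "G3", 500, "proximal"),
        ]
        t = classify_intersections(records)
        assert (t["exonic"], t["intronic"], t["proximal"], t["none_within_limit"]) == (1, 1, 1, 0)
        assert t["by_biotype"] == {"protein_coding": 1, "lncRNA": 1}

    def test_classify_empty_input(self):
        t = classify_intersections([])
        assert t["exonic"] == t["intronic"] == t["proximal"] == t["none_within_limit"] == 0

    def test_forced_linkage_leaves_no_unfound_de_hervs(self):
        cfg = SimulationConfig(
            n_genes=300, n_hervs=100, proximity_link_prob=1.0,
            set_size_range=(5, 10), n_enriched_sets=0, seed=5,
        )
        ann, truth = simulate_annotation(cfg)
        de_ids = set().union(*truth.de_herv_ids.values())
        recs = proximity_table([h for h in ann.hervs if h.locus_id in de_ids], ann)
        tally = classify_intersections(recs)
        assert tally["none_within_limit"] == 0
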
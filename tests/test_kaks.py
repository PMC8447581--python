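"""Alignment identity, duplicate detection/classification, NG86 estimates."""

import math

import numpy as np
import pytest

from ringkit.annotation import GeneModel
from ringkit.kaks import (
    AlignScoring,
    DupPair,
    build_codon_alignment,
    classify_duplication,
    detect_duplicate_pairs,
    global_align_stats,
    ng86_kaks,
    ng86_site_counts,
    pairwise_identity,
    selection_summary,
)

from .oracles import oracle_align


def gene(gid, chrom, start, end):
    return GeneModel(gid, chrom, start, end, "+", ((start, end),))


class TestAlignment:
    def test_identical(self):
        assert pairwise_identity("ACGT", "ACGT") == (100.0, 100.0)

    def test_disjoint(self):
        ident, _ = pairwise_identity("AAAA", "TTTT")
        assert ident == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_matches_exhaustive_alignment_oracle(self, rng):
        sc = AlignScoring()
        for _ in range(60):
            la, lb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            a = "".join(rng.choice(list("ACGT"), la))
            b = "".join(rng.choice(list("ACGT"), lb))
            got = global_align_stats(a, b, sc)
            want = oracle_align(a, b, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
            assert got == want, (a, b)

    def test_numba_and_python_paths_agree(self, rng):
        from ringkit.kaks import _global_align_stats_py

        sc = AlignScoring()
        for _ in range(5):
            a = "".join(rng.choice(list("ACGT"), 120))
            b = "".join(rng.choice(list("ACGT"), 110))
            assert global_align_stats(a, b, sc) == _global_align_stats_py(a, b, sc)


class TestDetectPairs:
    def test_identical_cds_detected(self):
        models = [gene("a", "chr1", 100, 160), gene("b", "chr1", 5000, 5060)]
        cds = {"a": "ATGGCT" * 10, "b": "ATGGCT" * 10}
        pairs = detect_duplicate_pairs(models, cds)
        assert len(pairs) == 1 and pairs[0].identity == 100.0

    def test_unrelated_random_cds_not_detected(self, rng):
        models = [gene(f"g{i}", "chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 300)
                  for i in range(6)]
        cds = {
            f"g{i}": "".join(rng.choice(list("ACGT"), 300)) for i in range(6)
        }
        assert detect_duplicate_pairs(models, cds) == []

    def test_planted_pairs_recovered(self):
        from ringkit.simulate import child_rng, evolve_cds_pair

        rng = child_rng(5, "bundle")
        models, cds = [], {}
        for k in range(9):
            a, b, _ = evolve_cds_pair(120, omega=0.3, target_ks=0.2, seed=100 + k)
            ga, gb = f"a{k}", f"b{k}"
            cds[ga], cds[gb] = a, b
            models += [gene(ga, f"chr{k + 1}", 1000, 1360),
                       gene(gb, f"chr{k + 1}", 9000, 9360)]
        pairs = detect_duplicate_pairs(models, cds)
        found = {frozenset((p.gene_a, p.gene_b)) for p in pairs}
        assert found == {frozenset((f"a{k}", f"b{k}")) for k in range(9)}

    def test_missing_cds_skipped(self, caplog):
        models = [gene("a", "chr1", 100, 160), gene("b", "chr1", 5000, 5060)]
        pairs = detect_duplicate_pairs(models, {"a": "ATG" * 20})
        assert pairs == []


class TestClassification:
    def test_adjacent_same_chromosome_is_tandem(self):
        models = [gene("a", "chr1", 1000, 2000), gene("b", "chr1", 12_000, 13_000)]
        p = DupPair("a", "b", 90.0, 90.0)
        assert classify_duplication(p, models) == "tandem"

    def test_different_chromosomes_segmental(self):
        models = [gene("a", "chr1", 1000, 2000), gene("b", "chr2", 1000, 2000)]
        assert classify_duplication(DupPair("a", "b", 90.0, 90.0), models) == "segmental"

    def test_distant_same_chromosome_segmental(self):
        # ~1.9 Mb apart on one chromosome exceeds the tandem distance rule
        models = [gene("a", "chr3", 11_239_802, 11_241_097),
                  gene("b", "chr3", 9_340_156, 9_341_562)]
        assert classify_duplication(DupPair("a", "b", 90.0, 90.0), models) == "segmental"

    def test_many_intervening_family_genes_breaks_tandem(self):
        models = [gene("a", "chr1", 1_000, 1_500), gene("b", "chr1", 80_000, 80_500)]
        models += [gene(f"m{i}", "chr1", 10_000 + 9_000 * i, 10_100 + 9_000 * i)
                   for i in range(7)]
        assert classify_duplication(DupPair("a", "b", 90.0, 90.0), models) == "segmental"

    def test_every_pair_gets_exactly_one_class(self):
        models = [gene("a", "chr1", 1000, 2000), gene("b", "chr1", 3000, 4000)]
        cls = classify_duplication(DupPair("a", "b", 99.0, 99.0), models)
        assert cls in ("tandem", "segmental")


class TestNG86:
    def test_identical_sequences(self):
        res = ng86_kaks(("ATGGCTAAA", "ATGGCTAAA"))
        assert res.ka == 0.0 and res.ks == 0.0 and res.ratio is None

    def test_hand_counted_synonymous_change(self):
        # GGT->GGC third-position change: S=2 sites, Sd=1, pS=0.5,
        # Jukes-Cantor gives -(3/4) ln(1/3)
        res = ng86_kaks(("GGTGGT", "GGCGGT"))
        assert res.ka == 0.0
        assert res.ks == pytest.approx(-0.75 * math.log(1.0 / 3.0), abs=1e-9)
        assert (res.s_sites, res.n_sites) == (2.0, 4.0)

    def test_site_counts_sum_to_three_per_codon(self, rng):
        from ringkit.simulate import _random_cds, child_rng

        r = child_rng(2, "cds")
        for _ in range(10):
            a = _random_cds(r, 30)
            b = _random_cds(r, 30)
            s, n, _, _ = ng86_site_counts((a, b))
            assert s + n == pytest.approx(90.0, abs=1e-9)

    def test_symmetry(self, rng):
        from ringkit.simulate import _random_cds, child_rng

        r = child_rng(3, "cds")
        a, b = _random_cds(r, 40), _random_cds(r, 40)
        ra, rb = ng86_kaks((a, b)), ng86_kaks((b, a))
        assert ra.ks == pytest.approx(rb.ks) and ra.ka == pytest.approx(rb.ka)

    def test_internal_stop_rejected_with_codon_index(self):
        with pytest.raises(ValueError, match="codon 2"):
            ng86_kaks(("ATGTAAGGG", "ATGAAAGGG"))

    def test_saturation_flagged_not_raised(self):
        # every codon column maximally different drives pN beyond the
        # Jukes-Cantor domain
        a = "TTTTTTTTTTTT"
        b = "GGCGGCGGCGGC"
        res = ng86_kaks((a, b))
        assert res.ka is None and res.ka_saturated
        assert res.ratio is None

    def test_ratio_reproduces_reported_pair(self):
        # a published pair: Ka 0.143, Ks 0.674 -> ratio 0.212
        assert round(0.143 / 0.674, 3) == 0.212

    def test_omega_recovery_at_long_length(self):
        from ringkit.simulate import evolve_cds_pair

        a, b, truth = evolve_cds_pair(2000, omega=0.5, target_ks=0.4, seed=17)
        res = ng86_kaks(build_codon_alignment(a, b))
        assert res.ratio == pytest.approx(0.5, abs=0.15)


class TestCodonAlignment:
    def test_backthreading_preserves_codons(self):
        a = "ATGGCTGCTAAAGGT"
        b = "ATGGCTAAAGGT"  # one codon deleted
        aln_a, aln_b = build_codon_alignment(a, b)
        assert len(aln_a) == len(aln_b)
        assert aln_a.replace("-", "") == a
        assert aln_b.replace("-", "") == b
        assert len(aln_a) % 3 == 0

    def test_frame_breaking_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_codon_alignment("ATGGC", "ATGGCT")


class TestSelectionSummary:
    def test_published_pairs_summary(self):
        from ringkit.reference import load_duplicate_pairs

        pairs = load_duplicate_pairs()
        by_name = {frozenset((p.gene_a, p.gene_b)): p for p in pairs}
        p57 = by_name[frozenset(("VvRCHC5", "VvRCHC7"))]
        assert round(p57.ratio, 3) == 0.212
        s = selection_summary(pairs)
        assert s.n_pairs == 9
        assert s.class_counts == {"tandem": 7, "segmental": 2}
        assert s.n_below_half == 8
        assert s.mean_ratio_below_half == 0.325

    def test_single_pair_mean(self):
        p = DupPair("a", "b", 99.0, 99.0, "tandem", 0.2, 0.5, 0.4)
        assert selection_summary([p]).mean_ratio_below_half == 0.400
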
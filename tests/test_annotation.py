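"""GFF parsing, intron statistics, positional family naming."""

import pytest

from ringkit.annotation import (
    GeneModel,
    assign_family_names,
    chromosome_distribution,
    intron_stats,
    load_gene_models,
    natural_chromosome_key,
)


def make_gff(genes):
    """genes: list of (gid, chrom, exons, strand)."""
    lines = ["##gff-version 3"]
    for gid, chrom, exons, strand in genes:
        start, end = exons[0][0], exons[-1][1]
        lines.append(f"{chrom}\tt\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}")
        lines.append(
            f"{chrom}\tt\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={gid}.t1;Parent={gid}"
        )
        for k, (a, b) in enumerate(exons):
            lines.append(
                f"{chrom}\tt\texon\t{a}\t{b}\t.\t{strand}\t.\tID={gid}.t1.e{k};Parent={gid}.t1"
            )
    return "\n".join(lines) + "\n"


def model(gid, chrom, start, end=None, introns=0):
    end = end or start + 1000
    width = (end - start + 1) // (introns + 1) // 2 or 1
    exons = tuple(
        (start + i * 2 * width, start + i * 2 * width + width - 1)
        for i in range(introns + 1)
    )
    return GeneModel(gid, chrom, start, end, "+", exons)


class TestLoadGeneModels:
    def test_three_exons_two_introns(self):
        gff = make_gff([("g1", "chr1", [(100, 200), (300, 400), (500, 600)], "+")])
        (m,) = load_gene_models(gff)
        assert m.exon_count == 3 and m.intron_count == 2
        assert (m.start, m.end) == (100, 600)

    def test_single_exon_gene(self):
        gff = make_gff([("g1", "chr1", [(100, 600)], "-")])
        (m,) = load_gene_models(gff)
        assert m.intron_count == 0 and m.strand == "-"

    def test_longest_cds_transcript_selected(self):
        gff = (
            "##gff-version 3\n"
            "chr1\tt\tgene\t100\t900\t.\t+\t.\tID=g1\n"
            "chr1\tt\tmRNA\t100\t900\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "chr1\tt\texon\t100\t900\t.\t+\t.\tID=e1;Parent=g1.t1\n"
            "chr1\tt\tCDS\t100\t400\t.\t+\t0\tID=c1;Parent=g1.t1\n"
            "chr1\tt\tmRNA\t100\t900\t.\t+\t.\tID=g1.t2;Parent=g1\n"
            "chr1\tt\texon\t100\t500\t.\t+\t.\tID=e2;Parent=g1.t2\n"
            "chr1\tt\texon\t600\t900\t.\t+\t.\tID=e3;Parent=g1.t2\n"
            "chr1\tt\tCDS\t100\t500\t.\t+\t0\tID=c2;Parent=g1.t2\n"
            "chr1\tt\tCDS\t600\t900\t.\t+\t0\tID=c3;Parent=g1.t2\n"
        )
        (m,) = load_gene_models(gff)
        assert m.transcript_id == "g1.t2" and m.intron_count == 1

    def test_malformed_line_reports_line_number(self):
        gff = "##gff-version 3\nchr1\tonly\tthree\n"
        with pytest.raises(ValueError, match="line 2"):
            load_gene_models(gff)

    def test_roundtrip_against_generator_truth(self):
        from ringkit.simulate import gen_gff

        gff, _, truth = gen_gff(40, seed=9)
        models = load_gene_models(gff)
        assert len(models) == 40
        for m in models:
            t = truth["genes"][m.gene_id]
            assert m.intron_count == t["intron_count"]
            assert (m.chromosome, m.start, m.end, m.strand) == (
                t["chromosome"], t["start"], t["end"], t["strand"],
            )


class TestIntronStats:
    def test_simple_share(self):
        models = [model(f"g{i}", "chr1", 1000 * (i + 1), introns=k)
                  for i, k in enumerate([0, 0, 1, 3])]
        st = intron_stats(models)
        assert st.pct_at_most_k == 75.00
        assert st.max_intron_count == 3

    def test_family_sized_share(self):
        # 96 of 143 genes with at most two introns
        ks = [0] * 57 + [1] * 20 + [2] * 19 + [3] * 46 + [19]
        models = [model(f"g{i}", "chr1", 5000 * (i + 1), introns=k)
                  for i, k in enumerate(ks)]
        st = intron_stats(models)
        assert st.pct_at_most_k == 67.13
        assert st.max_intron_count == 19
        assert st.zero_intron_count == 57

    def test_all_single_exon(self):
        models = [model(f"g{i}", "chr1", 1000 * (i + 1)) for i in range(5)]
        st = intron_stats(models)
        assert st.max_intron_count == 0 and st.zero_intron_count == 5

    def test_empty_signalled(self):
        with pytest.raises(ValueError):
            intron_stats([])


class TestFamilyNaming:
    def test_position_order(self):
        models = [
            model("a", "chr1", 100), model("b", "chr1", 500), model("c", "chr2", 50),
        ]
        named = assign_family_names(models, "F")
        assert [(m.gene_id, m.family_name) for m in named] == [
            ("a", "F1"), ("b", "F2"), ("c", "F3"),
        ]

    def test_unanchored_sorts_after_numbered(self):
        named = assign_family_names(
            [model("u", "chrUn", 10), model("g", "chr19", 99)], "F"
        )
        assert named[0].gene_id == "g" and named[1].family_name == "F2"

    def test_permutation_invariant(self):
        models = [model(f"g{i}", f"chr{1 + i % 3}", 100 * (i + 7)) for i in range(12)]
        a = assign_family_names(models, "F")
        b = assign_family_names(list(reversed(models)), "F")
        assert {m.gene_id: m.family_name for m in a} == {
            m.gene_id: m.family_name for m in b
        }

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assign_family_names([model("g", "chr1", 1), model("g", "chr1", 900_000)])

    def test_natural_order_key(self):
        names = ["chr2", "chr10", "chr1", "chrUn", "chr19"]
        assert sorted(names, key=natural_chromosome_key) == [
            "chr1", "chr2", "chr10", "chr19", "chrUn",
        ]


class TestChromosomeDistribution:
    def test_counts(self):
        models = [model(f"g{i}", "chr1", 100 * (i + 1)) for i in range(3)]
        models.append(model("h", "chr2", 100))
        assert chromosome_distribution(models) == {"chr1": 3, "chr2": 1}

    def test_empty(self):
        assert chromosome_distribution([]) == {}

    def test_total_preserved(self):
        from ringkit.simulate import gen_gff

        gff, _, _ = gen_gff(35, seed=4)
        models = load_gene_models(gff)
        dist = chromosome_distribution(models)
        assert sum(dist.values()) == 35


class TestPublishedFamilyTable:
    def test_chromosome_retabulation(self):
        from ringkit.reference import family_gene_models

        models = family_gene_models()
        assert len(models) == 143
        dist = chromosome_distribution(models)
        assert dist["chr11"] == 12
        assert max(dist.values()) == 12
        assert dist["chrUn"] == 3

    def test_published_positional_naming_is_reproduced(self):
        from ringkit.reference import family_gene_models

        named = assign_family_names(family_gene_models(), "VvRCHC")
        assert all(m.gene_id == m.family_name for m in named)
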
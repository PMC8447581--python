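"""Scanner correctness: consensus examples, oracle equivalence, censuses."""

import numpy as np
import pytest

from ringkit.domain_scan import (
    ProteinRecord,
    SpacerBounds,
    RingDomainHit,
    domain_length_distribution,
    enumerate_assignments,
    expected_random_assignments,
    position_bias,
    scan_c3h2c3,
    spacer_census,
)

from .oracles import oracle_assignments, oracle_assignments_naive, oracle_select

MINIMAL = "C" + "AA" + "C" + "A" * 9 + "C" + "A" + "H" + "AA" + "H" + "AA" + "C" + "AAAA" + "C" + "AA" + "C"


def hit_from_spacers(spacers, protein_id="syn", p1=0):
    positions = [p1]
    for s in spacers:
        positions.append(positions[-1] + s + 1)
    return RingDomainHit(protein_id, tuple(positions))


class TestScan:
    def test_minimal_consensus_domain(self):
        hits = scan_c3h2c3(ProteinRecord("t", MINIMAL))
        assert len(hits) == 1
        h = hits[0]
        assert h.positions == (0, 3, 13, 15, 18, 21, 26, 29)
        assert h.spacers == (2, 9, 1, 2, 2, 4, 2)
        assert h.span == 30

    def test_no_ligands_means_no_hits(self):
        assert scan_c3h2c3(ProteinRecord("t", "A" * 100)) == []

    def test_invalid_residue_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            ProteinRecord("t", "AAZAA")

    def test_case_insensitive(self):
        lower = scan_c3h2c3(ProteinRecord("t", MINIMAL.lower()))
        upper = scan_c3h2c3(ProteinRecord("t", MINIMAL))
        assert [h.positions for h in lower] == [h.positions for h in upper]

    def test_x_never_a_ligand_but_legal_spacer(self):
        seq = MINIMAL.replace("A", "X")
        hits = scan_c3h2c3(ProteinRecord("t", seq))
        assert len(hits) == 1
        no_first_c = "X" + MINIMAL[1:]
        assert scan_c3h2c3(ProteinRecord("t", no_first_c)) == []

    def test_span_identity_on_every_hit(self, rng):
        bounds = SpacerBounds()
        for _ in range(30):
            seq = "".join(rng.choice(list("ACDHGS"), size=200))
            for h in scan_c3h2c3(ProteinRecord("t", seq), bounds):
                assert h.span == 8 + sum(h.spacers)

    def test_matches_recursive_oracle_on_random_sequences(self, rng):
        bounds = SpacerBounds()
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            seq = "".join(rng.choice(alphabet, size=300))
            rec = ProteinRecord("t", seq)
            assert enumerate_assignments(rec, bounds) == sorted(
                oracle_assignments(seq, bounds.gaps)
            )
            expected = oracle_select(oracle_assignments(seq, bounds.gaps))
            assert [h.positions for h in scan_c3h2c3(rec, bounds)] == expected

    def test_matches_naive_product_oracle_on_dense_short_sequences(self, rng):
        # high C/H density maximizes combinatorial stress at small length
        bounds = SpacerBounds(((0, 3), (1, 6), (0, 3), (0, 3), (0, 3), (1, 6), (0, 3)))
        alphabet = list("CHADEFG")
        for _ in range(20):
            seq = "".join(rng.choice(alphabet, size=30))
            rec = ProteinRecord("t", seq)
            assert sorted(enumerate_assignments(rec, bounds)) == oracle_assignments_naive(
                seq, bounds.gaps
            )

    def test_alternates_do_not_overlap_selection_rule(self):
        # two chained candidate domains sharing a middle cysteine
        seq = MINIMAL + MINIMAL
        hits, alternates = scan_c3h2c3(
            ProteinRecord("t", seq), return_alternates=True
        )
        assert len(hits) == 2
        spans = sorted((h.positions[0], h.positions[-1]) for h in hits)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 < a2


class TestPlantedRecovery:
    def test_planted_domains_recovered_exactly(self):
        from ringkit.simulate import gen_proteome

        proteins, truth = gen_proteome(60, 40, seed=11)
        for p in proteins:
            expected = truth["proteins"][p.id]
            hits = scan_c3h2c3(p)
            if expected is None:
                assert hits == []
            else:
                assert len(hits) == 1
                assert list(hits[0].positions) == expected["positions"]

    def test_background_false_positives_match_analytic_expectation(self, rng):
        n, length = 400, 300
        bounds = SpacerBounds()
        expect = expected_random_assignments(length, bounds) * n
        total = 0
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(n):
            seq = "".join(rng.choice(alphabet, size=length))
            total += len(enumerate_assignments(ProteinRecord("t", seq), bounds))
        # Poisson-ish count: 3 standard errors around the analytic mean
        se = np.sqrt(expect)
        assert abs(total - expect) <= max(3 * se, 3)


class TestCensus:
    def test_single_hit_census(self):
        c = spacer_census([hit_from_spacers((2, 11, 1, 2, 2, 8, 2))])
        assert c.gap_min[1] == c.gap_max[1] == 11
        assert c.gap_min[5] == c.gap_max[5] == 8
        assert c.spans == [36]

    def test_census_brackets_observed_range(self):
        hits = [
            hit_from_spacers((2, 11, 1, 2, 2, 8, 2)),
            hit_from_spacers((2, 24, 1, 2, 2, 8, 2)),
        ]
        c = spacer_census(hits)
        assert (c.gap_min[1], c.gap_max[1]) == (11, 24)
        assert sum(c.gap_histograms[1].values()) == 2

    def test_span_equals_eight_plus_spacers(self):
        hits = [
            hit_from_spacers((2, 14, 1, 2, 2, 10, 2)),  # sums to 33
            hit_from_spacers((2, 15, 1, 2, 2, 10, 2)),  # sums to 34
        ]
        assert spacer_census(hits).spans == [41, 42]

    def test_empty_census_signalled(self):
        with pytest.raises(ValueError, match="empty"):
            spacer_census([])


class TestPositionBias:
    def test_planted_proline_after_ml7(self, rng):
        proteins, hits = {}, []
        for i in range(10):
            seq = list(MINIMAL + "AAAA")
            h = hit_from_spacers((2, 9, 1, 2, 2, 4, 2), protein_id=f"p{i}")
            seq[h.positions[6] + 1] = "P"
            proteins[f"p{i}"] = ProteinRecord(f"p{i}", "".join(seq))
            hits.append(h)
        bias = position_bias(hits, proteins, flank=2)
        assert bias[(7, 1)]["P"] == 1.0

    def test_frequencies_sum_to_one(self, rng):
        from ringkit.simulate import gen_proteome

        proteins, _ = gen_proteome(30, 30, seed=3)
        pmap = {p.id: p for p in proteins}
        hits = [h for p in proteins for h in scan_c3h2c3(p)]
        bias = position_bias(hits, pmap, flank=3)
        for vec in bias.values():
            assert abs(sum(vec.values()) - 1.0) < 1e-9

    def test_boundary_offsets_excluded_not_errors(self):
        h = hit_from_spacers((2, 9, 1, 2, 2, 4, 2), p1=0)
        proteins = {"syn": ProteinRecord("syn", MINIMAL)}
        bias = position_bias([h], proteins, flank=2)
        assert (1, -1) not in bias  # nothing left of the protein start

    def test_flank_must_be_positive(self):
        with pytest.raises(ValueError):
            position_bias([], {}, flank=0)


class TestLengthDistribution:
    @pytest.mark.parametrize(
        "spans, expected_pct",
        [
            ([41, 41, 42, 50], 75.0),
            ([41] * 70 + [42] * 57 + [36] * 16, 88.8),  # 127 of 143
            ([30, 30, 30], 0.0),
        ],
    )
    def test_fraction_in_dominant_spans(self, spans, expected_pct):
        hits = [hit_from_spacers((2, s - 8 - 11, 1, 2, 2, 2, 2)) for s in spans]
        counts, pct = domain_length_distribution(hits)
        assert pct == expected_pct
        assert sum(counts.values()) == len(spans)

    def test_empty_signalled(self):
        with pytest.raises(ValueError, match="empty"):
            domain_length_distribution([])
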
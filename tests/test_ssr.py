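"""SSR scanner: planted repeats, canonicalization, list crossing, spectrum."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pomdiv.simulate import PlantedContigSpec, generate_contigs
from pomdiv.ssr import (
    MISA_DEFAULT_MIN_COPIES,
    SSRLocus,
    canonical_motif,
    intersect_ssrs,
    is_primitive,
    motif_spectrum,
    reverse_complement,
    scan_sequence,
    scan_ssrs,
    unit_length_spectrum,
)

from conftest import regex_ssr_oracle


class TestScan:
    def test_planted_dinucleotide(self):
        loci = scan_sequence("c", "CCCC" + "AG" * 6 + "TTTT")
        assert [(l.motif, l.copies, l.start, l.strand_class) for l in loci] == [
            ("AG", 6, 4, "+")
        ]

    def test_below_copy_threshold_is_silent(self):
        assert scan_sequence("c", "AT" * 5) == []

    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("A" * 10, [("A", 10, 0, 1)]),
            ("A" * 9, []),  # mono threshold is 10
            ("GAA" * 5, [("AAG", 5, 0, 3)]),  # canonical = min rotation
            ("AGAGAGAGAGAGA", [("AG", 6, 0, 2)]),  # truncated partial unit
            ("N" + "AC" * 6 + "N", [("AC", 6, 1, 2)]),  # N breaks but flanks fine
        ],
    )
    def test_edge_repeats(self, seq, expected):
        got = [(l.motif, l.copies, l.start, l.unit_length) for l in scan_sequence("c", seq)]
        assert got == expected

    def test_non_acgtn_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            scan_sequence("c", "ACGTX" * 10)

    def test_nested_repeat_resolved_to_longest(self):
        # AT run of 8 copies contains shorter phase-shifted candidates;
        # exactly one call must survive
        loci = scan_sequence("c", "GGGCC" + "AT" * 8 + "GGCCC")
        assert len(loci) == 1 and loci[0].copies == 8

    def test_scanner_matches_regex_oracle_on_random_contigs(self, rng):
        nucs = np.array(list("ACGT"))
        for i in range(60):
            seq = "".join(rng.choice(nucs, size=300))
            # inject a couple of repeats half the time
            if i % 2:
                seq = seq[:50] + "TA" * 7 + seq[50:150] + "CTT" * 6 + seq[150:]
            got = [
                (l.contig_id, l.start, l.motif, l.strand_class, l.copies, l.unit_length)
                for l in scan_sequence("c", seq)
            ]
            assert got == regex_ssr_oracle("c", seq)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=80))
    def test_scanner_equals_oracle_property(self, seq):
        got = [
            (l.start, l.motif, l.strand_class, l.copies, l.unit_length)
            for l in scan_sequence("c", seq)
        ]
        oracle = [(s, m, st_, c, u) for _, s, m, st_, c, u in regex_ssr_oracle("c", seq)]
        assert got == oracle


class TestCanonicalization:
    @pytest.mark.parametrize(
        "unit, motif, strand",
        [("AG", "AG", "+"), ("GA", "AG", "+"), ("CT", "AG", "-"), ("TC", "AG", "-"),
         ("AT", "AT", "+"), ("GAA", "AAG", "+"), ("TTC", "AAG", "-")],
    )
    def test_examples(self, unit, motif, strand):
        assert canonical_motif(unit) == (motif, strand)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_rotation_and_revcomp_share_canonical_motif(self, unit):
        motif, _ = canonical_motif(unit)
        for r in range(len(unit)):
            rot = unit[r:] + unit[:r]
            assert canonical_motif(rot)[0] == motif
        assert canonical_motif(reverse_complement(unit))[0] == motif

    def test_reverse_complementing_contig_flips_strand_and_mirrors_start(self):
        seq = "CCCCC" + "AG" * 6 + "TTTTT"
        fwd = scan_sequence("c", seq)[0]
        rev = scan_sequence("c", reverse_complement(seq))[0]
        assert rev.motif == fwd.motif
        assert {rev.strand_class, fwd.strand_class} == {"+", "-"}
        assert rev.start == len(seq) - fwd.end


class TestIntersect:
    def _mk(self, contig, motif, start, copies=6):
        m, s = canonical_motif(motif)
        return SSRLocus(contig, start, m, s, copies, len(motif))

    def test_identity(self):
        a = [self._mk("c1", "AG", 3), self._mk("c2", "AAG", 9)]
        assert intersect_ssrs(a, a) == a

    def test_disjoint_contigs_empty(self):
        a = [self._mk("c1", "AG", 3)]
        b = [self._mk("c2", "AG", 3)]
        assert intersect_ssrs(a, b) == []

    def test_planted_common_subset_recovered(self, rng):
        common = [self._mk(f"c{i}", "AG", int(rng.integers(100))) for i in range(30)]
        only_a = [self._mk(f"a{i}", "AC", 5) for i in range(50)]
        only_b = [self._mk(f"b{i}", "AT", 7) for i in range(60)]
        a = common + only_a
        b = common + only_b
        got = intersect_ssrs(a, b)
        assert sorted(l.key() for l in got) == sorted(l.key() for l in common)
        # symmetry and cardinality bound
        assert {l.key() for l in intersect_ssrs(b, a)} == {l.key() for l in got}
        assert len(got) <= min(len(a), len(b))


class TestSpectrum:
    def test_counts_partition_input(self, rng):
        loci = [
            SSRLocus("c", i, m, "+", 6, len(m))
            for i, m in enumerate(["AG"] * 5 + ["AAG"] * 3 + ["A"] * 2)
        ]
        spec = motif_spectrum(loci)
        assert spec["count"].sum() == len(loci)
        assert np.isclose(spec["percent"].sum(), 100.0)

    def test_empty_input_gives_empty_table(self):
        assert len(motif_spectrum([])) == 0

    def test_single_motif_is_total(self):
        loci = [SSRLocus("c", i, "AG", "+", 6, 2) for i in range(7)]
        spec = motif_spectrum(loci)
        assert len(spec) == 1
        assert spec["percent"].iloc[0] == 100.0 and spec["percent_int"].iloc[0] == 100


class TestPlantedContigs:
    def test_scanner_recall_and_precision_on_planted_contigs(self, rng):
        specs = []
        motifs = ["A", "AG", "AAG", "AAAG", "AAAAG", "AAAACG", "CT", "GAT"]
        for i in range(40):
            motif = motifs[int(rng.integers(len(motifs)))]
            copies = int(MISA_DEFAULT_MIN_COPIES[len(motif)] + rng.integers(0, 4))
            specs.append(
                PlantedContigSpec(f"c{i:03d}", motif, copies, int(50 + rng.integers(100)), 400)
            )
        contigs = generate_contigs(specs, seed=99)
        found = scan_ssrs(contigs)
        expected = sorted(
            (s.expected_locus() for s in specs), key=lambda l: (l.contig_id, l.start)
        )
        assert found == expected  # recall and precision both 1.0

    def test_zero_specs_zero_ssrs(self):
        assert generate_contigs([], seed=1) == {}

    def test_colliding_plants_raise(self):
        specs = [
            PlantedContigSpec("c", "AG", 6, 10, 200),
            PlantedContigSpec("c", "CT", 6, 15, 200),
        ]
        with pytest.raises(ValueError, match="collide"):
            generate_contigs(specs, seed=1)


def test_primitivity():
    assert is_primitive("AG") and is_primitive("AAG")
    assert not is_primitive("AGAG") and not is_primitive("AA")
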
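"""Ortholog grouping, isoform selection, codon-aware alignment, block filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psgscan.alignment import CodonAlignment
from psgscan.orthologs import (
    codon_aware_align,
    conserved_block_filter,
    protein_identity,
    reciprocal_best_hits,
    select_isoforms,
)

SENSE = ["ATG", "AAA", "CCC", "GGG", "TTT", "GAA", "CTG", "TGG", "AGA", "GAT"]


def _cds(*codons):
    return "".join(codons)


class TestReciprocalBestHits:
    def test_empty(self):
        assert reciprocal_best_hits({}) == {}

    def test_mutual_pair(self):
        assert reciprocal_best_hits({("a", "x"): 5.0}) == {"a": "x"}

    def test_asymmetric_best_leaves_gene_unassigned(self):
        # A's best is X, but X prefers B; B and X are mutual
        scores = {
            ("A", "X"): 10.0,
            ("A", "Y"): 3.0,
            ("B", "X"): 12.0,
            ("B", "Y"): 1.0,
            ("C", "Y"): 8.0,
            ("C", "X"): 2.0,
        }
        pairs = reciprocal_best_hits(scores)
        assert pairs == {"B": "X", "C": "Y"}

    def test_deterministic_tie_break(self):
        scores = {("a", "x"): 1.0, ("a", "y"): 1.0}
        assert reciprocal_best_hits(scores) == {"a": "x"}


class TestSelectIsoforms:
    def _stub_scorer(self, table):
        return lambda a, b: table.get((a, b), table.get((b, a), 1.0))

    def test_passing_isoform_retained(self):
        ref = _cds("ATG", "AAA")
        iso = _cds("ATG", "AAA")
        scorer = self._stub_scorer({(ref, iso): 0.80})
        group = select_isoforms("R", "g|t1", ref, {"S": [("g|t1", iso)]}, scorer=scorer)
        assert group.members == {"R": "g|t1", "S": "g|t1"}

    def test_below_reference_floor_drops_species(self):
        ref = _cds("ATG", "AAA")
        iso = _cds("ATG", "CCC")
        scorer = self._stub_scorer({(ref, iso): 0.65})
        group = select_isoforms("R", "g|t1", ref, {"S": [("g|t1", iso)]}, scorer=scorer)
        assert "S" not in group.members

    def test_most_similar_isoform_wins(self):
        ref = _cds("ATG", "AAA")
        iso1, iso2 = _cds("ATG", "GGG"), _cds("ATG", "TTT")
        scorer = self._stub_scorer({(ref, iso1): 0.72, (ref, iso2): 0.91})
        group = select_isoforms(
            "R", "g|t1", ref, {"S": [("g|t1", iso1), ("g|t2", iso2)]}, scorer=scorer
        )
        assert group.members["S"] == "g|t2"
        assert group.similarities["S"] == pytest.approx(0.91)

    def test_pairwise_floor_drops_worst_member(self):
        ref = _cds("ATG", "AAA")
        isoA, isoB = _cds("ATG", "GGG"), _cds("ATG", "TTT")
        scorer = self._stub_scorer({
            (ref, isoA): 0.75, (ref, isoB): 0.92, (isoA, isoB): 0.4,
        })
        group = select_isoforms(
            "R", "g|t1", ref,
            {"S1": [("a|t1", isoA)], "S2": [("b|t1", isoB)]}, scorer=scorer,
        )
        # A and B violate the 50% pairwise floor; the one less similar to
        # the reference (A at 0.75) is dropped
        assert set(group.members) == {"R", "S2"}

    def test_never_increases_species_count(self):
        ref = _cds("ATG", "AAA")
        group = select_isoforms("R", "g|t1", ref, {"S": []})
        assert set(group.members) == {"R"}


class TestProteinIdentity:
    def test_identical(self):
        cds = _cds("ATG", "AAA", "CCC")
        assert protein_identity(cds, cds) == 1.0

    def test_known_fraction(self):
        a = _cds("ATG", "AAA", "CCC", "GGG")
        b = _cds("ATG", "AAA", "CCC", "TTT")
        assert protein_identity(a, b) == pytest.approx(0.75)


class TestCodonAwareAlign:
    def test_identical_sequences_gapless(self):
        cds = _cds(*SENSE)
        aln = codon_aware_align({"A": cds, "B": cds})
        assert aln.n_sites == len(SENSE)
        assert np.all(aln.codes >= 0)

    def test_single_codon_deletion_gives_one_gap(self):
        full = _cds(*SENSE)
        missing = _cds(*(SENSE[:4] + SENSE[5:]))  # codon 4 deleted
        aln = codon_aware_align({"A": full, "B": missing}, reference="A")
        assert aln.n_sites == len(SENSE)
        row_b = aln.codes[aln.taxa.index("B")]
        gaps = np.nonzero(row_b < 0)[0]
        assert list(gaps) == [4]
        assert aln.sequence("A") == full

    def test_insertion_relative_to_reference(self):
        short = _cds(*SENSE[:6])
        longer = _cds(*(SENSE[:3] + ["GAT"] + SENSE[3:6]))
        aln = codon_aware_align({"A": short, "B": longer}, reference="A")
        row_a = aln.codes[aln.taxa.index("A")]
        assert np.sum(row_a < 0) == 1  # one codon-sized gap in the reference

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            codon_aware_align({"A": _cds("ATG", "TAA", "AAA"), "B": _cds("ATG", "AAA", "AAA")})

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, derandomize=True, deadline=None)
    def test_output_length_divisible_by_three(self, seed):
        rng = np.random.default_rng(seed)
        seqs = {}
        for name in "AB":
            k = rng.integers(5, 15)
            seqs[name] = "".join(rng.choice(SENSE, size=k))
        aln = codon_aware_align(seqs)
        assert len(aln.sequence("A")) % 3 == 0


class TestConservedBlockFilter:
    def _aln(self, rows):
        return CodonAlignment.from_sequences(list(rows.items()))

    def test_fully_conserved_kept(self):
        cds = _cds(*(["AAA"] * 100))
        res = conserved_block_filter(self._aln({"A": cds, "B": cds, "C": cds}))
        assert res.n_kept == 100
        assert res.removed_intervals == []

    def test_short_block_removed_by_b4(self):
        # 20 conserved codons flanked by long (> b3) non-conserved runs:
        # the flanks go first, then the stranded 20-codon block (< b4 = 30)
        conserved = ["AAA"] * 20
        row_a = ["CCC"] * 10 + conserved + ["GGG"] * 10
        row_b = ["TTT"] * 10 + conserved + ["ATG"] * 10
        res = conserved_block_filter(
            self._aln({"A": _cds(*row_a), "B": _cds(*row_b)}), b4=30
        )
        assert res.n_kept == 0
        assert res.removed_intervals == [(0, 40)]

    def test_isolated_variable_columns_kept_inside_blocks(self):
        # a short (<= b3) variable stretch inside a long conserved block
        # survives: these columns carry the substitution signal
        row_a = ["AAA"] * 40 + ["CCC"] * 3 + ["AAA"] * 40
        row_b = ["AAA"] * 40 + ["TTT"] * 3 + ["AAA"] * 40
        res = conserved_block_filter(self._aln({"A": _cds(*row_a), "B": _cds(*row_b)}))
        assert res.n_kept == 83
        assert res.removed_intervals == []

    def test_gap_column_removed_and_recorded(self):
        base = ["AAA"] * 80
        row_a = base.copy()
        row_b = base.copy()
        row_b[40] = "---"
        res = conserved_block_filter(self._aln({"A": _cds(*row_a), "B": _cds(*row_b)}))
        assert res.removed_intervals == [(40, 41)]
        assert res.n_kept == 79
        kept_origins = set(res.alignment.origin.tolist())
        assert 40 not in kept_origins

    def test_kept_and_removed_tile_input(self):
        rng = np.random.default_rng(6)
        codes = rng.integers(0, 61, size=(3, 120))
        codes[:, 30:40] = codes[0, 30:40]  # a conserved stretch
        aln = CodonAlignment(list("ABC"), codes)
        res = conserved_block_filter(aln, b4=5)
        covered = set(res.alignment.origin.tolist())
        for a, b in res.removed_intervals:
            covered |= set(range(a, b))
        assert covered == set(range(120))

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        codes = rng.integers(0, 61, size=(3, 200))
        codes[:, 50:120] = codes[0, 50:120]
        aln = CodonAlignment(list("ABC"), codes)
        once = conserved_block_filter(aln, b4=10)
        twice = conserved_block_filter(once.alignment, b4=10)
        assert np.array_equal(once.alignment.codes, twice.alignment.codes)
        assert twice.removed_intervals == []

    def test_b4_validation(self):
        aln = self._aln({"A": "AAA", "B": "AAA"})
        with pytest.raises(ValueError):
            conserved_block_filter(aln, b4=0)
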
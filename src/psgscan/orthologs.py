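"""From per-species transcript catalogs to filtered per-gene codon alignments.

The stages mirror a classical positive-selection scan front end:

1. ortholog grouping by the reciprocal-best-hit criterion against a
   reference species (the scorer is pluggable; the default is global
   protein alignment percent identity);
2. isoform selection: per species the isoform most similar to the
   reference isoform is kept, and the species is dropped when it misses
   the 70% (to reference) or any pairwise 50% protein-similarity floor;
3. codon-aware alignment: global protein alignment back-translated to
   codons, so all gaps are codon-sized;
4. conserved-block filtering in the spirit of Gblocks at codon
   granularity, with the removed-column map kept for the edge-site
   adjustment downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .alignment import CodonAlignment
from .genetics import standard_codon_space

__all__ = [
    "TranscriptCatalog",
    "OrthologGroup",
    "BlockFilterResult",
    "protein_identity",
    "reciprocal_best_hits",
    "select_isoforms",
    "codon_aware_align",
    "conserved_block_filter",
]

SIMILARITY_TO_REFERENCE = 0.70
SIMILARITY_PAIRWISE = 0.50


# --------------------------------------------------------------------------
# catalogs
# --------------------------------------------------------------------------
@dataclass
class TranscriptCatalog:
    """Per-species coding sequences, multiple isoforms per gene allowed.

    Headers follow ``gene|isoform``; a header without ``|`` is a
    single-isoform gene.
    """

    species: str
    sequences: dict  # isoform id -> CDS (in-frame nucleotide string)
    gene_of: dict  # isoform id -> gene id

    @classmethod
    def read_fasta(cls, species: str, path) -> "TranscriptCatalog":
        seqs, gene_of = {}, {}
        for rec in SeqIO.parse(str(path), "fasta"):
            iso = rec.id
            seqs[iso] = str(rec.seq).upper()
            gene_of[iso] = iso.split("|")[0]
        return cls(species, seqs, gene_of)

    @classmethod
    def from_entries(cls, species: str, entries) -> "TranscriptCatalog":
        seqs = {h: s for h, s in entries}
        return cls(species, seqs, {h: h.split("|")[0] for h in seqs})

    def isoforms(self, gene: str) -> list:
        return [i for i, g in self.gene_of.items() if g == gene]


@dataclass
class OrthologGroup:
    """One reference gene with its chosen per-species isoform."""

    reference_gene: str
    members: dict  # species -> isoform id
    sequences: dict  # species -> CDS
    similarities: dict = field(default_factory=dict)  # species -> identity to reference


# --------------------------------------------------------------------------
# similarity scoring
# --------------------------------------------------------------------------
_aligner = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        a.mode = "global"
        _aligner = a
    return _aligner


def translate_cds(cds: str, trim_terminal_stop: bool = True) -> str:
    """Protein sequence of an in-frame CDS; internal stops raise."""
    space = standard_codon_space()
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    if trim_terminal_stop and len(seq) >= 3 and seq[-3:] in space.stop_codons:
        seq = seq[:-3]
    return space.translate(seq)


def protein_identity(cds_a: str, cds_b: str) -> float:
    """Percent identity (fraction) over aligned positions of a global
    protein alignment of two CDSs."""
    prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
    if not prot_a or not prot_b:
        return 0.0
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    a, b = aln[0], aln[1]
    aligned = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    if aligned == 0:
        return 0.0
    same = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return same / aligned


def alignment_score(cds_a: str, cds_b: str) -> float:
    """Global protein alignment score (the RBH ranking statistic)."""
    return float(_protein_aligner().score(translate_cds(cds_a), translate_cds(cds_b)))


# --------------------------------------------------------------------------
# reciprocal best hits
# --------------------------------------------------------------------------
def reciprocal_best_hits(scores: dict) -> dict:
    """Pair genes that are mutually best-scoring matches.

    ``scores[(a, b)] -> score`` holds cross-species similarity scores in
    either or both directions (a missing direction is filled from the
    other, treating the scorer as symmetric). Returns ``{a: b}`` for each
    mutual-best pair, keyed by the first element of the pair as given.
    Ties break toward the lexicographically smallest partner.
    """
    if not scores:
        return {}
    sym: dict = {}
    for (a, b), v in scores.items():
        sym.setdefault(a, {})
        sym.setdefault(b, {})
        sym[a][b] = max(sym[a].get(b, -np.inf), v)
        sym[b][a] = max(sym[b].get(a, -np.inf), v)

    def best(x):
        partners = sym[x]
        top = max(partners.values())
        return min(p for p, v in partners.items() if v == top)

    out = {}
    for a in sorted(sym):
        b = best(a)
        if a < b and best(b) == a:
            out[a] = b
    return out


def rbh_against_reference(reference_catalog, other_catalog, scorer=alignment_score) -> dict:
    """Reference gene -> other-species gene pairs by reciprocal best hit.

    Genes are compared through their first-listed isoform (catalog order),
    which is the primary isoform by construction of the catalog format.
    """
    ref_genes = _primary_isoforms(reference_catalog)
    other_genes = _primary_isoforms(other_catalog)
    scores = {}
    for ga, (ia, sa) in ref_genes.items():
        for gb, (ib, sb) in other_genes.items():
            scores[(f"R:{ga}", f"O:{gb}")] = scorer(sa, sb)
    pairs = reciprocal_best_hits(scores)
    out = {}
    for a, b in pairs.items():
        ga = a[2:] if a.startswith("R:") else b[2:]
        gb = b[2:] if b.startswith("O:") else a[2:]
        out[ga] = gb
    return out


def _primary_isoforms(catalog: TranscriptCatalog) -> dict:
    out = {}
    for iso, gene in catalog.gene_of.items():
        if gene not in out:
            out[gene] = (iso, catalog.sequences[iso])
    return out


# --------------------------------------------------------------------------
# isoform selection
# --------------------------------------------------------------------------
def select_isoforms(
    reference_species: str,
    reference_isoform: str,
    reference_cds: str,
    candidates: dict,
    min_reference_similarity: float = SIMILARITY_TO_REFERENCE,
    min_pairwise_similarity: float = SIMILARITY_PAIRWISE,
    scorer=protein_identity,
) -> OrthologGroup:
    """Choose one isoform per species and apply the similarity floors.

    ``candidates[species] -> [(isoform_id, cds), ...]``. Per species the
    isoform most similar to the reference is chosen (ties to the smaller
    isoform id); the species is dropped if that isoform is below the
    reference floor, and then iteratively if it is below the pairwise
    floor with any remaining species.
    """
    gene = reference_isoform.split("|")[0]
    members = {reference_species: reference_isoform}
    sequences = {reference_species: reference_cds}
    sims = {reference_species: 1.0}
    for sp in sorted(candidates):
        if sp == reference_species or not candidates[sp]:
            continue
        scored = sorted(
            ((scorer(reference_cds, cds), iso, cds) for iso, cds in candidates[sp]),
            key=lambda t: (-t[0], t[1]),
        )
        top_sim, top_iso, top_cds = scored[0]
        if top_sim < min_reference_similarity:
            continue
        members[sp] = top_iso
        sequences[sp] = top_cds
        sims[sp] = top_sim

    # pairwise floor among non-reference species: drop greedily, worst first
    changed = True
    while changed:
        changed = False
        others = [sp for sp in members if sp != reference_species]
        worst = None
        for i, sa in enumerate(others):
            for sb in others[i + 1 :]:
                sim = scorer(sequences[sa], sequences[sb])
                if sim < min_pairwise_similarity:
                    # drop the member less similar to the reference
                    victim = sa if sims[sa] <= sims[sb] else sb
                    if worst is None or sims[victim] < sims[worst]:
                        worst = victim
        if worst is not None:
            del members[worst], sequences[worst], sims[worst]
            changed = True
    return OrthologGroup(gene, members, sequences, sims)


# --------------------------------------------------------------------------
# codon-aware alignment
# --------------------------------------------------------------------------
def codon_aware_align(sequences: dict, reference: str | None = None) -> CodonAlignment:
    """Protein-guided multiple alignment back-translated to codons.

    A center-star strategy around the reference sequence (default: first
    key): every other protein is aligned globally to the reference and
    the pairwise alignments are merged on reference coordinates, so every
    gap is a whole number of codons. Sequences with internal stop codons
    are rejected.
    """
    if not sequences:
        raise ValueError("no sequences to align")
    names = list(sequences)
    reference = reference or names[0]
    if reference not in sequences:
        raise ValueError(f"reference {reference!r} not among sequences")

    space = standard_codon_space()
    prots, codons = {}, {}
    for name, cds in sequences.items():
        seq = cds.upper().replace("U", "T")
        if len(seq) >= 3 and seq[-3:] in space.stop_codons:
            seq = seq[:-3]
        prot = space.translate(seq)  # raises on internal stop
        prots[name] = prot
        codons[name] = [seq[i : i + 3] for i in range(0, len(seq), 3)]

    if len(names) == 1:
        return CodonAlignment.from_sequences([(reference, "".join(codons[reference]))])

    aligner = _protein_aligner()
    ref_prot = prots[reference]
    # per pairwise alignment: for each reference residue, the run of
    # other-sequence residue indices aligned before it (insertions) and at it
    pair_maps = {}
    for name in names:
        if name == reference:
            continue
        aln = aligner.align(ref_prot, prots[name])[0]
        a, b = aln[0], aln[1]
        at = [None] * len(ref_prot)  # other index aligned to ref residue i
        before = [[] for _ in range(len(ref_prot) + 1)]  # insertions
        ri = oi = 0
        for x, y in zip(a, b):
            if x != "-" and y != "-":
                at[ri] = oi
                ri += 1
                oi += 1
            elif x != "-":
                ri += 1
            else:
                before[ri].append(oi)
                oi += 1
        pair_maps[name] = (at, before)

    # merged column plan: before-column insertions (max over sequences), then
    # the reference column, for each reference position; trailing insertions
    n_ref = len(ref_prot)
    rows = {name: [] for name in names}

    def emit_insertions(pos):
        ins = {n: pair_maps[n][1][pos] for n in pair_maps}
        width = max((len(v) for v in ins.values()), default=0)
        for w in range(width):
            for n in names:
                if n == reference:
                    rows[n].append("---")
                else:
                    lst = ins[n]
                    rows[n].append(codons[n][lst[w]] if w < len(lst) else "---")

    for i in range(n_ref):
        emit_insertions(i)
        rows[reference].append(codons[reference][i])
        for n in pair_maps:
            oi = pair_maps[n][0][i]
            rows[n].append(codons[n][oi] if oi is not None else "---")
    emit_insertions(n_ref)

    return CodonAlignment.from_sequences([(n, "".join(rows[n])) for n in names])


# --------------------------------------------------------------------------
# conserved-block filter
# --------------------------------------------------------------------------
@dataclass
class BlockFilterResult:
    """Outcome of the conserved-block filter.

    ``removed_intervals`` are 0-based half-open codon-column intervals in
    the coordinates of the *input* alignment; together with the kept
    columns they tile the input exactly.
    """

    alignment: CodonAlignment
    removed_intervals: list
    n_input_columns: int
    total_codons: dict = field(default_factory=dict)  # taxon -> non-gap codons in input

    @property
    def n_kept(self) -> int:
        return self.alignment.n_sites

    @property
    def fraction_kept(self) -> float:
        return self.n_kept / self.n_input_columns if self.n_input_columns else 0.0

    def reference_kept_fraction(self, reference: str) -> float:
        """Fraction of the reference species' non-gap codons that survive."""
        aln = self.alignment
        if reference not in aln.taxa:
            return 0.0
        kept = int(np.sum(aln.codes[aln.taxa.index(reference)] >= 0))
        total = self.total_codons.get(reference, 0)
        return kept / total if total else 0.0


def conserved_block_filter(
    alignment: CodonAlignment,
    b2: int | None = None,
    b3: int = 8,
    b4: int = 30,
    mode: str = "codon",
) -> BlockFilterResult:
    """Remove gapped columns, long variable stretches and short blocks.

    Emulates the cited block filter at codon granularity. A column is
    *conserved* when it contains no gap (or ambiguity) and at least
    ``b2`` sequences share the majority amino acid (default ``b2`` =
    number of sequences, the strictest setting). Removal rules:

    * every gap-containing column is removed (the ``t=c`` all-gap policy);
    * maximal runs of more than ``b3`` contiguous non-conserved columns
      are removed (isolated variable columns inside conserved blocks are
      kept — they carry the substitution signal);
    * surviving maximal blocks shorter than ``b4`` codons are removed.

    The removed intervals are recorded in input coordinates.
    """
    if mode != "codon":
        raise ValueError("only codon mode is implemented")
    if b4 < 1:
        raise ValueError("b4 must be >= 1")
    if b3 < 0:
        raise ValueError("b3 must be >= 0")
    n_seq, n_col = alignment.codes.shape
    if b2 is None:
        b2 = n_seq
    if b2 < 1:
        raise ValueError("b2 must be >= 1")
    b2 = min(b2, n_seq)  # a pipeline-wide b2 may exceed a small group's size

    space = alignment.space
    gapped = np.any(alignment.codes < 0, axis=0)
    conserved = np.zeros(n_col, dtype=bool)
    for j in range(n_col):
        if gapped[j]:
            continue
        counts = {}
        for c in alignment.codes[:, j]:
            aa = space.amino_acids[c]
            counts[aa] = counts.get(aa, 0) + 1
        conserved[j] = max(counts.values()) >= b2

    keep = ~gapped
    # remove runs of more than b3 contiguous non-conserved (gap-free) columns;
    # gap columns break blocks, so runs are measured between kept anchors
    for a, b in _runs(np.nonzero(~conserved & ~gapped)[0]):
        if b - a > b3:
            keep[a:b] = False

    # drop surviving blocks shorter than b4 codons, and trim non-conserved
    # block edges so every block starts and ends on a conserved column
    j = 0
    while j < n_col:
        if keep[j]:
            j2 = j
            while j2 < n_col and keep[j2]:
                j2 += 1
            lo, hi = j, j2
            while lo < hi and not conserved[lo]:
                lo += 1
            while hi > lo and not conserved[hi - 1]:
                hi -= 1
            keep[j:lo] = False
            keep[hi:j2] = False
            if hi - lo < b4:
                keep[lo:hi] = False
            j = j2
        else:
            j += 1

    kept_cols = np.nonzero(keep)[0]
    # removed intervals reported in the coordinates the alignment carries,
    # so repeated filtering never mislabels previously removed columns
    removed_in_origin = _runs(alignment.origin[~keep])

    return BlockFilterResult(
        alignment=alignment.take_columns(kept_cols),
        removed_intervals=removed_in_origin,
        n_input_columns=n_col,
        total_codons={
            t: int(np.sum(alignment.codes[i] >= 0)) for i, t in enumerate(alignment.taxa)
        },
    )


def _runs(indices: np.ndarray) -> list:
    """Consecutive-integer runs as half-open (start, stop) pairs."""
    if len(indices) == 0:
        return []
    out = []
    start = prev = int(indices[0])
    for v in indices[1:]:
        v = int(v)
        if v == prev + 1:
            prev = v
            continue
        out.append((start, prev + 1))
        start = prev = v
    out.append((start, prev + 1))
    return out
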
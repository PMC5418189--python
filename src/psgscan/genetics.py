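"""Codon state space for Goldman–Yang-style substitution models.

The state space of a codon model is the set of *sense* codons of a genetic
code (61 for the standard code); stop codons are excluded because coding
sequence is assumed to stay open. Precomputed neighbor structure (which
codon pairs differ at exactly one nucleotide, whether that change is a
transition, and whether it is non-synonymous) is what the rate-matrix
builder consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass(frozen=True)
class CodonSpace:
    """Ordered sense-codon alphabet of a genetic code plus neighbor masks.

    Attributes
    ----------
    codons : tuple of str
        Sense codons in a fixed order (TCAG within each position, the
        conventional codon-table order).
    amino_acids : tuple of str
        One-letter amino acid per sense codon, parallel to ``codons``.
    single_step : ndarray of bool, (n, n)
        True where two codons differ at exactly one nucleotide position.
    transition : ndarray of bool, (n, n)
        True where that single change is a transition (A<->G or C<->T).
    nonsynonymous : ndarray of bool, (n, n)
        True where the encoded amino acid changes.
    """

    codons: tuple
    amino_acids: tuple
    stop_codons: frozenset
    single_step: np.ndarray = field(repr=False)
    transition: np.ndarray = field(repr=False)
    nonsynonymous: np.ndarray = field(repr=False)

    @classmethod
    def standard(cls) -> "CodonSpace":
        return cls.from_ncbi_table(1)

    @classmethod
    def from_ncbi_table(cls, table_id: int) -> "CodonSpace":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        stops = frozenset(table.stop_codons)
        codons = tuple(
            n1 + n2 + n3
            for n1 in NUCLEOTIDES
            for n2 in NUCLEOTIDES
            for n3 in NUCLEOTIDES
            if n1 + n2 + n3 not in stops
        )
        aas = tuple(table.forward_table[c] for c in codons)
        n = len(codons)
        single = np.zeros((n, n), dtype=bool)
        ts = np.zeros((n, n), dtype=bool)
        nonsyn = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                diffs = [p for p in range(3) if codons[i][p] != codons[j][p]]
                if len(diffs) != 1:
                    continue
                p = diffs[0]
                single[i, j] = True
                ts[i, j] = _is_transition(codons[i][p], codons[j][p])
                nonsyn[i, j] = aas[i] != aas[j]
        return cls(codons, aas, stops, single, ts, nonsyn)

    @property
    def n_states(self) -> int:
        return len(self.codons)

    def index(self, codon: str) -> int:
        try:
            return self.codons.index(codon.upper().replace("U", "T"))
        except ValueError:
            raise KeyError(f"not a sense codon: {codon!r}") from None

    def encode(self, sequence: str) -> np.ndarray:
        """Encode an in-frame nucleotide sequence as sense-codon indices.

        Gap codons (``---``) and codons containing ambiguous characters
        are encoded as -1 (missing data). Stop codons raise.
        """
        seq = sequence.upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError(f"sequence length {len(seq)} not divisible by 3")
        lut = {c: i for i, c in enumerate(self.codons)}
        out = np.empty(len(seq) // 3, dtype=np.int64)
        for k in range(0, len(seq), 3):
            codon = seq[k : k + 3]
            if codon in lut:
                out[k // 3] = lut[codon]
            elif codon in self.stop_codons:
                raise ValueError(f"stop codon {codon} at codon position {k // 3}")
            else:
                out[k // 3] = -1  # gap or ambiguity -> missing
        return out

    def decode(self, indices: np.ndarray) -> str:
        return "".join("---" if i < 0 else self.codons[i] for i in indices)

    def translate(self, sequence: str) -> str:
        """Translate an in-frame nucleotide sequence; gaps become '-', ambiguity 'X'."""
        idx = self.encode(sequence)
        aa = []
        for k, i in enumerate(idx):
            if i >= 0:
                aa.append(self.amino_acids[i])
            elif sequence[3 * k : 3 * k + 3] == "---":
                aa.append("-")
            else:
                aa.append("X")
        return "".join(aa)


_STANDARD = None


def standard_codon_space() -> CodonSpace:
    """Shared standard-code instance (61 sense codons)."""
    global _STANDARD
    if _STANDARD is None:
        _STANDARD = CodonSpace.standard()
    return _STANDARD
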
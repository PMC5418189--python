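"""Codon alignment container with column provenance.

A :class:`CodonAlignment` is a gap-aware matrix of codon states over taxa.
Each column remembers its coordinate in the original (pre-filtering)
alignment, so downstream steps — conserved-block filtering, edge-site
removal, adjusted likelihood-ratio tests — can always be expressed in one
shared codon coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import CodonSpace, standard_codon_space


@dataclass
class CodonAlignment:
    """In-frame multiple alignment at codon granularity.

    ``codes[i, j]`` is the sense-codon index of taxon ``i`` at codon column
    ``j``, or -1 for a gap / ambiguous codon (treated as missing data by
    the likelihood). ``origin`` maps each current column to its 0-based
    codon coordinate in the alignment the object was first built from.
    """

    taxa: list
    codes: np.ndarray
    origin: np.ndarray = None
    space: CodonSpace = field(default_factory=standard_codon_space)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (taxa x codon columns)")
        if len(self.taxa) != self.codes.shape[0]:
            raise ValueError("taxa count does not match codes rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if self.origin is None:
            self.origin = np.arange(self.codes.shape[1], dtype=np.int64)
        else:
            self.origin = np.asarray(self.origin, dtype=np.int64)
            if self.origin.shape != (self.codes.shape[1],):
                raise ValueError("origin must have one entry per column")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        """Number of codon columns."""
        return self.codes.shape[1]

    @classmethod
    def from_sequences(
        cls,
        named_sequences: Sequence,
        space: CodonSpace | None = None,
    ) -> "CodonAlignment":
        """Build from ``[(name, in-frame nucleotide string), ...]``."""
        space = space or standard_codon_space()
        names = [n for n, _ in named_sequences]
        lengths = {len(s) for _, s in named_sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        codes = np.vstack([space.encode(s) for _, s in named_sequences])
        return cls(names, codes, space=space)

    @classmethod
    def read_fasta(cls, path, space: CodonSpace | None = None) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences([(r.id, str(r.seq)) for r in records], space=space)

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.space.decode(self.codes[i])), id=name, description="")
            for i, name in enumerate(self.taxa)
        ]
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        SeqIO.write(records, str(path), "fasta")

    def sequence(self, taxon: str) -> str:
        return self.space.decode(self.codes[self.taxa.index(taxon)])

    def take_columns(self, columns: Iterable[int]) -> "CodonAlignment":
        """Column subset preserving provenance (codon coordinates)."""
        cols = np.asarray(list(columns), dtype=np.int64)
        return CodonAlignment(
            list(self.taxa), self.codes[:, cols], self.origin[cols], self.space
        )

    def drop_columns(self, columns: Iterable[int]) -> "CodonAlignment":
        drop = set(int(c) for c in columns)
        keep = [j for j in range(self.n_sites) if j not in drop]
        return self.take_columns(keep)

    def subset_taxa(self, names: Sequence[str]) -> "CodonAlignment":
        idx = [self.taxa.index(n) for n in names]
        return CodonAlignment(list(names), self.codes[idx], self.origin.copy(), self.space)

    def gap_fraction(self, taxon: str) -> float:
        row = self.codes[self.taxa.index(taxon)]
        return float(np.mean(row < 0))

    def pack_patterns(self):
        """Collapse identical columns into (patterns, weights, column->pattern).

        Site patterns are the unit of likelihood computation: identical
        columns contribute identical per-site likelihoods.
        """
        patterns, inverse, counts = np.unique(
            self.codes, axis=1, return_inverse=True, return_counts=True
        )
        return patterns, counts.astype(np.float64), inverse
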
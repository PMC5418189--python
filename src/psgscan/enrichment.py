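"""Downstream enrichment statistics for positive-selection scans.

Four statistics live here:

* Fisher's exact test for over-representation of a gene set among scan
  hits (one-sided hypergeometric tail), with the full 2x2 table reported;
* expression-quantile trimming of a background universe to the 5-95%
  expression range of a reference set (bias control before resampling);
* the multi-stratum draw-and-sum null: per round, a fixed-size draw
  without replacement from each stratum's universe, counting members of a
  special subset, summed across strata — available both as a seeded
  simulation and as the exact convolution of hypergeometric PMFs;
* an exact one-sided binomial test (e.g. expression-direction concordance
  against a 1/4 chance level).

P-values are deliberately not corrected for multiple testing; a
Benjamini–Hochberg helper is provided for callers that want it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

__all__ = [
    "GeneUniverse",
    "EnrichmentResult",
    "NullDistribution",
    "fisher_set_enrichment",
    "trim_background_by_expression",
    "draw_sum_null",
    "binomial_direction_test",
    "benjamini_hochberg",
]


@dataclass
class GeneUniverse:
    """Gene IDs with expression values and named set memberships."""

    genes: list
    expression: dict = field(default_factory=dict)
    sets: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene IDs in universe")
        universe = set(self.genes)
        for name, members in self.sets.items():
            extra = set(members) - universe
            if extra:
                raise ValueError(f"set {name!r} has members outside the universe: {sorted(extra)[:5]}")
            self.sets[name] = set(members)

    def __len__(self) -> int:
        return len(self.genes)

    def set_members(self, name: str) -> set:
        return set(self.sets[name])

    def subset(self, genes) -> "GeneUniverse":
        keep = set(genes)
        return GeneUniverse(
            [g for g in self.genes if g in keep],
            {g: v for g, v in self.expression.items() if g in keep},
            {n: set(m) & keep for n, m in self.sets.items()},
        )

    # -------------------------------------------------------------- file io
    @classmethod
    def read(cls, expression_tsv=None, sets_file=None, genes=None) -> "GeneUniverse":
        """Assemble from a 2-column expression TSV (gene, value) and a
        one-set-per-line file (set name, tab, member, member, ...)."""
        expression: dict = {}
        if expression_tsv is not None:
            df = pd.read_csv(expression_tsv, sep="\t", header=None, comment="#")
            expression = dict(zip(df[0].astype(str), df[1].astype(float)))
        if genes is None:
            genes = list(expression)
        sets = {}
        if sets_file is not None:
            universe = set(genes)
            for line in Path(sets_file).read_text().splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                name, *members = line.rstrip("\n").split("\t")
                sets[name] = set(members) & universe
        return cls(list(genes), expression, sets)

    def write_expression(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f"{g}\t{self.expression.get(g, float('nan'))}\n")

    def write_sets(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                fh.write("\t".join([name, *sorted(self.sets[name])]) + "\n")


@dataclass
class EnrichmentResult:
    """One-sided over-representation test on a 2x2 table."""

    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    fold_enrichment: float
    pvalue: float

    @property
    def table(self):
        """2x2 contingency table [[in both, query only], [set only, neither]]."""
        a = self.overlap
        b = self.query_size - a
        c = self.set_size - a
        d = self.universe_size - a - b - c
        return [[a, b], [c, d]]


def fisher_set_enrichment(query, target, universe: GeneUniverse | int, *,
                          target_size: int | None = None) -> EnrichmentResult:
    """Over-representation of ``target`` among ``query`` within a universe.

    One-sided P = P(overlap >= observed) under the hypergeometric law;
    fold enrichment = (overlap/|query|) / (|target|/|universe|).
    """
    if isinstance(universe, GeneUniverse):
        uni = set(universe.genes)
        query = universe.set_members(query) if isinstance(query, str) else set(query)
        target = universe.set_members(target) if isinstance(target, str) else set(target)
        outside = (query | target) - uni
        if outside:
            raise ValueError(f"genes outside the universe: {sorted(outside)[:5]}")
        n_universe = len(uni)
        k, nq, nt = len(query & target), len(query), len(target)
    else:
        n_universe = int(universe)
        nq = len(set(query))
        nt = target_size if target_size is not None else len(set(target))
        k = len(set(query) & set(target))
    if n_universe == 0:
        raise ValueError("empty universe")
    if nq == 0:
        raise ValueError("empty query set")
    p = float(hypergeom.sf(k - 1, n_universe, nt, nq))
    expected = nq * nt / n_universe
    fold = (k / expected) if expected > 0 else float("nan")
    return EnrichmentResult(k, nq, nt, n_universe, fold, p)


def trim_background_by_expression(
    universe: GeneUniverse, reference, q_lo: float = 0.05, q_hi: float = 0.95
) -> GeneUniverse:
    """Restrict a universe to genes inside the reference set's expression
    quantile band (linear-interpolation quantiles).

    Genes without an expression value are dropped; reference genes lacking
    expression are ignored for the band but must not all be absent.
    """
    ref = [g for g in reference if g in universe.expression]
    if not ref:
        raise ValueError("reference set has no genes with expression values")
    vals = np.array([universe.expression[g] for g in ref], float)
    lo, hi = np.quantile(vals, [q_lo, q_hi])
    keep = [
        g
        for g in universe.genes
        if g in universe.expression and lo <= universe.expression[g] <= hi
    ]
    return universe.subset(keep)


@dataclass
class NullDistribution:
    """Distribution of the summed special-gene count across strata.

    Exact mode stores the convolved PMF; simulation mode stores sorted
    draws. Both expose the same accessors. The reported ``quantile(q)`` is
    the smallest support value whose CDF reaches ``q``.
    """

    mode: str
    support: np.ndarray = None
    pmf: np.ndarray = None
    samples: np.ndarray = None
    rounds: int = 0
    seed: int | None = None

    @property
    def max_observed(self) -> int:
        if self.mode == "simulate":
            return int(self.samples[-1])
        return int(self.support[np.nonzero(self.pmf)[0][-1]])

    def _support_cdf(self):
        if self.mode == "simulate":
            vals, counts = np.unique(self.samples, return_counts=True)
            return vals, np.cumsum(counts) / len(self.samples)
        return self.support, np.cumsum(self.pmf)

    def quantile(self, q: float, convention: str = "lower") -> int:
        """q-quantile of a discrete distribution.

        ``"lower"`` (default): the largest support value x with
        P(X <= x) <= q — the convention under which the scan's reported
        null quantile is defined; falls back to the minimum if even that
        exceeds q. ``"upper"``: the usual inverse CDF, the smallest x
        with P(X <= x) >= q.
        """
        if not 0 < q <= 1:
            raise ValueError("q must be in (0, 1]")
        vals, cdf = self._support_cdf()
        if convention == "upper":
            return int(vals[np.searchsorted(cdf, q - 1e-12)])
        if convention != "lower":
            raise ValueError(f"unknown quantile convention {convention!r}")
        below = np.nonzero(cdf <= q + 1e-12)[0]
        return int(vals[below[-1]]) if len(below) else int(vals[0])

    def tail_probability(self, x: float) -> float:
        """P(sum >= x)."""
        if self.mode == "simulate":
            return float(np.mean(self.samples >= x))
        return float(self.pmf[self.support >= x].sum())

    def mean(self) -> float:
        if self.mode == "simulate":
            return float(self.samples.mean())
        return float(np.dot(self.support, self.pmf))

    def to_frame(self) -> pd.DataFrame:
        if self.mode == "simulate":
            vals, counts = np.unique(self.samples, return_counts=True)
            return pd.DataFrame({"value": vals, "probability": counts / len(self.samples)})
        return pd.DataFrame({"value": self.support, "probability": self.pmf})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def draw_sum_null(
    strata,
    rounds: int = 1_000_000,
    seed: int | None = None,
    mode: str = "exact",
) -> NullDistribution:
    """Null distribution of the summed special count over independent strata.

    ``strata`` is a list of ``(universe_size, special_size, draws)``
    triples. Per stratum a sample of ``draws`` genes is taken without
    replacement from ``universe_size`` of which ``special_size`` are
    special; the statistic is the total number of special genes drawn.

    ``mode="exact"`` convolves the per-stratum hypergeometric PMFs;
    ``mode="simulate"`` performs seeded Monte-Carlo rounds (the count per
    stratum per round is a hypergeometric draw).
    """
    strata = [tuple(int(v) for v in s) for s in strata]
    for n, k, d in strata:
        if not (0 <= k <= n) or not (0 <= d <= n):
            raise ValueError(f"invalid stratum (universe={n}, special={k}, draws={d})")
    if mode == "exact":
        pmf = np.array([1.0])
        for n, k, d in strata:
            top = min(k, d)
            part = hypergeom.pmf(np.arange(top + 1), n, k, d)
            pmf = np.convolve(pmf, part)
        pmf = np.maximum(pmf, 0.0)
        pmf /= pmf.sum()
        return NullDistribution("exact", support=np.arange(len(pmf)), pmf=pmf, rounds=0, seed=seed)
    if mode != "simulate":
        raise ValueError(f"unknown mode {mode!r}")
    if rounds < 1:
        raise ValueError("rounds must be positive")
    rng = np.random.default_rng(seed)
    total = np.zeros(rounds, dtype=np.int64)
    for n, k, d in strata:
        total += rng.hypergeometric(k, n - k, d, size=rounds)
    return NullDistribution("simulate", samples=np.sort(total), rounds=rounds, seed=seed)


def draw_sum_null_from_lists(
    strata_lists, rounds: int = 1_000_000, seed: int | None = None
) -> NullDistribution:
    """List-based wrapper: strata given as (background genes, special genes,
    draw count); only the counts matter for the distribution."""
    strata = []
    for background, special, draws in strata_lists:
        background = set(background)
        special = set(special) & background
        strata.append((len(background), len(special), draws))
    return draw_sum_null(strata, rounds=rounds, seed=seed, mode="simulate")


def binomial_direction_test(
    k: int, n: int, p0: float = 0.25, alternative: str = "greater"
) -> float:
    """Exact binomial test for direction concordance.

    Under independence, a gene changes expression the same way in two
    independent short-lived/long-lived contrasts with chance 1/4, so k
    concordant genes of n are tested against Binomial(n, p0).

    ``alternative="greater"`` gives the upper-tail P(X >= k);
    ``"two-sided"`` gives the exact two-sided (minimum-likelihood) P — the
    convention of R's ``binom.test``, which is what the published
    concordance P-value of this analysis corresponds to.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if alternative == "greater":
        return float(binom.sf(k - 1, n, p0))
    if alternative == "two-sided":
        from scipy.stats import binomtest

        return float(binomtest(int(k), int(n), p0, alternative="two-sided").pvalue)
    raise ValueError(f"unknown alternative {alternative!r}")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (off by default everywhere in this package)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out
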
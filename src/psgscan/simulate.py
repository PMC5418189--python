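"""Synthetic inputs with known ground truth for the selection scan.

Three generators:

* codon alignments evolved under the branch-site mixture on a labelled
  tree (site classes drawn i.i.d. per column; root states from the
  stationary distribution; per-branch transition sampling through the
  exact matrix exponential, so the process is distributionally faithful
  for any branch length);
* multi-isoform transcript catalogs with one true ortholog per species
  and decoy isoforms whose protein similarity to the reference is steered
  into a target band (for exercising ortholog grouping and isoform
  selection);
* gene universes with log-scale expression values and a designated
  special set (for exercising the enrichment statistics).

Fixing the seed reproduces outputs byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import CodonAlignment
from .codon_model import (
    BACKGROUND_OMEGA,
    FOREGROUND_OMEGA,
    N_CLASSES,
    branch_site_class_mixture,
    build_codon_rate_matrix,
    stationary_rate,
    transition_probabilities,
)
from .enrichment import GeneUniverse
from .genetics import CodonSpace, standard_codon_space
from .phylo import Tree

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_codon_alignment",
    "simulate_transcript_catalog",
    "simulate_gene_universe",
    "CLASS_NAMES",
]

CLASS_NAMES = ("0", "1", "2a", "2b")

#: Canonical eight-taxon study tree for calibration experiments: a balanced
#: topology with background branches of 0.08-0.12 expected substitutions
#: per codon site (total length ~1.8, comparable to a moderately deep
#: teleost radiation) and a single foreground branch of 0.25 — the stem of
#: the (C, D) clade, playing the role of a tested ancestral branch.
STUDY_TREE_8 = (
    "(((A:0.12,B:0.12):0.08,(C:0.12,D:0.12) #1:0.25):0.08,"
    "((E:0.12,F:0.12):0.08,(G:0.12,H:0.12):0.08):0.08);"
)


def study_tree() -> Tree:
    """The canonical labelled 8-taxon tree used by calibration experiments."""
    return Tree.parse(STUDY_TREE_8)


@dataclass
class SimulationConfig:
    """Branch-site simulation settings.

    ``tree`` carries branch lengths in expected substitutions per codon
    site (under the mixture-averaged background rate, matching the
    likelihood's unit) and the foreground labels (``#1`` tags or set via
    :meth:`psgscan.phylo.Tree.set_foreground`).
    """

    tree: Tree
    n_sites: int
    kappa: float = 2.0
    omega0: float = 0.2
    omega2: float = 1.0
    p0: float = 0.45
    p1: float = 0.45
    pi: np.ndarray | None = None
    seed: int = 0
    gap_fraction: float = 0.0
    space: CodonSpace = field(default_factory=standard_codon_space)

    def __post_init__(self):
        if isinstance(self.tree, str):
            self.tree = Tree.parse(self.tree)
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0 < self.omega0 < 1:
            raise ValueError("omega0 must be in (0, 1)")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")
        branch_site_class_mixture(self.p0, self.p1)  # validates weights
        if any(n.length < 0 for n in self.tree.edges()):
            raise ValueError("branch lengths must be non-negative")
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must be in [0, 1)")
        if self.pi is None:
            self.pi = np.full(self.space.n_states, 1.0 / self.space.n_states)
        else:
            self.pi = np.asarray(self.pi, float)
            if self.pi.shape != (self.space.n_states,) or np.any(self.pi <= 0):
                raise ValueError("pi must be strictly positive over sense codons")
            if abs(self.pi.sum() - 1.0) > 1e-8:
                raise ValueError("pi must sum to 1")

    @property
    def class_weights(self):
        return branch_site_class_mixture(self.p0, self.p1)


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated alignment."""

    site_classes: np.ndarray  # index into CLASS_NAMES per codon column
    selected: bool  # was omega2 > 1 on the foreground?
    seed: int

    def class_fractions(self) -> np.ndarray:
        return np.bincount(self.site_classes, minlength=N_CLASSES) / len(self.site_classes)


def simulate_codon_alignment(config: SimulationConfig):
    """Evolve one alignment under the branch-site mixture.

    Returns ``(CodonAlignment, SyntheticTruth)``. Foreground edges use
    omega2 for classes 2a/2b; all other class/branch combinations use the
    background omegas (omega0, 1, omega0, 1).
    """
    rng = np.random.default_rng(config.seed)
    space = config.space
    pi = config.pi
    weights = np.array(config.class_weights)

    site_classes = rng.choice(N_CLASSES, size=config.n_sites, p=weights)

    # transition kernels; branch lengths are expected substitutions per
    # codon site under the mixture-averaged background rate, mirroring the
    # likelihood's normalization
    omegas = (config.omega0, 1.0, config.omega2)
    Qs = [build_codon_rate_matrix(config.kappa, om, pi, space, normalize=False) for om in omegas]
    rates = [stationary_rate(Q, pi) for Q in Qs]
    rho = sum(weights[k] * rates[BACKGROUND_OMEGA[k]] for k in range(N_CLASSES))

    tree = config.tree
    root = tree.root
    states = {id(root): _draw_categorical(rng, np.tile(pi, (config.n_sites, 1)))}
    for node in reversed(tree.nodes()):  # preorder
        for child in node.children:
            parent_states = states[id(node)]
            child_states = np.empty_like(parent_states)
            for slot in range(3):
                classes = [
                    k
                    for k in range(N_CLASSES)
                    if (FOREGROUND_OMEGA[k] if child.foreground else BACKGROUND_OMEGA[k]) == slot
                ]
                mask = np.isin(site_classes, classes)
                if not mask.any():
                    continue
                P = transition_probabilities(Qs[slot], child.length / rho, pi=pi)
                child_states[mask] = _draw_categorical(rng, P[parent_states[mask]])
            states[id(child)] = child_states

    taxa = tree.leaf_names()
    codes = np.vstack([states[id(tree.find_leaf(t))] for t in taxa])
    if config.gap_fraction > 0:
        gaps = rng.random(codes.shape) < config.gap_fraction
        codes = np.where(gaps, -1, codes)
    alignment = CodonAlignment(taxa, codes, space=space)
    truth = SyntheticTruth(site_classes, selected=config.omega2 > 1, seed=config.seed)
    return alignment, truth


def _draw_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """One draw per row of a row-stochastic matrix."""
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    r = rng.random((probs.shape[0], 1))
    return (r > cum).sum(axis=1)


# --------------------------------------------------------------------------
# transcript catalogs
# --------------------------------------------------------------------------
def simulate_transcript_catalog(
    n_genes: int,
    species: list,
    reference: str | None = None,
    n_codons: int = 200,
    isoforms_per_gene: int = 1,
    ortholog_identity: float = 0.95,
    decoy_identity: float | None = None,
    identity_band: float = 0.02,
    seed: int = 0,
):
    """Per-species transcript catalogs with a known orthology map.

    Every gene gets one true ortholog per species, mutated from the
    reference sequence to about ``ortholog_identity`` protein identity.
    Additional isoforms (``isoforms_per_gene`` > 1) are decoys steered to
    ``decoy_identity`` (default: clearly below the true ortholog, at
    0.75 * ortholog_identity) within ``+-identity_band``.

    Returns ``(catalogs, truth)``: ``catalogs[species]`` is a list of
    ``(header, cds)`` with headers ``gene|isoform``, and
    ``truth[gene_id][species]`` names the true ortholog isoform.
    """
    if len(species) < 1:
        raise ValueError("need at least one species")
    if len(set(species)) != len(species):
        raise ValueError("duplicate species names")
    reference = reference or species[0]
    if reference not in species:
        raise ValueError(f"reference {reference!r} not among species")
    if decoy_identity is None:
        decoy_identity = 0.75 * ortholog_identity
    rng = np.random.default_rng(seed)
    space = standard_codon_space()

    catalogs = {sp: [] for sp in species}
    truth: dict = {}
    for g in range(n_genes):
        gene = f"g{g:04d}"
        ref_codes = rng.integers(0, space.n_states, size=n_codons)
        truth[gene] = {}
        for sp in species:
            if sp == reference:
                codes = ref_codes.copy()
            else:
                codes = _mutate_to_identity(rng, ref_codes, ortholog_identity, identity_band, space)
            iso = f"{gene}|t1"
            catalogs[sp].append((iso, space.decode(codes)))
            truth[gene][sp] = iso
            for extra in range(2, isoforms_per_gene + 1):
                decoy = _mutate_to_identity(rng, ref_codes, decoy_identity, identity_band, space)
                catalogs[sp].append((f"{gene}|t{extra}", space.decode(decoy)))
    return catalogs, truth


def _mutate_to_identity(rng, codes: np.ndarray, target: float, band: float, space) -> np.ndarray:
    """Randomly substitute codons until protein identity to the source
    enters ``[target - band, target + band]`` (documented band ±2%)."""
    aas = np.array([space.amino_acids[c] for c in codes])
    out = codes.copy()
    if target >= 1.0:
        return out
    for _ in range(20 * len(codes)):
        cur = np.mean(np.array([space.amino_acids[c] for c in out]) == aas)
        if target - band <= cur <= target + band:
            return out
        if cur > target:  # mutate a currently-matching position
            pool = np.nonzero(np.array([space.amino_acids[c] for c in out]) == aas)[0]
        else:  # revert a mismatching position
            pool = np.nonzero(np.array([space.amino_acids[c] for c in out]) != aas)[0]
        if len(pool) == 0:
            return out
        pos = rng.choice(pool)
        out[pos] = codes[pos] if cur < target else rng.integers(0, space.n_states)
    return out  # pragma: no cover - band is always reachable in practice


def write_catalogs(catalogs: dict, directory) -> dict:
    """Write per-species multi-FASTA files; returns species -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sp, entries in catalogs.items():
        path = directory / f"{sp}.fasta"
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths[sp] = path
    return paths


# --------------------------------------------------------------------------
# gene universes
# --------------------------------------------------------------------------
def simulate_gene_universe(
    n_background: int,
    n_special: int,
    log_mean: float = 3.0,
    log_sd: float = 1.5,
    seed: int = 0,
    special_name: str = "special",
) -> GeneUniverse:
    """Universe of genes with log-normal expression and a special subset.

    Defaults put expression on a positive, strongly right-skewed scale
    (log-normal), the shape typical of transcript abundances.
    """
    if n_special > n_background:
        raise ValueError("n_special cannot exceed n_background")
    if n_background < 1:
        raise ValueError("n_background must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_background)]
    expr = dict(zip(genes, np.exp(rng.normal(log_mean, log_sd, size=n_background))))
    special = set(rng.choice(genes, size=n_special, replace=False)) if n_special else set()
    return GeneUniverse(genes, expr, {special_name: special})
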
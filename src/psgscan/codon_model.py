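"""Branch-site codon model: rate matrices, pruning likelihood, class mixture.

The substitution process is the Goldman–Yang codon model: instantaneous
rates between sense codons differing at one nucleotide are

    q_ij = pi_j * kappa^[transition] * omega^[non-synonymous]

(zero for multi-nucleotide changes), with kappa the transition/transversion
rate ratio and omega = dN/dS. The branch-site alternative ("model A")
mixes four site classes:

    class 0 : omega0 on every branch           (weight p0)
    class 1 : omega=1 on every branch          (weight p1)
    class 2a: omega0 background, omega2 foreground  (weight p2a)
    class 2b: omega=1 background, omega2 foreground (weight p2b)

with p2a = (1-p0-p1) p0/(p0+p1) and p2b = (1-p0-p1) p1/(p0+p1), i.e. the
class-2 mass is split in proportion to p0:p1. The null model fixes
omega2 = 1. Per-site likelihoods are mixtures over the four classes of
Felsenstein-pruning likelihoods; branch lengths are measured in expected
substitutions per codon site under the mixture-averaged background rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .alignment import CodonAlignment
from .genetics import CodonSpace, standard_codon_space
from .phylo import Tree

__all__ = [
    "BranchSiteParams",
    "branch_site_class_mixture",
    "build_codon_rate_matrix",
    "transition_probabilities",
    "stationary_rate",
    "BranchSiteLikelihood",
    "codon_frequencies",
]

# class -> omega selector: 0 = omega0, 1 = one, 2 = omega2
BACKGROUND_OMEGA = (0, 1, 0, 1)
FOREGROUND_OMEGA = (0, 1, 2, 2)
N_CLASSES = 4


def branch_site_class_mixture(p0: float, p1: float):
    """Expand (p0, p1) into the four class weights (p0, p1, p2a, p2b)."""
    if p0 < 0 or p1 < 0:
        raise ValueError("class proportions must be non-negative")
    total = p0 + p1
    if total == 0:
        raise ValueError("p0 + p1 must be positive")
    if total > 1 + 1e-12:
        raise ValueError(f"p0 + p1 = {total} exceeds 1")
    p2 = max(0.0, 1.0 - total)
    return (p0, p1, p2 * p0 / total, p2 * p1 / total)


def build_codon_rate_matrix(
    kappa: float,
    omega: float,
    pi: np.ndarray,
    space: CodonSpace | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Goldman–Yang rate matrix over sense codons.

    With ``normalize=True`` the matrix is scaled so the expected number of
    substitutions per codon site per unit time is 1 at stationarity; the
    branch-site mixture instead applies one shared scale across classes
    (see :class:`BranchSiteLikelihood`), so it builds unnormalized matrices.
    """
    space = space or standard_codon_space()
    pi = np.asarray(pi, dtype=float)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if pi.shape != (space.n_states,) or np.any(pi <= 0):
        raise ValueError("pi must be strictly positive over all sense codons")
    Q = np.where(space.single_step, pi[None, :], 0.0)
    Q = Q * np.where(space.transition, kappa, 1.0)
    Q = Q * np.where(space.nonsynonymous, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        rate = stationary_rate(Q, pi)
        if rate > 0:
            Q = Q / rate
    return Q


def stationary_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per site per unit time: -sum_i pi_i Q_ii."""
    return float(-np.dot(pi, np.diag(Q)))


def transition_probabilities(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1.

    For a reversible Q (the Goldman–Yang case) the matrix exponential is
    computed by symmetrized eigendecomposition when ``pi`` is supplied,
    which is both faster and more stable than generic scaling-and-squaring.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if pi is not None:
        lam, B, C = _reversible_eigen(Q, np.asarray(pi, float))
        return _prob_from_eigen(lam, B, C, t)
    from scipy.linalg import expm

    return expm(Q * t)


def _reversible_eigen(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a pi-reversible generator.

    Returns (lam, B, C) with expm(Q t) = (B * exp(lam t)) @ C.
    """
    sqrt_pi = np.sqrt(pi)
    S = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    S = 0.5 * (S + S.T)  # symmetrize away rounding noise
    lam, U = np.linalg.eigh(S)
    B = U / sqrt_pi[:, None]
    C = U.T * sqrt_pi[None, :]
    return lam, B, C


def _prob_from_eigen(lam, B, C, t: float) -> np.ndarray:
    P = (B * np.exp(lam * t)) @ C
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def codon_frequencies(
    alignment: CodonAlignment, mode: str = "f3x4", floor: float = 1e-6
) -> np.ndarray:
    """Equilibrium codon frequencies estimated from an alignment.

    ``f3x4`` (default): product of per-codon-position nucleotide
    frequencies, renormalized over sense codons — the convention of codeml.
    ``f1x4``: one shared nucleotide distribution. ``uniform``: 1/61 each.
    A small floor keeps unobserved codons at positive frequency.
    """
    space = alignment.space
    if mode == "uniform":
        return np.full(space.n_states, 1.0 / space.n_states)
    counts = np.zeros((3, 4))
    nuc_index = {"T": 0, "C": 1, "A": 2, "G": 3}
    for row in alignment.codes:
        for code in row:
            if code < 0:
                continue
            codon = space.codons[code]
            for p in range(3):
                counts[p, nuc_index[codon[p]]] += 1
    if counts.sum() == 0:
        return np.full(space.n_states, 1.0 / space.n_states)
    if mode == "f1x4":
        freq = counts.sum(axis=0)
        freq = freq / freq.sum()
        counts = np.tile(freq, (3, 1))
    elif mode == "f3x4":
        counts = counts / counts.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown codon frequency mode {mode!r}")
    pi = np.array(
        [
            counts[0, nuc_index[c[0]]] * counts[1, nuc_index[c[1]]] * counts[2, nuc_index[c[2]]]
            for c in space.codons
        ]
    )
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


@dataclass(frozen=True)
class BranchSiteParams:
    """Free parameters of the branch-site model (model A).

    ``branch_lengths`` is ordered along the postorder edge list of the tree
    the parameters were fitted on, in expected substitutions per codon site.
    """

    kappa: float
    omega0: float
    omega2: float
    p0: float
    p1: float
    branch_lengths: np.ndarray
    pi: np.ndarray = field(repr=False, default=None)
    fix_omega2: bool = False

    def __post_init__(self):
        if not (0 < self.omega0 <= 1):
            raise ValueError(f"omega0 must be in (0, 1], got {self.omega0}")
        if self.fix_omega2 and abs(self.omega2 - 1.0) > 1e-9:
            raise ValueError("fix_omega2 requires omega2 = 1")
        if self.omega2 < 1:
            raise ValueError(f"omega2 must be >= 1, got {self.omega2}")
        branch_site_class_mixture(self.p0, self.p1)  # validates
        if np.any(np.asarray(self.branch_lengths) < 0):
            raise ValueError("branch lengths must be non-negative")

    @property
    def class_weights(self) -> tuple:
        return branch_site_class_mixture(self.p0, self.p1)

    @property
    def p2a(self) -> float:
        return self.class_weights[2]

    @property
    def p2b(self) -> float:
        return self.class_weights[3]

    def with_(self, **kwargs) -> "BranchSiteParams":
        return replace(self, **kwargs)


class BranchSiteLikelihood:
    """Pruning-algorithm likelihood of a codon alignment under model A.

    The object is built once per (alignment, tree) pair and precomputes the
    site-pattern compression, the postorder edge arrays, and the foreground
    flags; repeated likelihood evaluations during optimization then only
    rebuild the three omega-specific transition kernels.

    Gaps and ambiguous codons are missing data: their tip partial
    likelihood is 1 for every state (implemented by an extra all-ones
    column in each transition matrix).
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: Tree,
        pi: np.ndarray | None = None,
        pi_mode: str = "f3x4",
    ):
        self.space = alignment.space
        self.alignment = alignment
        missing = set(alignment.taxa) - set(tree.leaf_names())
        if missing:
            raise ValueError(f"alignment taxa missing from tree: {sorted(missing)}")
        if set(tree.leaf_names()) - set(alignment.taxa):
            tree = tree.prune_to(alignment.taxa)
        self.tree = tree
        self.pi = np.asarray(pi, float) if pi is not None else codon_frequencies(alignment, pi_mode)

        patterns, weights, inverse = alignment.pack_patterns()
        self.pattern_weights = weights
        self.pattern_of_column = inverse
        self.n_patterns = patterns.shape[1]

        # postorder node arrays; edge i = edge above postorder node i
        self.nodes = tree.nodes()
        self._node_index = {id(n): i for i, n in enumerate(self.nodes)}
        self.edge_nodes = [n for n in self.nodes if n.parent is not None]
        self.edge_index = {id(n): i for i, n in enumerate(self.edge_nodes)}
        self.foreground = np.array([n.foreground for n in self.edge_nodes], bool)
        self.initial_branch_lengths = np.array([n.length for n in self.edge_nodes])

        taxa_row = {t: i for i, t in enumerate(alignment.taxa)}
        # tip codes per leaf node, with -1 remapped to the ones-column index
        n = self.space.n_states
        self.tip_codes = {}
        for node in self.nodes:
            if node.is_leaf:
                codes = patterns[taxa_row[node.name]].copy()
                codes[codes < 0] = n
                self.tip_codes[id(node)] = codes

    @property
    def n_edges(self) -> int:
        return len(self.edge_nodes)

    # ------------------------------------------------------------- kernels
    def eigen_kernels(self, kappa: float, omega0: float, omega2: float):
        """Eigendecomposed unnormalized generators for the three omega slots
        (omega0, 1, omega2) plus their stationary substitution rates."""
        eigs, rates = [], []
        for om in (omega0, 1.0, omega2):
            Q = build_codon_rate_matrix(kappa, om, self.pi, self.space, normalize=False)
            rates.append(stationary_rate(Q, self.pi))
            eigs.append(_reversible_eigen(Q, self.pi))
        return eigs, tuple(rates)

    def rate_scale(self, p0: float, p1: float, rates: tuple) -> float:
        """Mixture-averaged background substitution rate (the branch-length unit)."""
        w = branch_site_class_mixture(p0, p1)
        return sum(w[k] * rates[BACKGROUND_OMEGA[k]] for k in range(N_CLASSES))

    def _transition_mats(self, eigs, u: np.ndarray, need_slot2: bool):
        """Per-edge transition matrices for each omega slot, with an extra
        all-ones column (missing-data state).

        ``u`` holds branch lengths in raw units of the *unnormalized*
        generators. Returns ``mats[omega_slot][edge]``.
        """
        n = self.space.n_states
        ones = np.ones((n, 1))
        needed = {0: set(range(self.n_edges)), 1: set(range(self.n_edges)), 2: set()}
        if need_slot2:
            needed[2] = set(np.nonzero(self.foreground)[0])
        mats = {slot: {} for slot in range(3)}
        for slot, (lam, B, C) in enumerate(eigs):
            for e in needed[slot]:
                P = _prob_from_eigen(lam, B, C, u[e])
                mats[slot][e] = np.hstack([P, ones])
        return mats

    # ----------------------------------------------------------- likelihood
    def _class_site_loglik(self, mats, omega_slots: np.ndarray) -> np.ndarray:
        """Log per-pattern likelihood for one site class.

        ``omega_slots[e]`` selects the omega kernel used on edge ``e``.
        """
        npat = self.n_patterns
        logscale = np.zeros(npat)
        partial: dict[int, np.ndarray] = {}
        for node in self.nodes:
            if node.is_leaf:
                continue
            M: np.ndarray | None = None
            for child in node.children:
                e = self.edge_index[id(child)]
                P = mats[omega_slots[e]][e]
                if child.is_leaf:
                    contrib = P[:, self.tip_codes[id(child)]]
                else:
                    contrib = P[:, :-1] @ partial[id(child)]
                M = contrib if M is None else M * contrib
            mx = M.max(axis=0)
            mx[mx <= 0] = 1.0
            M = M / mx
            logscale += np.log(mx)
            partial[id(node)] = M
        root = self.nodes[-1]
        if root.is_leaf:  # single-taxon alignment
            codes = self.tip_codes[id(root)]
            pi_ext = np.append(self.pi, 1.0)
            return np.log(pi_ext[codes])
        site = self.pi @ partial[id(root)]
        return np.log(np.maximum(site, 1e-300)) + logscale

    def _class_site_logliks_multi(self, mats, slot_rows) -> np.ndarray:
        """Batched pruning: one traversal for several class slot profiles.

        ``slot_rows`` is a (K, n_edges) integer array; returns (K, npat).
        """
        K = len(slot_rows)
        npat = self.n_patterns
        n = self.space.n_states
        logscale = np.zeros((K, npat))
        partial: dict[int, np.ndarray] = {}
        for node in self.nodes:
            if node.is_leaf:
                continue
            M: np.ndarray | None = None
            for child in node.children:
                e = self.edge_index[id(child)]
                P = np.stack([mats[slot_rows[k][e]][e] for k in range(K)])
                if child.is_leaf:
                    contrib = P[:, :, self.tip_codes[id(child)]]
                else:
                    contrib = P[:, :, :-1] @ partial[id(child)]
                M = contrib if M is None else M * contrib
            mx = M.max(axis=1)
            mx[mx <= 0] = 1.0
            M = M / mx[:, None, :]
            logscale += np.log(mx)
            partial[id(node)] = M
        root = self.nodes[-1]
        if root.is_leaf:  # single-taxon alignment
            pi_ext = np.append(self.pi, 1.0)
            return np.tile(np.log(pi_ext[self.tip_codes[id(root)]]), (K, 1))
        site = np.einsum("i,kip->kp", self.pi, partial[id(root)])
        return np.log(np.maximum(site, 1e-300)) + logscale

    def class_site_logliks_raw(
        self, kappa: float, omega0: float, omega2: float, u: np.ndarray
    ) -> np.ndarray:
        """(4, n_patterns) class-conditional log-likelihoods, raw branch units.

        This is the workhorse of the fitter: the result does not depend on
        the class weights, so (p0, p1) can be optimized against cached
        output without re-running the pruning algorithm.
        """
        eigs, _ = self.eigen_kernels(kappa, omega0, omega2)
        mats = self._transition_mats(eigs, np.asarray(u, float), omega2 != 1.0)
        fg = self.foreground
        # with omega2 = 1 the foreground kernel for classes 2a/2b is the
        # neutral kernel, so those pruning passes can reuse slot 1
        fg_slots = FOREGROUND_OMEGA if omega2 != 1.0 else (0, 1, 1, 1)
        rows = [tuple(np.where(fg, fg_slots[k], BACKGROUND_OMEGA[k])) for k in range(N_CLASSES)]
        out = np.empty((N_CLASSES, self.n_patterns))
        cache: dict[tuple, int] = {}
        for k, key in enumerate(rows):
            if key in cache:
                out[k] = out[cache[key]]
                continue
            out[k] = self._class_site_loglik(mats, np.asarray(key))
            cache[key] = k
        return out

    def raw_branch_lengths(self, params: BranchSiteParams) -> np.ndarray:
        """Convert branch lengths from substitutions/codon to raw units."""
        _, rates = self.eigen_kernels(params.kappa, params.omega0, params.omega2)
        rho = self.rate_scale(params.p0, params.p1, rates)
        if rho <= 0:
            raise ValueError("degenerate model: zero expected substitution rate")
        return np.asarray(params.branch_lengths, float) / rho

    def class_site_logliks(self, params: BranchSiteParams) -> np.ndarray:
        """(4, n_patterns) log-likelihoods conditional on each site class."""
        return self.class_site_logliks_raw(
            params.kappa, params.omega0, params.omega2, self.raw_branch_lengths(params)
        )

    def site_logliks(self, params: BranchSiteParams) -> np.ndarray:
        """Per-pattern log mixture likelihood."""
        per_class = self.class_site_logliks(params)
        logw = np.log(np.maximum(params.class_weights, 1e-300))
        return logsumexp(per_class + logw[:, None], axis=0)

    def log_likelihood(self, params: BranchSiteParams) -> float:
        return float(np.dot(self.pattern_weights, self.site_logliks(params)))

    def mixture_loglik(self, class_logliks: np.ndarray, p0: float, p1: float) -> float:
        """Total lnL from cached class-conditional site log-likelihoods."""
        w = branch_site_class_mixture(p0, p1)
        logw = np.log(np.maximum(w, 1e-300))
        site = logsumexp(class_logliks + logw[:, None], axis=0)
        return float(np.dot(self.pattern_weights, site))

    def log_likelihood_raw(
        self, kappa: float, omega0: float, omega2: float, p0: float, p1: float, u: np.ndarray
    ) -> float:
        return self.mixture_loglik(self.class_site_logliks_raw(kappa, omega0, omega2, u), p0, p1)
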
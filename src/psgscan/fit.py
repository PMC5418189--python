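"""Maximum-likelihood fitting of the branch-site model and the LRT.

The alternative model frees omega2 >= 1 on the foreground branches; the
null fixes omega2 = 1. Twice the log-likelihood difference is referred to
a chi-square distribution with one degree of freedom, exactly as the scan
this package implements defines its P-value (the 1/2:1/2 boundary mixture
is available behind a flag and is anti-conservative relative to plain
chi-square, never more).

Optimization is coordinate ascent tailored to the model's structure:

* class weights (p0, p1) never require new pruning passes — the
  class-conditional site likelihoods are cached and the 2-D weight
  problem is solved directly against them;
* (kappa, omega0, omega2) plus one global branch-scale factor are
  optimized by bounded quasi-Newton with numerical gradients;
* individual branch lengths are optimized by 1-D line searches against
  analytic per-edge likelihood profiles obtained from one extra "uppass"
  of outside-subtree partials, so a full branch sweep costs only a few
  likelihood-evaluation equivalents.

Branch lengths are optimized internally in raw units of the unnormalized
generator and converted to expected substitutions per codon site (the
mixture-averaged background rate is the unit) on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import chi2

from .alignment import CodonAlignment
from .codon_model import (
    BACKGROUND_OMEGA,
    FOREGROUND_OMEGA,
    N_CLASSES,
    BranchSiteLikelihood,
    BranchSiteParams,
    _prob_from_eigen,
    _reversible_eigen,
    branch_site_class_mixture,
    build_codon_rate_matrix,
)
from .phylo import Tree

__all__ = [
    "FitResult",
    "LRTResult",
    "SitePosterior",
    "fit_branch_site_model",
    "branch_site_lrt",
    "lrt_pvalue",
    "site_posteriors",
]

_BOUNDS = {
    "kappa": (0.05, 50.0),
    "omega0": (1e-5, 1.0),
    "omega2": (1.0, 99.0),
    "branch": (1e-8, 30.0),
}


@dataclass
class FitResult:
    params: BranchSiteParams
    lnL: float
    converged: bool
    n_evals: int
    n_rounds: int
    message: str = ""


@dataclass
class LRTResult:
    """Branch-site likelihood-ratio test of positive selection."""

    lnL_alt: float
    lnL_null: float
    statistic: float
    pvalue: float
    params_alt: BranchSiteParams
    params_null: BranchSiteParams
    converged: bool
    fit_alt: FitResult = field(repr=False, default=None)
    fit_null: FitResult = field(repr=False, default=None)


@dataclass
class SitePosterior:
    """Per-site posterior class membership under the fitted model."""

    posteriors: np.ndarray  # (n_sites, 4), rows sum to 1
    method: str  # "neb" or "beb"

    @property
    def p_selected(self) -> np.ndarray:
        """Per-site P(class 2a) + P(class 2b): positive selection on foreground."""
        return self.posteriors[:, 2] + self.posteriors[:, 3]

    def selected_sites(self, threshold: float = 0.5) -> np.ndarray:
        """Indices (codon columns) with P(selected) above ``threshold``."""
        return np.nonzero(self.p_selected > threshold)[0]


def lrt_pvalue(lnL_alt: float, lnL_null: float, mixture: bool = False) -> float:
    """Chi-square(1) upper-tail P of the LRT; negative statistics clamp to 0.

    ``mixture=True`` halves the tail (the 1/2 chi2_0 + 1/2 chi2_1 boundary
    null), capped at 1.
    """
    stat = max(0.0, 2.0 * (lnL_alt - lnL_null))
    p = float(chi2.sf(stat, df=1))
    if mixture:
        p = min(1.0, 0.5 * p) if stat > 0 else 1.0
    return p


# --------------------------------------------------------------------------
# internal optimizer
# --------------------------------------------------------------------------
class _Fitter:
    def __init__(self, engine: BranchSiteLikelihood, null: bool, tol: float, max_rounds: int):
        self.eng = engine
        self.null = null
        self.tol = tol
        self.max_rounds = max_rounds
        self.n_evals = 0

    # -- cached class likelihoods ------------------------------------------
    def _class_logliks(self, kappa, om0, om2, u):
        self.n_evals += 1
        return self.eng.class_site_logliks_raw(kappa, om0, om2, u)

    def _mix(self, cls_ll, p0, p1):
        return self.eng.mixture_loglik(cls_ll, p0, p1)

    # -- weight step (no pruning) ------------------------------------------
    def _optimize_weights(self, cls_ll, s, r):
        wts = self.eng.pattern_weights

        def neg(z):
            ss = 1.0 / (1.0 + math.exp(-z[0]))
            rr = 1.0 / (1.0 + math.exp(-z[1]))
            w = branch_site_class_mixture(ss * rr, ss * (1 - rr))
            logw = np.log(np.maximum(w, 1e-300))
            site = logsumexp(cls_ll + logw[:, None], axis=0)
            return -float(np.dot(wts, site))

        s = min(max(s, 1e-6), 1 - 1e-9)
        r = min(max(r, 1e-6), 1 - 1e-6)
        z0 = [math.log(s / (1 - s)), math.log(r / (1 - r))]
        best = minimize(neg, z0, method="Nelder-Mead",
                        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
        ss = 1.0 / (1.0 + math.exp(-best.x[0]))
        rr = 1.0 / (1.0 + math.exp(-best.x[1]))
        return ss, rr, -best.fun

    # -- model-parameter step ----------------------------------------------
    def _optimize_rates(self, kappa, om0, om2, s, r, u):
        p0, p1 = s * r, s * (1 - r)
        lo_k, hi_k = _BOUNDS["kappa"]

        def unpack(z):
            k = math.exp(z[0])
            w0 = math.exp(z[1])
            if self.null:
                w2, c = 1.0, math.exp(z[2])
            else:
                w2, c = 1.0 + math.exp(z[2]), math.exp(z[3])
            return k, w0, w2, c

        def neg(z):
            k, w0, w2, c = unpack(z)
            cls_ll = self._class_logliks(k, w0, w2, u * c)
            return -self._mix(cls_ll, p0, p1)

        if self.null:
            z0 = [math.log(kappa), math.log(max(om0, 1e-5)), 0.0]
            bounds = [(math.log(lo_k), math.log(hi_k)), (math.log(1e-5), 0.0), (-2.0, 2.0)]
        else:
            z0 = [math.log(kappa), math.log(max(om0, 1e-5)),
                  math.log(max(om2 - 1.0, 1e-6)), 0.0]
            bounds = [(math.log(lo_k), math.log(hi_k)), (math.log(1e-5), 0.0),
                      (math.log(1e-6), math.log(_BOUNDS["omega2"][1] - 1.0)), (-2.0, 2.0)]
        res = minimize(neg, z0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 5, "ftol": 1e-10, "eps": 1e-5})
        k, w0, w2, c = unpack(res.x)
        return k, w0, w2, np.clip(u * c, *_BOUNDS["branch"]), -res.fun

    # -- joint polish with hybrid analytic/numeric gradient ----------------
    def _pack(self, kappa, om0, om2, s, r, u):
        z = [math.log(kappa), math.log(max(om0, 1e-5))]
        if not self.null:
            z.append(math.log(max(om2 - 1.0, 1e-8)))
        s = min(max(s, 1e-7), 1 - 1e-9)
        r = min(max(r, 1e-7), 1 - 1e-7)
        z += [math.log(s / (1 - s)), math.log(r / (1 - r))]
        z += list(np.log(np.clip(u, *_BOUNDS["branch"])))
        return np.array(z)

    def _unpack(self, z):
        kappa = math.exp(z[0])
        om0 = math.exp(z[1])
        i = 2
        om2 = 1.0
        if not self.null:
            om2 = 1.0 + math.exp(z[2])
            i = 3
        s = 1.0 / (1.0 + math.exp(-z[i]))
        r = 1.0 / (1.0 + math.exp(-z[i + 1]))
        u = np.exp(z[i + 2 :])
        return kappa, om0, om2, s, r, u

    def _bounds(self, n_edges):
        lo_k, hi_k = _BOUNDS["kappa"]
        b = [(math.log(lo_k), math.log(hi_k)), (math.log(1e-5), 0.0)]
        if not self.null:
            b.append((math.log(1e-8), math.log(_BOUNDS["omega2"][1] - 1.0)))
        b += [(-9.2, 11.5), (-9.2, 9.2)]
        b += [(math.log(_BOUNDS["branch"][0]), math.log(_BOUNDS["branch"][1]))] * n_edges
        return b

    def _value_and_grad(self, z):
        """Total -lnL and its gradient in packed coordinates.

        Branch-length and class-weight partials are analytic (outside-
        subtree partials give d lnL / d u_e from one extra pass; the
        product form of the class weights gives the (s, r) partials from
        the class responsibilities); kappa and the omegas are finite
        differences in log space.
        """
        eng = self.eng
        kappa, om0, om2, s, r, u = self._unpack(z)
        p0, p1 = s * r, s * (1 - r)
        eigs, _ = eng.eigen_kernels(kappa, om0, om2)
        mats = eng._transition_mats(eigs, u, om2 != 1.0)
        profiles = self._class_slot_profiles(om2)
        cache = {}
        per_class = []
        for key in profiles:
            if key not in cache:
                cache[key] = self._down_up(mats, key, with_root=True)
                self.n_evals += 1
            per_class.append(cache[key])
        cls_ll = np.stack([pc[3] for pc in per_class])
        w = np.array(branch_site_class_mixture(p0, p1))
        logw = np.log(np.maximum(w, 1e-300))
        joint = cls_ll + logw[:, None]
        logmix = logsumexp(joint, axis=0)
        wts = eng.pattern_weights
        lnl = float(np.dot(wts, logmix))
        resp = np.exp(joint - logmix)  # (4, npat) responsibilities

        grad = np.zeros_like(z)
        # weights (logit coordinates)
        R = resp @ wts  # total responsibility mass per class
        iw = 2 if self.null else 3
        grad[iw] = (R[0] + R[1]) * (1 - s) - (R[2] + R[3]) * s
        grad[iw + 1] = (R[0] + R[2]) * (1 - r) - (R[1] + R[3]) * r

        # branch lengths (log coordinates), analytic via dP/du = B lam e C
        n = eng.space.n_states
        zeros = np.zeros((n, 1))
        for e in range(eng.n_edges):
            acc = np.zeros(eng.n_patterns)
            dP_cache = {}
            for k in range(N_CLASSES):
                if w[k] <= 0:
                    continue
                A, als, down, _ = per_class[k]
                m_v, ls_v, is_tip = down[e]
                slot = profiles[k][e]
                if slot not in dP_cache:
                    lam, B, C = eigs[slot]
                    dP = (B * (lam * np.exp(lam * u[e]))) @ C
                    dP_cache[slot] = np.hstack([dP, zeros])
                dP = dP_cache[slot]
                if is_tip:
                    g = (A[e] * dP[:, m_v]).sum(axis=0)
                else:
                    g = (A[e] * (dP[:, :-1] @ m_v)).sum(axis=0)
                acc += w[k] * g * np.exp(als[e] + ls_v - logmix)
            grad[iw + 2 + e] = float(np.dot(wts, acc)) * u[e]

        # kappa / omegas by forward differences in packed coordinates; a
        # perturbed omega only touches the classes whose kernels use it, so
        # the other class rows and transition matrices are reused
        h = 1e-4
        slot_of_param = {0: None, 1: 0}  # kappa -> all slots, omega0 -> slot 0
        if not self.null:
            slot_of_param[2] = 2
        for j in range(iw):
            zj = z.copy()
            zj[j] += h
            kj, w0j, w2j, _, _, _ = self._unpack(zj)
            lj = self._perturbed_lnl(
                kj, w0j, w2j, u, p0, p1, slot_of_param[j], eigs, mats, profiles, cls_ll
            )
            grad[j] = (lj - lnl) / h

        return -lnl, -grad

    def _perturbed_lnl(self, kappa, om0, om2, u, p0, p1, slot, eigs, mats, profiles, cls_ll):
        """Mixture lnL after perturbing one rate parameter.

        ``slot=None`` (kappa) rebuilds everything; otherwise only the
        transition matrices of ``slot`` and the class rows whose profile
        uses that slot are recomputed.
        """
        eng = self.eng
        self.n_evals += 1
        if slot is None:
            return self._mix(eng.class_site_logliks_raw(kappa, om0, om2, u), p0, p1)
        om = {0: om0, 2: om2}[slot]
        Q = build_codon_rate_matrix(kappa, om, eng.pi, eng.space, normalize=False)
        lam, B, C = _reversible_eigen(Q, eng.pi)
        n = eng.space.n_states
        ones = np.ones((n, 1))
        new_mats = dict(mats)
        new_mats[slot] = {
            e: np.hstack([_prob_from_eigen(lam, B, C, u[e]), ones])
            for e in mats[slot]
        }
        out = cls_ll.copy()
        done = {}
        for k, key in enumerate(profiles):
            if slot not in key:
                continue
            if key not in done:
                done[key] = self._class_site_loglik_from(new_mats, key)
            out[k] = done[key]
        return self._mix(out, p0, p1)

    def _class_site_loglik_from(self, mats, slots):
        return self.eng._class_site_loglik(mats, np.asarray(slots))

    def _polish(self, kappa, om0, om2, s, r, u, maxiter):
        z0 = self._pack(kappa, om0, om2, s, r, u)
        res = minimize(
            self._value_and_grad,
            z0,
            jac=True,
            method="L-BFGS-B",
            bounds=self._bounds(len(u)),
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-3},
        )
        kappa, om0, om2, s, r, u = self._unpack(res.x)
        return kappa, om0, om2, s, r, u, -res.fun, bool(res.success)

    # -- branch sweep with analytic per-edge profiles ----------------------
    def _class_slot_profiles(self, om2):
        fg_slots = FOREGROUND_OMEGA if om2 != 1.0 else (0, 1, 1, 1)
        return [
            tuple(np.where(self.eng.foreground, fg_slots[k], BACKGROUND_OMEGA[k]))
            for k in range(N_CLASSES)
        ]

    def _down_up(self, mats, slots, with_root: bool = True):
        """Down- and up-pass partials for one class slot profile.

        Returns ``(A, als, down, root_loglik)``: per-edge outside-subtree
        partials with their log-scales, per-edge below structures, and the
        per-pattern class-conditional log-likelihood, enabling cheap
        evaluation of the site likelihood as a function of any single
        branch length and the analytic branch-length gradient.
        """
        eng = self.eng
        P = {e: mats[slots[e]][e] for e in range(eng.n_edges)}
        npat = eng.n_patterns
        S, M, ls = {}, {}, {}
        for node in eng.nodes:
            if node.is_leaf:
                continue
            acc, sc = None, np.zeros(npat)
            for child in node.children:
                e = eng.edge_index[id(child)]
                if child.is_leaf:
                    S[e] = P[e][:, eng.tip_codes[id(child)]]
                else:
                    S[e] = P[e][:, :-1] @ M[id(child)]
                    sc = sc + ls[id(child)]
                acc = S[e].copy() if acc is None else acc * S[e]
            mx = acc.max(axis=0)
            mx[mx <= 0] = 1.0
            acc /= mx
            M[id(node)] = acc
            ls[id(node)] = sc + np.log(mx)

        root = eng.nodes[-1]
        A, als = {}, {}
        T = {id(root): (np.repeat(eng.pi[:, None], npat, axis=1), np.zeros(npat))}
        for node in reversed(eng.nodes):  # preorder
            if node.is_leaf:
                continue
            Tp, Tsc = T[id(node)]
            kids = node.children
            for i, child in enumerate(kids):
                e = eng.edge_index[id(child)]
                acc = Tp.copy()
                sc = Tsc.copy()
                for j, sib in enumerate(kids):
                    if j == i:
                        continue
                    es = eng.edge_index[id(sib)]
                    acc *= S[es]
                    if not sib.is_leaf:
                        sc += ls[id(sib)]
                mx = acc.max(axis=0)
                mx[mx <= 0] = 1.0
                acc /= mx
                sc = sc + np.log(mx)
                A[e], als[e] = acc, sc
                if not child.is_leaf:
                    T[id(child)] = (P[e][:, :-1].T @ acc, sc)
        # per-edge: site logL(u_e) = log(sum_x A_e(x) * [P m_v](x)) + als_e + ls_v
        down = {}
        for node in eng.edge_nodes:
            e = eng.edge_index[id(node)]
            if node.is_leaf:
                down[e] = (eng.tip_codes[id(node)], np.zeros(npat), True)
            else:
                down[e] = (M[id(node)], ls[id(node)], False)
        root_ll = None
        if with_root:
            if root.is_leaf:
                pi_ext = np.append(eng.pi, 1.0)
                root_ll = np.log(pi_ext[eng.tip_codes[id(root)]])
            else:
                site = eng.pi @ M[id(root)]
                root_ll = np.log(np.maximum(site, 1e-300)) + ls[id(root)]
        return A, als, down, root_ll

    def _branch_sweep(self, kappa, om0, om2, p0, p1, u, lnl0):
        eng = self.eng
        eigs, _ = eng.eigen_kernels(kappa, om0, om2)
        mats = eng._transition_mats(eigs, u, om2 != 1.0)
        profiles = self._class_slot_profiles(om2)
        cache = {}
        per_class = []
        for k in range(N_CLASSES):
            key = profiles[k]
            if key not in cache:
                cache[key] = self._down_up(mats, key)
                self.n_evals += 1
            per_class.append(cache[key])
        logw = np.log(np.maximum(branch_site_class_mixture(p0, p1), 1e-300))
        wts = eng.pattern_weights
        n = eng.space.n_states
        ones = np.ones((n, 1))
        lo, hi = _BOUNDS["branch"]

        u_new = u.copy()
        for e in range(eng.n_edges):
            slot_of = [profiles[k][e] for k in range(N_CLASSES)]

            def neg(log_ue):
                ue = math.exp(log_ue)
                site = np.empty((N_CLASSES, eng.n_patterns))
                pm = {}
                for k in range(N_CLASSES):
                    A, als, down, _ = per_class[k]
                    m_v, ls_v, is_tip = down[e]
                    s = slot_of[k]
                    if s not in pm:
                        lam, B, C = eigs[s]
                        pm[s] = np.hstack([_prob_from_eigen(lam, B, C, ue), ones])
                    P = pm[s]
                    if is_tip:
                        vals = (A[e] * P[:, m_v]).sum(axis=0)
                    else:
                        vals = (A[e] * (P[:, :-1] @ m_v)).sum(axis=0)
                    site[k] = np.log(np.maximum(vals, 1e-300)) + als[e] + ls_v
                mix = logsumexp(site + logw[:, None], axis=0)
                return -float(np.dot(wts, mix))

            span = 1.2  # max log-change per sweep keeps stale-partial error local
            z0 = math.log(np.clip(u[e], lo, hi))
            res = minimize_scalar(
                neg,
                bounds=(max(math.log(lo), z0 - span), min(math.log(hi), z0 + span)),
                method="bounded",
                options={"xatol": 1e-4},
            )
            u_new[e] = math.exp(res.x)

        cls_ll = self._class_logliks(kappa, om0, om2, u_new)
        lnl1 = self._mix(cls_ll, p0, p1)
        if lnl1 >= lnl0:
            return u_new, cls_ll, lnl1
        # simultaneous updates overshot: back off geometrically toward u
        for _ in range(3):
            u_new = np.sqrt(u_new * u)
            cls_ll = self._class_logliks(kappa, om0, om2, u_new)
            lnl1 = self._mix(cls_ll, p0, p1)
            if lnl1 >= lnl0:
                return u_new, cls_ll, lnl1
        cls_ll = self._class_logliks(kappa, om0, om2, u)
        return u, cls_ll, self._mix(cls_ll, p0, p1)

    # -- main loop ----------------------------------------------------------
    def warmup(self, kappa, om0, om2, s, r, u, rounds: int = 1):
        """Cheap coordinate-ascent rounds locating the basin of attraction."""
        if self.null:
            om2 = 1.0
        u = np.clip(np.asarray(u, float), *_BOUNDS["branch"])
        cls_ll = self._class_logliks(kappa, om0, om2, u)
        s, r, lnl = self._optimize_weights(cls_ll, s, r)
        history = [lnl]
        for _ in range(rounds):
            prev = lnl
            kappa, om0, om2, u, lnl = self._optimize_rates(kappa, om0, om2, s, r, u)
            if self.null:
                om2 = 1.0
            u, cls_ll, lnl = self._branch_sweep(
                kappa, om0, om2, s * r, s * (1 - r), u, max(prev, lnl)
            )
            s, r, lnl = self._optimize_weights(cls_ll, s, r)
            history.append(lnl)
            if lnl - prev < self.tol:
                break
        return dict(kappa=kappa, omega0=om0, omega2=om2, s=s, r=r, u=u,
                    lnL=lnl, converged=False, rounds=len(history) - 1, history=history)

    def run(self, kappa, om0, om2, s, r, u, warmup_rounds: int = 2, polish_iter: int = 200):
        """Coordinate-ascent warmup, then joint quasi-Newton polish."""
        out = self.warmup(kappa, om0, om2, s, r, u, rounds=warmup_rounds)
        return self.finish(out, polish_iter=polish_iter)

    def finish(self, out: dict, polish_iter: int = 200) -> dict:
        """Joint polish of a warmup result to the final optimum."""
        kappa, om0, om2, s, r, u, lnl, ok = self._polish(
            out["kappa"], out["omega0"], out["omega2"], out["s"], out["r"], out["u"],
            maxiter=polish_iter,
        )
        if lnl < out["lnL"]:  # line search stopped on numerical noise
            return dict(out, converged=True)
        history = out["history"] + [lnl]
        return dict(kappa=kappa, omega0=om0, omega2=om2, s=s, r=r, u=u,
                    lnL=lnl, converged=ok, rounds=len(history) - 1, history=history)


def _default_start(null: bool):
    return dict(kappa=2.0, om0=0.4, om2=1.0 if null else 2.5, s=0.85, r=0.6)


def fit_branch_site_model(
    alignment: CodonAlignment,
    tree: Tree,
    foreground=None,
    null: bool = False,
    pi: np.ndarray | None = None,
    pi_mode: str = "f3x4",
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_rounds: int = 10,
    start: dict | None = None,
    engine: BranchSiteLikelihood | None = None,
) -> FitResult:
    """Fit the branch-site model (alternative, or null with omega2 = 1).

    ``foreground`` may be a list of taxa (the edge above their MRCA is
    marked) or None to use the ``#1`` tags already present in the tree.
    The first start is either ``start`` (e.g. warm parameters from the
    null fit) or standard defaults; the remaining ``n_starts - 1`` starts
    are seeded random perturbations given a reduced round budget, guarding
    against local optima. The best final likelihood wins.
    """
    if engine is None:
        tree = tree.copy()
        if foreground is not None:
            tree.set_foreground(foreground)
        if not tree.foreground_edges():
            raise ValueError("no foreground branch: tag the tree or pass `foreground`")
        engine = BranchSiteLikelihood(alignment, tree, pi=pi, pi_mode=pi_mode)

    if alignment.n_taxa < 2 or alignment.n_sites < 1:
        raise ValueError("alignment must have >= 2 taxa and >= 1 codon site")

    fitter = _Fitter(engine, null, tol, max_rounds)
    rng = np.random.default_rng(seed)

    # convert the tree's branch lengths (substitutions/codon) to raw units
    # at the starting parameters
    base = start or _default_start(null)
    _, rates = engine.eigen_kernels(base["kappa"], base["om0"], base["om2"])
    p0 = base["s"] * base["r"]
    p1 = base["s"] * (1 - base["r"])
    rho = engine.rate_scale(p0, p1, rates)
    u0 = base.get("u")
    if u0 is None:
        u0 = np.maximum(engine.initial_branch_lengths, 1e-4) / rho

    # all starts get cheap warmup probes; only the best basin is polished
    best = None
    for i in range(max(1, n_starts)):
        if i == 0:
            st = dict(base, u=u0)
            # a provided warm start (e.g. the null optimum) is already in
            # its basin; cold starts get an extra coordinate round
            rounds = min(1 if start is not None else 2, max_rounds)
        else:
            # restarts probe other basins, notably high omega2 for the
            # alternative model
            st = dict(
                kappa=float(np.exp(rng.normal(np.log(2.0), 0.6))),
                om0=float(rng.uniform(0.05, 0.95)),
                om2=1.0 if null else float(1.0 + rng.exponential(4.0)),
                s=float(rng.uniform(0.5, 0.98)),
                r=float(rng.uniform(0.2, 0.8)),
                u=u0 * np.exp(rng.normal(0.0, 0.3, size=len(u0))),
            )
            rounds = 1
        out = fitter.warmup(st["kappa"], st["om0"], st["om2"], st["s"], st["r"], st["u"],
                            rounds=rounds)
        if best is None or out["lnL"] > best["lnL"]:
            best = out
    best = fitter.finish(best, polish_iter=200)

    # convert raw branch units back to expected substitutions per codon site
    _, rates = engine.eigen_kernels(best["kappa"], best["omega0"], best["omega2"])
    p0, p1 = best["s"] * best["r"], best["s"] * (1 - best["r"])
    rho = engine.rate_scale(p0, p1, rates)
    params = BranchSiteParams(
        kappa=best["kappa"],
        omega0=min(best["omega0"], 1.0),
        omega2=max(best["omega2"], 1.0),
        p0=p0,
        p1=p1,
        branch_lengths=best["u"] * rho,
        pi=engine.pi,
        fix_omega2=null,
    )
    return FitResult(
        params=params,
        lnL=best["lnL"],
        converged=best["converged"],
        n_evals=fitter.n_evals,
        n_rounds=best["rounds"],
        message="" if best["converged"] else "round budget exhausted before lnL tolerance",
    )


def branch_site_lrt(
    alignment: CodonAlignment,
    tree: Tree,
    foreground=None,
    pi: np.ndarray | None = None,
    pi_mode: str = "f3x4",
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_rounds: int = 10,
    mixture_null: bool = False,
) -> LRTResult:
    """Run both fits and the chi-square(1) LRT of positive selection.

    The null model (omega2 = 1) is fitted first from standard starting
    values; the alternative is warm-started at the null's optimum (where
    it is nested) plus random restarts.
    """
    tree = tree.copy()
    if foreground is not None:
        tree.set_foreground(foreground)
    if not tree.foreground_edges():
        raise ValueError("no foreground branch: tag the tree or pass `foreground`")
    engine = BranchSiteLikelihood(alignment, tree, pi=pi, pi_mode=pi_mode)

    fit_null = fit_branch_site_model(
        alignment, tree, null=True, n_starts=max(1, n_starts - 1), seed=seed,
        tol=tol, max_rounds=max_rounds, engine=engine,
    )
    pn = fit_null.params
    # cap the class-2 mass away from zero: at s = p0+p1 = 1 the likelihood
    # is flat in omega2 and the alternative fit could never leave the null
    warm = dict(
        kappa=pn.kappa, om0=pn.omega0, om2=2.5,
        s=min(pn.p0 + pn.p1, 0.90),
        r=pn.p0 / max(pn.p0 + pn.p1, 1e-12),
        u=engine.raw_branch_lengths(pn),
    )
    fit_alt = fit_branch_site_model(
        alignment, tree, null=False, n_starts=n_starts, seed=seed + 1,
        tol=tol, max_rounds=max_rounds, start=warm, engine=engine,
    )
    lnL_alt, lnL_null = fit_alt.lnL, fit_null.lnL
    stat = max(0.0, 2.0 * (lnL_alt - lnL_null))
    return LRTResult(
        lnL_alt=lnL_alt,
        lnL_null=lnL_null,
        statistic=stat,
        pvalue=lrt_pvalue(lnL_alt, lnL_null, mixture=mixture_null),
        params_alt=fit_alt.params,
        params_null=fit_null.params,
        converged=fit_alt.converged and fit_null.converged,
        fit_alt=fit_alt,
        fit_null=fit_null,
    )


# --------------------------------------------------------------------------
# empirical-Bayes site classification
# --------------------------------------------------------------------------
def site_posteriors(
    alignment: CodonAlignment,
    tree: Tree,
    params: BranchSiteParams,
    method: str = "neb",
    grid: int = 10,
    engine: BranchSiteLikelihood | None = None,
) -> SitePosterior:
    """Posterior site-class probabilities under fitted parameters.

    ``"neb"`` (naive empirical Bayes) conditions on the MLEs. ``"beb"``
    integrates over a uniform discrete prior on a grid of ``grid`` points
    per dimension: the (p0, p1) simplex, omega0 in (0, 1) and omega2 in
    [1, 11], with kappa and branch lengths held at their MLEs.
    """
    if engine is None:
        engine = BranchSiteLikelihood(alignment, tree)
    if method == "neb":
        cls_ll = engine.class_site_logliks(params)
        logw = np.log(np.maximum(params.class_weights, 1e-300))
        joint = cls_ll + logw[:, None]
        post = np.exp(joint - logsumexp(joint, axis=0, keepdims=True))
        return SitePosterior(post.T[engine.pattern_of_column], "neb")
    if method != "beb":
        raise ValueError(f"unknown site-posterior method {method!r}")

    d = grid
    u = engine.raw_branch_lengths(params)
    kappa = params.kappa
    fg = engine.foreground
    npat = engine.n_patterns

    om0_grid = (np.arange(d) + 0.5) / d
    om2_grid = 1.0 + (np.arange(d) + 0.5) * (10.0 / d)

    def one_pass(bg_omega, fg_omega):
        eigs, _ = engine.eigen_kernels(kappa, bg_omega, fg_omega)
        slots = tuple(np.where(fg, 2, 0))
        mats = engine._transition_mats(eigs, u, need_slot2=True)
        return engine._class_site_loglik(mats, slots)

    L1 = one_pass(1.0, 1.0)  # class 1: neutral everywhere
    L0 = np.stack([one_pass(w0, w0) for w0 in om0_grid])  # (d, npat)
    L2b = np.stack([one_pass(1.0, w2) for w2 in om2_grid])  # (d, npat)
    L2a = np.stack(
        [one_pass(w0, w2) for w0 in om0_grid for w2 in om2_grid]
    ).reshape(d, d, npat)

    pairs = [
        ((i + 0.5) / d, (j + 0.5) / d)
        for i in range(d)
        for j in range(d)
        if (i + 0.5) / d + (j + 0.5) / d < 1.0
    ]
    logw_pairs = np.log(
        np.maximum([branch_site_class_mixture(p0, p1) for p0, p1 in pairs], 1e-300)
    )  # (npairs, 4)

    ip, io0, io2 = np.meshgrid(
        np.arange(len(pairs)), np.arange(d), np.arange(d), indexing="ij"
    )
    ip, io0, io2 = ip.ravel(), io0.ravel(), io2.ravel()
    # (ncombo, 4, npat) class-conditional logliks per grid combination
    L = np.stack(
        [L0[io0], np.broadcast_to(L1, (len(ip), npat)), L2a[io0, io2], L2b[io2]], axis=1
    )
    joint = L + logw_pairs[ip][:, :, None]
    site_mix = logsumexp(joint, axis=1)  # (ncombo, npat)
    log_f = site_mix @ engine.pattern_weights  # log f(X | combo), uniform prior
    post_combo = np.exp(log_f - logsumexp(log_f))
    resp = np.exp(joint - site_mix[:, None, :])  # responsibilities per combo
    post = np.einsum("c,ckp->pk", post_combo, resp)
    post /= post.sum(axis=1, keepdims=True)
    return SitePosterior(post[engine.pattern_of_column], "beb")
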
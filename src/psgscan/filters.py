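"""Candidate filters I-V and the edge-site adjustment.

Genome-scale branch-site scans produce false positives from sparse
alignments, alignment errors and pathological fits; candidates are
therefore required to pass five hard criteria:

I    at least one species from the sister branch of the tested branch is
     present in the alignment (otherwise the foreground branch is not
     anchored);
II   at least four species in the alignment;
III  enough alignment survives block filtering: >= 60 codon columns kept,
     >= 66.67% of columns kept, and >= 60% of the reference species'
     codons kept;
IV   no disproportional dN/dS estimates: foreground omega2 < 100,
     foreground omega2 >= 0.85, background omega summary <= 1;
V    at most 20% of sites called positively selected.

Separately, called sites that lie within a two-codon window of an
alignment block removed by the conserved-block filter are discarded and
the likelihood-ratio test is recomputed on the alignment without those
columns ("adjusted P-value"), since filter-edge columns are the classic
home of alignment-error artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import CodonAlignment
from .codon_model import BranchSiteParams
from .fit import LRTResult, SitePosterior, branch_site_lrt
from .phylo import Tree

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "apply_candidate_filters",
    "background_omega_summary",
    "edge_site_adjust",
    "EdgeAdjustResult",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of criteria I-V (defaults are the scan's published values)."""

    min_species: int = 4  # II
    min_columns: int = 60  # III
    min_fraction_kept: float = 2.0 / 3.0  # III (66.67%)
    min_reference_kept: float = 0.60  # III
    max_foreground_omega: float = 100.0  # IV
    min_foreground_omega: float = 0.85  # IV
    max_background_omega: float = 1.0  # IV
    max_selected_fraction: float = 0.20  # V
    site_call_threshold: float = 0.5  # posterior cut defining a "called" site


@dataclass
class FilterReport:
    """Per-gene verdict with supporting numbers and reason codes."""

    gene: str
    passed: bool
    failed_criteria: list  # subset of ["I","II","III","IV","V","manual"]
    n_species: int
    has_sister_species: bool
    n_columns_kept: int
    fraction_kept: float
    reference_kept_fraction: float
    foreground_omega: float
    background_omega: float
    fraction_selected_sites: float
    manual_flag: bool = False

    def reasons(self) -> str:
        return ";".join(self.failed_criteria)


def background_omega_summary(params: BranchSiteParams) -> float:
    """Single background dN/dS summary of the fitted mixture.

    The branch-site model has no single background omega; the summary used
    for criterion IV is the class-proportion-weighted mean omega on
    background branches, (p0 + p2a) * omega0 + (p1 + p2b) * 1.
    """
    p0, p1, p2a, p2b = params.class_weights
    return (p0 + p2a) * params.omega0 + (p1 + p2b) * 1.0


def apply_candidate_filters(
    gene: str,
    species: list,
    sister_species: list,
    n_columns_kept: int,
    fraction_kept: float,
    reference_kept_fraction: float,
    params_alt: BranchSiteParams,
    posterior: SitePosterior | None,
    thresholds: FilterThresholds | None = None,
    manual_flag: bool = False,
) -> FilterReport:
    """Evaluate criteria I-V independently and collect every failure.

    ``species`` is the taxon list of the tested alignment;
    ``sister_species`` the species of the sister branch of the tested
    branch (criterion I demands at least one of them present).
    """
    th = thresholds or FilterThresholds()
    for name, value in [
        ("gene", gene), ("species", species), ("params_alt", params_alt),
    ]:
        if value is None:
            raise ValueError(f"missing required input: {name}")

    failed = []
    present = set(species)
    has_sister = bool(present & set(sister_species))
    if not has_sister:
        failed.append("I")
    if len(species) < th.min_species:
        failed.append("II")
    if (
        n_columns_kept < th.min_columns
        or fraction_kept < th.min_fraction_kept
        or reference_kept_fraction < th.min_reference_kept
    ):
        failed.append("III")
    bg_omega = background_omega_summary(params_alt)
    if (
        params_alt.omega2 >= th.max_foreground_omega
        or params_alt.omega2 < th.min_foreground_omega
        or bg_omega > th.max_background_omega
    ):
        failed.append("IV")
    frac_selected = 0.0
    if posterior is not None and posterior.posteriors.shape[0] > 0:
        frac_selected = float(
            np.mean(posterior.p_selected > th.site_call_threshold)
        )
    if frac_selected > th.max_selected_fraction:
        failed.append("V")
    if manual_flag:
        failed.append("manual")

    return FilterReport(
        gene=gene,
        passed=not failed,
        failed_criteria=failed,
        n_species=len(species),
        has_sister_species=has_sister,
        n_columns_kept=n_columns_kept,
        fraction_kept=fraction_kept,
        reference_kept_fraction=reference_kept_fraction,
        foreground_omega=params_alt.omega2,
        background_omega=bg_omega,
        fraction_selected_sites=frac_selected,
        manual_flag=manual_flag,
    )


@dataclass
class EdgeAdjustResult:
    """Original vs adjusted test after removing filter-edge sites."""

    pvalue_original: float
    pvalue_adjusted: float
    dropped_sites: list  # codon columns (alignment coordinates) removed
    kept_called_sites: list  # called sites surviving the window rule
    lrt_adjusted: LRTResult | None = None


def _near_removed(origin_coord: int, removed_intervals, window: int) -> bool:
    for a, b in removed_intervals:
        if a - window <= origin_coord <= b - 1 + window:
            return True
    return False


def edge_site_adjust(
    alignment: CodonAlignment,
    tree: Tree,
    lrt: LRTResult,
    posterior: SitePosterior,
    removed_intervals,
    window: int = 2,
    site_call_threshold: float = 0.5,
    mode: str = "refit",
    **fit_kwargs,
) -> EdgeAdjustResult:
    """Drop called sites near removed blocks and recompute the LRT.

    A called site (posterior P(selected) above the threshold) is dropped
    when its codon column lies within ``window`` columns (inclusive) of
    any removed interval; intervals and the alignment's column provenance
    are in the same original codon coordinate system. ``mode="refit"``
    recomputes both model fits on the alignment with the flagged columns
    excluded; ``mode="report_only"`` only prunes the site list and keeps
    the original P.
    """
    if posterior.posteriors.shape[0] != alignment.n_sites:
        raise ValueError(
            f"posterior covers {posterior.posteriors.shape[0]} sites but the "
            f"alignment has {alignment.n_sites} columns"
        )
    called = posterior.selected_sites(site_call_threshold)
    if np.any(called >= alignment.n_sites):
        raise ValueError("called site index beyond alignment length")
    removed_intervals = [(int(a), int(b)) for a, b in removed_intervals]
    dropped = [
        int(c)
        for c in called
        if _near_removed(int(alignment.origin[c]), removed_intervals, window)
    ]
    kept_called = [int(c) for c in called if c not in set(dropped)]

    if not removed_intervals or not dropped or mode == "report_only":
        return EdgeAdjustResult(
            pvalue_original=lrt.pvalue,
            pvalue_adjusted=lrt.pvalue,
            dropped_sites=dropped,
            kept_called_sites=kept_called,
            lrt_adjusted=None,
        )
    if mode != "refit":
        raise ValueError(f"unknown mode {mode!r}")
    masked = alignment.drop_columns(dropped)
    lrt2 = branch_site_lrt(masked, tree, **fit_kwargs)
    return EdgeAdjustResult(
        pvalue_original=lrt.pvalue,
        pvalue_adjusted=lrt2.pvalue,
        dropped_sites=dropped,
        kept_called_sites=kept_called,
        lrt_adjusted=lrt2,
    )
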
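"""Candidate filters I-V and the edge-site adjustment."""

import numpy as np
import pytest

from psgscan.codon_model import BranchSiteParams
from psgscan.filters import (
    FilterThresholds,
    apply_candidate_filters,
    background_omega_summary,
    edge_site_adjust,
)
from psgscan.fit import SitePosterior, branch_site_lrt, site_posteriors
from psgscan.phylo import Tree
from psgscan.simulate import SimulationConfig, simulate_codon_alignment


def _params(omega0=0.3, omega2=2.0, p0=0.5, p1=0.4):
    return BranchSiteParams(2.0, omega0, omega2, p0, p1, np.array([0.1, 0.1]))


def _posterior(p_selected):
    n = len(p_selected)
    post = np.zeros((n, 4))
    post[:, 2] = np.asarray(p_selected)
    post[:, 0] = 1.0 - post[:, 2]
    return SitePosterior(post, "neb")


def _report(**overrides):
    kw = dict(
        gene="g1",
        species=["R", "S1", "S2", "S3", "Sister"],
        sister_species=["Sister"],
        n_columns_kept=100,
        fraction_kept=0.8,
        reference_kept_fraction=0.9,
        params_alt=_params(),
        posterior=_posterior([0.1] * 100),
    )
    kw.update(overrides)
    return apply_candidate_filters(**kw)


class TestCandidateFilters:
    def test_clean_candidate_passes(self):
        rep = _report()
        assert rep.passed and rep.failed_criteria == []

    def test_criterion_one_missing_sister(self):
        rep = _report(species=["R", "S1", "S2", "S3"])
        assert rep.failed_criteria == ["I"]

    def test_criterion_two_three_species(self):
        rep = _report(species=["R", "S1", "Sister"])
        assert rep.failed_criteria == ["II"]

    def test_criterion_three_variants(self):
        # 50 of 100 columns kept: fails both the absolute and fraction rule
        rep = _report(n_columns_kept=50, fraction_kept=0.5)
        assert rep.failed_criteria == ["III"]
        # exactly at the floors: passes
        ok = _report(n_columns_kept=60, fraction_kept=2 / 3, reference_kept_fraction=0.6)
        assert "III" not in ok.failed_criteria
        bad_ref = _report(reference_kept_fraction=0.55)
        assert bad_ref.failed_criteria == ["III"]

    @pytest.mark.parametrize(
        "kwargs, expect",
        [
            (dict(omega2=150.0), True),  # >= 100 in foreground
            (dict(omega2=99.0), False),
        ],
    )
    def test_criterion_four(self, kwargs, expect):
        rep = _report(params_alt=_params(**kwargs))
        assert ("IV" in rep.failed_criteria) == expect

    def test_criterion_four_background_rule(self):
        """The mixture's background mean omega never exceeds 1 (omega0 <= 1
        by construction), so the background rule only fires when its
        threshold is tightened below 1."""
        p = _params(omega0=0.9, p0=0.9, p1=0.05)
        assert background_omega_summary(p) <= 1.0
        th = FilterThresholds(max_background_omega=0.5)
        rep = _report(params_alt=p, thresholds=th)
        assert "IV" in rep.failed_criteria

    def test_criterion_four_low_foreground_threshold(self):
        """A fitted omega2 below 0.85 would fail IV; with the model's
        omega2 >= 1 constraint the configurable threshold must still be
        honored when raised above 1."""
        th = FilterThresholds(min_foreground_omega=1.5)
        rep = _report(params_alt=_params(omega2=1.2), thresholds=th)
        assert "IV" in rep.failed_criteria

    def test_criterion_five_too_many_selected_sites(self):
        rep = _report(posterior=_posterior([0.9] * 25 + [0.1] * 75))
        assert rep.failed_criteria == ["V"]
        ok = _report(posterior=_posterior([0.9] * 20 + [0.1] * 80))
        assert "V" not in ok.failed_criteria

    def test_multiple_failures_all_reported(self):
        rep = _report(
            species=["R", "S1"],
            n_columns_kept=10,
            fraction_kept=0.1,
            params_alt=_params(omega2=200.0),
            posterior=_posterior([0.95] * 10),
        )
        assert rep.failed_criteria == ["I", "II", "III", "IV", "V"]
        assert not rep.passed

    def test_manual_flag(self):
        rep = _report(manual_flag=True)
        assert rep.failed_criteria == ["manual"]

    def test_missing_input_named(self):
        with pytest.raises(ValueError, match="params_alt"):
            _report(params_alt=None)

    def test_background_omega_summary(self):
        p = _params(omega0=0.4, p0=0.5, p1=0.25)
        # weights (0.5, 0.25, 1/6, 1/12); background omega = (p0+p2a)*0.4 + (p1+p2b)
        expected = (0.5 + 1 / 6) * 0.4 + (0.25 + 1 / 12)
        assert background_omega_summary(p) == pytest.approx(expected)


@pytest.fixture(scope="module")
def scanned_gene():
    tree = Tree.parse("((A:0.15,B:0.15):0.1,(C:0.15,D:0.15) #1:0.35);")
    cfg = SimulationConfig(tree.copy(), n_sites=120, omega0=0.2, omega2=8.0,
                           p0=0.4, p1=0.4, seed=31)
    aln, _ = simulate_codon_alignment(cfg)
    lrt = branch_site_lrt(aln, tree, n_starts=1, seed=0)
    post = site_posteriors(aln, tree, lrt.params_alt, method="neb")
    return tree, aln, lrt, post


class TestEdgeSiteAdjust:

    def test_no_removed_blocks_is_identity(self, scanned_gene):
        tree, aln, lrt, post = scanned_gene
        adj = edge_site_adjust(aln, tree, lrt, post, [])
        assert adj.pvalue_adjusted == lrt.pvalue
        assert adj.dropped_sites == []

    def test_window_boundary_inclusive_two(self, scanned_gene):
        tree, aln, lrt, post = scanned_gene
        called = post.selected_sites(0.5)
        if len(called) == 0:
            pytest.skip("no called sites in this replicate")
        c = int(called[0])
        # removed interval ending exactly 2 columns before the called site
        near = [(max(0, c - 5), c - 2 + 1)] if c >= 3 else [(c + 2, c + 3)]
        adj_near = edge_site_adjust(aln, tree, lrt, post, near, mode="report_only")
        assert c in adj_near.dropped_sites
        far = [(c + 3, c + 4)] if c + 4 <= aln.n_sites else [(0, max(0, c - 3))]
        adj_far = edge_site_adjust(aln, tree, lrt, post, far, mode="report_only")
        assert c not in adj_far.dropped_sites

    def test_adjusted_p_equals_fresh_lrt_on_masked_alignment(self, scanned_gene):
        """The adjusted P must equal an independent from-scratch LRT on the
        alignment with the flagged columns excluded."""
        tree, aln, lrt, post = scanned_gene
        called = post.selected_sites(0.5)
        if len(called) == 0:
            pytest.skip("no called sites in this replicate")
        c = int(called[0])
        intervals = [(c + 1, c + 2)]  # distance 1: drops site c
        adj = edge_site_adjust(aln, tree, lrt, post, intervals, n_starts=1, seed=0)
        assert c in adj.dropped_sites
        masked = aln.drop_columns(adj.dropped_sites)
        fresh = branch_site_lrt(masked, tree, n_starts=1, seed=0)
        assert adj.pvalue_adjusted == pytest.approx(fresh.pvalue, abs=1e-9)

    def test_never_adds_called_sites(self, scanned_gene):
        tree, aln, lrt, post = scanned_gene
        called = set(post.selected_sites(0.5).tolist())
        adj = edge_site_adjust(aln, tree, lrt, post, [(0, 3)], mode="report_only")
        assert set(adj.kept_called_sites) | set(adj.dropped_sites) == called

    def test_coordinate_mismatch_rejected(self, scanned_gene):
        tree, aln, lrt, post = scanned_gene
        bad = SitePosterior(post.posteriors[:50], "neb")
        with pytest.raises(ValueError):
            edge_site_adjust(aln, tree, lrt, bad, [])
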
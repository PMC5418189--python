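"""Branch-site test of positive selection on a single simulated gene.

Simulates a 500-codon alignment on the canonical 8-taxon study tree with
omega2 = 4 acting on ~10% of sites along the foreground branch, fits the
null (omega2 = 1) and alternative models, and prints the likelihood-ratio
test together with the sites classified as positively selected.
"""

from psgscan import (
    SimulationConfig,
    branch_site_lrt,
    simulate_codon_alignment,
    site_posteriors,
    study_tree,
)

tree = study_tree()
config = SimulationConfig(
    tree.copy(), n_sites=500, kappa=2.0, omega0=0.2, omega2=4.0,
    p0=0.45, p1=0.45, seed=101,
)
alignment, truth = simulate_codon_alignment(config)
print(f"simulated {alignment.n_taxa} taxa x {alignment.n_sites} codons; "
      f"{(truth.site_classes >= 2).sum()} sites truly under foreground selection")

result = branch_site_lrt(alignment, tree, n_starts=2, seed=0)
p = result.params_alt
print(f"lnL null = {result.lnL_null:.3f}   lnL alt = {result.lnL_alt:.3f}")
print(f"2*delta-lnL = {result.statistic:.3f}   P = {result.pvalue:.4g}  (chi-square, 1 df)")
print(f"MLEs: kappa={p.kappa:.2f} omega0={p.omega0:.3f} omega2={p.omega2:.2f} "
      f"p0={p.p0:.3f} p1={p.p1:.3f}")

posterior = site_posteriors(alignment, tree, p, method="beb")
called = posterior.selected_sites(0.8)
hits = set(called) & set((truth.site_classes >= 2).nonzero()[0])
print(f"sites with P(selected) > 0.8: {len(called)}; "
      f"{len(hits)} of them are truly selected sites")
# P below 0.05 rejects neutral evolution on the foreground branch; the
# posterior list localizes the signal to individual codons.
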
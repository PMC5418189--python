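"""End-to-end scan orchestration: catalogs -> ortholog groups -> filtered
codon alignments -> branch-site tests -> candidate filters -> per-gene-tree
confirmation -> enrichment statistics.

Every run is driven by a :class:`RunConfig` (loadable from YAML), seeded,
and written to a results directory as TSV/newick/JSON with a manifest
that fully determines a rerun. Per-gene failures are never silently
dropped: each input gene ends up in exactly one of the PSG table, the
filter-rejected set, or the failed-with-reason set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import CodonAlignment
from .enrichment import (
    GeneUniverse,
    draw_sum_null,
    fisher_set_enrichment,
    trim_background_by_expression,
)
from .filters import FilterThresholds, apply_candidate_filters, edge_site_adjust
from .fit import branch_site_lrt, site_posteriors
from .orthologs import (
    SIMILARITY_PAIRWISE,
    SIMILARITY_TO_REFERENCE,
    TranscriptCatalog,
    codon_aware_align,
    conserved_block_filter,
    rbh_against_reference,
    select_isoforms,
)
from .phylo import Tree
from .trees import estimate_tree, fragment_alignment, majority_consensus, per_gene_retest

__all__ = ["RunConfig", "validate_config", "run_scan", "build_gene_alignments"]


@dataclass
class RunConfig:
    """All settings of a scan; defaults are the scan's published values."""

    catalogs: dict = field(default_factory=dict)  # species -> FASTA path
    reference_species: str = ""
    tree: str = ""  # newick path; empty -> estimate from concatenation
    foreground_branches: dict = field(default_factory=dict)  # name -> [taxa]
    sets_file: str = ""
    expression_file: str = ""
    special_set: str = ""  # set whose draw-and-sum null is simulated
    output_dir: str = "psgscan_results"

    alpha: float = 0.05
    min_reference_similarity: float = SIMILARITY_TO_REFERENCE
    min_pairwise_similarity: float = SIMILARITY_PAIRWISE
    gblocks_b2: int | None = None  # None -> number of sequences (strictest)
    gblocks_b4: int = 30
    fragment_size: int = 15_000
    filter_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    enrichment_rounds: int = 1_000_000
    expression_quantiles: tuple = (0.05, 0.95)
    retest_with_gene_trees: bool = True
    n_starts: int = 2
    seed: int = 0

    def validate(self) -> list:
        errors = []
        if not self.catalogs:
            errors.append("catalogs: at least one species catalog is required")
        if self.reference_species and self.catalogs and self.reference_species not in self.catalogs:
            errors.append(f"reference_species: {self.reference_species!r} has no catalog")
        if not self.foreground_branches:
            errors.append("foreground_branches: at least one branch to test is required")
        for check, name in [
            (0 < self.alpha < 1, "alpha"),
            (0 <= self.min_reference_similarity <= 1, "min_reference_similarity"),
            (0 <= self.min_pairwise_similarity <= 1, "min_pairwise_similarity"),
            (self.gblocks_b4 >= 1, "gblocks_b4"),
            (self.fragment_size >= 1, "fragment_size"),
            (self.enrichment_rounds >= 1, "enrichment_rounds"),
            (self.n_starts >= 1, "n_starts"),
        ]:
            if not check:
                errors.append(f"{name}: value out of range")
        th = self.filter_thresholds
        for check, name in [
            (th.min_species >= 1, "filter_thresholds.min_species"),
            (th.min_columns >= 0, "filter_thresholds.min_columns"),
            (0 <= th.min_fraction_kept <= 1, "filter_thresholds.min_fraction_kept"),
            (0 <= th.min_reference_kept <= 1, "filter_thresholds.min_reference_kept"),
            (0 < th.max_selected_fraction <= 1, "filter_thresholds.max_selected_fraction"),
            (0 < th.site_call_threshold < 1, "filter_thresholds.site_call_threshold"),
        ]:
            if not check:
                errors.append(f"{name}: value out of range")
        q = self.expression_quantiles
        if not (0 <= q[0] < q[1] <= 1):
            errors.append("expression_quantiles: need 0 <= lo < hi <= 1")
        return errors


def validate_config(source) -> RunConfig:
    """Load and validate a config from a YAML path, dict or RunConfig.

    All problems are collected and reported together in the error message.
    """
    if isinstance(source, RunConfig):
        cfg = source
    else:
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                data = yaml.safe_load(fh) or {}
            if not isinstance(data, dict):
                raise ValueError(f"config file {source} must hold a mapping")
        else:
            data = dict(source)
        th = data.pop("filter_thresholds", None)
        known = {f for f in RunConfig.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = RunConfig(**data)
        if th:
            cfg.filter_thresholds = FilterThresholds(**th)
        if isinstance(cfg.expression_quantiles, list):
            cfg.expression_quantiles = tuple(cfg.expression_quantiles)
    errors = cfg.validate()
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------
def build_gene_alignments(config: RunConfig):
    """Catalogs -> per-gene filtered codon alignments.

    Returns ``(alignments, failures)`` where ``alignments[gene]`` is a
    :class:`~psgscan.orthologs.BlockFilterResult` and ``failures[gene]``
    a reason string for genes that produced no usable alignment.
    """
    catalogs = {
        sp: cat if isinstance(cat, TranscriptCatalog) else TranscriptCatalog.read_fasta(sp, cat)
        for sp, cat in config.catalogs.items()
    }
    reference = config.reference_species or sorted(catalogs)[0]
    ref_cat = catalogs[reference]

    # reciprocal best hits of every other species against the reference
    rbh = {
        sp: rbh_against_reference(ref_cat, cat)
        for sp, cat in catalogs.items()
        if sp != reference
    }

    alignments, failures = {}, {}
    ref_genes = sorted({g for g in ref_cat.gene_of.values()})
    for gene in ref_genes:
        ref_iso = ref_cat.isoforms(gene)[0]
        candidates = {}
        for sp, cat in catalogs.items():
            if sp == reference:
                continue
            partner = rbh[sp].get(gene)
            if partner is None:
                continue
            candidates[sp] = [(iso, cat.sequences[iso]) for iso in cat.isoforms(partner)]
        group = select_isoforms(
            reference, ref_iso, ref_cat.sequences[ref_iso], candidates,
            config.min_reference_similarity, config.min_pairwise_similarity,
        )
        if len(group.members) < 2:
            failures[gene] = "no species passed ortholog/isoform selection"
            continue
        try:
            aln = codon_aware_align(group.sequences, reference=reference)
        except ValueError as exc:
            failures[gene] = f"alignment rejected: {exc}"
            continue
        result = conserved_block_filter(aln, b2=config.gblocks_b2, b4=config.gblocks_b4)
        if result.n_kept == 0:
            failures[gene] = "no columns survived conserved-block filtering"
            continue
        alignments[gene] = result
    return alignments, failures


def build_species_tree(config: RunConfig, alignments) -> Tree:
    """Read the configured tree, or estimate it by fragment consensus."""
    if config.tree:
        return Tree.read(config.tree)
    taxa = sorted(config.catalogs)
    blocks = []
    for gene in sorted(alignments):
        aln = alignments[gene].alignment
        if set(taxa) <= set(aln.taxa):
            blocks.append(np.vstack([aln.codes[aln.taxa.index(t)] for t in taxa]))
    if not blocks:
        raise ValueError("no gene alignment covers all species; provide a tree")
    concat = CodonAlignment(taxa, np.hstack(blocks))
    frags = fragment_alignment(concat.n_sites * 3, config.fragment_size)
    trees = []
    for start, stop in frags.intervals:
        sub = concat.take_columns(range(start // 3, stop // 3))
        trees.append(estimate_tree(sub))
    return majority_consensus(trees).tree


def _scan_one_branch(config, branch_name, fg_taxa, species_tree, alignments, failures):
    rows = []
    sister = _sister_taxa(species_tree, fg_taxa)
    for gene in sorted(alignments):
        blk = alignments[gene]
        aln = blk.alignment
        fg_present = [t for t in fg_taxa if t in aln.taxa]
        row = dict(gene=gene, branch=branch_name, n_species=aln.n_taxa,
                   n_columns=aln.n_sites)
        if len(fg_present) == 0 or set(aln.taxa) == set(fg_present):
            row.update(status="failed", reason="foreground branch not testable in this gene")
            rows.append(row)
            continue
        tree = species_tree.prune_to(aln.taxa)
        try:
            tree.set_foreground(fg_present)
        except ValueError as exc:
            row.update(status="failed", reason=str(exc))
            rows.append(row)
            continue
        lrt = branch_site_lrt(aln, tree, n_starts=config.n_starts, seed=config.seed)
        post = site_posteriors(aln, tree, lrt.params_alt, method="neb")
        adj = edge_site_adjust(
            aln, tree, lrt, post, blk.removed_intervals,
            site_call_threshold=config.filter_thresholds.site_call_threshold,
            n_starts=config.n_starts, seed=config.seed,
        )
        report = apply_candidate_filters(
            gene, aln.taxa, sister, blk.n_kept, blk.fraction_kept,
            blk.reference_kept_fraction(config.reference_species or sorted(config.catalogs)[0]),
            lrt.params_alt, post, config.filter_thresholds,
        )
        called = [int(aln.origin[c]) for c in adj.kept_called_sites]
        significant = adj.pvalue_adjusted <= config.alpha
        row.update(
            status="psg" if (significant and report.passed) else "rejected",
            reason="" if (significant and report.passed) else (
                report.reasons() if not report.passed else "P above alpha"
            ),
            lnL_null=lrt.lnL_null, lnL_alt=lrt.lnL_alt, statistic=lrt.statistic,
            pvalue=lrt.pvalue, pvalue_adjusted=adj.pvalue_adjusted,
            kappa=lrt.params_alt.kappa, omega0=lrt.params_alt.omega0,
            omega2=lrt.params_alt.omega2, p0=lrt.params_alt.p0, p1=lrt.params_alt.p1,
            n_called_sites=len(called),
            called_sites=",".join(map(str, called)),
            filter_pass=report.passed, filter_reasons=report.reasons(),
            converged=lrt.converged,
        )
        if row["status"] == "psg" and config.retest_with_gene_trees and aln.n_taxa >= 3:
            rt = per_gene_retest(gene, aln, adj.pvalue_adjusted, fg_present,
                                 alpha=config.alpha, n_starts=config.n_starts,
                                 seed=config.seed)
            row.update(retest_pvalue=rt.pvalue_gene_tree, retest_confirmed=rt.confirmed,
                       retest_reason=rt.reason)
        rows.append(row)
    for gene in sorted(failures):
        rows.append(dict(gene=gene, branch=branch_name, status="failed",
                         reason=failures[gene]))
    return pd.DataFrame(rows)


def _sister_taxa(tree: Tree, fg_taxa) -> list:
    """Leaves of the sister clade of the foreground MRCA."""
    node = tree.mrca([t for t in fg_taxa if t in tree.leaf_names()])
    if node.parent is None:
        return []
    below = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            below.add(n.name)
        stack.extend(n.children)
    sisters = []
    for sib in node.parent.children:
        if sib is node:
            continue
        stack = [sib]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                sisters.append(n.name)
            stack.extend(n.children)
    return sorted(sisters)


def _enrichment_reports(config: RunConfig, psg_by_branch: dict, out_dir: Path):
    if not (config.sets_file and config.expression_file):
        return
    universe = GeneUniverse.read(config.expression_file, config.sets_file)
    all_psgs = sorted(set().union(*psg_by_branch.values()) & set(universe.genes))
    fisher_rows = []
    for branch, psgs in sorted(psg_by_branch.items()):
        psgs = sorted(set(psgs) & set(universe.genes))
        if not psgs:
            continue
        for set_name in sorted(universe.sets):
            res = fisher_set_enrichment(psgs, set_name, universe)
            fisher_rows.append(dict(branch=branch, set=set_name, overlap=res.overlap,
                                    psgs=res.query_size, set_size=res.set_size,
                                    universe=res.universe_size,
                                    fold_enrichment=res.fold_enrichment, pvalue=res.pvalue))
    if fisher_rows:
        pd.DataFrame(fisher_rows).to_csv(out_dir / "enrichment_fisher.tsv",
                                         sep="\t", index=False)
    if config.special_set and config.special_set in universe.sets and all_psgs:
        lo, hi = config.expression_quantiles
        trimmed = trim_background_by_expression(universe, all_psgs, lo, hi)
        special = trimmed.set_members(config.special_set)
        strata, observed = [], 0
        for branch, psgs in sorted(psg_by_branch.items()):
            draws = len(set(psgs) & set(universe.genes))
            strata.append((len(trimmed), len(special), draws))
            observed += len(set(psgs) & special)
        null = draw_sum_null(strata, rounds=config.enrichment_rounds,
                             seed=config.seed, mode="simulate")
        exact = draw_sum_null(strata, mode="exact")
        summary = dict(
            special_set=config.special_set, observed_sum=observed,
            rounds=config.enrichment_rounds,
            simulated_tail_p=null.tail_probability(observed),
            exact_tail_p=exact.tail_probability(observed),
            quantile95=null.quantile(0.95), max_observed=null.max_observed,
            strata=strata,
        )
        (out_dir / "enrichment_drawsum.json").write_text(json.dumps(summary, indent=2))


def run_scan(config: RunConfig | str | dict) -> Path:
    """Run the full scan; returns the output directory.

    Outputs: per-branch scan tables (``scan_<branch>.tsv``), the species
    tree used, removed-block and retention tables, enrichment reports,
    and ``manifest.json`` (config hash, seed, package version).
    """
    config = validate_config(config)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    alignments, failures = build_gene_alignments(config)
    species_tree = build_species_tree(config, alignments)
    for name, taxa in config.foreground_branches.items():
        missing = set(taxa) - set(species_tree.leaf_names())
        if missing:
            raise ValueError(
                f"foreground branch {name!r} references unknown taxa: {sorted(missing)}"
            )
    species_tree.write(out_dir / "species_tree.nwk")

    blocks_rows, retention_rows = [], []
    for gene in sorted(alignments):
        blk = alignments[gene]
        for a, b in blk.removed_intervals:
            blocks_rows.append(dict(gene=gene, start=a, end=b))
        retention_rows.append(dict(
            gene=gene, columns_kept=blk.n_kept, columns_input=blk.n_input_columns,
            fraction_kept=blk.fraction_kept,
        ))
        blk.alignment.write_fasta(out_dir / "alignments" / f"{gene}.fasta")
    pd.DataFrame(blocks_rows, columns=["gene", "start", "end"]).to_csv(
        out_dir / "removed_blocks.tsv", sep="\t", index=False)
    pd.DataFrame(retention_rows).to_csv(out_dir / "retention.tsv", sep="\t", index=False)

    psg_by_branch = {}
    for branch, fg_taxa in sorted(config.foreground_branches.items()):
        table = _scan_one_branch(config, branch, fg_taxa, species_tree, alignments, failures)
        table.to_csv(out_dir / f"scan_{branch}.tsv", sep="\t", index=False)
        psg_by_branch[branch] = list(table.loc[table["status"] == "psg", "gene"])

    _enrichment_reports(config, psg_by_branch, out_dir)

    cfg_dict = asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = dict(
        config=cfg_dict,
        config_sha256=hashlib.sha256(cfg_json.encode()).hexdigest(),
        seed=config.seed,
        psgscan_version=__version__,
        n_genes=len(alignments) + len(failures),
        n_psgs={b: len(v) for b, v in psg_by_branch.items()},
    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out_dir
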
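"""Taxonomic-rank association scanning with per-rank FDR control.

The scan walks every taxon at every rank from kingdom (the entire
community) down to species.  OTUs sharing a taxon label form a group; the
group's counts are sub-composed, its subtree pruned from the full
phylogeny, and the appropriate test applied:

* groups of two or more OTUs with phylogenetic disparity: the full
  min-P combination over SPU and all seven kernels;
* groups whose UniFrac measures are uninformative (no phylogenetic
  disparity between any sample pair): SPU pool plus the Bray-Curtis
  kernel only;
* single-OTU taxa: the two-sided score test on that OTU's standardized
  column.

One null fit and one permutation set serve every taxon, so p-values are
mutually consistent and a re-run with the same seed reproduces the scan
exactly.  Within each rank, Benjamini-Hochberg adjustment controls the
false discovery rate at 5%; unnamed (unassigned) taxa are not formed into
pseudo-groups and are simply not tested at that rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode
from statsmodels.stats.multitest import multipletests

from . import assoc, kernels as kmod, nullmodel
from .io import RANKS, AlignedDataset, InputError

logger = logging.getLogger("omiat")

#: Label used for the whole-community group at the kingdom rank.
COMMUNITY_LABEL = "(community)"

METHODS = ("omiat", "optimal_mirkat", "aspu", "aggregate")


@dataclass(frozen=True)
class TaxonGroup:
    """A taxon at one rank: its member OTUs and degeneracy bookkeeping."""

    rank: str
    label: str
    otu_ids: tuple
    indices: np.ndarray

    @property
    def size(self) -> int:
        return len(self.otu_ids)


@dataclass(frozen=True)
class ScanRow:
    group: TaxonGroup
    result: assoc.TestResult
    qvalue: float = float("nan")
    discovered: bool = False


@dataclass
class MicamReport:
    """Per-rank scan results plus per-OTU effect directions."""

    method: str
    alpha: float
    B: int
    seed: int
    rank_scans: dict = field(default_factory=dict)  # rank -> list[ScanRow]
    effect_signs: dict = field(default_factory=dict)  # otu id -> '+'/'-'

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rank in RANKS:
            for row in self.rank_scans.get(rank, []):
                rows.append({
                    "rank": rank,
                    "taxon": row.group.label,
                    "n_otus": row.group.size,
                    "test": row.result.method,
                    "p": row.result.pvalue,
                    "q": row.qvalue,
                    "discovered": row.discovered,
                })
        return pd.DataFrame(rows)

    def community_row(self) -> ScanRow:
        for row in self.rank_scans.get("kingdom", []):
            if row.group.label == COMMUNITY_LABEL:
                return row
        raise KeyError("no community-level row in report")


# ---------------------------------------------------------------------------
# Group construction and tree pruning
# ---------------------------------------------------------------------------

def build_taxa_groups(taxonomy: pd.DataFrame, otu_ids) -> dict:
    """Partition OTUs into named taxa at every rank.

    The kingdom rank always contains the entire-community group; named
    kingdom groups are added only when more than one named kingdom is
    present.  At lower ranks, OTUs whose label is unassigned (empty) are
    not tested at that rank (they remain members of their named
    higher-rank taxa).  Groups are keyed by the full lineage down to the
    rank, so same-named taxa under different parents stay distinct.
    """
    otu_ids = [str(o) for o in otu_ids]
    tax = taxonomy.loc[otu_ids]
    out = {}
    for ri, rank in enumerate(RANKS):
        groups = []
        if rank == "kingdom":
            groups.append(TaxonGroup(rank, COMMUNITY_LABEL, tuple(otu_ids),
                                     np.arange(len(otu_ids))))
            named = [l for l in tax["kingdom"].unique() if l]
            if len(named) > 1:
                for label in named:
                    mask = (tax["kingdom"] == label).to_numpy()
                    groups.append(TaxonGroup(rank, label,
                                             tuple(np.array(otu_ids)[mask]),
                                             np.flatnonzero(mask)))
        else:
            lineage_cols = list(RANKS[:ri + 1])
            labels = tax[lineage_cols].agg(";".join, axis=1)
            assigned = tax[rank].to_numpy() != ""
            for key in labels[assigned].unique():
                mask = (labels == key).to_numpy() & assigned
                ids = tuple(np.array(otu_ids)[mask])
                groups.append(TaxonGroup(rank, key.split(";")[-1] or key, ids,
                                         np.flatnonzero(mask)))
        out[rank] = groups
    return out


def prune_tree(tree: TreeNode, member_set) -> TreeNode:
    """Minimal subtree spanning ``member_set``, degree-2 nodes collapsed.

    Collapsing sums branch lengths, so leaf-to-leaf path lengths are
    preserved.
    """
    members = [str(m) for m in member_set]
    if not members:
        raise InputError("cannot prune to an empty member set")
    tips = {t.name for t in tree.tips()}
    missing = set(members) - tips
    if missing:
        raise InputError(f"members absent from tree: {sorted(missing)[:10]}")
    if len(members) == 1:
        leaf = TreeNode(name=members[0], length=0.0)
        root = TreeNode(length=0.0, children=[leaf])
        return root
    sub = tree.shear(members)
    sub.prune()
    if sub.length is None:
        sub.length = 0.0
    return sub


def select_test_config(group: TaxonGroup, unifrac_degenerate: bool = False) -> str:
    """Which test a taxon gets: 'single_otu', 'bray_curtis_only' or 'full'."""
    if group.size == 1:
        return "single_otu"
    if unifrac_degenerate:
        return "bray_curtis_only"
    return "full"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------

def _renormalize(counts: np.ndarray) -> np.ndarray:
    """Within-group proportions; samples with zero group total stay zero."""
    totals = counts.sum(axis=1)
    safe = np.where(totals > 0, totals, 1.0)
    return counts / safe[:, None]


def _test_group(group, config, method, fit, Z_full, counts, tree_index_cache,
                tree, perms, grid, alphas):
    if config == "single_otu":
        return assoc.single_otu_test(fit, Z_full.values[:, group.indices], perms)
    sub_counts = counts[:, group.indices]
    P_sub = _renormalize(sub_counts)
    Z_sub = nullmodel.StandardizedComposition(
        Z_full.values[:, group.indices], Z_full.zero_variance[group.indices])
    if method == "aspu":
        return assoc.aspu_test(fit, Z_sub, perms, grid)
    if method == "aggregate":
        return assoc.aggregate_test(fit, Z_sub, perms)
    key = group.otu_ids
    if key not in tree_index_cache:
        sub_tree = prune_tree(tree, group.otu_ids)
        tree_index_cache[key] = kmod.TreeIndex(sub_tree, group.otu_ids)
    tindex = tree_index_cache[key]
    kernels, degenerate = kmod.candidate_kernels(P_sub, tindex, alphas)
    if degenerate or config == "bray_curtis_only":
        kernels = {"bray_curtis": kernels["bray_curtis"]}
    if method == "optimal_mirkat":
        if len(kernels) == 1:
            return assoc.mirkat_test(fit, kernels["bray_curtis"], perms)
        return assoc.optimal_mirkat_test(fit, kernels, perms)
    return assoc.omiat_test(fit, Z_sub, kernels, perms, grid)


def micam_scan(dataset: AlignedDataset, method: str = "omiat",
               n_perm: int = 50_000, seed: int = 0, alpha: float = 0.05,
               grid=assoc.DEFAULT_GAMMA_GRID,
               alphas=kmod.DEFAULT_ALPHAS) -> MicamReport:
    """Test every taxon at every rank with shared permutations and per-rank BH.

    Parameters
    ----------
    method : one of 'omiat', 'optimal_mirkat', 'aspu', 'aggregate'
        The group-analytic engine used for multi-OTU taxa (single-OTU taxa
        always use the score test).
    n_perm : permutations shared by every statistic of every taxon.
    alpha : per-rank FDR level for the discovery flag.
    """
    if method not in METHODS:
        raise InputError(f"unknown method {method!r}; choose from {METHODS}")
    fit = nullmodel.fit_null(dataset.design)
    perms = assoc.make_permutations(fit.n_samples, n_perm, seed)
    counts = dataset.otu.counts
    P_full = nullmodel.to_composition(dataset.otu)
    Z_full = nullmodel.standardize_composition(P_full)
    U_full = nullmodel.score_vector(fit, Z_full)
    signs = {o: nullmodel.effect_sign(u) for o, u in zip(dataset.otu_ids, U_full)}

    groups_by_rank = build_taxa_groups(dataset.taxonomy, dataset.otu_ids)
    report = MicamReport(method, alpha, n_perm, seed, effect_signs=signs)
    cache = {}
    for rank in RANKS:
        rows = []
        for group in groups_by_rank[rank]:
            config = select_test_config(group)
            try:
                result = _test_group(group, config, method, fit, Z_full,
                                     counts, cache, dataset.tree, perms,
                                     grid, alphas)
            except Exception as exc:
                logger.warning("scan: taxon %s at rank %s failed: %s",
                               group.label, rank, exc)
                continue
            rows.append(ScanRow(group, result))
        if rows:
            q = bh_adjust([r.result.pvalue for r in rows])
            rows = [ScanRow(r.group, r.result, float(qi), bool(qi <= alpha))
                    for r, qi in zip(rows, q)]
        report.rank_scans[rank] = rows
    return report


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_map(report: MicamReport, dataset: AlignedDataset, out_prefix):
    """Hierarchical discovery map (SVG) plus its companion TSV.

    OTUs are stacked vertically (sorted by lineage so members of a taxon
    are contiguous), ranks run left to right, and each cell is colored red
    when the OTU's taxon at that rank was discovered, gray when tested but
    not discovered, and left white when the OTU is unassigned at that
    rank.  The right-hand column shows each OTU's effect direction.
    Returns (figure path, table path).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    tax = dataset.taxonomy.loc[list(dataset.otu_ids)]
    order = tax.apply(tuple, axis=1).sort_values(kind="stable").index
    otu_order = list(order)

    status = {}  # (otu, rank) -> 'discovered' | 'tested'
    labels = {}
    for rank, rows in report.rank_scans.items():
        for row in rows:
            for o in row.group.otu_ids:
                key = (o, rank)
                if row.discovered or key not in status:
                    status[key] = "discovered" if row.discovered else "tested"
                    labels[key] = row.group.label

    n, m = len(otu_order), len(RANKS)
    fig, ax = plt.subplots(figsize=(1.1 * m + 2.5, max(3.0, 0.22 * n)))
    colors = {"discovered": "#d62728", "tested": "#bfbfbf"}
    for yi, o in enumerate(otu_order):
        for xi, rank in enumerate(RANKS):
            st = status.get((o, rank))
            if st is None:
                continue
            ax.add_patch(Rectangle((xi, n - 1 - yi), 1, 1,
                                   facecolor=colors[st], edgecolor="white",
                                   linewidth=0.4))
        ax.text(m + 0.35, n - 1 - yi + 0.5, report.effect_signs.get(o, ""),
                ha="center", va="center", fontsize=7)
    ax.set_xlim(0, m + 0.8)
    ax.set_ylim(0, n)
    ax.set_xticks(np.arange(m) + 0.5)
    ax.set_xticklabels(RANKS, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(np.arange(n) + 0.5)
    ax.set_yticklabels(list(reversed(otu_order)), fontsize=6)
    ax.set_title(f"discovery map ({report.method}, FDR {report.alpha:g} per rank)")
    ax.tick_params(length=0)
    for s in ax.spines.values():
        s.set_visible(False)
    fig.tight_layout()
    fig_path = f"{out_prefix}_map.svg"
    tsv_path = f"{out_prefix}_taxa.tsv"
    fig.savefig(fig_path)
    plt.close(fig)
    report.to_dataframe().to_csv(tsv_path, sep="\t", index=False)
    return fig_path, tsv_path
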
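"""Weighted gene coexpression network analysis.

Pearson correlation -> soft-thresholded adjacency (|cor|^beta, beta chosen by
the scale-free topology criterion) -> topological overlap matrix (TOM) ->
average-linkage clustering of 1 - TOM with a dynamic (min-size-respecting)
tree cut -> modules, connectivity, hub genes.  A consensus network over the
two response groups (percentile-scaled per-group TOMs combined by elementwise
minimum) supports detection of group-specific modules: modules found in one
group whose genes are left unassigned ("grey") in the consensus.

Everything here is deterministic given the input expression matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .data import AlignmentError, ConfigError, ExpressionMatrix, PipelineError

logger = logging.getLogger(__name__)

GREY = "grey"

#: conventional module color sequence; overflow falls back to numbered labels
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


@dataclass
class AdjacencyMatrix:
    """Soft-thresholded adjacency: a_ij = |cor_ij|^beta, zero diagonal."""

    values: np.ndarray
    beta: float
    gene_ids: list[str]


@dataclass
class TOMatrix:
    """Topological overlap similarities in [0, 1], unit diagonal."""

    values: np.ndarray
    gene_ids: list[str]


@dataclass
class ModuleAssignment:
    """Gene -> module label; ``grey`` marks unassigned genes.

    Non-grey labels are ordered by decreasing module size.
    """

    labels: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return self.labels.index.tolist()

    def modules(self, include_grey: bool = False) -> list[str]:
        sizes = self.labels.value_counts()
        names = [m for m in sizes.index if m != GREY or include_grey]
        return names

    def members(self, module: str) -> list[str]:
        return self.labels.index[self.labels == module].tolist()

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


@dataclass
class ScaleFreeFit:
    """Scale-free topology fit across the candidate beta grid."""

    table: pd.DataFrame  # beta, r_squared, slope, mean_connectivity, fit_error
    chosen_beta: float
    met_target: bool
    r2_target: float


@dataclass
class CoexpressionResult:
    """Bundle of one network build (single group or consensus)."""

    fit: ScaleFreeFit
    assignment: ModuleAssignment
    connectivity: pd.Series
    hubs: dict[str, list[str]]
    dendrogram: np.ndarray
    tom: TOMatrix | None = None


def correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Gene-by-gene Pearson correlations (genes are rows of the input)."""
    x = expr.values
    if x.shape[1] < 3:
        raise ConfigError("correlation needs at least 3 samples")
    sds = x.std(axis=1)
    if np.any(sds == 0):
        offenders = [g for g, s in zip(expr.probe_ids, sds) if s == 0]
        raise PipelineError(f"zero-variance gene(s) present: {offenders[:5]}; remove before network construction")
    cor = np.corrcoef(x)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(np.clip(cor, -1.0, 1.0), index=expr.probe_ids, columns=expr.probe_ids)


def adjacency(cor: pd.DataFrame | np.ndarray, beta: float) -> AdjacencyMatrix:
    """Unsigned soft-threshold adjacency |cor|^beta with zero diagonal."""
    if beta <= 0:
        raise ConfigError("beta must be positive")
    if isinstance(cor, pd.DataFrame):
        gene_ids, vals = cor.index.tolist(), cor.to_numpy()
    else:
        vals = np.asarray(cor)
        gene_ids = [f"g{i}" for i in range(vals.shape[0])]
    a = np.abs(vals) ** beta
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(a, float(beta), gene_ids)


def connectivity(adj: AdjacencyMatrix) -> pd.Series:
    """Per-gene connectivity: sum of adjacency to all other genes."""
    return pd.Series(adj.values.sum(axis=1), index=adj.gene_ids, name="connectivity")


def soft_threshold(
    cor: pd.DataFrame,
    beta_grid: list[float] | None = None,
    r2_target: float = 0.85,
    n_bins: int = 10,
    min_mean_connectivity: float = 1.0,
) -> ScaleFreeFit:
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each beta, the connectivity distribution is binned (``n_bins``
    equal-width bins over k) and log10 p(k) is regressed on log10 of the mean
    k per bin.  The criterion balances fit against network density: among
    betas whose mean connectivity stays at or above ``min_mean_connectivity``
    (raising the power indefinitely empties the network, which makes the
    log-log fit look spuriously scale-free), the chosen beta is the smallest
    with a decreasing fit of R^2 >= ``r2_target``; if none qualifies, the beta
    with the best decreasing fit is returned with ``met_target=False`` and a
    warning.
    """
    if beta_grid is None:
        beta_grid = list(range(1, 21))
    if not beta_grid or any(b2 <= b1 for b1, b2 in zip(beta_grid, beta_grid[1:])):
        raise ConfigError("beta_grid must be non-empty and strictly ascending")

    abs_cor = np.abs(cor.to_numpy())
    np.fill_diagonal(abs_cor, 0.0)
    rows = []
    for beta in beta_grid:
        k = (abs_cor ** beta).sum(axis=1)
        row = {"beta": beta, "mean_connectivity": float(k.mean()),
               "median_connectivity": float(np.median(k)),
               "r_squared": np.nan, "slope": np.nan, "fit_error": ""}
        counts, edges = np.histogram(k, bins=n_bins)
        centers = []
        freqs = []
        for i in range(n_bins):
            if counts[i] == 0:
                continue
            in_bin = (k >= edges[i]) & (k <= edges[i + 1] if i == n_bins - 1 else k < edges[i + 1])
            mean_k = k[in_bin].mean()
            if mean_k > 0:
                centers.append(mean_k)
                freqs.append(counts[i] / k.size)
        if len(centers) < 3:
            row["fit_error"] = f"only {len(centers)} usable connectivity bins"
            rows.append(row)
            continue
        log_k = np.log10(np.asarray(centers))
        log_p = np.log10(np.asarray(freqs))
        slope, intercept = np.polyfit(log_k, log_p, 1)
        resid = log_p - (slope * log_k + intercept)
        ss_tot = float(((log_p - log_p.mean()) ** 2).sum())
        r2 = 0.0 if ss_tot == 0 else float(1.0 - (resid ** 2).sum() / ss_tot)
        row["r_squared"] = max(0.0, min(1.0, r2))
        row["slope"] = float(slope)
        rows.append(row)

    table = pd.DataFrame(rows)
    scale_free = table[(table["fit_error"] == "") & (table["slope"] < 0)]
    dense_enough = scale_free[scale_free["mean_connectivity"] >= min_mean_connectivity]
    qualifying = dense_enough[dense_enough["r_squared"] >= r2_target]
    if len(qualifying):
        chosen = float(qualifying.iloc[0]["beta"])
        met = True
    else:
        # fall back to the strongest penalization of weak correlations that
        # still leaves the network connected on average; failing that, the
        # best decreasing fit anywhere on the grid
        met = False
        if len(dense_enough):
            chosen = float(dense_enough["beta"].max())
        elif len(scale_free):
            chosen = float(scale_free.loc[scale_free["r_squared"].idxmax(), "beta"])
        else:
            chosen = float(beta_grid[-1])
        logger.warning(
            "no beta reached scale-free R^2 >= %.2f at mean connectivity >= %g; "
            "falling back to beta=%g", r2_target, min_mean_connectivity, chosen)
    return ScaleFreeFit(table=table, chosen_beta=chosen, met_target=met, r2_target=r2_target)


def topological_overlap(adj: AdjacencyMatrix) -> TOMatrix:
    """Unsigned topological overlap.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j,
    TOM_ii = 1.  Quantifies shared-neighbor structure on top of the direct
    adjacency; entries lie in [0, 1] when the adjacency does.
    """
    a = adj.values
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return TOMatrix(np.clip(tom, 0.0, 1.0), adj.gene_ids)


def _label_by_size(cluster_ids: np.ndarray, gene_ids: list[str], min_module_size: int) -> pd.Series:
    """Map raw cluster ids to color labels ordered by decreasing size; clusters
    below the size floor become grey.  Ties in size break by first gene id."""
    labels = pd.Series(GREY, index=gene_ids, dtype=object)
    ids, counts = np.unique(cluster_ids, return_counts=True)
    keep = [(int(c), int(i)) for i, c in zip(ids, counts) if c >= min_module_size]
    # decreasing size; deterministic tie-break via position of first member
    first_pos = {int(i): int(np.flatnonzero(cluster_ids == i)[0]) for _, i in keep}
    keep.sort(key=lambda t: (-t[0], first_pos[t[1]]))
    for rank, (_, cid) in enumerate(keep):
        name = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.iloc[np.flatnonzero(cluster_ids == cid)] = name
    return labels


def cluster_and_cut(
    tom: TOMatrix,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> tuple[ModuleAssignment, np.ndarray]:
    """Average-linkage clustering of 1 - TOM with a dynamic tree cut.

    Branches of the dendrogram that complete below ``cut_height`` (on the
    bounded 1 - TOM dissimilarity scale) become candidate modules; candidates
    smaller than ``min_module_size`` are left unassigned (grey).  Module labels
    are assigned in decreasing size order.
    """
    n = len(tom.gene_ids)
    if min_module_size > n:
        raise ConfigError(f"min_module_size={min_module_size} exceeds gene count {n}")
    dissim = 1.0 - tom.values
    np.fill_diagonal(dissim, 0.0)
    tree = linkage(squareform(np.clip(dissim, 0.0, 1.0), checks=False), method="average")
    cluster_ids = fcluster(tree, t=cut_height, criterion="distance")
    labels = _label_by_size(cluster_ids, tom.gene_ids, min_module_size)
    return ModuleAssignment(labels), tree


def consensus_tom(toms: dict[str, TOMatrix], percentile: float = 95.0) -> TOMatrix:
    """Consensus TOM: per-group TOMs scaled to a common ``percentile`` (the
    smallest across groups, so scaling never exceeds 1), then elementwise
    minimum."""
    gene_sets = {tuple(t.gene_ids) for t in toms.values()}
    if len(gene_sets) != 1:
        raise AlignmentError("group TOMs cover different gene sets")
    offdiag = ~np.eye(len(next(iter(toms.values())).gene_ids), dtype=bool)
    quantiles = {g: np.percentile(t.values[offdiag], percentile) for g, t in toms.items()}
    target = min(quantiles.values())
    scaled = []
    for g, t in toms.items():
        factor = target / quantiles[g] if quantiles[g] > 0 else 1.0
        s = t.values * factor
        np.fill_diagonal(s, 1.0)
        scaled.append(s)
    cons = np.minimum.reduce(scaled)
    return TOMatrix(np.clip(cons, 0.0, 1.0), next(iter(toms.values())).gene_ids)


def build_network(
    expr: ExpressionMatrix,
    beta_grid: list[float] | None = None,
    r2_target: float = 0.85,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    hub_fraction: float = 0.20,
    keep_tom: bool = False,
) -> CoexpressionResult:
    """Run the full single-network stage on one expression matrix."""
    cor = correlation_matrix(expr)
    fit = soft_threshold(cor, beta_grid, r2_target)
    adj = adjacency(cor, fit.chosen_beta)
    k = connectivity(adj)
    tom = topological_overlap(adj)
    assignment, tree = cluster_and_cut(tom, min_module_size, cut_height)
    hubs = hub_genes(assignment, k, hub_fraction)
    return CoexpressionResult(
        fit=fit, assignment=assignment, connectivity=k, hubs=hubs,
        dendrogram=tree, tom=tom if keep_tom else None,
    )


def consensus_modules(
    expr_by_group: dict[str, ExpressionMatrix],
    beta_grid: list[float] | None = None,
    r2_target: float = 0.85,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    scaling_percentile: float = 95.0,
) -> tuple[ModuleAssignment, dict[str, ModuleAssignment]]:
    """Consensus and per-group module assignments over a shared gene set.

    Each group gets its own soft threshold (the criterion is applied per data
    set) and TOM; per-group modules come from the group TOMs, and consensus
    modules from the percentile-scaled elementwise-minimum TOM.
    """
    gene_sets = {g: set(e.probe_ids) for g, e in expr_by_group.items()}
    if len({frozenset(s) for s in gene_sets.values()}) != 1:
        raise AlignmentError("gene sets differ between groups")
    for g, e in expr_by_group.items():
        if e.shape[1] < 3:
            raise ConfigError(f"group {g!r} has fewer than 3 samples")

    ref_order = next(iter(expr_by_group.values())).probe_ids
    toms: dict[str, TOMatrix] = {}
    group_assignments: dict[str, ModuleAssignment] = {}
    for g, e in expr_by_group.items():
        aligned = ExpressionMatrix(e.frame.loc[ref_order], e.scale_tag)
        cor = correlation_matrix(aligned)
        fit = soft_threshold(cor, beta_grid, r2_target)
        tom = topological_overlap(adjacency(cor, fit.chosen_beta))
        toms[g] = tom
        group_assignments[g], _ = cluster_and_cut(tom, min_module_size, cut_height)
    cons_tom = consensus_tom(toms, scaling_percentile)
    cons_assignment, _ = cluster_and_cut(cons_tom, min_module_size, cut_height)
    return cons_assignment, group_assignments


def module_overlap_test(
    assign_a: ModuleAssignment,
    assign_b: ModuleAssignment,
    include_grey: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric P values for every pair of modules.

    For modules of sizes m and n sharing k genes in a universe of N genes,
    P = P(X >= k) under Hypergeometric(N, m, n).
    """
    if set(assign_a.gene_ids) != set(assign_b.gene_ids):
        raise AlignmentError("module assignments cover different gene universes")
    n_universe = len(assign_a.gene_ids)
    b_labels = assign_b.labels.loc[assign_a.labels.index]
    mods_a = assign_a.modules(include_grey)
    mods_b = assign_b.modules(include_grey)
    out = pd.DataFrame(index=mods_a, columns=mods_b, dtype=float)
    for ma in mods_a:
        in_a = assign_a.labels == ma
        m = int(in_a.sum())
        for mb in mods_b:
            in_b = b_labels == mb
            n = int(in_b.sum())
            k = int((in_a & in_b).sum())
            out.loc[ma, mb] = float(hypergeom.sf(k - 1, n_universe, m, n))
    return out


def detect_group_specific_modules(
    group_assign: ModuleAssignment,
    consensus_assign: ModuleAssignment,
    grey_fraction_threshold: float = 0.5,
) -> pd.DataFrame:
    """Group modules whose members are mostly unassigned in the consensus.

    Reports every module of the group network whose member genes are grey in
    the consensus network at a fraction strictly above the threshold, together
    with that fraction and the hypergeometric P value of the overlap with the
    consensus grey set.
    """
    if set(group_assign.gene_ids) != set(consensus_assign.gene_ids):
        raise AlignmentError("assignments cover different gene universes")
    cons = consensus_assign.labels.loc[group_assign.labels.index]
    n_universe = len(cons)
    grey_mask = cons == GREY
    n_grey = int(grey_mask.sum())
    rows = []
    for module in group_assign.modules():
        members = group_assign.labels == module
        m = int(members.sum())
        k = int((members & grey_mask).sum())
        frac = k / m
        if frac > grey_fraction_threshold:
            p = float(hypergeom.sf(k - 1, n_universe, m, n_grey))
            rows.append({"module": module, "size": m, "grey_fraction": frac,
                         "grey_overlap_p": p})
    return pd.DataFrame(rows, columns=["module", "size", "grey_fraction", "grey_overlap_p"])


def hub_genes(
    assign: ModuleAssignment,
    k: pd.Series,
    fraction: float = 0.20,
) -> dict[str, list[str]]:
    """Top-connectivity genes per module.

    Per module the ceil(fraction * size) most connected genes are selected;
    connectivity ties break lexicographically on gene id.  Grey is excluded.
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigError("hub fraction must lie in (0, 1]")
    out: dict[str, list[str]] = {}
    for module in assign.modules():
        members = assign.members(module)
        n_hubs = int(np.ceil(fraction * len(members)))
        ranked = sorted(members, key=lambda g: (-k.loc[g], g))
        out[module] = ranked[:n_hubs]
    return out
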
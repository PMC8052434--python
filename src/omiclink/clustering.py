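"""Feature and sample ordering.

Hierarchical clustering (metric x linkage x leaf order) with three modes:

* independent — each layer clustered on its own;
* synchronized — one anchor layer is clustered and its display order is
  transported to linked layers through a LinkMap;
* nested (two-level) — parents (e.g. proteins) are clustered on a summary
  profile of their children (e.g. phosphosites), then children are clustered
  independently within each parent.

Distances are pairwise-complete: each pair of rows is compared over the
coordinates both have observed, rescaled to the full dimension (as R's
``dist`` does); pairs sharing fewer than 2 coordinates — or whose Pearson
correlation is undefined — receive the maximal defined distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy as sch

from .errors import ResolutionError, ValidationError
from .io_model import OmicsLayer, SampleTable
from .linking import LinkMap, NestedGrouping

METRICS = ("euclidean", "correlation")
LINKAGES = ("average", "complete", "single", "ward")
LEAF_ORDERS = ("none", "optimal")


@dataclass(frozen=True)
class ClusterConfig:
    metric: str = "euclidean"
    linkage: str = "average"
    leaf_order: str = "none"
    axis: str = "features"

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValidationError(f"metric {self.metric!r} not in {METRICS}")
        if self.linkage not in LINKAGES:
            raise ValidationError(f"linkage {self.linkage!r} not in {LINKAGES}")
        if self.leaf_order not in LEAF_ORDERS:
            raise ValidationError(f"leaf_order {self.leaf_order!r} not in {LEAF_ORDERS}")
        if self.axis not in ("features", "samples"):
            raise ValidationError(f"axis {self.axis!r} not in ('features', 'samples')")


@dataclass
class OrderingResult:
    """A display ordering of a set of rows, with its dendrogram if clustered."""

    layer: str
    row_ids: tuple            # rows being ordered, in input order
    order: tuple              # permutation of range(len(row_ids)): display order
    mode: str = "independent"
    anchor_layer: str | None = None
    linkage_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.row_ids))):
            raise ValidationError(
                f"ordering of layer {self.layer!r}: order is not a permutation of its rows"
            )
        if self.mode == "synchronized" and self.anchor_layer is None:
            raise ValidationError("synchronized ordering requires an anchor_layer")

    def ordered_rows(self) -> list:
        return [self.row_ids[i] for i in self.order]


def pairwise_complete_distances(matrix: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance vector with per-pair missing-data handling."""
    mat = np.asarray(matrix, dtype=float)
    n, p = mat.shape
    for i in range(n):
        if np.all(np.isnan(mat[i])):
            raise ValidationError(f"row {i} has no observed values; cannot be clustered")
    obs = ~np.isnan(mat)
    d = np.full(n * (n - 1) // 2, np.nan)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[i] & obs[j]
            m = int(shared.sum())
            if m >= 2 or (metric == "euclidean" and m >= 1):
                xi, xj = mat[i, shared], mat[j, shared]
                if metric == "euclidean":
                    d[idx] = np.sqrt(np.sum((xi - xj) ** 2) * (p / m))
                else:
                    sx, sy = xi.std(), xj.std()
                    if sx > 0 and sy > 0:
                        r = np.corrcoef(xi, xj)[0, 1]
                        d[idx] = 1.0 - r
            idx += 1
    undefined = np.isnan(d)
    if undefined.any():
        fallback = np.nanmax(d) if not undefined.all() else (2.0 if metric == "correlation" else 1.0)
        d[undefined] = fallback
    return np.maximum(d, 0.0)


def hcluster(matrix: np.ndarray, config: ClusterConfig,
             layer: str = "", row_ids=None) -> OrderingResult:
    """Agglomerative clustering of one axis of a numeric matrix."""
    mat = np.asarray(matrix, dtype=float)
    if config.axis == "samples":
        mat = mat.T
    n = mat.shape[0]
    if n < 2:
        raise ValidationError("clustering requires at least 2 rows on the clustered axis")
    ids = tuple(range(n)) if row_ids is None else tuple(row_ids)
    dvec = pairwise_complete_distances(mat, config.metric)
    z = sch.linkage(dvec, method=config.linkage)
    if config.leaf_order == "optimal":
        z = sch.optimal_leaf_ordering(z, dvec)
    leaves = tuple(int(i) for i in sch.leaves_list(z))
    return OrderingResult(layer=layer, row_ids=ids, order=leaves,
                          mode="independent", linkage_matrix=z)


def synchronize(anchor: OrderingResult, target_layer: str, target_rows,
                links: LinkMap) -> OrderingResult:
    """Transport the anchor layer's display order to a linked layer.

    Each target row takes the display position of its first (earliest-shown)
    linked anchor row; ties keep the targets contiguous in their original
    relative order. Unlinked target rows are appended afterwards, also in
    original relative order.
    """
    if not links.edges:
        raise ValidationError(
            f"no links between {anchor.layer!r} and {target_layer!r}: "
            "synchronization is meaningless; use independent mode"
        )
    oriented = links.oriented(anchor.layer)
    anchor_pos = {row: pos for pos, row in enumerate(anchor.ordered_rows())}
    target_rows = list(target_rows)
    first_pos: dict = {}
    for e in oriented.edges:
        if e.row_a in anchor_pos:
            cur = first_pos.get(e.row_b)
            if cur is None or anchor_pos[e.row_a] < cur:
                first_pos[e.row_b] = anchor_pos[e.row_a]
    linked = [(first_pos[r], k) for k, r in enumerate(target_rows) if r in first_pos]
    unlinked = [k for k, r in enumerate(target_rows) if r not in first_pos]
    order = tuple(k for _, k in sorted(linked)) + tuple(unlinked)
    return OrderingResult(layer=target_layer, row_ids=tuple(target_rows), order=order,
                          mode="synchronized", anchor_layer=anchor.layer)


SUMMARIES = {
    "average": np.nanmean,
    "maximum": np.nanmax,
    "minimum": np.nanmin,
    "sum": np.nansum,
}


def nested_hcluster(layer: OmicsLayer, nesting: NestedGrouping,
                    config: ClusterConfig, summary: str = "average") -> OrderingResult:
    """Two-level clustering of nested features.

    Level 1 clusters parents on a per-sample summary (default: average) of
    their child rows; level 2 clusters each parent's children independently.
    Singleton parents skip level 2; with a single parent level 1 is skipped.
    """
    if summary not in SUMMARIES:
        raise ValidationError(f"unknown summary {summary!r}; choose from {sorted(SUMMARIES)}")
    agg = SUMMARIES[summary]
    mat = layer.matrix()
    parents = list(nesting.groups.keys())           # first-appearance order
    child_rows = [nesting.groups[pkey] for pkey in parents]
    for rows in child_rows:
        for r in rows:
            if not (0 <= r < mat.shape[0]):
                raise ValidationError(f"nesting references row {r} outside layer {layer.name!r}")
    # level 1: parent order from summary profiles
    if len(parents) >= 2:
        profiles = np.vstack([
            np.array([agg(mat[rows, c]) if np.any(~np.isnan(mat[rows, c])) else np.nan
                      for c in range(mat.shape[1])])
            for rows in child_rows
        ])
        level1 = hcluster(profiles, config)
        parent_order = level1.order
        z = level1.linkage_matrix
    else:
        parent_order = (0,)
        z = None
    # level 2: children within each parent
    out_rows: list = []
    for pi in parent_order:
        rows = child_rows[pi]
        if len(rows) >= 2:
            sub = hcluster(mat[rows, :], config)
            out_rows.extend(rows[i] for i in sub.order)
        else:
            out_rows.extend(rows)
    all_rows = [r for rows in child_rows for r in rows]
    pos = {r: k for k, r in enumerate(all_rows)}
    order = tuple(pos[r] for r in out_rows)
    return OrderingResult(layer=layer.name, row_ids=tuple(all_rows), order=order,
                          mode="independent", linkage_matrix=z)


def sort_features(rows, by: str, test_results=None, group_rows=None,
                  ordering: OrderingResult | None = None) -> OrderingResult:
    """Non-clustering feature sorts: by significance, by group blocks, or delegate.

    * ``significance`` — ascending p-value (untestable features last);
    * ``group-membership`` — rows blocked by the first selected group that
      contains them (blocks in selection order, leftovers appended);
    * ``clustering`` — delegate to a precomputed OrderingResult.
    """
    rows = list(rows)
    if by == "significance":
        if test_results is None:
            raise ValidationError("significance sort requires test results")
        import math

        pmap = {r.feature_row: r.p_value for r in test_results}
        keyed = []
        for k, r in enumerate(rows):
            p = pmap.get(r, math.nan)
            keyed.append((1 if math.isnan(p) else 0, p if not math.isnan(p) else 0.0, k))
        order = tuple(k for _, _, k in sorted(keyed))
    elif by == "group-membership":
        if group_rows is None:
            raise ValidationError("group sort requires per-group row sets")
        assigned: dict = {}
        for gi, grows in enumerate(group_rows):
            for r in grows:
                assigned.setdefault(r, gi)       # first selected group wins
        order = tuple(k for k in sorted(range(len(rows)),
                                        key=lambda k: (assigned.get(rows[k], len(group_rows)), k)))
    elif by == "clustering":
        if ordering is None:
            raise ValidationError("clustering sort requires an OrderingResult")
        return ordering
    else:
        raise ValidationError(f"unknown sort mode {by!r}")
    return OrderingResult(layer="", row_ids=tuple(rows), order=order)


def sort_samples(samples: SampleTable, by_phenotypes, sample_order=None) -> list:
    """Stable lexicographic sample ordering by up to five phenotypes.

    Returns positions into ``sample_order`` (default: the table's sample
    list). Numeric phenotypes compare numerically, others as strings.
    """
    names = list(by_phenotypes)
    if len(names) > 5:
        raise ValidationError(f"at most 5 phenotypes may order samples; got {len(names)}")
    if not names:
        raise ValidationError("at least one phenotype is required")
    base = list(samples.sample_names) if sample_order is None else list(sample_order)
    columns = [samples.phenotype_values(n, base) for n in names]

    def key(k: int):
        out = []
        for col in columns:
            v = col[k]
            if isinstance(v, (int, float, np.integer, np.floating)):
                out.append((0, float(v), ""))
            else:
                out.append((1, 0.0, str(v)))
        return tuple(out)

    return sorted(range(len(base)), key=key)


def cluster_samples(layer: OmicsLayer, config: ClusterConfig) -> OrderingResult:
    cfg = ClusterConfig(metric=config.metric, linkage=config.linkage,
                        leaf_order=config.leaf_order, axis="samples")
    return hcluster(layer.matrix(), cfg, layer=layer.name)


def to_newick(result: OrderingResult, labels=None) -> str:
    """Dendrogram of an OrderingResult in Newick format (heights as branch lengths)."""
    if result.linkage_matrix is None:
        raise ValidationError("this ordering has no dendrogram (not produced by clustering)")
    tree = sch.to_tree(result.linkage_matrix)
    names = labels or [str(r) for r in result.row_ids]

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:g}"
        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def export_ordering(result: OrderingResult, path: str) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["row", "rank"])
        for rank, row in enumerate(result.ordered_rows()):
            w.writerow([row, rank])
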
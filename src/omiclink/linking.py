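"""Cross-layer feature linking and nested-identifier grouping.

Two layers are connected either by inference — every tagged standard
identifier is mapped to Entrez anchors and rows sharing an anchor are joined
— or by an uploaded network file, which overrides inference for that layer
pair. Within a layer, nested identifiers (e.g. phosphosites under a parent
protein accession) are grouped by a parent metadata column.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .errors import ResolutionError, ValidationError
from .io_model import NetworkSpec, OmicsLayer, is_missing_token
from .knowledge import KnowledgeBase


@dataclass(frozen=True)
class LinkEdge:
    row_a: int
    row_b: int
    color: str | None = None
    descriptor: str | None = None


@dataclass
class LinkMap:
    """Feature-feature edges between one pair of layers.

    ``provenance`` records whether edges were inferred from shared anchors
    or uploaded as a network file; an uploaded map shadows the inferred one.
    """

    layer_pair: tuple  # (layer name a, layer name b)
    edges: frozenset   # of LinkEdge
    provenance: str    # "inferred" | "uploaded"

    def __post_init__(self) -> None:
        if self.provenance not in ("inferred", "uploaded"):
            raise ValidationError(f"provenance must be inferred/uploaded, got {self.provenance!r}")

    @property
    def cardinality(self) -> str:
        if not self.edges:
            return "none"
        from collections import Counter

        ca = Counter(e.row_a for e in self.edges)
        cb = Counter(e.row_b for e in self.edges)
        many_a = any(v > 1 for v in cb.values())  # one b row hit by several a rows
        many_b = any(v > 1 for v in ca.values())  # one a row linked to several b rows
        if many_a and many_b:
            return "many-to-many"
        if many_b:
            return "one-to-many"
        if many_a:
            return "many-to-one"
        return "one-to-one"

    def transposed(self) -> "LinkMap":
        return LinkMap(
            layer_pair=(self.layer_pair[1], self.layer_pair[0]),
            edges=frozenset(LinkEdge(e.row_b, e.row_a, e.color, e.descriptor) for e in self.edges),
            provenance=self.provenance,
        )

    def oriented(self, anchor_layer: str) -> "LinkMap":
        """Return this map with ``anchor_layer`` on the a-side."""
        if anchor_layer == self.layer_pair[0]:
            return self
        if anchor_layer == self.layer_pair[1]:
            return self.transposed()
        raise ResolutionError(f"layer {anchor_layer!r} is not part of pair {self.layer_pair}")

    def validate_against(self, layer_a: OmicsLayer, layer_b: OmicsLayer) -> None:
        for e in self.edges:
            if not (0 <= e.row_a < layer_a.n_features):
                raise ValidationError(f"link row_a={e.row_a} out of range for layer {layer_a.name!r}")
            if not (0 <= e.row_b < layer_b.n_features):
                raise ValidationError(f"link row_b={e.row_b} out of range for layer {layer_b.name!r}")


def row_anchor_sets(layer: OmicsLayer, kb: KnowledgeBase) -> list:
    """Entrez anchor set of every row, via the layer's tagged standard identifiers."""
    out = []
    for i in range(layer.n_features):
        anchors = set()
        for col, vocab in layer.standard_id_tags.items():
            anchors |= kb.anchors_for(vocab, str(layer.metadata.iloc[i][col]))
        out.append(anchors)
    return out


def infer_links(layer_a: OmicsLayer, layer_b: OmicsLayer, kb: KnowledgeBase) -> LinkMap:
    """Connect rows of two layers that share at least one Entrez anchor.

    Rows with no tagged identifiers (or unmappable values) join no edges.
    Layers with no tagged identifiers at all yield an empty map — the pair
    is then displayed in independent mode.
    """
    anchors_a = row_anchor_sets(layer_a, kb)
    anchors_b = row_anchor_sets(layer_b, kb)
    # invert the smaller side for linear-time intersection
    by_anchor: dict = {}
    for j, bset in enumerate(anchors_b):
        for anc in bset:
            by_anchor.setdefault(anc, []).append(j)
    edges = set()
    for i, aset in enumerate(anchors_a):
        hit = set()
        for anc in aset:
            hit.update(by_anchor.get(anc, ()))
        for j in hit:
            edges.add(LinkEdge(i, j))
    return LinkMap(layer_pair=(layer_a.name, layer_b.name), edges=frozenset(edges), provenance="inferred")


def apply_network(spec: NetworkSpec, layer_a: OmicsLayer, layer_b: OmicsLayer) -> LinkMap:
    """Build an uploaded LinkMap from a network file.

    The file's two identifier columns must exist as metadata columns of the
    respective layers; every row matching id_a is joined to every row
    matching id_b (cross product).
    """
    if spec.column_a not in layer_a.metadata.columns:
        raise ResolutionError(
            f"network column {spec.column_a!r} is not a metadata column of layer {layer_a.name!r} "
            f"(has {layer_a.metadata_columns})"
        )
    if spec.column_b not in layer_b.metadata.columns:
        raise ResolutionError(
            f"network column {spec.column_b!r} is not a metadata column of layer {layer_b.name!r} "
            f"(has {layer_b.metadata_columns})"
        )
    col_a = layer_a.metadata[spec.column_a].astype(str)
    col_b = layer_b.metadata[spec.column_b].astype(str)
    rows_a: dict = {}
    for i, v in enumerate(col_a):
        rows_a.setdefault(v, []).append(i)
    rows_b: dict = {}
    for j, v in enumerate(col_b):
        rows_b.setdefault(v, []).append(j)
    edges = set()
    for e in spec.edges:
        for i in rows_a.get(e.id_a, ()):
            for j in rows_b.get(e.id_b, ()):
                edges.add(LinkEdge(i, j, e.color, e.descriptor))
    return LinkMap(layer_pair=(layer_a.name, layer_b.name), edges=frozenset(edges), provenance="uploaded")


@dataclass
class NestedGrouping:
    """Partition of a layer's rows by a parent identifier column.

    Rows with a missing parent value become their own singleton group keyed
    by ``__row<i>``. Group order is first appearance (pre-clustering).
    """

    layer: str
    parent_key: str
    groups: dict = field(default_factory=dict)  # parent value -> ordered list of row indices

    def validate_partition(self, n_rows: int) -> None:
        seen: list = []
        for rows in self.groups.values():
            seen.extend(rows)
        if sorted(seen) != list(range(n_rows)):
            raise ValidationError(
                f"nesting of layer {self.layer!r} does not partition rows 0..{n_rows - 1}"
            )

    @property
    def all_singletons(self) -> bool:
        return all(len(r) == 1 for r in self.groups.values())


def detect_nesting(layer: OmicsLayer, parent_key: str) -> NestedGrouping:
    if parent_key not in layer.metadata.columns:
        raise ResolutionError(
            f"parent key {parent_key!r} is not a metadata column of layer {layer.name!r}"
        )
    groups: dict = {}
    for i in range(layer.n_features):
        val = str(layer.metadata.iloc[i][parent_key])
        key = f"__row{i}" if is_missing_token(val) else val
        groups.setdefault(key, []).append(i)
    return NestedGrouping(layer=layer.name, parent_key=parent_key, groups=groups)


def export_link_map(links: LinkMap, path: str, layer_a: OmicsLayer, layer_b: OmicsLayer) -> None:
    """Audit export: one row per edge with feature labels and provenance."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["feature_a", "feature_b", "color", "descriptor", "provenance"])
        for e in sorted(links.edges, key=lambda e: (e.row_a, e.row_b)):
            w.writerow(
                [
                    layer_a.feature_label(e.row_a),
                    layer_b.feature_label(e.row_b),
                    e.color or "",
                    e.descriptor or "",
                    links.provenance,
                ]
            )
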
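"""The analysis workspace: full serializable state plus the operation log.

A workspace bundles the loaded omics layers, the sample table, the knowledge
base, the user's selections, link maps, orderings, filters and view settings
into one versioned JSON document (``.omnl``). Data are embedded, not
referenced, so a saved workspace is self-contained and shareable; floats are
serialized losslessly and save -> load -> save is byte-identical.

Every mutating operation appends a ``provenance_log`` entry; replaying the
log against the raw input files reproduces the workspace deterministically.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering, knowledge, linking, render, stats
from .errors import FormatError, OmiclinkError, ResolutionError, ValidationError
from .io_model import (
    NetworkEdge,
    NetworkSpec,
    OmicsLayer,
    SampleTable,
    read_network_file,
    read_omics_layer,
    read_pathway_file,
    read_sample_table,
)
from .knowledge import FunctionalGroup, KnowledgeBase
from .linking import LinkEdge, LinkMap

FORMAT_NAME = "omiclink-workspace"
FORMAT_VERSION = "1.1"
#: older minor versions accepted on load, with defaults for fields added since
COMPATIBLE_VERSIONS = ("1.0", "1.1")

DEFAULT_VIEW = {
    "orientation": "samples-as-columns",
    "cell_w": 14.0,
    "cell_h": 14.0,
    "phenotypes": [],
    "tag_track_side": "right",   # added in format 1.1
}


def _pair_key(a: str, b: str) -> str:
    return f"{a}|{b}"


@dataclass
class Workspace:
    layers: list = field(default_factory=list)          # OmicsLayer, display order
    samples: SampleTable = None
    kb: KnowledgeBase = None
    selections: list = field(default_factory=list)      # FunctionalGroup with color_tag
    link_maps: dict = field(default_factory=dict)       # "a|b" -> {"inferred": LinkMap, "uploaded": LinkMap|None}
    orderings: dict = field(default_factory=dict)       # layer -> OrderingResult
    filters: dict = field(default_factory=dict)         # layer -> {settings..., "retained_rows": [...]}
    view: dict = field(default_factory=lambda: dict(DEFAULT_VIEW))
    sample_order: list = field(default_factory=list)    # global display order of sample names
    provenance_log: list = field(default_factory=list)

    # -- construction -------------------------------------------------------

    @classmethod
    def create(cls, layers: list, samples: SampleTable, kb: KnowledgeBase) -> "Workspace":
        ws = cls(layers=list(layers), samples=samples, kb=kb)
        for layer in ws.layers:
            samples.check_covers(layer)
        names = [l.name for l in ws.layers]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate layer names: {names}")
        ws.sample_order = list(samples.sample_names)
        ws._infer_all_links()
        return ws

    @classmethod
    def init_from_files(cls, layer_specs: list, sample_path: str,
                        kb_dir: str | None = None, log: bool = True) -> "Workspace":
        """Build a workspace from raw input files.

        ``layer_specs``: list of dicts with keys path, name, metadata_columns,
        standard_id_tags, delimiter. ``kb_dir`` None loads the bundled
        miniature knowledge base.
        """
        layers = [
            read_omics_layer(
                s["path"],
                metadata_columns=s["metadata_columns"],
                standard_id_tags=s.get("standard_id_tags") or {},
                delimiter=s.get("delimiter"),
                name=s.get("name"),
            )
            for s in layer_specs
        ]
        samples = read_sample_table(sample_path)
        kb = knowledge.load_kb(kb_dir) if kb_dir else knowledge.load_fixture_kb()
        ws = cls.create(layers, samples, kb)
        if log:
            ws.provenance_log.append({
                "op": "init",
                "params": {"layers": layer_specs, "sample_path": sample_path, "kb_dir": kb_dir},
            })
        return ws

    def _layer(self, name: str) -> OmicsLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise ResolutionError(f"unknown layer {name!r}; known: {[l.name for l in self.layers]}")

    def _infer_all_links(self) -> None:
        for i, a in enumerate(self.layers):
            for b in self.layers[i + 1:]:
                key = _pair_key(a.name, b.name)
                entry = self.link_maps.setdefault(key, {"inferred": None, "uploaded": None})
                entry["inferred"] = linking.infer_links(a, b, self.kb)

    def display_link_map(self, layer_a: str, layer_b: str) -> LinkMap:
        """The effective map for a pair: an uploaded map shadows the inferred one."""
        for key in (_pair_key(layer_a, layer_b), _pair_key(layer_b, layer_a)):
            if key in self.link_maps:
                entry = self.link_maps[key]
                m = entry["uploaded"] if entry["uploaded"] is not None else entry["inferred"]
                return m.oriented(layer_a)
        raise ResolutionError(f"no link map for pair ({layer_a!r}, {layer_b!r})")

    # -- selection ----------------------------------------------------------

    def op_select(self, keys: list) -> None:
        """Select search-hit keys: KB group ids or ``vocabulary:identifier`` genes."""
        by_id = {g.group_id: g for g in self.kb.gene_sets}
        for key in keys:
            if any(s.group_id == key for s in self.selections):
                continue
            color = render.GROUP_COLOR_CYCLE[len(self.selections) % len(render.GROUP_COLOR_CYCLE)]
            if key in by_id:
                self.selections.append(by_id[key].with_color(color))
            elif ":" in key:
                vocab, ident = key.split(":", 1)
                self.selections.append(FunctionalGroup(
                    group_id=key, display_name=ident, source="user",
                    members=frozenset({(vocab, ident)}), color_tag=color,
                ))
            else:
                raise ResolutionError(f"cannot select {key!r}: not a group id or vocab:identifier key")
        self._invalidate_downstream()
        self.provenance_log.append({"op": "select", "params": {"keys": list(keys)}})

    def op_upload_pathways(self, path: str) -> None:
        spec = read_pathway_file(path)
        groups = knowledge.groups_from_pathway_file(spec, [l.name for l in self.layers])
        for g in groups:
            color = render.GROUP_COLOR_CYCLE[len(self.selections) % len(render.GROUP_COLOR_CYCLE)]
            self.selections.append(g.with_color(color))
        self._invalidate_downstream()
        self.provenance_log.append({"op": "upload_pathways", "params": {"path": path}})

    def op_upload_network(self, path: str, layer_a: str, layer_b: str) -> None:
        spec = read_network_file(path)
        la, lb = self._layer(layer_a), self._layer(layer_b)
        lmap = linking.apply_network(spec, la, lb)
        key = self._existing_pair_key(layer_a, layer_b)
        self.link_maps[key]["uploaded"] = lmap.oriented(key.split("|")[0])
        self.provenance_log.append({
            "op": "upload_network", "params": {"path": path, "layer_a": layer_a, "layer_b": layer_b},
        })

    def op_remove_network(self, layer_a: str, layer_b: str) -> None:
        """Drop an uploaded map; the inferred map for the pair is back in force."""
        key = self._existing_pair_key(layer_a, layer_b)
        self.link_maps[key]["uploaded"] = None
        self.provenance_log.append({
            "op": "remove_network", "params": {"layer_a": layer_a, "layer_b": layer_b},
        })

    def _existing_pair_key(self, layer_a: str, layer_b: str) -> str:
        for key in (_pair_key(layer_a, layer_b), _pair_key(layer_b, layer_a)):
            if key in self.link_maps:
                return key
        raise ResolutionError(f"no layer pair ({layer_a!r}, {layer_b!r})")

    def selected_rows(self, layer_name: str) -> list:
        """Base selection for a layer: union over selected groups, in selection order."""
        layer = self._layer(layer_name)
        rows: list = []
        seen = set()
        for g in self.selections:
            for r in knowledge.resolve_group_rows(g, layer, self.kb):
                if r not in seen:
                    seen.add(r)
                    rows.append(r)
        return rows

    def visible_rows(self, layer_name: str) -> list:
        """Selection after filtering, in display (ordered) sequence."""
        rows = self.selected_rows(layer_name)
        flt = self.filters.get(layer_name)
        if flt is not None:
            retained = set(flt["retained_rows"])
            rows = [r for r in rows if r in retained]
        ordering = self.orderings.get(layer_name)
        if ordering is not None and set(ordering.row_ids) == set(rows):
            rows = ordering.ordered_rows()
        return rows

    def _invalidate_downstream(self) -> None:
        self.orderings.clear()
        self.filters.clear()

    # -- statistics ---------------------------------------------------------

    def phenotype(self, name: str, layer: OmicsLayer, kind: str | None = None):
        values = self.samples.phenotype_values(name, layer.sample_columns)
        return stats.classify_phenotype(values, name=name, kind=kind)

    def op_filter(self, phenotype: str, family: str = "parametric",
                  alpha_p: float = 0.05, alpha_fdr: float | None = None,
                  layer: str | None = None) -> dict:
        """Differential-expression filter on the selected molecules.

        Returns ``{layer: retained row count}``. BH runs per layer over the
        selected-molecule background.
        """
        targets = [self._layer(layer)] if layer else self.layers
        counts = {}
        for lay in targets:
            rows = self.selected_rows(lay.name)
            if not rows:
                continue
            pheno = self.phenotype(phenotype, lay)
            results = stats.de_test(lay, pheno, family=family, rows=rows)
            retained = stats.filter_by_significance(results, alpha_p, alpha_fdr)
            self.filters[lay.name] = {
                "phenotype": phenotype, "family": family,
                "alpha_p": alpha_p, "alpha_fdr": alpha_fdr,
                "retained_rows": sorted(retained),
            }
            self.orderings.pop(lay.name, None)
            counts[lay.name] = len(retained)
        self.provenance_log.append({
            "op": "filter",
            "params": {"phenotype": phenotype, "family": family, "alpha_p": alpha_p,
                       "alpha_fdr": alpha_fdr, "layer": layer},
        })
        return counts

    def op_enrich(self, phenotype: str, layer: str, family: str = "parametric",
                  alpha_p: float = 0.05, alpha_fdr: float | None = None,
                  min_group_size: int = 1, min_de_members: int = 1) -> list:
        """DE analysis on one layer, then hypergeometric enrichment of KB gene sets.

        The background is every molecule of the layer mappable to an anchor.
        """
        lay = self._layer(layer)
        anchor_sets = linking.row_anchor_sets(lay, self.kb)
        background = set().union(*anchor_sets) if anchor_sets else set()
        pheno = self.phenotype(phenotype, lay)
        mappable = [r for r in range(lay.n_features) if anchor_sets[r]]
        results = stats.de_test(lay, pheno, family=family, rows=mappable)
        de_rows = stats.filter_by_significance(results, alpha_p, alpha_fdr)
        de_anchors = set().union(*(anchor_sets[r] for r in de_rows)) if de_rows else set()
        report = stats.enrich(self.kb, de_anchors, background,
                              min_group_size=min_group_size, min_de_members=min_de_members)
        self.provenance_log.append({
            "op": "enrich",
            "params": {"phenotype": phenotype, "layer": layer, "family": family,
                       "alpha_p": alpha_p, "alpha_fdr": alpha_fdr,
                       "min_group_size": min_group_size, "min_de_members": min_de_members},
        })
        return report

    # -- ordering -----------------------------------------------------------

    def op_cluster(self, mode: str = "independent", anchor: str | None = None,
                   metric: str = "euclidean", linkage: str = "average",
                   leaf_order: str = "none", nested_parent: dict | None = None,
                   summary: str = "average") -> None:
        """Cluster features, independently per layer or synchronized to an anchor.

        ``nested_parent`` maps layer name -> parent identifier column for
        two-level nested clustering of that layer.
        """
        cfg = clustering.ClusterConfig(metric=metric, linkage=linkage, leaf_order=leaf_order)
        nested_parent = nested_parent or {}

        def cluster_layer(lay: OmicsLayer, rows: list):
            if len(rows) < 2:
                return None
            if lay.name in nested_parent:
                nesting = linking.detect_nesting(lay, nested_parent[lay.name])
                sub = {k: [r for r in v if r in set(rows)] for k, v in nesting.groups.items()}
                nesting.groups = {k: v for k, v in sub.items() if v}
                return clustering.nested_hcluster(lay, nesting, cfg, summary=summary)
            mat = lay.matrix()[rows, :]
            res = clustering.hcluster(mat, cfg, layer=lay.name)
            return clustering.OrderingResult(
                layer=lay.name, row_ids=tuple(rows), order=res.order,
                mode="independent", linkage_matrix=res.linkage_matrix)

        if mode == "independent":
            for lay in self.layers:
                rows = self._filtered_rows(lay.name)
                res = cluster_layer(lay, rows)
                if res is not None:
                    self.orderings[lay.name] = res
        elif mode == "synchronized":
            if not anchor:
                raise ValidationError("synchronized clustering requires an anchor layer")
            anchor_layer = self._layer(anchor)
            rows = self._filtered_rows(anchor)
            res = cluster_layer(anchor_layer, rows)
            if res is None:
                raise ValidationError(f"anchor layer {anchor!r} has fewer than 2 selected features")
            self.orderings[anchor] = res
            for lay in self.layers:
                if lay.name == anchor:
                    continue
                lmap = self.display_link_map(anchor, lay.name)
                target_rows = self._filtered_rows(lay.name)
                if not lmap.edges or not target_rows:
                    continue   # pair stays independent (no shared linker)
                self.orderings[lay.name] = clustering.synchronize(
                    res, lay.name, target_rows, lmap)
        else:
            raise ValidationError(f"unknown clustering mode {mode!r}")
        self.provenance_log.append({
            "op": "cluster",
            "params": {"mode": mode, "anchor": anchor, "metric": metric, "linkage": linkage,
                       "leaf_order": leaf_order, "nested_parent": nested_parent,
                       "summary": summary},
        })

    def _filtered_rows(self, layer_name: str) -> list:
        rows = self.selected_rows(layer_name)
        flt = self.filters.get(layer_name)
        if flt is not None:
            retained = set(flt["retained_rows"])
            rows = [r for r in rows if r in retained]
        return rows

    def op_sort_features(self, by: str, phenotype: str | None = None,
                         family: str = "parametric", layer: str | None = None) -> None:
        targets = [self._layer(layer)] if layer else self.layers
        for lay in targets:
            rows = self._filtered_rows(lay.name)
            if not rows:
                continue
            if by == "significance":
                if not phenotype:
                    raise ValidationError("significance sort requires a phenotype")
                pheno = self.phenotype(phenotype, lay)
                results = stats.de_test(lay, pheno, family=family, rows=rows)
                res = clustering.sort_features(rows, "significance", test_results=results)
            elif by == "group-membership":
                group_rows = [set(knowledge.resolve_group_rows(g, lay, self.kb))
                              for g in self.selections]
                res = clustering.sort_features(rows, "group-membership", group_rows=group_rows)
            else:
                raise ValidationError(f"unknown feature sort {by!r}")
            self.orderings[lay.name] = clustering.OrderingResult(
                layer=lay.name, row_ids=res.row_ids, order=res.order)
        self.provenance_log.append({
            "op": "sort_features",
            "params": {"by": by, "phenotype": phenotype, "family": family, "layer": layer},
        })

    def op_sort_samples(self, phenotypes: list) -> None:
        perm = clustering.sort_samples(self.samples, phenotypes)
        self.sample_order = [self.samples.sample_names[i] for i in perm]
        self.view["phenotypes"] = list(phenotypes)
        self.provenance_log.append({"op": "sort_samples", "params": {"phenotypes": list(phenotypes)}})

    # -- rendering ----------------------------------------------------------

    def layer_sample_display(self, layer: OmicsLayer) -> list:
        return [s for s in self.sample_order if s in layer.sample_columns]

    def build_scene(self) -> render.HeatmapScene:
        panels = []
        shown_layers = []
        for lay in self.layers:
            rows = self.visible_rows(lay.name)
            if not rows:
                continue
            cols = self.layer_sample_display(lay)
            mat = lay.values[cols].to_numpy(dtype=float)[rows, :]
            tracks = []
            for g in self.selections:
                grows = set(knowledge.resolve_group_rows(g, lay, self.kb)) & set(rows)
                if grows:
                    tracks.append(render.TagTrack(group_id=g.group_id,
                                                  color=g.color_tag or render.GROUP_COLOR_CYCLE[0],
                                                  rows=frozenset(grows)))
            panels.append({
                "layer": lay.name, "rows": rows,
                "row_labels": [lay.feature_label(r) for r in rows],
                "sample_labels": cols, "values": mat, "tag_tracks": tracks,
            })
            shown_layers.append(lay.name)
        if not panels:
            raise ValidationError("selection is empty: nothing to render")
        link_edges = {}
        for i in range(len(panels) - 1):
            try:
                lmap = self.display_link_map(shown_layers[i], shown_layers[i + 1])
            except ResolutionError:
                continue
            link_edges[(i, i + 1)] = [(e.row_a, e.row_b, e.color, e.descriptor)
                                      for e in lmap.edges]
        pheno_tracks = []
        for name in self.view.get("phenotypes", [])[:5]:
            first = self._layer(shown_layers[0])
            vals = self.samples.phenotype_values(name, self.layer_sample_display(first))
            pheno_tracks.append((name, render.phenotype_track_colors(vals)))
        return render.build_scene(
            panels, link_edges=link_edges, pheno_tracks=pheno_tracks,
            orientation=self.view.get("orientation", "samples-as-columns"),
            cell_w=float(self.view.get("cell_w", 14.0)),
            cell_h=float(self.view.get("cell_h", 14.0)),
        )

    def op_render(self, path: str) -> None:
        scene = self.build_scene()
        if path.endswith(".pdf"):
            render.export_pdf(scene, path)
        else:
            render.export_svg(scene, path)
        self.provenance_log.append({"op": "render", "params": {"path": path}})

    # -- replay -------------------------------------------------------------

    _REPLAYABLE = ("select", "upload_pathways", "upload_network", "remove_network",
                   "filter", "enrich", "cluster", "sort_features", "sort_samples", "render")

    @classmethod
    def replay(cls, log: list) -> "Workspace":
        """Re-execute a provenance log from its ``init`` entry onward."""
        if not log or log[0]["op"] != "init":
            raise ValidationError("provenance log must start with an init entry")
        p = log[0]["params"]
        ws = cls.init_from_files(p["layers"], p["sample_path"], p.get("kb_dir"))
        for entry in log[1:]:
            op, params = entry["op"], entry["params"]
            if op not in cls._REPLAYABLE:
                raise ValidationError(f"cannot replay unknown operation {op!r}")
            getattr(ws, f"op_{op}")(**params)
        return ws


# ---------------------------------------------------------------------------
# serialization


def _df_to_doc(df: pd.DataFrame, numeric: bool) -> dict:
    if numeric:
        rows = [[None if (isinstance(v, float) and math.isnan(v)) else float(v) for v in row]
                for row in df.to_numpy(dtype=float).tolist()]
    else:
        rows = [[str(v) for v in row] for row in df.to_numpy(dtype=object).tolist()]
    return {"columns": list(map(str, df.columns)), "rows": rows}


def _df_from_doc(doc: dict, numeric: bool) -> pd.DataFrame:
    if numeric:
        rows = [[math.nan if v is None else float(v) for v in row] for row in doc["rows"]]
        return pd.DataFrame(rows, columns=doc["columns"], dtype=float)
    return pd.DataFrame([[str(v) for v in row] for row in doc["rows"]],
                        columns=doc["columns"], dtype=str)


def _linkmap_to_doc(m: LinkMap | None):
    if m is None:
        return None
    return {
        "layer_pair": list(m.layer_pair),
        "provenance": m.provenance,
        "edges": [[e.row_a, e.row_b, e.color, e.descriptor]
                  for e in sorted(m.edges, key=lambda e: (e.row_a, e.row_b,
                                                          e.color or "", e.descriptor or ""))],
    }


def _linkmap_from_doc(doc, field_name: str) -> LinkMap | None:
    if doc is None:
        return None
    try:
        edges = frozenset(LinkEdge(int(e[0]), int(e[1]), e[2], e[3]) for e in doc["edges"])
        return LinkMap(layer_pair=tuple(doc["layer_pair"]), edges=edges,
                       provenance=doc["provenance"])
    except (KeyError, TypeError, IndexError) as exc:
        raise ValidationError(f"workspace field {field_name!r} is malformed: {exc}") from exc


def workspace_to_doc(ws: Workspace) -> dict:
    return {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "layers": [
            {
                "name": l.name,
                "metadata": _df_to_doc(l.metadata, numeric=False),
                "values": _df_to_doc(l.values, numeric=True),
                "standard_id_tags": dict(sorted(l.standard_id_tags.items())),
            }
            for l in ws.layers
        ],
        "samples": {
            "sample_names": list(ws.samples.sample_names),
            "phenotypes": {
                "columns": list(map(str, ws.samples.phenotypes.columns)),
                "rows": [
                    [None if (isinstance(v, float) and math.isnan(v))
                     else (float(v) if isinstance(v, (int, float, np.integer, np.floating))
                           else str(v))
                     for v in row]
                    for row in ws.samples.phenotypes.to_numpy(dtype=object).tolist()
                ],
            },
        },
        "kb": {
            "gene_sets": [
                {"group_id": g.group_id, "display_name": g.display_name, "source": g.source,
                 "members": sorted(map(list, g.members))}
                for g in ws.kb.gene_sets
            ],
            "id_map": _df_to_doc(ws.kb.id_map.astype(str), numeric=False),
            "networks": [
                {"name": n.name, "kind": n.kind, "directed": n.directed,
                 "edges": sorted(map(list, n.edges))}
                for n in sorted(ws.kb.networks.values(), key=lambda n: n.name)
            ],
        },
        "selections": [
            {"group_id": g.group_id, "display_name": g.display_name, "source": g.source,
             "members": sorted(map(list, g.members)), "color_tag": g.color_tag,
             "layer_scope": sorted(map(list, g.layer_scope))}
            for g in ws.selections
        ],
        "link_maps": {
            key: {"inferred": _linkmap_to_doc(entry["inferred"]),
                  "uploaded": _linkmap_to_doc(entry["uploaded"])}
            for key, entry in sorted(ws.link_maps.items())
        },
        "orderings": {
            name: {
                "layer": o.layer,
                "row_ids": list(o.row_ids),
                "order": list(o.order),
                "mode": o.mode,
                "anchor_layer": o.anchor_layer,
                "linkage_matrix": (None if o.linkage_matrix is None
                                   else [[float(v) for v in row] for row in o.linkage_matrix]),
            }
            for name, o in sorted(ws.orderings.items())
        },
        "filters": {name: dict(f) for name, f in sorted(ws.filters.items())},
        "view": dict(sorted(ws.view.items())),
        "sample_order": list(ws.sample_order),
        "provenance_log": list(ws.provenance_log),
    }


def save_workspace(ws: Workspace, path: str) -> None:
    doc = workspace_to_doc(ws)
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True, allow_nan=False)
            fh.write("\n")
    except OSError as exc:
        raise OmiclinkError(f"cannot write workspace to {path}: {exc}") from exc


def load_workspace(path: str) -> Workspace:
    """Load and fully re-validate a workspace; violations abort the load."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid workspace JSON: {exc}") from exc
    if doc.get("format") != FORMAT_NAME:
        raise FormatError(f"{path}: not an omiclink workspace file")
    version = doc.get("version")
    if version not in COMPATIBLE_VERSIONS:
        raise FormatError(
            f"{path}: unknown workspace format version {version!r}; "
            f"this build reads {COMPATIBLE_VERSIONS}"
        )
    layers = [
        OmicsLayer(
            name=l["name"],
            metadata=_df_from_doc(l["metadata"], numeric=False),
            values=_df_from_doc(l["values"], numeric=True),
            standard_id_tags=dict(l["standard_id_tags"]),
        )
        for l in doc["layers"]
    ]
    sdoc = doc["samples"]
    phen = pd.DataFrame(
        [[math.nan if v is None else v for v in row] for row in sdoc["phenotypes"]["rows"]],
        columns=sdoc["phenotypes"]["columns"],
    )
    samples = SampleTable(sample_names=list(sdoc["sample_names"]), phenotypes=phen)
    kdoc = doc["kb"]
    gene_sets = [
        FunctionalGroup(g["group_id"], g["display_name"], g["source"],
                        frozenset(map(tuple, g["members"])))
        for g in kdoc["gene_sets"]
    ]
    kb = KnowledgeBase(
        gene_sets=gene_sets,
        id_map=_df_from_doc(kdoc["id_map"], numeric=False),
        networks={
            n["name"]: knowledge.Network(n["name"], n["kind"], bool(n["directed"]),
                                         [tuple(e) for e in n["edges"]])
            for n in kdoc["networks"]
        },
    )
    ws = Workspace(layers=layers, samples=samples, kb=kb)
    for s in doc["selections"]:
        ws.selections.append(FunctionalGroup(
            s["group_id"], s["display_name"], s["source"],
            frozenset(map(tuple, s["members"])), s["color_tag"],
            tuple(map(tuple, s["layer_scope"])),
        ))
    by_name = {l.name: l for l in layers}
    for key, entry in doc["link_maps"].items():
        a, b = key.split("|", 1)
        if a not in by_name or b not in by_name:
            raise ValidationError(f"link_maps[{key!r}]: unknown layer in pair")
        maps = {}
        for kind in ("inferred", "uploaded"):
            m = _linkmap_from_doc(entry[kind], f"link_maps[{key}].{kind}")
            if m is not None:
                m.validate_against(by_name[m.layer_pair[0]], by_name[m.layer_pair[1]])
            maps[kind] = m
        ws.link_maps[key] = maps
    for name, o in doc["orderings"].items():
        if name not in by_name:
            raise ValidationError(f"orderings[{name!r}]: unknown layer")
        n = by_name[name].n_features
        row_ids = [int(r) for r in o["row_ids"]]
        bad = [r for r in row_ids if not (0 <= r < n)]
        if bad:
            raise ValidationError(f"orderings[{name!r}].row_ids: row(s) {bad} out of range 0..{n - 1}")
        ws.orderings[name] = clustering.OrderingResult(
            layer=o["layer"], row_ids=tuple(row_ids), order=tuple(int(i) for i in o["order"]),
            mode=o["mode"], anchor_layer=o["anchor_layer"],
            linkage_matrix=(None if o["linkage_matrix"] is None
                            else np.array(o["linkage_matrix"], dtype=float)),
        )
    for name, f in doc["filters"].items():
        if name not in by_name:
            raise ValidationError(f"filters[{name!r}]: unknown layer")
        n = by_name[name].n_features
        bad = [r for r in f["retained_rows"] if not (0 <= int(r) < n)]
        if bad:
            raise ValidationError(f"filters[{name!r}].retained_rows: row(s) {bad} out of range")
        ws.filters[name] = dict(f)
    ws.view = dict(DEFAULT_VIEW)
    ws.view.update(doc["view"])     # 1.0 files lack tag_track_side; default applies
    ws.sample_order = list(doc["sample_order"])
    unknown = [s for s in ws.sample_order if s not in samples.sample_names]
    if unknown:
        raise ValidationError(f"sample_order: unknown sample(s) {unknown}")
    ws.provenance_log = list(doc["provenance_log"])
    return ws
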
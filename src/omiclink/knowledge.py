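"""Annotation knowledge base: gene sets, identifier maps, molecular networks.

The KB anchors every standard identifier (gene symbol, Ensembl, RefSeq,
UniProt, miRBase id, or Entrez itself) to an Entrez-style anchor string.
Ambiguity is preserved: one identifier may map to several anchors, and
downstream linking connects through every anchor rather than collapsing.

Storage is flat delimited tables plus a JSON manifest — deliberately
service-free so a KB can ship inside a repository and load deterministically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, ResolutionError, ValidationError
from .io_model import OmicsLayer, PathwayFileSpec, is_missing_token

GROUP_SOURCES = ("pathway", "GO", "user")
NETWORK_KINDS = ("PPI", "TF-target", "kinase-substrate", "miRNA-target")


@dataclass(frozen=True)
class FunctionalGroup:
    """A named feature set: a pathway, GO term, or user-defined group.

    ``members`` are (vocabulary, identifier) pairs; for user groups built
    from a pathway file the "vocabulary" is the raw identifier column name
    and ``layer_scope`` restricts matching to the named data file.
    """

    group_id: str
    display_name: str
    source: str
    members: frozenset  # of (vocabulary, identifier)
    color_tag: str | None = None
    layer_scope: tuple = ()  # (data_filename, identifier_name, identifier_value) rows, user groups only

    def __post_init__(self) -> None:
        if self.source not in GROUP_SOURCES:
            raise ValidationError(f"group {self.group_id!r}: source must be one of {GROUP_SOURCES}")
        if not self.members:
            raise ValidationError(f"group {self.group_id!r}: members must be nonempty")

    def with_color(self, color: str) -> "FunctionalGroup":
        return FunctionalGroup(
            self.group_id, self.display_name, self.source, self.members, color, self.layer_scope
        )


@dataclass
class Network:
    name: str
    kind: str
    directed: bool
    edges: list  # of (anchor_a, anchor_b)

    def __post_init__(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise ValidationError(f"network {self.name!r}: kind must be one of {NETWORK_KINDS}")


@dataclass
class KnowledgeBase:
    """Gene sets + identifier map + molecular networks."""

    gene_sets: list = field(default_factory=list)     # of FunctionalGroup
    id_map: pd.DataFrame = None                        # columns: vocabulary, identifier, anchor
    networks: dict = field(default_factory=dict)       # name -> Network

    def __post_init__(self) -> None:
        if self.id_map is None:
            self.id_map = pd.DataFrame(columns=["vocabulary", "identifier", "anchor"])
        ids = [g.group_id for g in self.gene_sets]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValidationError(f"duplicate group_id(s) in knowledge base: {dupes}")
        self._index = {}
        for vocab, ident, anchor in self.id_map.itertuples(index=False):
            self._index.setdefault((vocab, str(ident)), set()).add(str(anchor))

    def anchors_for(self, vocabulary: str, identifier: str) -> set:
        """Entrez anchors of one identifier. Entrez identifiers anchor to themselves."""
        if is_missing_token(str(identifier)):
            return set()
        found = set(self._index.get((vocabulary, str(identifier)), ()))
        if vocabulary == "Entrez":
            found.add(str(identifier))
        return found

    def group_anchors(self, group: FunctionalGroup) -> set:
        out = set()
        for vocab, ident in group.members:
            out |= self.anchors_for(vocab, ident)
        return out

    def networks_of_kind(self, kind: str) -> list:
        return [n for n in self.networks.values() if n.kind == kind]


@dataclass(frozen=True)
class SearchHit:
    kind: str          # "pathway" | "GO" | "gene"
    name: str          # display name or gene identifier
    key: str           # group_id, or "vocabulary:identifier" for genes
    keyword: str
    match_position: int


def keyword_search(kb: KnowledgeBase, keywords: list) -> list:
    """Case-insensitive substring search over group names and gene identifiers.

    Multiple keywords give the union of their hits, deduplicated by key.
    Order: (kind, match position, name) — pathways, then GO terms, then genes.
    """
    if not keywords or any(not str(k).strip() for k in keywords):
        raise ValidationError("keywords must be nonempty strings")
    kind_rank = {"pathway": 0, "GO": 1, "gene": 2}
    hits: dict = {}
    for kw in keywords:
        low = str(kw).lower()
        for g in kb.gene_sets:
            pos = g.display_name.lower().find(low)
            if pos >= 0:
                kind = g.source if g.source in ("pathway", "GO") else "pathway"
                hits.setdefault(g.group_id, SearchHit(kind, g.display_name, g.group_id, str(kw), pos))
        for vocab, ident in {(v, str(i)) for v, i, _ in kb.id_map.itertuples(index=False)}:
            pos = ident.lower().find(low)
            if pos >= 0:
                key = f"{vocab}:{ident}"
                hits.setdefault(key, SearchHit("gene", ident, key, str(kw), pos))
    return sorted(
        hits.values(), key=lambda h: (kind_rank[h.kind], h.match_position, h.name, h.key)
    )


def neighborhood_search(kb: KnowledgeBase, anchor: str, network_kind: str, degree: int = 1) -> dict:
    """First-degree network neighbors of an anchor.

    Returns ``{neighbor_anchor: direction}`` with direction ``"neighbor"``
    on undirected networks and ``"target"``/``"regulator"`` on directed ones
    (a node that is both keeps ``"target+regulator"``).
    """
    if network_kind not in ("PPI", "TF-target"):
        raise ValidationError(f"network kind {network_kind!r} not searchable; use 'PPI' or 'TF-target'")
    if degree != 1:
        raise ValidationError("only first-degree neighborhoods are supported")
    nets = kb.networks_of_kind(network_kind)
    if not nets:
        raise ResolutionError(f"knowledge base has no network of kind {network_kind!r}")
    out: dict = {}

    def _note(node: str, direction: str) -> None:
        prev = out.get(node)
        if prev is None or prev == direction:
            out[node] = direction
        else:
            out[node] = "target+regulator"

    for net in nets:
        for a, b in net.edges:
            if not net.directed:
                if a == anchor and b != anchor:
                    _note(b, "neighbor")
                if b == anchor and a != anchor:
                    _note(a, "neighbor")
            else:
                if a == anchor and b != anchor:
                    _note(b, "target")
                if b == anchor and a != anchor:
                    _note(a, "regulator")
    return out


def resolve_group_rows(group: FunctionalGroup, layer: OmicsLayer, kb: KnowledgeBase) -> list:
    """Row indices of a layer matching a functional group, in row order.

    KB groups match through Entrez anchors of the layer's tagged standard
    identifier columns. User groups match raw identifier columns, restricted
    to the data file named in their pathway-file rows.
    """
    rows = []
    if group.source == "user" and group.layer_scope:
        for fname, id_name, id_value in group.layer_scope:
            if fname != layer.name:
                continue
            if id_name not in layer.metadata.columns:
                raise ResolutionError(
                    f"group {group.group_id!r}: identifier column {id_name!r} "
                    f"absent from layer {layer.name!r}"
                )
            col = layer.metadata[id_name].astype(str)
            rows.extend(int(i) for i in col.index[col == id_value])
        return sorted(set(rows))

    target = kb.group_anchors(group)
    # members naming a raw metadata column of this layer match directly
    direct = {
        (vocab, ident) for vocab, ident in group.members if vocab in layer.metadata.columns
    }
    for i in range(layer.n_features):
        anchors = set()
        for col, vocab in layer.standard_id_tags.items():
            anchors |= kb.anchors_for(vocab, str(layer.metadata.iloc[i][col]))
        if target and anchors & target:
            rows.append(i)
            continue
        if direct and any(str(layer.metadata.iloc[i][col]) == ident for col, ident in direct):
            rows.append(i)
    return rows


def groups_from_pathway_file(
    spec: PathwayFileSpec, known_layers: list, prefix: str = "user"
) -> list:
    """Build user FunctionalGroups from a parsed pathway file.

    Raises if a row references a data filename that is not a loaded layer.
    Rows matching zero features are a resolution-time concern, not an error.
    """
    known = list(known_layers)
    groups: dict = {}
    order: list = []
    for r in spec.rows:
        if r.data_filename not in known:
            raise ResolutionError(
                f"pathway file references unknown data file {r.data_filename!r}; "
                f"known layers: {known}"
            )
        if r.group_name not in groups:
            groups[r.group_name] = []
            order.append(r.group_name)
        groups[r.group_name].append(r)
    out = []
    for name in order:
        rows = groups[name]
        out.append(
            FunctionalGroup(
                group_id=f"{prefix}:{name}",
                display_name=name,
                source="user",
                members=frozenset((r.identifier_name, r.identifier_value) for r in rows),
                layer_scope=tuple((r.data_filename, r.identifier_name, r.identifier_value) for r in rows),
            )
        )
    return out


# ---------------------------------------------------------------------------
# manifest persistence

def save_kb(kb: KnowledgeBase, directory: str) -> None:
    """Write a KB as delimited tables plus a JSON manifest."""
    os.makedirs(directory, exist_ok=True)
    gs_rows = []
    for g in kb.gene_sets:
        for vocab, ident in sorted(g.members):
            gs_rows.append((g.group_id, g.display_name, g.source, vocab, ident))
    pd.DataFrame(
        gs_rows, columns=["group_id", "display_name", "source", "vocabulary", "identifier"]
    ).to_csv(os.path.join(directory, "gene_sets.tsv"), sep="\t", index=False)
    kb.id_map.to_csv(os.path.join(directory, "id_map.tsv"), sep="\t", index=False)
    net_files = {}
    for name, net in kb.networks.items():
        fname = f"network_{name}.tsv"
        pd.DataFrame(net.edges, columns=["anchor_a", "anchor_b"]).to_csv(
            os.path.join(directory, fname), sep="\t", index=False
        )
        net_files[name] = {"file": fname, "kind": net.kind, "directed": net.directed}
    manifest = {
        "format": "omiclink-kb",
        "version": 1,
        "gene_sets": "gene_sets.tsv",
        "id_map": "id_map.tsv",
        "networks": net_files,
    }
    with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_kb(directory: str) -> KnowledgeBase:
    with open(os.path.join(directory, "manifest.json"), "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "omiclink-kb":
        raise FormatError(f"{directory}: not a knowledge-base manifest")
    gs = pd.read_csv(os.path.join(directory, manifest["gene_sets"]), sep="\t", dtype=str)
    groups: dict = {}
    order: list = []
    meta: dict = {}
    for gid, disp, source, vocab, ident in gs.itertuples(index=False):
        if gid not in groups:
            groups[gid] = set()
            order.append(gid)
            meta[gid] = (disp, source)
        groups[gid].add((vocab, ident))
    gene_sets = [
        FunctionalGroup(gid, meta[gid][0], meta[gid][1], frozenset(groups[gid])) for gid in order
    ]
    id_map = pd.read_csv(os.path.join(directory, manifest["id_map"]), sep="\t", dtype=str)
    networks = {}
    for name, info in manifest["networks"].items():
        edges_df = pd.read_csv(os.path.join(directory, info["file"]), sep="\t", dtype=str)
        networks[name] = Network(
            name=name,
            kind=info["kind"],
            directed=bool(info["directed"]),
            edges=[tuple(t) for t in edges_df.itertuples(index=False)],
        )
    return KnowledgeBase(gene_sets=gene_sets, id_map=id_map, networks=networks)


def load_fixture_kb() -> KnowledgeBase:
    """Deterministic miniature knowledge base (~50 genes, 10 gene sets, 4 networks).

    Built in code, no files required; identical on every call. Serves tests,
    tutorials, and the bundled miniature case studies.
    """
    symbols = [
        "HSPA5", "XBP1", "ATF4", "DDIT3", "EIF2AK3", "ERN1", "ATF6", "HSP90B1", "CALR", "CANX",
        "PLEC", "LMNA", "FLNA", "VIM", "CDK1", "CDK2", "GSK3A", "GSK3B", "CAMK2A", "CAMK2B",
        "AKT1", "TP53", "MYC", "EGFR", "MTOR", "INSR", "IRS1", "SLC2A4", "LDLR", "APOB",
        "ALB", "CRP", "IL6", "TNF", "ADIPOQ", "LEP", "PPARG", "SREBF1", "FASN", "SCD",
        "G6PC1", "PCK1", "GCK", "HK2", "PFKL", "PKM", "LDHA", "CS", "SDHA", "MDH2",
    ]
    rows = []
    for k, sym in enumerate(symbols):
        entrez = str(1000 + k)
        rows.append(("GeneSymbol", sym, entrez))
        rows.append(("Ensembl", f"ENSG{90000 + k:08d}", entrez))
        rows.append(("RefSeq", f"NM_{20000 + k:06d}", entrez))
        rows.append(("UniProt", f"P{10000 + k:05d}", entrez))
        rows.append(("Entrez", entrez, entrez))
    # an ambiguous symbol mapping to two anchors (preserved, not collapsed)
    rows.append(("GeneSymbol", "DUP1", "1100"))
    rows.append(("GeneSymbol", "DUP1", "1101"))
    mirnas = [f"hsa-miR-{n}" for n in ("130a-3p", "128-3p", "21-5p", "155-5p", "375", "122-5p")]
    for k, mir in enumerate(mirnas):
        rows.append(("miRBase", mir, str(2000 + k)))
    id_map = pd.DataFrame(rows, columns=["vocabulary", "identifier", "anchor"])

    def gs(gid, name, source, syms):
        return FunctionalGroup(gid, name, source, frozenset(("GeneSymbol", s) for s in syms))

    gene_sets = [
        gs("GO:0030968", "endoplasmic reticulum unfolded protein response", "GO", symbols[:10]),
        gs("GO:0031012", "extracellular matrix", "GO", ["PLEC", "LMNA", "FLNA", "VIM"]),
        gs("PW:0001", "AKT1 signaling", "pathway", ["AKT1", "MTOR", "GSK3B", "INSR", "IRS1"]),
        gs("PW:0002", "DNA replication", "pathway", ["CDK1", "CDK2", "MYC", "TP53"]),
        gs("PW:0003", "complement cascade", "pathway", ["CRP", "IL6", "TNF", "ALB"]),
        gs("PW:0004", "metabolic pathways", "pathway", symbols[40:50]),
        gs("PW:0005", "glucose transport", "pathway", ["SLC2A4", "INSR", "IRS1", "GCK", "HK2"]),
        gs("PW:0006", "lipid homeostasis", "pathway", ["LDLR", "APOB", "SREBF1", "FASN", "SCD"]),
        gs("PW:0007", "inflammatory response", "pathway", ["IL6", "TNF", "CRP", "LEP"]),
        gs("GO:0006412", "translation", "GO", ["ATF4", "EIF2AK3", "PKM", "LDHA"]),
    ]

    def a(sym):  # anchor of a symbol
        return str(1000 + symbols.index(sym))

    ppi = Network(
        "fixture_ppi", "PPI", directed=False,
        edges=[(a("HSPA5"), a("ATF6")), (a("HSPA5"), a("ERN1")), (a("HSPA5"), a("EIF2AK3")),
               (a("AKT1"), a("MTOR")), (a("AKT1"), a("GSK3B")), (a("TP53"), a("MYC")),
               (a("VIM"), a("PLEC")), (a("CALR"), a("CANX"))],
    )
    tf = Network(
        "fixture_tf", "TF-target", directed=True,
        edges=[(a("ATF4"), a("DDIT3")), (a("ATF6"), a("HSPA5")), (a("XBP1"), a("HSPA5")),
               (a("MYC"), a("LDHA")), (a("TP53"), a("DDIT3")), (a("SREBF1"), a("LDLR")),
               (a("SREBF1"), a("FASN"))],
    )
    ks = Network(
        "fixture_kinase", "kinase-substrate", directed=True,
        edges=[(a("CDK1"), a("VIM")), (a("CDK1"), a("LMNA")), (a("CDK2"), a("LMNA")),
               (a("GSK3B"), a("IRS1")), (a("CAMK2A"), a("VIM"))],
    )
    mt = Network(
        "fixture_mirna", "miRNA-target", directed=True,
        edges=[("2000", a("LDLR")), ("2001", a("LDLR")), ("2002", a("PPARG")),
               ("2003", a("ADIPOQ")), ("2004", a("INSR"))],
    )
    return KnowledgeBase(
        gene_sets=gene_sets,
        id_map=id_map,
        networks={n.name: n for n in (ppi, tf, ks, mt)},
    )
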
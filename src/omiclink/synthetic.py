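"""Deterministic synthetic multi-omics fixtures with planted structure.

Everything every other module needs to be exercised — layers with standard
identifiers drawn from the bundled miniature knowledge base, group designs
with planted mean shifts, nested phosphosite-style layers, disjoint-vocabulary
miRNA/protein pairs with negatively correlated planted targets — is generated
here from a seed, in memory or as files in the standard input formats.

The noise model is independent Gaussian per feature (unit SD), with planted
effects expressed as mean shifts in SD units; a heavier-tailed Student-t
(df=3) option exercises the rank tests. Negative miRNA-target correlation
comes from a shared latent factor loaded with opposite signs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_model import (
    NetworkEdge,
    NetworkSpec,
    OmicsLayer,
    PathwayFileSpec,
    PathwayRow,
    SampleTable,
    write_network_file,
    write_omics_layer,
    write_pathway_file,
    write_sample_table,
)
from .knowledge import load_fixture_kb, save_kb


@dataclass(frozen=True)
class LayerFixture:
    name: str
    n_features: int = 50
    vocabulary: str | None = "GeneSymbol"   # standard tag of the id column; None = unlinkable
    id_column: str = "gene_symbol"
    nested: tuple | None = None             # (parent_column, children_per_parent tuple)


@dataclass(frozen=True)
class PlantedEffect:
    layer: str
    rows: tuple          # feature row indices carrying the shift
    group: str           # group label receiving it
    effect_size: float = 3.0
    sign: int = 1


@dataclass
class FixtureSpec:
    seed: int = 7
    n_samples_per_group: int = 10
    groups: tuple = ("A", "B")
    layers: tuple = (LayerFixture("mrna"),)
    planted: tuple = ()
    noise: str = "gaussian"                 # "gaussian" | "t3"
    negative_pairs: int = 0                 # latent-factor miRNA-target pairs (first two layers)

    def __post_init__(self) -> None:
        if self.noise not in ("gaussian", "t3"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if len(self.groups) < 1 or self.n_samples_per_group < 1:
            raise ValidationError("need at least one group and one sample per group")
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate layer names in fixture spec: {names}")
        for eff in self.planted:
            if eff.layer not in names:
                raise ValidationError(f"planted effect references unknown layer {eff.layer!r}")
            lay = next(l for l in self.layers if l.name == eff.layer)
            bad = [r for r in eff.rows if not (0 <= r < lay.n_features)]
            if bad:
                raise ValidationError(f"planted rows {bad} outside layer {eff.layer!r}")
            if eff.group not in self.groups:
                raise ValidationError(f"planted effect group {eff.group!r} not a design group")


def _noise(rng: np.random.Generator, shape, model: str) -> np.ndarray:
    if model == "t3":
        return rng.standard_t(3, size=shape)
    return rng.standard_normal(shape)


def _identifiers(kb, vocabulary: str | None, n: int, rng: np.random.Generator) -> list:
    """Identifier values for a layer: KB-mapped ids first, synthetic fill after."""
    if vocabulary is None:
        return [f"feat_{k:04d}" for k in range(n)]
    pool = sorted(kb.id_map.loc[kb.id_map["vocabulary"] == vocabulary, "identifier"].unique())
    ids = list(pool[:n])
    k = 0
    while len(ids) < n:
        ids.append(f"UNMAPPED_{vocabulary}_{k:04d}")
        k += 1
    return ids


def build_fixture(spec: FixtureSpec) -> dict:
    """Generate the fixture in memory.

    Returns layers, sample table, the bundled KB, the set of planted truly
    differential rows per layer, and any planted negative-correlation pairs.
    """
    rng = np.random.default_rng(spec.seed)
    kb = load_fixture_kb()
    n_samples = spec.n_samples_per_group * len(spec.groups)
    sample_names = [f"S{k + 1:02d}" for k in range(n_samples)]
    labels = [g for g in spec.groups for _ in range(spec.n_samples_per_group)]
    samples = SampleTable(
        sample_names=sample_names,
        phenotypes=pd.DataFrame({"group": labels}),
    )
    layers = []
    true_rows: dict = {}
    for lf in spec.layers:
        values = _noise(rng, (lf.n_features, n_samples), spec.noise)
        for eff in spec.planted:
            if eff.layer != lf.name:
                continue
            mask = np.array([g == eff.group for g in labels])
            for r in eff.rows:
                values[r, mask] += eff.sign * eff.effect_size
            true_rows.setdefault(lf.name, set()).update(eff.rows)
        ids = _identifiers(kb, lf.vocabulary, lf.n_features, rng)
        meta = {lf.id_column: ids}
        if lf.nested is not None:
            parent_col, children_per_parent = lf.nested
            parents = []
            for pi, n_children in enumerate(children_per_parent):
                parents.extend([ids[pi]] * n_children)
            if len(parents) != lf.n_features:
                raise ValidationError(
                    f"nested layer {lf.name!r}: children counts sum to {len(parents)}, "
                    f"expected {lf.n_features}"
                )
            meta = {
                parent_col: parents,
                lf.id_column: [f"{p}_site{si}" for si, p in enumerate(parents)],
            }
        tags = {}
        if lf.vocabulary is not None and lf.nested is None:
            tags[lf.id_column] = lf.vocabulary
        if lf.nested is not None and lf.vocabulary is not None:
            tags[lf.nested[0]] = lf.vocabulary
        layers.append(OmicsLayer(
            name=lf.name,
            metadata=pd.DataFrame(meta, dtype=str),
            values=pd.DataFrame(values, columns=sample_names),
            standard_id_tags=tags,
        ))
    negative_pairs = []
    if spec.negative_pairs:
        if len(layers) < 2:
            raise ValidationError("negative_pairs requires at least two layers")
        la, lb = layers[0], layers[1]
        n_pairs = min(spec.negative_pairs, la.n_features, lb.n_features)
        for k in range(n_pairs):
            z = rng.standard_normal(n_samples)
            la.values.iloc[k] = z + 0.3 * rng.standard_normal(n_samples)
            lb.values.iloc[k] = -z + 0.3 * rng.standard_normal(n_samples)
            negative_pairs.append((k, k))
    return {
        "layers": layers,
        "samples": samples,
        "kb": kb,
        "true_rows": {k: sorted(v) for k, v in true_rows.items()},
        "negative_pairs": negative_pairs,
    }


def default_planted_spec(seed: int = 7) -> FixtureSpec:
    """The reference planted-effect study: 100 features, 20 true at 3 SD, n=10/group."""
    return FixtureSpec(
        seed=seed,
        n_samples_per_group=10,
        groups=("A", "B"),
        layers=(LayerFixture("mrna", n_features=100),),
        planted=(PlantedEffect("mrna", rows=tuple(range(20)), group="B", effect_size=3.0),),
    )


def generate_fixture(spec: FixtureSpec, out_dir: str) -> dict:
    """Write a fixture as standard input files; returns the paths written."""
    fx = build_fixture(spec)
    os.makedirs(out_dir, exist_ok=True)
    paths: dict = {"layers": {}}
    for layer in fx["layers"]:
        p = os.path.join(out_dir, f"{layer.name}.tsv")
        write_omics_layer(layer, p)
        paths["layers"][layer.name] = p
    paths["samples"] = os.path.join(out_dir, "samples.tsv")
    write_sample_table(fx["samples"], paths["samples"])
    kb_dir = os.path.join(out_dir, "kb")
    save_kb(fx["kb"], kb_dir)
    paths["kb"] = kb_dir
    if fx["negative_pairs"]:
        la, lb = fx["layers"][0], fx["layers"][1]
        edges = [
            NetworkEdge(str(la.metadata.iloc[i, 0]), str(lb.metadata.iloc[j, 0]))
            for i, j in fx["negative_pairs"]
        ]
        net = NetworkSpec(column_a=la.metadata_columns[0], column_b=lb.metadata_columns[0],
                          edges=edges)
        paths["network"] = os.path.join(out_dir, "network.tsv")
        write_network_file(net, paths["network"])
    paths["true_rows"] = fx["true_rows"]
    return paths


def random_layer_pair(seed: int) -> tuple:
    """Two small random layers with overlapping, ambiguous and missing identifiers.

    Identifier values mix KB-mapped ids from random vocabularies, unmapped
    strings, duplicates, and missing tokens — the awkward cases cross-layer
    link inference must survive. Returns ``(layer_a, layer_b, kb)``.
    """
    rng = np.random.default_rng(seed)
    kb = load_fixture_kb()
    vocabs = ["GeneSymbol", "UniProt", "Ensembl", "RefSeq", "Entrez", "miRBase"]

    def make(name: str) -> OmicsLayer:
        vocab = vocabs[int(rng.integers(len(vocabs)))]
        pool = sorted(kb.id_map.loc[kb.id_map["vocabulary"] == vocab, "identifier"].unique())
        n = int(rng.integers(3, 12))
        ids = []
        for _ in range(n):
            u = rng.random()
            if u < 0.70:
                ids.append(pool[int(rng.integers(len(pool)))])   # mapped, duplicates possible
            elif u < 0.85:
                ids.append(f"unmapped_{int(rng.integers(100))}")
            else:
                ids.append("")                                    # missing identifier
        values = rng.standard_normal((n, 4))
        return OmicsLayer(
            name=name,
            metadata=pd.DataFrame({"id": ids}, dtype=str),
            values=pd.DataFrame(values, columns=[f"S{k + 1}" for k in range(4)]),
            standard_id_tags={"id": vocab},
        )

    return make("layer_a"), make("layer_b"), kb


# ---------------------------------------------------------------------------
# miniature case studies


def _timecourse_samples(timepoints, replicates) -> SampleTable:
    names, times, reps = [], [], []
    for t in timepoints:
        for r in range(1, replicates + 1):
            names.append(f"T{t}h_r{r}")
            times.append(float(t))
            reps.append(f"r{r}")
    return SampleTable(sample_names=names,
                       phenotypes=pd.DataFrame({"time": times, "replicate": reps}))


def cs1_miniature(seed: int = 11) -> dict:
    """Time-course mRNA + protein miniature: one-to-one links via gene symbols.

    Eight timepoints (0, 0.5, 1, 2, 8, 16, 24, 30 h) x 2 replicates; twelve
    genes shared by both layers, the first six carrying a stress-response
    trend (rising with log-time).
    """
    rng = np.random.default_rng(seed)
    kb = load_fixture_kb()
    symbols = ["HSPA5", "XBP1", "ATF4", "DDIT3", "EIF2AK3", "ERN1",
               "ATF6", "HSP90B1", "CALR", "CANX", "TP53", "MYC"]
    samples = _timecourse_samples((0, 0.5, 1, 2, 8, 16, 24, 30), 2)
    t = samples.phenotypes["time"].to_numpy(dtype=float)
    trend = np.log1p(t) / np.log1p(30.0)
    layers = []
    for lname, lag in (("mrna", 0.0), ("protein", 0.2)):
        vals = 0.3 * rng.standard_normal((len(symbols), len(samples.sample_names)))
        for i in range(6):
            vals[i] += 2.0 * np.clip(trend - lag, 0.0, None)
        layers.append(OmicsLayer(
            name=lname,
            metadata=pd.DataFrame({"gene_symbol": symbols}, dtype=str),
            values=pd.DataFrame(vals, columns=samples.sample_names),
            standard_id_tags={"gene_symbol": "GeneSymbol"},
        ))
    return {"layers": layers, "samples": samples, "kb": kb, "genes": symbols}


def cs2_miniature(seed: int = 22) -> dict:
    """Proteome + nested phosphosite miniature with a kinase-substrate network.

    Five molecular subtypes x 4 samples. The phosphosite layer nests 12
    sites under 5 parent proteins; a 2-column network file connects kinases
    (protein layer) to substrate sites (phosphosite layer).
    """
    rng = np.random.default_rng(seed)
    kb = load_fixture_kb()
    prot_symbols = ["PLEC", "LMNA", "FLNA", "VIM", "CDK1", "CDK2", "GSK3B", "CAMK2A"]
    subtypes = ("differentiated", "immunoreactive", "proliferative", "mesenchymal", "stromal")
    n_per = 4
    names = [f"TU{k + 1:02d}" for k in range(n_per * len(subtypes))]
    labels = [s for s in subtypes for _ in range(n_per)]
    samples = SampleTable(sample_names=names, phenotypes=pd.DataFrame({"subtype": labels}))
    prot_vals = rng.standard_normal((len(prot_symbols), len(names)))
    # kinases CDK1/CDK2 elevated in the proliferative subtype
    prolif = np.array([s == "proliferative" for s in labels])
    for sym in ("CDK1", "CDK2"):
        prot_vals[prot_symbols.index(sym), prolif] += 2.5
    mesen = np.array([s in ("mesenchymal", "stromal") for s in labels])
    for sym in ("PLEC", "LMNA", "FLNA", "VIM"):
        prot_vals[prot_symbols.index(sym), mesen] += 2.0
    protein = OmicsLayer(
        name="protein",
        metadata=pd.DataFrame({"gene_symbol": prot_symbols}, dtype=str),
        values=pd.DataFrame(prot_vals, columns=names),
        standard_id_tags={"gene_symbol": "GeneSymbol"},
    )
    parents = ["PLEC"] * 3 + ["LMNA"] * 2 + ["FLNA"] * 2 + ["VIM"] * 4 + ["GSK3B"]
    sites = [f"{p}_S{k * 7 + 3}" for k, p in enumerate(parents)]
    ps_vals = rng.standard_normal((len(sites), len(names)))
    for i, p in enumerate(parents):
        if p in ("VIM", "LMNA"):
            ps_vals[i, mesen] += 2.0
    psite = OmicsLayer(
        name="psite",
        metadata=pd.DataFrame({"protein": parents, "site": sites}, dtype=str),
        values=pd.DataFrame(ps_vals, columns=names),
        standard_id_tags={"protein": "GeneSymbol"},
    )
    network = NetworkSpec(
        column_a="gene_symbol", column_b="site",
        edges=[NetworkEdge("CDK1", s, "#8c510a", "curated") for s in sites if "VIM" in s or "LMNA" in s]
        + [NetworkEdge("CDK2", s) for s in sites if "LMNA" in s],
    )
    return {"layers": [protein, psite], "samples": samples, "kb": kb,
            "network": network, "parents": parents}


def cs3_miniature(seed: int = 33) -> dict:
    """Plasma miRNA + protein miniature: disjoint vocabularies, uploaded targets.

    Eight insulin-resistant (IR) vs nine insulin-sensitive (IS) subjects.
    The miRNA and protein layers share no identifiers, so inference yields
    no links; a TargetScan-style 2-column file connects miR families to
    target gene symbols, with two planted negatively correlated pairs.
    """
    rng = np.random.default_rng(seed)
    kb = load_fixture_kb()
    names = [f"P{k + 1:02d}" for k in range(17)]
    labels = ["IR"] * 8 + ["IS"] * 9
    samples = SampleTable(sample_names=names, phenotypes=pd.DataFrame({"status": labels}))
    mirnas = ["hsa-miR-130a-3p", "hsa-miR-128-3p", "hsa-miR-21-5p",
              "hsa-miR-155-5p", "hsa-miR-375", "hsa-miR-122-5p"]
    prots = ["LDLR", "APOB", "ALB", "CRP", "IL6", "ADIPOQ", "LEP", "INSR"]
    ir = np.array([l == "IR" for l in labels])
    mir_vals = rng.standard_normal((len(mirnas), 17))
    prot_vals = rng.standard_normal((len(prots), 17))
    # most selected plasma proteins run higher in IR subjects
    prot_vals[2:, ir] += 1.5
    # planted negative correlation: miR-130a/miR-128 up in IS, LDLR down
    for mi in (0, 1):
        z = rng.standard_normal(17)
        mir_vals[mi] = z + 0.3 * rng.standard_normal(17)
        mir_vals[mi, ~ir] += 1.5
    prot_vals[0] = -0.5 * (mir_vals[0] + mir_vals[1]) + 0.4 * rng.standard_normal(17)
    mirna = OmicsLayer(
        name="mirna",
        metadata=pd.DataFrame({"mirna_id": mirnas}, dtype=str),
        values=pd.DataFrame(mir_vals, columns=names),
        standard_id_tags={"mirna_id": "miRBase"},
    )
    protein = OmicsLayer(
        name="protein",
        metadata=pd.DataFrame({"gene_symbol": prots}, dtype=str),
        values=pd.DataFrame(prot_vals, columns=names),
        standard_id_tags={"gene_symbol": "GeneSymbol"},
    )
    network = NetworkSpec(
        column_a="mirna_id", column_b="gene_symbol",
        edges=[NetworkEdge("hsa-miR-130a-3p", "LDLR"), NetworkEdge("hsa-miR-128-3p", "LDLR"),
               NetworkEdge("hsa-miR-21-5p", "INSR"), NetworkEdge("hsa-miR-375", "ADIPOQ")],
    )
    return {"layers": [mirna, protein], "samples": samples, "kb": kb, "network": network}


def case_study_miniatures() -> dict:
    """The three bundled miniature studies, regenerated deterministically."""
    return {"cs1": cs1_miniature(), "cs2": cs2_miniature(), "cs3": cs3_miniature()}


def write_miniature(mini: dict, out_dir: str) -> dict:
    """Write one miniature study to disk in the standard formats."""
    os.makedirs(out_dir, exist_ok=True)
    paths: dict = {"layers": {}}
    for layer in mini["layers"]:
        p = os.path.join(out_dir, f"{layer.name}.tsv")
        write_omics_layer(layer, p)
        paths["layers"][layer.name] = p
    paths["samples"] = os.path.join(out_dir, "samples.tsv")
    write_sample_table(mini["samples"], paths["samples"])
    kb_dir = os.path.join(out_dir, "kb")
    save_kb(mini["kb"], kb_dir)
    paths["kb"] = kb_dir
    if "network" in mini:
        paths["network"] = os.path.join(out_dir, "network.tsv")
        write_network_file(mini["network"], paths["network"])
    # a pathway file exercising the user-group route on the first layer
    first = mini["layers"][0]
    rows = [
        PathwayRow("fixture group", first.name, first.metadata_columns[0],
                   str(first.metadata.iloc[i, 0]))
        for i in range(min(3, first.n_features))
    ]
    paths["pathways"] = os.path.join(out_dir, "pathways.tsv")
    write_pathway_file(PathwayFileSpec(rows=rows), paths["pathways"])
    return paths
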
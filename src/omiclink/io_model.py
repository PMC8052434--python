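"""Input file formats and core domain types.

Four delimited-text formats are supported, all plain ASCII/UTF-8:

* **omics data file** — features x samples; a declared subset of columns is
  feature metadata (identifiers), the rest are numeric sample measurements.
* **sample file** — samples x phenotypes; the first column holds sample names
  identical to the data files' measurement column headers.
* **network file** — 2 to 4 columns: identifier in layer A, identifier in
  layer B, then optionally a line color and a free-text descriptor.
* **pathway file** — exactly 4 columns: functional group name, data filename,
  identifier name, identifier value; one file may define many groups.

Values are assumed preprocessed/normalized upstream; no transformation is
applied here. Missing data cells are recognized from the tokens "", "NA" and
"NaN" (case-insensitive) and preserved as NaN, never coerced to zero.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ResolutionError, ValidationError

#: The six standard identifier vocabularies usable as cross-layer linkers.
STANDARD_VOCABULARIES = frozenset(
    {"Entrez", "GeneSymbol", "Ensembl", "RefSeq", "UniProt", "miRBase"}
)

MISSING_TOKENS = frozenset({"", "na", "nan"})

_DELIMITERS = ("\t", ",", ";")


def detect_delimiter(first_line: str) -> str:
    """Pick the delimiter (tab/comma/semicolon) with the most first-line votes."""
    counts = {d: first_line.count(d) for d in _DELIMITERS}
    best = max(counts, key=lambda d: counts[d])
    if counts[best] == 0:
        raise FormatError("could not detect a delimiter (no tab, comma or semicolon in header line)")
    return best


def _read_rows(path: str, delimiter: str | None) -> tuple[str, list[list[str]]]:
    with open(path, "r", encoding="utf-8", errors="replace", newline="") as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    delim = delimiter or detect_delimiter(lines[0])
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    rows = [row for row in reader if any(cell.strip() for cell in row)]
    return delim, rows


def is_missing_token(cell: str) -> bool:
    return cell.strip().lower() in MISSING_TOKENS


@dataclass(frozen=True)
class FeatureRecord:
    """One feature row: its position and its identifier values.

    ``tagged_standard_ids`` restricts to the identifier columns declared as
    one of the six standard vocabularies; those are the linker candidates.
    """

    row_index: int
    identifiers: dict[str, str]
    tagged_standard_ids: dict[str, str]  # vocabulary -> identifier value


@dataclass
class OmicsLayer:
    """One omics table: feature metadata columns plus a numeric sample matrix.

    Duplicate identifier values across rows are allowed and preserved; nested
    data (e.g. several phosphosites of one protein) depends on it.
    """

    name: str
    metadata: pd.DataFrame           # features x metadata columns, str dtype
    values: pd.DataFrame             # features x sample columns, float dtype
    standard_id_tags: dict[str, str] = field(default_factory=dict)  # column -> vocabulary

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.metadata.columns) < 1:
            raise ValidationError(f"layer {self.name!r}: at least one metadata column required")
        if len(self.values.columns) < 1:
            raise ValidationError(f"layer {self.name!r}: at least one data (sample) column required")
        headers = list(self.metadata.columns) + list(self.values.columns)
        if len(set(headers)) != len(headers):
            dupes = sorted({h for h in headers if headers.count(h) > 1})
            raise FormatError(f"layer {self.name!r}: duplicate column header(s) {dupes}")
        if len(self.metadata) != len(self.values):
            raise ValidationError(f"layer {self.name!r}: metadata/value row count mismatch")
        for col, vocab in self.standard_id_tags.items():
            if col not in self.metadata.columns:
                raise ValidationError(f"layer {self.name!r}: tagged column {col!r} not a metadata column")
            if vocab not in STANDARD_VOCABULARIES:
                raise ValidationError(
                    f"layer {self.name!r}: tag {vocab!r} not one of {sorted(STANDARD_VOCABULARIES)}"
                )

    @property
    def n_features(self) -> int:
        return len(self.values)

    @property
    def sample_columns(self) -> list[str]:
        return list(self.values.columns)

    @property
    def metadata_columns(self) -> list[str]:
        return list(self.metadata.columns)

    def feature_records(self) -> list[FeatureRecord]:
        records = []
        for i in range(self.n_features):
            idents = {c: self.metadata.iloc[i][c] for c in self.metadata.columns}
            tagged = {
                vocab: idents[col]
                for col, vocab in self.standard_id_tags.items()
                if not is_missing_token(str(idents[col]))
            }
            records.append(FeatureRecord(row_index=i, identifiers=idents, tagged_standard_ids=tagged))
        return records

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def feature_label(self, row: int) -> str:
        return str(self.metadata.iloc[row, 0])


@dataclass
class SampleTable:
    """Sample names plus phenotype attribute columns (numeric or string)."""

    sample_names: list[str]
    phenotypes: pd.DataFrame  # samples x phenotype columns

    def __post_init__(self) -> None:
        if len(set(self.sample_names)) != len(self.sample_names):
            dupes = sorted({s for s in self.sample_names if self.sample_names.count(s) > 1})
            raise ValidationError(f"duplicate sample name(s): {dupes}")
        if len(self.phenotypes.columns) == 0:
            raise FormatError("sample file has no phenotype columns (need at least 2 columns)")
        if len(self.phenotypes) != len(self.sample_names):
            raise ValidationError("phenotype row count does not match sample count")

    @property
    def phenotype_names(self) -> list[str]:
        return list(self.phenotypes.columns)

    def phenotype_values(self, name: str, sample_order: list[str] | None = None) -> np.ndarray:
        """Values of one phenotype, optionally reindexed to a layer's sample columns."""
        if name not in self.phenotypes.columns:
            raise ResolutionError(f"unknown phenotype {name!r}; known: {self.phenotype_names}")
        series = pd.Series(list(self.phenotypes[name]), index=self.sample_names)
        if sample_order is not None:
            missing = [s for s in sample_order if s not in series.index]
            if missing:
                raise ValidationError(f"sample(s) {missing} not present in sample table")
            series = series.reindex(sample_order)
        return series.to_numpy()

    def check_covers(self, layer: OmicsLayer) -> None:
        missing = [s for s in layer.sample_columns if s not in self.sample_names]
        if missing:
            raise ValidationError(
                f"layer {layer.name!r} sample column(s) {missing} absent from sample table"
            )


@dataclass(frozen=True)
class NetworkEdge:
    id_a: str
    id_b: str
    color: str | None = None
    descriptor: str | None = None


@dataclass
class NetworkSpec:
    """A user-supplied cross-layer relationship file.

    ``column_a``/``column_b`` come from the file's header line and must match
    identifier columns of the two layers when the network is applied.
    """

    column_a: str
    column_b: str
    edges: list[NetworkEdge]
    layer_a: str | None = None
    layer_b: str | None = None


@dataclass(frozen=True)
class PathwayRow:
    group_name: str
    data_filename: str
    identifier_name: str
    identifier_value: str


@dataclass
class PathwayFileSpec:
    """Parsed pathway file: rows defining user functional groups.

    Group order is order of first appearance. Resolution against loaded
    layers happens later (see :mod:`omiclink.knowledge`).
    """

    rows: list[PathwayRow]

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.group_name not in seen:
                seen.append(r.group_name)
        return seen


# ---------------------------------------------------------------------------
# readers

def read_omics_layer(
    path: str,
    metadata_columns: list[str],
    standard_id_tags: dict[str, str] | None = None,
    delimiter: str | None = None,
    name: str | None = None,
) -> OmicsLayer:
    """Parse an omics data file into an :class:`OmicsLayer`.

    ``metadata_columns`` declares which header names are identifiers; every
    other column is a sample measurement column and must parse as numeric
    (missing tokens excepted).
    """
    _, rows = _read_rows(path, delimiter)
    header = [h.strip() for h in rows[0]]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate column header(s) {dupes}")
    missing_meta = [c for c in metadata_columns if c not in header]
    if missing_meta:
        raise FormatError(f"{path}: declared metadata column(s) {missing_meta} not in header {header}")
    data_cols = [h for h in header if h not in metadata_columns]
    if not data_cols:
        raise FormatError(f"{path}: no data (sample) columns remain after metadata declaration")

    meta_idx = [header.index(c) for c in metadata_columns]
    data_idx = [header.index(c) for c in data_cols]

    meta_rows: list[list[str]] = []
    value_rows: list[list[float]] = []
    for rnum, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}: line {rnum} has {len(row)} fields, expected {len(header)}")
        meta_rows.append([row[i].strip() for i in meta_idx])
        vals = []
        for i in data_idx:
            cell = row[i].strip()
            if is_missing_token(cell):
                vals.append(math.nan)
            else:
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} at line {rnum}, column {header[i]!r}"
                    ) from None
        value_rows.append(vals)

    metadata = pd.DataFrame(meta_rows, columns=metadata_columns, dtype=str)
    values = pd.DataFrame(value_rows, columns=data_cols, dtype=float)
    import os

    layer_name = name if name is not None else os.path.basename(path)
    return OmicsLayer(
        name=layer_name,
        metadata=metadata,
        values=values,
        standard_id_tags=dict(standard_id_tags or {}),
    )


def read_sample_table(path: str, delimiter: str | None = None) -> SampleTable:
    """Parse a sample-information file: first column sample names, rest phenotypes."""
    _, rows = _read_rows(path, delimiter)
    header = [h.strip() for h in rows[0]]
    if len(header) < 2:
        raise FormatError(f"{path}: sample file needs at least 2 columns (names + 1 phenotype)")
    names: list[str] = []
    pheno_rows: list[list[str]] = []
    for rnum, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}: line {rnum} has {len(row)} fields, expected {len(header)}")
        names.append(row[0].strip())
        pheno_rows.append([c.strip() for c in row[1:]])
    phen = pd.DataFrame(pheno_rows, columns=header[1:])
    # phenotype columns that parse fully numeric become numeric vectors
    for col in phen.columns:
        converted = pd.to_numeric(phen[col].replace({t: np.nan for t in ("", "NA", "NaN")}), errors="coerce")
        non_missing = phen[col].map(lambda c: not is_missing_token(str(c)))
        if converted[non_missing].notna().all():
            phen[col] = converted
    return SampleTable(sample_names=names, phenotypes=phen)


def read_network_file(path: str, delimiter: str | None = None) -> NetworkSpec:
    """Parse a 2-4 column network file; color/descriptor absent stays ``None``."""
    try:
        _, rows = _read_rows(path, delimiter)
    except FormatError as exc:
        if "delimiter" in str(exc):
            raise FormatError(f"{path}: network file needs at least 2 columns") from None
        raise
    header = [h.strip() for h in rows[0]]
    if len(header) < 2:
        raise FormatError(f"{path}: network file needs at least 2 columns, found {len(header)}")
    edges: list[NetworkEdge] = []
    for rnum, row in enumerate(rows[1:], start=2):
        cells = [c.strip() for c in row]
        if len(cells) < 2:
            raise FormatError(f"{path}: line {rnum} has fewer than 2 fields")
        color = cells[2] if len(cells) >= 3 and cells[2] != "" else None
        descriptor = cells[3] if len(cells) >= 4 and cells[3] != "" else None
        edges.append(NetworkEdge(cells[0], cells[1], color, descriptor))
    return NetworkSpec(column_a=header[0], column_b=header[1], edges=edges)


def read_pathway_file(path: str, delimiter: str | None = None) -> PathwayFileSpec:
    """Parse a pathway file (exactly 4 columns)."""
    _, rows = _read_rows(path, delimiter)
    header = [h.strip() for h in rows[0]]
    if len(header) != 4:
        raise FormatError(f"{path}: pathway file must have exactly 4 columns, found {len(header)}")
    out: list[PathwayRow] = []
    for rnum, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise FormatError(f"{path}: line {rnum} has {len(row)} fields, expected 4")
        out.append(PathwayRow(*(c.strip() for c in row)))
    return PathwayFileSpec(rows=out)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers; used by the synthetic module)

def _fmt_value(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return repr(float(v))


def write_omics_layer(layer: OmicsLayer, path: str, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(list(layer.metadata.columns) + list(layer.values.columns))
        for i in range(layer.n_features):
            meta = [str(layer.metadata.iloc[i][c]) for c in layer.metadata.columns]
            vals = [_fmt_value(layer.values.iloc[i][c]) for c in layer.values.columns]
            w.writerow(meta + vals)


def write_sample_table(table: SampleTable, path: str, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["sample"] + table.phenotype_names)
        for i, name in enumerate(table.sample_names):
            row = [name]
            for col in table.phenotype_names:
                v = table.phenotypes.iloc[i][col]
                if isinstance(v, (float, int)) and not isinstance(v, bool):
                    row.append("NA" if (isinstance(v, float) and math.isnan(v)) else repr(float(v)))
                else:
                    row.append(str(v))
            w.writerow(row)


def write_network_file(spec: NetworkSpec, path: str, delimiter: str = "\t") -> None:
    has_color = any(e.color is not None for e in spec.edges)
    has_desc = any(e.descriptor is not None for e in spec.edges)
    ncol = 4 if has_desc else (3 if has_color else 2)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        header = [spec.column_a, spec.column_b, "color", "descriptor"][:ncol]
        w.writerow(header)
        for e in spec.edges:
            row = [e.id_a, e.id_b, e.color or "", e.descriptor or ""][:ncol]
            w.writerow(row)


def write_pathway_file(spec: PathwayFileSpec, path: str, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["group_name", "data_filename", "identifier_name", "identifier_value"])
        for r in spec.rows:
            w.writerow([r.group_name, r.data_filename, r.identifier_name, r.identifier_value])
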
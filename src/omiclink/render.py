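"""Connected multi-heatmap scene composition and SVG/PDF export.

A scene is a pure function of the workspace: panel geometry, cell colors,
group tag tracks, phenotype header tracks, and cross-panel connection lines
are all computed deterministically, so identical workspaces export
byte-identical SVG. Panels are laid out left-to-right (samples as columns,
the default orientation) or top-to-bottom (samples as rows); each panel has
its own color scale because absolute values are not comparable across omics
platforms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import OmiclinkError, ValidationError

# diverging blue-white-red default; missing values render light gray
DEFAULT_PALETTE = ((33, 102, 172), (255, 255, 255), (178, 24, 43))
MISSING_COLOR = (224, 224, 224)
NEUTRAL_LINE_COLOR = "#9e9e9e"

GROUP_COLOR_CYCLE = (
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
    "#e6ab02", "#a6761d", "#666666",
)
PHENO_COLOR_CYCLE = (
    "#8dd3c7", "#bebada", "#fb8072", "#80b1d3", "#fdb462",
    "#b3de69", "#fccde5", "#d9d9d9",
)


def _hex(rgb) -> str:
    return "#{:02x}{:02x}{:02x}".format(*(int(round(c)) for c in rgb))


@dataclass(frozen=True)
class ColorScale:
    vmin: float
    vmax: float
    palette: tuple = DEFAULT_PALETTE
    missing_color: tuple = MISSING_COLOR

    def __post_init__(self) -> None:
        if not (math.isfinite(self.vmin) and math.isfinite(self.vmax)):
            raise ValidationError("color scale limits must be finite")
        if not self.vmin < self.vmax:
            raise ValidationError(f"degenerate color scale: min {self.vmin} >= max {self.vmax}")
        if len(self.palette) < 2:
            raise ValidationError("palette needs at least 2 stops")


def map_color(value: float, scale: ColorScale) -> str:
    """Linear interpolation into the palette; out-of-range clamps; missing is gray."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return _hex(scale.missing_color)
    t = (float(value) - scale.vmin) / (scale.vmax - scale.vmin)
    t = min(1.0, max(0.0, t))
    stops = scale.palette
    seg = t * (len(stops) - 1)
    lo = min(int(seg), len(stops) - 2)
    frac = seg - lo
    rgb = tuple(stops[lo][k] + frac * (stops[lo + 1][k] - stops[lo][k]) for k in range(3))
    return _hex(rgb)


def default_scale(values: np.ndarray) -> ColorScale:
    """Symmetric-about-zero scale at the 1st/99th percentile of displayed values."""
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValidationError("cannot build a color scale from all-missing values")
    lo, hi = np.percentile(finite, [1, 99])
    bound = max(abs(lo), abs(hi))
    if bound == 0.0:
        bound = 1.0
    return ColorScale(-bound, bound)


@dataclass
class TagTrack:
    group_id: str
    color: str
    rows: frozenset  # original row ids carrying this tag


@dataclass
class HeatmapPanel:
    layer: str
    rows: list                 # original row ids, display order
    row_labels: list
    sample_labels: list
    cell_colors: list          # [row][col] hex strings, display order
    scale: ColorScale
    tag_tracks: list = field(default_factory=list)
    # geometry (canonical orientation: samples as columns), filled by build
    x_heat: float = 0.0
    y_heat: float = 0.0
    heat_w: float = 0.0
    heat_h: float = 0.0
    x_right: float = 0.0       # right edge including tag tracks

    def row_center_y(self, row_id, cell_h: float) -> float:
        pos = self.rows.index(row_id)
        return self.y_heat + pos * cell_h + cell_h / 2.0


@dataclass
class Connection:
    panel_a: int
    panel_b: int
    x1: float
    y1: float
    x2: float
    y2: float
    color: str
    descriptor: str | None = None


@dataclass
class HeatmapScene:
    panels: list
    connections: list
    pheno_tracks: list         # (name, [hex per sample])
    width: float
    height: float
    orientation: str           # "samples-as-columns" | "samples-as-rows"
    cell_w: float
    cell_h: float


MARGIN = 6.0
PANEL_GAP = 70.0
LABEL_W = 80.0
TAG_W = 9.0
TAG_GAP = 2.0
PHENO_H = 10.0
TITLE_H = 16.0


def build_scene(
    layer_panels: list,
    link_edges: dict | None = None,
    pheno_tracks: list | None = None,
    orientation: str = "samples-as-columns",
    cell_w: float = 14.0,
    cell_h: float = 14.0,
) -> HeatmapScene:
    """Lay out panels and connection lines.

    ``layer_panels`` is an ordered list of dicts with keys ``layer``,
    ``rows`` (display-ordered original row ids), ``row_labels``,
    ``sample_labels``, ``values`` (display-ordered matrix), optional
    ``scale`` and ``tag_tracks``. ``link_edges`` maps adjacent panel index
    pairs (i, i+1) to iterables of (row_a, row_b, color, descriptor).
    """
    if orientation not in ("samples-as-columns", "samples-as-rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if not layer_panels or any(len(p["rows"]) == 0 for p in layer_panels):
        raise ValidationError("selection is empty: nothing to render")
    panels: list = []
    n_pheno = len(pheno_tracks or [])
    y_top = MARGIN + TITLE_H + n_pheno * PHENO_H + (4.0 if n_pheno else 0.0)
    x = MARGIN
    for spec in layer_panels:
        values = np.asarray(spec["values"], dtype=float)
        scale = spec.get("scale") or default_scale(values)
        colors = [[map_color(values[r, c], scale) for c in range(values.shape[1])]
                  for r in range(values.shape[0])]
        panel = HeatmapPanel(
            layer=spec["layer"],
            rows=list(spec["rows"]),
            row_labels=list(spec["row_labels"]),
            sample_labels=list(spec["sample_labels"]),
            cell_colors=colors,
            scale=scale,
            tag_tracks=list(spec.get("tag_tracks", ())),
        )
        panel.x_heat = x + LABEL_W
        panel.y_heat = y_top
        panel.heat_w = values.shape[1] * cell_w
        panel.heat_h = values.shape[0] * cell_h
        ntracks = len(panel.tag_tracks)
        panel.x_right = panel.x_heat + panel.heat_w + (TAG_GAP + ntracks * (TAG_W + TAG_GAP) if ntracks else 0.0)
        panels.append(panel)
        x = panel.x_right + PANEL_GAP
    width = x - PANEL_GAP + MARGIN
    height = y_top + max(p.heat_h for p in panels) + MARGIN

    connections: list = []
    for (i, j), edges in sorted((link_edges or {}).items()):
        if j != i + 1:
            raise ValidationError("connections may only join adjacent panels")
        pa, pb = panels[i], panels[j]
        shown_a, shown_b = set(pa.rows), set(pb.rows)
        for row_a, row_b, color, descriptor in sorted(
            edges, key=lambda e: (e[0], e[1], e[2] or "", e[3] or "")
        ):
            if row_a in shown_a and row_b in shown_b:
                connections.append(Connection(
                    panel_a=i, panel_b=j,
                    x1=pa.x_right, y1=pa.row_center_y(row_a, cell_h),
                    x2=pb.x_heat, y2=pb.row_center_y(row_b, cell_h),
                    color=color or NEUTRAL_LINE_COLOR, descriptor=descriptor,
                ))
    return HeatmapScene(
        panels=panels, connections=connections, pheno_tracks=list(pheno_tracks or ()),
        width=width, height=height, orientation=orientation,
        cell_w=cell_w, cell_h=cell_h,
    )


def phenotype_track_colors(values) -> list:
    """Categorical color per sample (levels colored in first-appearance order)."""
    assigned: dict = {}
    out = []
    for v in values:
        key = str(v)
        if key not in assigned:
            assigned[key] = PHENO_COLOR_CYCLE[len(assigned) % len(PHENO_COLOR_CYCLE)]
        out.append(assigned[key])
    return out


# ---------------------------------------------------------------------------
# SVG


def _f(x: float) -> str:
    return f"{x:.2f}"


def _xy(x: float, y: float, flip: bool) -> tuple:
    return (y, x) if flip else (x, y)


def _rect(eid: str, x: float, y: float, w: float, h: float, fill: str, flip: bool) -> str:
    x, y = _xy(x, y, flip)
    if flip:
        w, h = h, w
    return (f'<rect id="{eid}" x="{_f(x)}" y="{_f(y)}" width="{_f(w)}" '
            f'height="{_f(h)}" fill="{fill}"/>')


def _text(eid: str, x: float, y: float, s: str, size: float, flip: bool, anchor: str = "start") -> str:
    x, y = _xy(x, y, flip)
    safe = (s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))
    return (f'<text id="{eid}" x="{_f(x)}" y="{_f(y)}" font-size="{_f(size)}" '
            f'font-family="Helvetica" text-anchor="{anchor}">{safe}</text>')


def render_svg(scene: HeatmapScene) -> str:
    """Serialize a scene to SVG 1.1 with stable element identifiers."""
    flip = scene.orientation == "samples-as-rows"
    w, h = (scene.height, scene.width) if flip else (scene.width, scene.height)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(w)}" height="{_f(h)}" viewBox="0 0 {_f(w)} {_f(h)}">',
        f'<rect id="background" x="0" y="0" width="{_f(w)}" height="{_f(h)}" fill="#ffffff"/>',
    ]
    for ti, (name, colors) in enumerate(scene.pheno_tracks):
        parts.append(f'<g id="pheno-{ti}">')
        y0 = MARGIN + TITLE_H + ti * PHENO_H
        parts.append(_text(f"pheno-{ti}-label", MARGIN, y0 + PHENO_H - 2, name, 8.0, flip))
        for pi, panel in enumerate(scene.panels):
            for c, color in enumerate(colors[: len(panel.sample_labels)]):
                parts.append(_rect(f"pheno-{ti}-p{pi}-c{c}", panel.x_heat + c * scene.cell_w,
                                   y0, scene.cell_w, PHENO_H - 1, color, flip))
        parts.append("</g>")
    for pi, panel in enumerate(scene.panels):
        parts.append(f'<g id="panel-{pi}">')
        parts.append(_text(f"p{pi}-title", panel.x_heat, MARGIN + 10, panel.layer, 10.0, flip))
        for r, label in enumerate(panel.row_labels):
            parts.append(_text(f"p{pi}-rowlabel-{r}", panel.x_heat - LABEL_W,
                               panel.y_heat + r * scene.cell_h + scene.cell_h * 0.75,
                               str(label)[:14], 8.0, flip))
        for r, rowcolors in enumerate(panel.cell_colors):
            for c, color in enumerate(rowcolors):
                parts.append(_rect(f"p{pi}-cell-{r}-{c}",
                                   panel.x_heat + c * scene.cell_w,
                                   panel.y_heat + r * scene.cell_h,
                                   scene.cell_w - 0.5, scene.cell_h - 0.5, color, flip))
        x_track = panel.x_heat + panel.heat_w + TAG_GAP
        for ti, track in enumerate(panel.tag_tracks):
            for r, row_id in enumerate(panel.rows):
                if row_id in track.rows:
                    parts.append(_rect(f"p{pi}-tag-{ti}-{r}", x_track,
                                       panel.y_heat + r * scene.cell_h,
                                       TAG_W, scene.cell_h - 0.5, track.color, flip))
            x_track += TAG_W + TAG_GAP
        parts.append("</g>")
    parts.append('<g id="connections">')
    for k, conn in enumerate(scene.connections):
        x1, y1 = _xy(conn.x1, conn.y1, flip)
        x2, y2 = _xy(conn.x2, conn.y2, flip)
        desc = f' data-descriptor="{conn.descriptor}"' if conn.descriptor else ""
        parts.append(f'<line id="conn-{k}" x1="{_f(x1)}" y1="{_f(y1)}" x2="{_f(x2)}" '
                     f'y2="{_f(y2)}" stroke="{conn.color}" stroke-width="1"{desc}/>')
    parts.append("</g>")
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def export_svg(scene: HeatmapScene, path: str) -> None:
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(render_svg(scene))
    except OSError as exc:
        raise OmiclinkError(f"cannot write SVG to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# PDF (same geometry via matplotlib's vector backend)


def export_pdf(scene: HeatmapScene, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.lines import Line2D
    from matplotlib.patches import Rectangle

    flip = scene.orientation == "samples-as-rows"
    w, h = (scene.height, scene.width) if flip else (scene.width, scene.height)
    fig = plt.figure(figsize=(w / 72.0, h / 72.0))
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)
    ax.axis("off")

    def rect(x, y, rw, rh, color):
        if flip:
            x, y, rw, rh = y, x, rh, rw
        ax.add_patch(Rectangle((x, y), rw, rh, facecolor=color, edgecolor="none"))

    for ti, (name, colors) in enumerate(scene.pheno_tracks):
        y0 = MARGIN + TITLE_H + ti * PHENO_H
        for pi, panel in enumerate(scene.panels):
            for c, color in enumerate(colors[: len(panel.sample_labels)]):
                rect(panel.x_heat + c * scene.cell_w, y0, scene.cell_w, PHENO_H - 1, color)
    for panel in scene.panels:
        for r, rowcolors in enumerate(panel.cell_colors):
            for c, color in enumerate(rowcolors):
                rect(panel.x_heat + c * scene.cell_w, panel.y_heat + r * scene.cell_h,
                     scene.cell_w - 0.5, scene.cell_h - 0.5, color)
        x_track = panel.x_heat + panel.heat_w + TAG_GAP
        for track in panel.tag_tracks:
            for r, row_id in enumerate(panel.rows):
                if row_id in track.rows:
                    rect(x_track, panel.y_heat + r * scene.cell_h, TAG_W, scene.cell_h - 0.5,
                         track.color)
            x_track += TAG_W + TAG_GAP
    for conn in scene.connections:
        x1, y1 = _xy(conn.x1, conn.y1, flip)
        x2, y2 = _xy(conn.x2, conn.y2, flip)
        ax.add_line(Line2D([x1, x2], [y1, y2], color=conn.color, linewidth=1))
    try:
        fig.savefig(path, format="pdf")
    except OSError as exc:
        raise OmiclinkError(f"cannot write PDF to {path}: {exc}") from exc
    finally:
        plt.close(fig)


def scene_to_json(scene: HeatmapScene) -> str:
    """Machine-readable scene dump (geometry + colors) for testing and audit."""
    doc = {
        "orientation": scene.orientation,
        "width": scene.width,
        "height": scene.height,
        "cell": [scene.cell_w, scene.cell_h],
        "panels": [
            {
                "layer": p.layer,
                "rows": list(p.rows),
                "row_labels": list(p.row_labels),
                "sample_labels": list(p.sample_labels),
                "scale": [p.scale.vmin, p.scale.vmax],
                "heat": [p.x_heat, p.y_heat, p.heat_w, p.heat_h],
                "cell_colors": p.cell_colors,
                "tag_tracks": [
                    {"group_id": t.group_id, "color": t.color, "rows": sorted(t.rows)}
                    for t in p.tag_tracks
                ],
            }
            for p in scene.panels
        ],
        "connections": [
            {"panels": [c.panel_a, c.panel_b], "from": [c.x1, c.y1], "to": [c.x2, c.y2],
             "color": c.color, "descriptor": c.descriptor}
            for c in scene.connections
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)
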
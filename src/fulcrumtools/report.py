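"""Project summary report: counts, interactive map, per-species box plots.

The report is a single self-contained HTML file (map tiles are the only
external reference, fetched from the standard OpenStreetMap tile servers
with attribution). Map pins are colored by the isolation outcome — red when
target organisms were present on the sample, blue when absent, orange when
only tracks were seen — with a popup carrying the C-label, best-photo
thumbnail, and species found. Environmental parameters (ambient and
substrate temperature, ambient humidity, elevation) are shown as Tukey box
plots grouped by identified species.
"""

from __future__ import annotations

import base64
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from string import Template

import numpy as np
import pandas as pd

from .errors import EmptyStatsError
from .project_io import ProjectLayout

PIN_COLORS = {
    "present": "red",
    "absent": "blue",
    "tracks_only": "orange",
    "unknown": "gray",
}

ENV_PARAMETERS = {
    "ambient_temperature_c": "Ambient temperature (°C)",
    "substrate_temperature_c": "Substrate temperature (°C)",
    "ambient_humidity": "Ambient humidity (%)",
    "altitude": "Elevation (m)",
}


@dataclass
class CollectionSummary:
    """Headline counts for one sampling project."""

    n_collections: int
    n_with_photos: int
    n_isolations: int
    n_s_labels: int
    species_counts: dict[str, int]
    n_ungenotyped: int
    date_range: tuple[str | None, str | None]
    flag_counts: dict[str, int] = field(default_factory=dict)


def summarize(final: pd.DataFrame) -> CollectionSummary:
    """Compute project-level counts over distinct keys."""
    if final.empty:
        return CollectionSummary(0, 0, 0, 0, {}, 0, (None, None), {})
    coll = final.drop_duplicates("collection_fulcrum_id")
    coll = coll[coll["collection_fulcrum_id"].notna()]
    n_collections = int(len(coll))
    n_with_photos = int(coll["best_photo_id"].notna().sum())
    n_isolations = int(final["isolation_fulcrum_id"].dropna().nunique())
    s_rows = final[final["s_label"].notna()].drop_duplicates("s_label")
    n_s_labels = int(len(s_rows))
    if "species_id" in s_rows.columns:
        species_counts = (
            s_rows["species_id"].dropna().value_counts().sort_index().astype(int).to_dict()
        )
        n_ungenotyped = int(s_rows["species_id"].isna().sum())
    else:
        species_counts, n_ungenotyped = {}, n_s_labels
    dates = coll["collection_date"].dropna()
    date_range = (dates.min(), dates.max()) if len(dates) else (None, None)
    flag_counts = {
        c: int(final[c].sum())
        for c in sorted(final.columns)
        if c.startswith("flag_") and final[c].any()
    }
    return CollectionSummary(
        n_collections=n_collections,
        n_with_photos=n_with_photos,
        n_isolations=n_isolations,
        n_s_labels=n_s_labels,
        species_counts=species_counts,
        n_ungenotyped=n_ungenotyped,
        date_range=date_range,
        flag_counts=flag_counts,
    )


def tukey_boxplot_stats(values) -> dict:
    """Five-number box-plot statistics using Tukey's hinge convention.

    Hinges are medians of the lower and upper halves of the sorted data,
    with the overall median included in both halves when n is odd. Whiskers
    extend to the most extreme points within 1.5×IQR of the hinges; points
    beyond are returned as outliers.
    """
    x = np.asarray([v for v in values if v is not None and not pd.isna(v)], dtype=float)
    if x.size == 0:
        raise EmptyStatsError("no non-missing values")
    x = np.sort(x)
    n = x.size
    median = float(np.median(x))
    half = (n + 1) // 2  # include the median in both halves when n is odd
    lower, upper = x[:half], x[n - half:]
    q1, q3 = float(np.median(lower)), float(np.median(upper))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "median": median,
        "q1": q1,
        "q3": q3,
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": [float(v) for v in x[(x < lo_fence) | (x > hi_fence)]],
    }


def _boxplot_svg(final: pd.DataFrame) -> str | None:
    """Per-species Tukey box plots of the four environmental parameters.

    Returns an SVG string, or None when no genotyped specimens exist.
    """
    if "species_id" not in final.columns or final["species_id"].dropna().empty:
        return None
    import matplotlib

    matplotlib.rcParams["svg.hashsalt"] = "fulcrumtools"
    from matplotlib.backends.backend_svg import FigureCanvasSVG
    from matplotlib.figure import Figure

    species = sorted(final["species_id"].dropna().unique())
    cmap = matplotlib.colormaps["tab10"]
    fig = Figure(figsize=(10, 8))
    FigureCanvasSVG(fig)
    axes = fig.subplots(2, 2).ravel()
    for ax, (col, label) in zip(axes, ENV_PARAMETERS.items()):
        boxes, positions, colors = [], [], []
        for i, sp in enumerate(species):
            vals = final.loc[final["species_id"] == sp, col].dropna()
            if vals.empty:
                continue
            st = tukey_boxplot_stats(vals)
            boxes.append(
                {
                    "med": st["median"],
                    "q1": st["q1"],
                    "q3": st["q3"],
                    "whislo": st["whisker_lo"],
                    "whishi": st["whisker_hi"],
                    "fliers": st["outliers"],
                    "label": sp,
                }
            )
            positions.append(len(boxes))
            colors.append(cmap(i % 10))
        if boxes:
            artists = ax.bxp(boxes, positions=positions, patch_artist=True)
            for patch, color in zip(artists["boxes"], colors):
                patch.set_facecolor(color)
        ax.set_title(label, fontsize=10)
        ax.tick_params(axis="x", rotation=45, labelsize=8)
    fig.tight_layout()
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    return buf.getvalue()


_TEMPLATE = Template(
    """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8"/>
<title>Collection report — $project</title>
<link rel="stylesheet" href="https://unpkg.com/leaflet@1.9.4/dist/leaflet.css"/>
<script src="https://unpkg.com/leaflet@1.9.4/dist/leaflet.js"></script>
<style>
 body { font-family: sans-serif; margin: 2em; }
 table { border-collapse: collapse; margin: 1em 0; }
 td, th { border: 1px solid #999; padding: 4px 10px; text-align: left; }
 #map { height: 480px; }
</style>
</head>
<body>
<h1>Collection report — $project</h1>
<p>$metadata</p>

<h2>Summary</h2>
$summary_table

<h2>Species</h2>
$species_table

<h2>Anomaly flags</h2>
$flag_table

<h2>Collection map</h2>
$map_section

<h2>Environmental parameters by species</h2>
$boxplot_section

</body>
</html>
"""
)

_MAP_SECTION = Template(
    """<div id="map"></div>
<script type="application/json" id="pin-data">$pins_json</script>
<script>
var pins = JSON.parse(document.getElementById("pin-data").textContent);
var map = L.map("map");
L.tileLayer("https://tile.openstreetmap.org/{z}/{x}/{y}.png", {
  attribution: "&copy; OpenStreetMap contributors"
}).addTo(map);
var group = L.featureGroup();
pins.forEach(function (p) {
  var m = L.circleMarker([p.lat, p.lon], {color: p.color, radius: 7, fillOpacity: 0.8});
  var html = "<b>" + p.c_label + "</b>";
  if (p.species.length) { html += "<br/>" + p.species.join(", "); }
  if (p.thumbnail) { html += '<br/><img src="' + p.thumbnail + '" width="200"/>'; }
  m.bindPopup(html);
  group.addLayer(m);
});
group.addTo(map);
if (pins.length) { map.fitBounds(group.getBounds().pad(0.2)); } else { map.setView([0, 0], 2); }
</script>
"""
)


def _html_table(rows: list[tuple], header: tuple) -> str:
    body = "\n".join(
        "<tr>" + "".join(f"<td>{v}</td>" for v in row) + "</tr>" for row in rows
    )
    head = "<tr>" + "".join(f"<th>{h}</th>" for h in header) + "</tr>"
    return f"<table>\n{head}\n{body}\n</table>"


def _build_pins(final: pd.DataFrame, layout: ProjectLayout) -> list[dict]:
    pins = []
    located = final[final["location_source"] != "none"]
    for cid, grp in located.groupby("collection_fulcrum_id", sort=True):
        row = grp.iloc[0]
        species = sorted(
            grp["species_id"].dropna().unique()
        ) if "species_id" in grp.columns else []
        thumb = None
        if "thumbnail_path" in grp.columns and pd.notna(row.get("thumbnail_path")):
            try:
                thumb = str(
                    Path(row["thumbnail_path"]).resolve().relative_to(
                        layout.reports_dir.resolve().parent
                    )
                )
                thumb = "../" + thumb
            except ValueError:
                thumb = str(row["thumbnail_path"])
        pins.append(
            {
                "c_label": None if pd.isna(row["c_label"]) else str(row["c_label"]),
                "lat": float(row["latitude"]),
                "lon": float(row["longitude"]),
                "color": PIN_COLORS.get(str(row["worms_on_sample"]), "gray"),
                "species": [str(s) for s in species],
                "thumbnail": thumb,
            }
        )
    return pins


def generate_report(
    final: pd.DataFrame,
    layout: ProjectLayout,
    deterministic: bool = False,
    project: str | None = None,
) -> Path:
    """Render the HTML collection report into ``reports/``.

    Also writes an editable copy of the page template into ``scripts/`` so
    users can customize future reports. With ``deterministic=True`` all
    timestamps come from the data, making output byte-identical across runs
    on the same table.
    """
    layout.reports_dir.mkdir(parents=True, exist_ok=True)
    layout.scripts_dir.mkdir(parents=True, exist_ok=True)

    summary = summarize(final)
    project = project or "sampling project"

    collectors = sorted(final.get("collection_by", pd.Series(dtype=object)).dropna().unique())
    isolators = sorted(final.get("isolation_by", pd.Series(dtype=object)).dropna().unique())
    meta_bits = []
    if summary.date_range[0]:
        meta_bits.append(
            f"Collections from {summary.date_range[0]} to {summary.date_range[1]}."
        )
    if collectors:
        meta_bits.append("Collected by: " + ", ".join(map(str, collectors)) + ".")
    if isolators:
        meta_bits.append("Isolations by: " + ", ".join(map(str, isolators)) + ".")
    if not deterministic:
        import datetime

        meta_bits.append(
            "Report generated " + datetime.datetime.now().isoformat(timespec="seconds") + "."
        )

    summary_table = _html_table(
        [
            ("Collections", summary.n_collections),
            ("Collections with photos", summary.n_with_photos),
            ("Isolations", summary.n_isolations),
            ("S-labels", summary.n_s_labels),
            ("Un-genotyped S-labels", summary.n_ungenotyped),
        ],
        ("Quantity", "Count"),
    )
    species_table = (
        _html_table(sorted(summary.species_counts.items()), ("Species", "S-labels"))
        if summary.species_counts
        else "<p>No species identifications available.</p>"
    )
    flag_table = (
        _html_table(sorted(summary.flag_counts.items()), ("Flag", "Count"))
        if summary.flag_counts
        else "<p>No anomaly flags raised.</p>"
    )

    pins = _build_pins(final, layout)
    if pins:
        map_section = _MAP_SECTION.substitute(
            pins_json=json.dumps(pins, sort_keys=True)
        )
    else:
        map_section = (
            '<p class="map-placeholder">No collections with resolvable locations; '
            "map omitted.</p>"
            '<script type="application/json" id="pin-data">[]</script>'
        )

    svg = _boxplot_svg(final)
    boxplot_section = svg if svg else "<p>No species data available for box plots.</p>"

    html = _TEMPLATE.substitute(
        project=project,
        metadata=" ".join(meta_bits),
        summary_table=summary_table,
        species_table=species_table,
        flag_table=flag_table,
        map_section=map_section,
        boxplot_section=boxplot_section,
    )
    out = layout.reports_dir / "sample_report.html"
    out.write_text(html, encoding="utf-8")

    template_copy = layout.scripts_dir / "report_template.html"
    template_copy.write_text(_TEMPLATE.template, encoding="utf-8")
    return out
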
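"""Reading and writing the pipeline's file formats.

Tracklogs come in as CSV (``time,x,y,elev,group,follow_id`` with projected
meters) or GPX 1.1 track files; results go out as plain CSV and GeoJSON
points.  Lon/lat inputs must be projected to meters upstream — the
analysis works in a projected CRS throughout.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import pandas as pd
import yaml

_GPX_NS = {"gpx": "http://www.topografix.com/GPX/1/1"}


def read_fixes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["time"])
    need = ["time", "x", "y", "elev", "group", "follow_id"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_gpx(path, group: str, follow_id: str | None = None) -> pd.DataFrame:
    """Track points from a GPX 1.1 file as a fix table.

    Coordinates are taken from the ``lat``/``lon`` attributes *as given*
    — callers supplying true lon/lat must project to meters afterward.
    One follow per track segment unless ``follow_id`` is forced.
    """
    root = ET.parse(str(path)).getroot()
    rows = []
    for ti, trk in enumerate(root.findall("gpx:trk", _GPX_NS)):
        for si, seg in enumerate(trk.findall("gpx:trkseg", _GPX_NS)):
            fid = follow_id or f"{Path(path).stem}_{ti}_{si}"
            for pt in seg.findall("gpx:trkpt", _GPX_NS):
                ele = pt.find("gpx:ele", _GPX_NS)
                tm = pt.find("gpx:time", _GPX_NS)
                rows.append({
                    "time": pd.Timestamp(tm.text) if tm is not None else pd.NaT,
                    "x": float(pt.get("lon")), "y": float(pt.get("lat")),
                    "elev": float(ele.text) if ele is not None else float("nan"),
                    "group": group, "follow_id": fid,
                })
    return pd.DataFrame(rows)


def write_points_geojson(df: pd.DataFrame, path, x="x", y="y") -> None:
    feats = []
    for _, row in df.iterrows():
        props = {k: (v.item() if hasattr(v, "item") else v)
                 for k, v in row.items() if k not in (x, y)}
        feats.append({"type": "Feature",
                      "geometry": {"type": "Point",
                                   "coordinates": [float(row[x]), float(row[y])]},
                      "properties": props})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}, default=str))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def result_table(result) -> pd.DataFrame:
    """Fixed-effects table in the conventional Estimate (SE) layout."""
    p = result.params.copy()
    p["estimate_se"] = [f"{e:.3f} ({s:.3f})"
                        for e, s in zip(p["estimate"], p["se"])]
    return p[["estimate", "se", "estimate_se", "z", "p_wald", "ci_lo", "ci_hi"]]
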
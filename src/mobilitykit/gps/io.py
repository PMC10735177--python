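"""Readers and writers for GPS track files.

Two CSV dialects are supported: the Qstarz logger export
(``INDEX, UTC DATE, UTC TIME, LATITUDE, LONGITUDE, SPEED`` with date
``yyyy/mm/dd`` and time ``HH:MM:SS``) and a generic dialect whose column
names are supplied as a mapping (e.g. from a YAML config).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .types import GpsTrack, Segment

QSTARZ_COLUMNS = {"index": "INDEX", "date": "UTC DATE", "time": "UTC TIME",
                  "lat": "LATITUDE", "lon": "LONGITUDE", "speed": "SPEED"}


def read_qstarz_csv(path, device: str = "qstarz") -> GpsTrack:
    df = pd.read_csv(path)
    df.columns = [c.strip().upper() for c in df.columns]
    ts = pd.to_datetime(df["UTC DATE"].astype(str).str.strip() + " "
                        + df["UTC TIME"].astype(str).str.strip(),
                        format="%Y/%m/%d %H:%M:%S")
    t = ts.astype("int64").to_numpy() / 1e9
    speed = df["SPEED"].to_numpy(dtype=float) if "SPEED" in df else None
    return GpsTrack(t, df["LATITUDE"].to_numpy(dtype=float),
                    df["LONGITUDE"].to_numpy(dtype=float), speed, device)


def read_generic_csv(path, columns: dict | None = None, device: str = "") -> GpsTrack:
    """Generic GPS CSV. ``columns`` maps the roles ``t`` (epoch seconds or
    ISO timestamps), ``lat``, ``lon`` and optionally ``speed`` to the file's
    column names; defaults to those same names."""
    columns = {**{"t": "t", "lat": "lat", "lon": "lon", "speed": "speed_kmh"},
               **(columns or {})}
    df = pd.read_csv(path)
    tcol = df[columns["t"]]
    if tcol.dtype == object:
        t = pd.to_datetime(tcol).astype("int64").to_numpy() / 1e9
    else:
        t = tcol.to_numpy(dtype=float)
    speed = None
    if columns.get("speed") in df:
        speed = df[columns["speed"]].to_numpy(dtype=float)
    return GpsTrack(t, df[columns["lat"]].to_numpy(dtype=float),
                    df[columns["lon"]].to_numpy(dtype=float), speed, device)


def write_qstarz_csv(track: GpsTrack, path) -> None:
    """The logger's export always carries a SPEED column; tracks without
    logged speeds get their derived point-to-point speeds."""
    from .cleaning import derived_speeds_kmh

    ts = pd.to_datetime((track.t * 1e9).astype("int64"))
    speed = track.speed_kmh if track.speed_kmh is not None else derived_speeds_kmh(track)
    pd.DataFrame({
        "INDEX": np.arange(1, len(track) + 1),
        "UTC DATE": ts.strftime("%Y/%m/%d"),
        "UTC TIME": ts.strftime("%H:%M:%S"),
        "LATITUDE": np.round(track.lat, 8),
        "LONGITUDE": np.round(track.lon, 8),
        "SPEED": np.round(speed, 3),
    }).to_csv(path, index=False)


def write_generic_csv(track: GpsTrack, path) -> None:
    track.to_frame().to_csv(path, index=False)


def segments_to_geojson(track: GpsTrack, segments: list[Segment], path=None) -> dict:
    """Segment-level GeoJSON (stops as points, moves as linestrings) for
    visual inspection in a GIS. Returns the dict; writes it when ``path``."""
    feats = []
    for seg in segments:
        if seg.kind == "stop":
            geom = {"type": "Point", "coordinates": [seg.centroid_lon, seg.centroid_lat]}
        else:
            coords = np.column_stack([track.lon[seg.i0:seg.i1 + 1],
                                      track.lat[seg.i0:seg.i1 + 1]]).tolist()
            geom = {"type": "LineString", "coordinates": coords}
        feats.append({"type": "Feature", "geometry": geom,
                      "properties": {"kind": seg.kind, "start_t": seg.start_t,
                                     "end_t": seg.end_t, "span_m": seg.span_m}})
    gj = {"type": "FeatureCollection", "features": feats}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(gj, fh)
    return gj
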
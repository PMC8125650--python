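"""Read, validate and write 1-Hz GPS walking-session traces.

The target device (a GlobalSat DG100-class logger) records, once per second,
a timestamp, WGS84 coordinates, GPS altitude and an instantaneous Doppler
speed.  Sessions are exported as GPX 1.1 track files in which the speed
travels as a per-point ``<speed>`` element inside ``<extensions>`` (the exact
namespace varies between export utilities, so any element whose local name is
``speed`` is accepted).  All speeds are held internally in km/h.

The canonical in-memory container is :class:`SpeedTrace`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per 1-s epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "SpeedTrace",
    "GpxParseError",
    "read_gpx",
    "write_gpx",
    "canonicalize",
    "merge_altitude",
    "read_altitude_csv",
    "haversine_m",
]

EARTH_RADIUS_M = 6_371_000.0
GPX_NS = "http://www.topografix.com/GPX/1/1"

#: DataFrame columns of a SpeedTrace, in order.
TRACE_COLUMNS = ["time", "lat", "lon", "ele_gps", "ele_corrected", "speed_kmh", "source"]


class GpxParseError(ValueError):
    """Raised when a GPX file violates the expected session dialect."""


@dataclass
class SpeedTrace:
    """One session's ordered 1-Hz speed + coordinate series.

    Parameters
    ----------
    df
        One row per epoch with columns ``time`` (tz-aware UTC timestamps),
        ``lat``, ``lon`` (decimal degrees), ``ele_gps``, ``ele_corrected``
        (metres, NaN when absent), ``speed_kmh`` and ``source`` (``raw`` /
        ``interpolated`` / ``derived``).
    epoch_s
        Nominal epoch duration; 1 s for this device.
    session_id
        Opaque session label carried through all exports.
    provenance
        Ordered processing-history tags.
    gaps
        Declared recording gaps as ``(gap_start_time, gap_length_s)`` pairs,
        populated by :func:`canonicalize` for holes it refuses to fill.
    """

    df: pd.DataFrame
    epoch_s: int = 1
    session_id: str = ""
    provenance: list[str] = field(default_factory=list)
    gaps: list[tuple[pd.Timestamp, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.df) < 1:
            raise ValueError("a SpeedTrace needs at least one point")
        lat, lon = self.df["lat"].to_numpy(), self.df["lon"].to_numpy()
        if np.nanmin(lat) < -90 or np.nanmax(lat) > 90:
            raise ValueError("latitude outside [-90, 90]")
        if np.nanmin(lon) < -180 or np.nanmax(lon) > 180:
            raise ValueError("longitude outside [-180, 180]")
        sp = self.df["speed_kmh"].to_numpy(float)
        if np.nanmin(sp) < 0:
            raise ValueError("negative speed values are an input error")
        t = self.df["time"]
        bad = np.flatnonzero(t.diff().dt.total_seconds().to_numpy()[1:] <= 0)
        if bad.size:
            raise ValueError(
                f"timestamps not strictly increasing: first offending point index {bad[0] + 1}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def speed(self) -> np.ndarray:
        """Speed vector in km/h (one value per epoch)."""
        return self.df["speed_kmh"].to_numpy(float)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.df["time"])

    @property
    def start_time(self) -> pd.Timestamp:
        return self.df["time"].iloc[0]

    def _resolve_time(self, t) -> pd.Timestamp:
        """Accept absolute timestamps or seconds offsets from trace start."""
        if isinstance(t, (int, float, np.integer, np.floating)):
            return self.start_time + pd.Timedelta(seconds=float(t))
        return pd.Timestamp(t)

    def slice_time(self, start, end) -> "SpeedTrace":
        """Sub-trace on the closed interval [start, end]."""
        start, end = self._resolve_time(start), self._resolve_time(end)
        if start > end:
            raise ValueError("window start must not be after window end")
        t = self.df["time"]
        mask = (t >= start) & (t <= end)
        sub = self.df.loc[mask].reset_index(drop=True)
        if len(sub) == 0:
            raise ValueError(f"empty selection: no epochs in [{start}, {end}]")
        return SpeedTrace(
            sub,
            epoch_s=self.epoch_s,
            session_id=self.session_id,
            provenance=list(self.provenance),
            gaps=[g for g in self.gaps if start <= g[0] <= end],
        )

    def with_speed(self, speed_kmh: np.ndarray, tag: str) -> "SpeedTrace":
        df = self.df.copy()
        df["speed_kmh"] = np.asarray(speed_kmh, float)
        return SpeedTrace(
            df,
            epoch_s=self.epoch_s,
            session_id=self.session_id,
            provenance=[*self.provenance, tag],
            gaps=list(self.gaps),
        )


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres on a 6371-km sphere (vectorised)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, float)) for a in (lat1, lon1, lat2, lon2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))


def _local_name(el) -> str:
    return etree.QName(el).localname


def read_gpx(
    path,
    speed_source: str = "extension",
    speed_unit: str = "m/s",
    session_id: str | None = None,
) -> SpeedTrace:
    """Parse a GPX 1.1 session file into a :class:`SpeedTrace`.

    All tracks and segments are concatenated in time order (one file = one
    session; window selection happens downstream).

    Parameters
    ----------
    speed_source
        ``"extension"`` reads the per-point Doppler ``speed`` element (any
        namespace); ``"derived"`` computes speed from consecutive fixes as
        haversine distance over the time step and tags the trace ``derived``.
    speed_unit
        Unit of the stored extension speed: ``"m/s"`` (common GPX dialect,
        default), ``"km/h"``, or ``"auto"`` — a magnitude heuristic that
        treats a 95th-percentile speed above 8 as km/h (walking sessions do
        not reach 8 m/s ≈ 29 km/h).
    """
    if speed_source not in ("extension", "derived"):
        raise ValueError("speed_source must be 'extension' or 'derived'")
    path = Path(path)
    tree = etree.parse(str(path))
    pts = tree.getroot().findall(f".//{{{GPX_NS}}}trkpt")
    if not pts:  # be liberal about the declared namespace
        pts = [el for el in tree.getroot().iter() if _local_name(el) == "trkpt"]
    if not pts:
        raise GpxParseError(f"{path.name}: no trkpt elements found")

    rows = []
    for i, pt in enumerate(pts):
        lat, lon = pt.get("lat"), pt.get("lon")
        if lat is None or lon is None:
            raise GpxParseError(f"{path.name}: trkpt {i} lacks lat/lon")
        time_el = ele_el = speed_el = None
        for el in pt.iter():
            name = _local_name(el)
            if name == "time" and time_el is None:
                time_el = el
            elif name == "ele" and ele_el is None:
                ele_el = el
            elif name == "speed" and speed_el is None:
                speed_el = el
        if time_el is None or not (time_el.text or "").strip():
            raise GpxParseError(f"{path.name}: trkpt {i} has no timestamp")
        rows.append(
            (
                pd.Timestamp(time_el.text.strip()),
                float(lat),
                float(lon),
                float(ele_el.text) if ele_el is not None and ele_el.text else math.nan,
                math.nan if speed_el is None or not (speed_el.text or "").strip() else float(speed_el.text),
            )
        )

    df = pd.DataFrame(rows, columns=["time", "lat", "lon", "ele_gps", "speed_raw"])
    df["time"] = pd.to_datetime(df["time"], utc=True)
    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    dt = df["time"].diff().dt.total_seconds().to_numpy()[1:]
    if (dt <= 0).any():
        first = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise GpxParseError(f"{path.name}: non-monotonic time at point {first}")

    provenance = [f"read_gpx:{path.name}"]
    if speed_source == "extension":
        if df["speed_raw"].isna().any():
            n_missing = int(df["speed_raw"].isna().sum())
            raise GpxParseError(
                f"{path.name}: {n_missing} point(s) lack a speed element; "
                "use speed_source='derived' to compute speed from coordinates"
            )
        speed = df["speed_raw"].to_numpy(float)
        unit = speed_unit
        if unit == "auto":
            unit = "km/h" if np.percentile(speed, 95) > 8.0 else "m/s"
        if unit == "m/s":
            speed = speed * 3.6
        elif unit != "km/h":
            raise ValueError(f"unknown speed_unit {speed_unit!r}")
        provenance.append(f"speed:extension:{unit}")
    else:
        d = np.zeros(len(df))
        d[1:] = haversine_m(
            df["lat"].to_numpy()[:-1], df["lon"].to_numpy()[:-1],
            df["lat"].to_numpy()[1:], df["lon"].to_numpy()[1:],
        )
        step = np.ones(len(df))
        step[1:] = df["time"].diff().dt.total_seconds().to_numpy()[1:]
        speed = d / step * 3.6  # first point: zero displacement by convention
        provenance.append("speed:derived")

    out = pd.DataFrame(
        {
            "time": df["time"],
            "lat": df["lat"],
            "lon": df["lon"],
            "ele_gps": df["ele_gps"],
            "ele_corrected": math.nan,
            "speed_kmh": speed,
            "source": "derived" if speed_source == "derived" else "raw",
        }
    )
    return SpeedTrace(
        out,
        session_id=session_id if session_id is not None else path.stem,
        provenance=provenance,
    )


def write_gpx(trace: SpeedTrace, path, creator: str = "gpsgait") -> None:
    """Write a trace as GPX 1.1, speed stored in m/s under <extensions>.

    Coordinates are written to 6 decimal places and speed to 6 decimals
    (m/s), so a read → write → read cycle is stable to 6 d.p. coordinates
    and well under 0.01 km/h in speed.
    """
    root = etree.Element("gpx", nsmap={None: GPX_NS}, version="1.1", creator=creator)
    trk = etree.SubElement(root, "trk")
    name = etree.SubElement(trk, "name")
    name.text = trace.session_id or "session"
    seg = etree.SubElement(trk, "trkseg")
    for row in trace.df.itertuples(index=False):
        pt = etree.SubElement(seg, "trkpt", lat=f"{row.lat:.6f}", lon=f"{row.lon:.6f}")
        if not math.isnan(row.ele_gps):
            etree.SubElement(pt, "ele").text = f"{row.ele_gps:.2f}"
        etree.SubElement(pt, "time").text = (
            pd.Timestamp(row.time).strftime("%Y-%m-%dT%H:%M:%SZ")
        )
        ext = etree.SubElement(pt, "extensions")
        etree.SubElement(ext, "speed").text = f"{row.speed_kmh / 3.6:.6f}"
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def canonicalize(trace: SpeedTrace, max_gap_fill_s: int = 2) -> SpeedTrace:
    """Re-index a trace onto an exact 1-Hz grid.

    Missing runs of ≤ ``max_gap_fill_s`` seconds are filled by linear
    interpolation of speed and coordinates (rows tagged ``interpolated``);
    longer holes are retained as declared gaps and listed in ``trace.gaps``.
    Longer-than-nominal epochs are thus never silently fabricated. Idempotent.
    """
    if max_gap_fill_s < 0:
        raise ValueError("max_gap_fill_s must be non-negative")
    df = trace.df
    times = df["time"]
    dt = times.diff().dt.total_seconds().to_numpy()
    epoch = float(trace.epoch_s)
    if len(df) == 1 or np.all(dt[1:] == epoch):
        if "canonical" in trace.provenance:
            return trace
        return SpeedTrace(
            df.copy(), trace.epoch_s, trace.session_id,
            [*trace.provenance, "canonical"], list(trace.gaps),
        )

    pieces = [df.iloc[[0]]]
    gaps: list[tuple[pd.Timestamp, float]] = []
    numeric = ["lat", "lon", "ele_gps", "ele_corrected", "speed_kmh"]
    for i in range(1, len(df)):
        step = dt[i]
        prev, cur = df.iloc[i - 1], df.iloc[i]
        missing = step - epoch
        if missing > 0 and missing <= max_gap_fill_s:
            n_fill = int(round(missing / epoch))
            for k in range(1, n_fill + 1):
                frac = k / (n_fill + 1)
                row = {"time": prev["time"] + pd.Timedelta(seconds=k * epoch), "source": "interpolated"}
                for c in numeric:
                    row[c] = prev[c] + frac * (cur[c] - prev[c])
                pieces.append(pd.DataFrame([row]))
        elif missing > max_gap_fill_s:
            gaps.append((prev["time"], float(missing)))
        pieces.append(df.iloc[[i]])
    out = pd.concat(pieces, ignore_index=True)[TRACE_COLUMNS]
    return SpeedTrace(
        out, trace.epoch_s, trace.session_id,
        [*trace.provenance, "canonical"], [*trace.gaps, *gaps],
    )


def read_altitude_csv(path) -> pd.DataFrame:
    """Load a corrected-altitude table.

    Expected columns: ``ele_corrected_m`` plus either ``timestamp``
    (ISO-8601) or ``index`` (0-based point position).
    """
    tbl = pd.read_csv(path)
    if "ele_corrected_m" not in tbl.columns:
        raise ValueError("altitude CSV needs an 'ele_corrected_m' column")
    if "timestamp" in tbl.columns:
        tbl["timestamp"] = pd.to_datetime(tbl["timestamp"], utc=True)
    elif "index" not in tbl.columns:
        raise ValueError("altitude CSV needs a 'timestamp' or 'index' column")
    return tbl


def merge_altitude(trace: SpeedTrace, altitude_table) -> SpeedTrace:
    """Populate ``ele_corrected`` from an external altitude series.

    ``altitude_table`` is a DataFrame from :func:`read_altitude_csv`, or any
    iterable of ``(timestamp, metres)`` pairs. Timestamp-keyed tables must
    cover every trace point; index-keyed tables join by position.
    """
    df = trace.df.copy()
    n = len(df)
    if isinstance(altitude_table, pd.DataFrame):
        tbl = altitude_table
    else:
        tbl = pd.DataFrame(list(altitude_table), columns=["timestamp", "ele_corrected_m"])
        if len(tbl):
            tbl["timestamp"] = pd.to_datetime(tbl["timestamp"], utc=True)

    if "timestamp" in tbl.columns and len(tbl):
        mapping = tbl.set_index("timestamp")["ele_corrected_m"]
        matched = df["time"].map(mapping)
        n_miss = int(matched.isna().sum())
        if n_miss:
            raise ValueError(f"{n - n_miss} of {n} timestamps matched in altitude table")
        df["ele_corrected"] = matched.to_numpy(float)
    elif "index" in tbl.columns and len(tbl):
        mapping = tbl.set_index("index")["ele_corrected_m"]
        matched = pd.Series(range(n)).map(mapping)
        n_miss = int(matched.isna().sum())
        if n_miss:
            raise ValueError(f"{n - n_miss} of {n} timestamps matched in altitude table")
        df["ele_corrected"] = matched.to_numpy(float)
    else:
        raise ValueError(f"0 of {n} timestamps matched in altitude table")
    return SpeedTrace(
        df, trace.epoch_s, trace.session_id,
        [*trace.provenance, "merge_altitude"], list(trace.gaps),
    )
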
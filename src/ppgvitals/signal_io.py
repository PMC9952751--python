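"""Reading PPG records, windowing them into labeled segments, and tabular I/O.

A :class:`PPGRecord` holds one continuous PPG waveform plus the time-stamped
reference vitals (respiration rate in breaths/min, SpO2 in %) that serve as
ground truth.  Records are cut into fixed-length overlapping windows
(:class:`PPGSegment`), each of which inherits a scalar label computed from the
reference samples falling inside it.  The default protocol is 32 s windows
with 50 % overlap, which at 125 Hz gives 4000-sample segments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceSeries",
    "PPGRecord",
    "PPGSegment",
    "SegmentSet",
    "read_record",
    "segment_record",
    "attach_labels",
    "quality_screen",
    "write_segments",
    "read_segments",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSeries:
    """Time-stamped reference vitals (typically 1 Hz numerics).

    ``rr`` and ``spo2`` may contain NaN where the monitor dropped out; such
    entries are ignored when labeling segments.
    """

    timestamps: np.ndarray          # seconds from record start, strictly increasing
    rr: np.ndarray | None = None    # breaths/min
    spo2: np.ndarray | None = None  # percent

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.rr is not None:
            self.rr = np.asarray(self.rr, dtype=float)
            if self.rr.shape != self.timestamps.shape:
                raise ValueError("rr and timestamps must have matching shapes")
        if self.spo2 is not None:
            self.spo2 = np.asarray(self.spo2, dtype=float)
            if self.spo2.shape != self.timestamps.shape:
                raise ValueError("spo2 and timestamps must have matching shapes")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("reference timestamps must be strictly increasing")

    @property
    def empty(self) -> bool:
        return self.timestamps.size == 0


@dataclass
class PPGRecord:
    """One continuous PPG recording with sampling metadata and reference vitals."""

    samples: np.ndarray
    fs: float
    record_id: str = "record"
    reference: ReferenceSeries | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("record has no samples")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(f"non-finite sample at index {bad} in record {self.record_id!r}")
        if self.reference is not None and not self.reference.empty:
            t = self.reference.timestamps
            if t[0] < 0 or t[-1] > self.duration + 1e-9:
                raise ValueError("reference timestamps fall outside [0, duration]")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs


@dataclass
class PPGSegment:
    """A fixed-length window of PPG with optional scalar RR / SpO2 labels."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    rr_label: float | None = None
    spo2_label: float | None = None
    record_id: str = "record"
    unlabeled_rr: bool = False
    unlabeled_spo2: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.rr_label is not None and not (0.0 <= self.rr_label <= 120.0):
            raise ValueError(f"rr_label out of range [0, 120]: {self.rr_label}")
        if self.spo2_label is not None and not (0.0 <= self.spo2_label <= 100.0):
            raise ValueError(f"spo2_label out of range [0, 100]: {self.spo2_label}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds relative to segment start."""
        return np.arange(self.samples.size) / self.fs


@dataclass
class SegmentSet:
    """An ordered collection of segments plus windowing provenance."""

    segments: list[PPGSegment] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[PPGSegment]:
        return iter(self.segments)

    def __getitem__(self, i: int) -> PPGSegment:
        return self.segments[i]

    def labels(self) -> pd.DataFrame:
        """Per-segment labels as a DataFrame (NaN where unlabeled)."""
        return pd.DataFrame(
            {
                "record_id": [s.record_id for s in self.segments],
                "start_time": [s.start_time for s in self.segments],
                "rr_label": [np.nan if s.rr_label is None else s.rr_label for s in self.segments],
                "spo2_label": [np.nan if s.spo2_label is None else s.spo2_label for s in self.segments],
            }
        )


# ---------------------------------------------------------------------------
# Record ingestion
# ---------------------------------------------------------------------------

def read_record(
    path: str | Path,
    format: str = "csv",
    *,
    fs: float | None = None,
    time_column: str = "Time [s]",
    ppg_column: str = "PLETH",
    numerics_path: str | Path | None = None,
    numerics_time_column: str = "Time [s]",
    rr_column: str = "RESP",
    spo2_column: str = "SpO2",
    record_id: str | None = None,
) -> PPGRecord:
    """Read a PPG record from CSV or a WFDB header/signal pair.

    For CSV, ``path`` names a signals file with a PPG column; sampling
    frequency is taken from the time column spacing unless ``fs`` is given.
    ``numerics_path`` optionally names a second CSV carrying the reference
    RR / SpO2 numerics.  For WFDB, ``path`` names the ``.hea`` header (or its
    stem); the PLETH channel is located by description and ``numerics_path``
    may point at the companion numerics record.
    """
    path = Path(path)
    if format == "csv":
        return _read_record_csv(
            path, fs=fs, time_column=time_column, ppg_column=ppg_column,
            numerics_path=numerics_path, numerics_time_column=numerics_time_column,
            rr_column=rr_column, spo2_column=spo2_column, record_id=record_id,
        )
    if format == "wfdb":
        return _read_record_wfdb(
            path, ppg_column=ppg_column, numerics_path=numerics_path,
            rr_column=rr_column, spo2_column=spo2_column, record_id=record_id,
        )
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")


def _read_record_csv(path, *, fs, time_column, ppg_column, numerics_path,
                     numerics_time_column, rr_column, spo2_column, record_id):
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if ppg_column not in df.columns:
        raise ValueError(f"PPG column {ppg_column!r} not found in {path.name}; "
                         f"columns: {list(df.columns)}")
    samples = df[ppg_column].to_numpy(dtype=float)
    if not np.all(np.isfinite(samples)):
        bad = int(np.flatnonzero(~np.isfinite(samples))[0])
        raise ValueError(f"non-finite PPG sample at row {bad} of {path.name}")
    if fs is None:
        if time_column in df.columns and len(df) > 1:
            dt = np.diff(df[time_column].to_numpy(dtype=float))
            if np.any(dt <= 0):
                raise ValueError(f"time column {time_column!r} is not increasing")
            fs = 1.0 / float(np.median(dt))
        else:
            raise ValueError("sampling frequency unavailable: no usable time column "
                             "and no fs override supplied")
    reference = None
    if numerics_path is not None:
        nd = pd.read_csv(numerics_path)
        nd.columns = [c.strip() for c in nd.columns]
        if numerics_time_column in nd.columns:
            t = nd[numerics_time_column].to_numpy(dtype=float)
        else:
            t = np.arange(len(nd), dtype=float)  # assume 1 Hz numerics
        rr = nd[rr_column].to_numpy(dtype=float) if rr_column in nd.columns else None
        spo2 = nd[spo2_column].to_numpy(dtype=float) if spo2_column in nd.columns else None
        reference = ReferenceSeries(t, rr=rr, spo2=spo2)
    return PPGRecord(samples, fs, record_id=record_id or path.stem, reference=reference)


# --- minimal WFDB support (text header + format-16 signal file) -------------

def _parse_wfdb_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    nsamp = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1:1 + nsig]:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0]
        gain, baseline, units = 200.0, 0, "mV"
        if len(parts) > 2:
            g = parts[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.split("(", 1)
                baseline = int(b.rstrip(")"))
            gain = float(g) if g else 200.0
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        desc = " ".join(parts[8:]) if len(parts) > 8 else f"sig{len(signals)}"
        signals.append(dict(file=fname, fmt=fmt, gain=gain or 200.0,
                            baseline=baseline if "(" in (parts[2] if len(parts) > 2 else "") else adc_zero,
                            units=units, description=desc))
    return name, nsig, fs, nsamp, signals


def _read_record_wfdb(path, *, ppg_column, numerics_path, rr_column, spo2_column, record_id):
    hea_path = Path(str(path) if str(path).endswith(".hea") else str(path) + ".hea")
    if not hea_path.exists():
        raise FileNotFoundError(hea_path)
    name, nsig, fs, nsamp, signals = _parse_wfdb_header(hea_path)
    # locate PPG channel by description (PLETH / PPG)
    idx = None
    for i, s in enumerate(signals):
        d = s["description"].upper()
        if ppg_column.upper() in d or "PLETH" in d or d == "PPG":
            idx = i
            break
    if idx is None:
        raise ValueError(f"no PLETH/PPG channel found in {hea_path.name}; "
                         f"channels: {[s['description'] for s in signals]}")
    sig = signals[idx]
    if sig["fmt"] != "16":
        raise NotImplementedError(f"WFDB signal format {sig['fmt']} not supported "
                                  "(only format 16); convert or supply CSV")
    dat_path = hea_path.parent / sig["file"]
    raw = np.fromfile(dat_path, dtype="<i2")
    raw = raw[: (raw.size // nsig) * nsig].reshape(-1, nsig)
    samples = (raw[:, idx].astype(float) - sig["baseline"]) / sig["gain"]
    if nsamp:
        samples = samples[:nsamp]
    reference = None
    if numerics_path is not None:
        nh = Path(str(numerics_path) if str(numerics_path).endswith(".hea") else str(numerics_path) + ".hea")
        _, n_nsig, n_fs, n_nsamp, n_sigs = _parse_wfdb_header(nh)
        ndat = nh.parent / n_sigs[0]["file"]
        nraw = np.fromfile(ndat, dtype="<i2")
        nraw = nraw[: (nraw.size // n_nsig) * n_nsig].reshape(-1, n_nsig)
        t = np.arange(nraw.shape[0]) / n_fs
        rr = spo2 = None
        for i, s in enumerate(n_sigs):
            d = s["description"].upper()
            vals = (nraw[:, i].astype(float) - s["baseline"]) / s["gain"]
            if rr_column.upper() in d or "RESP" in d:
                rr = vals
            elif spo2_column.upper() in d.replace(" ", "") or "SPO2" in d.replace(" ", ""):
                spo2 = vals
        reference = ReferenceSeries(t, rr=rr, spo2=spo2)
    return PPGRecord(samples, fs, record_id=record_id or name, reference=reference)


# ---------------------------------------------------------------------------
# Windowing and labeling
# ---------------------------------------------------------------------------

def segment_record(record: PPGRecord, window_s: float = 32.0,
                   overlap: float = 0.5) -> SegmentSet:
    """Cut a record into fixed windows with fractional overlap.

    Windows tile the record with step ``window_s * (1 - overlap)``; a trailing
    partial window is dropped (padding would distort spectral features).  For
    a record of duration T the count is ``floor((T - window_s)/step) + 1`` when
    ``T >= window_s`` and 0 otherwise.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    nwin = int(round(window_s * record.fs))
    if nwin < 2:
        raise ValueError("window shorter than 2 samples")
    step = window_s * (1.0 - overlap)
    nstep = int(round(step * record.fs))
    if nstep < 1:
        raise ValueError("window step below one sample")
    n = record.samples.size
    segments: list[PPGSegment] = []
    start = 0
    while start + nwin <= n:
        segments.append(
            PPGSegment(
                samples=record.samples[start:start + nwin].copy(),
                fs=record.fs,
                start_time=start / record.fs,
                record_id=record.record_id,
            )
        )
        start += nstep
    if not segments:
        warnings.warn(f"record {record.record_id!r} shorter than one window; "
                      "empty segment set", stacklevel=2)
    return SegmentSet(
        segments,
        provenance={
            "record_ids": [record.record_id],
            "window_s": window_s,
            "overlap": overlap,
            "fs": record.fs,
        },
    )


def attach_labels(segments: SegmentSet, record: PPGRecord,
                  rule: str = "mean") -> SegmentSet:
    """Assign per-segment RR / SpO2 labels from the record's reference series.

    ``rule`` is one of ``mean`` (default), ``median``, or ``midpoint`` (the
    reference sample nearest the window midpoint).  Labels use reference
    points with timestamps inside the half-open window [start, start+window);
    a segment with no usable in-window points is flagged unlabeled.
    """
    if rule not in ("mean", "median", "midpoint"):
        raise ValueError(f"unknown label rule {rule!r}")
    ref = record.reference
    out: list[PPGSegment] = []
    if ref is None or ref.empty:
        warnings.warn("empty reference series: all segments unlabeled", stacklevel=2)
        for seg in segments:
            out.append(replace(seg, rr_label=None, spo2_label=None,
                               unlabeled_rr=True, unlabeled_spo2=True))
        return SegmentSet(out, provenance={**segments.provenance, "label_rule": rule})

    for seg in segments:
        t0, t1 = seg.start_time, seg.start_time + seg.duration
        in_win = (ref.timestamps >= t0) & (ref.timestamps < t1)
        rr_val = _summarize(ref.rr, ref.timestamps, in_win, (t0 + t1) / 2, rule)
        spo2_val = _summarize(ref.spo2, ref.timestamps, in_win, (t0 + t1) / 2, rule)
        out.append(replace(
            seg,
            rr_label=rr_val, spo2_label=spo2_val,
            unlabeled_rr=rr_val is None, unlabeled_spo2=spo2_val is None,
        ))
    return SegmentSet(out, provenance={**segments.provenance, "label_rule": rule})


def _summarize(values, timestamps, in_win, midpoint, rule):
    if values is None:
        return None
    v = values[in_win]
    t = timestamps[in_win]
    ok = np.isfinite(v)
    v, t = v[ok], t[ok]
    if v.size == 0:
        return None
    if rule == "mean":
        return float(np.mean(v))
    if rule == "median":
        return float(np.median(v))
    return float(v[np.argmin(np.abs(t - midpoint))])


def quality_screen(segments: SegmentSet, *, flat_tol: float = 1e-10,
                   clip_frac: float = 0.05) -> SegmentSet:
    """Optional screen dropping flat-line or heavily clipped segments.

    Off by default in every pipeline; provided because monitor dropouts
    produce constant or railed windows that carry no pulse information.
    """
    kept = []
    for seg in segments:
        x = seg.samples
        if np.ptp(x) <= flat_tol:
            continue
        at_rail = np.mean((x == x.max()) | (x == x.min()))
        if at_rail > clip_frac:
            continue
        kept.append(seg)
    prov = {**segments.provenance, "quality_screen": {"flat_tol": flat_tol, "clip_frac": clip_frac}}
    return SegmentSet(kept, provenance=prov)


# ---------------------------------------------------------------------------
# Tabular interchange
# ---------------------------------------------------------------------------

def write_segments(segments: SegmentSet, path: str | Path) -> None:
    """Write a SegmentSet as CSV (one row per segment) plus a JSON sidecar.

    Samples are serialized at full double precision (%.17g) so a round trip
    is bit-exact.
    """
    path = Path(path)
    rows = []
    for i, seg in enumerate(segments):
        rows.append({
            "segment_id": i,
            "record_id": seg.record_id,
            "fs": repr(seg.fs),
            "start_time": repr(seg.start_time),
            "rr_label": "" if seg.rr_label is None else repr(seg.rr_label),
            "spo2_label": "" if seg.spo2_label is None else repr(seg.spo2_label),
            "samples": " ".join(f"{v:.17g}" for v in seg.samples),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"provenance": segments.provenance,
                                   "n_segments": len(segments)}, indent=2, default=str))


def read_segments(path: str | Path) -> SegmentSet:
    """Read a SegmentSet written by :func:`write_segments`."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    segs = []
    for _, row in df.iterrows():
        segs.append(PPGSegment(
            samples=np.array(row["samples"].split(), dtype=float),
            fs=float(row["fs"]),
            start_time=float(row["start_time"]),
            rr_label=float(row["rr_label"]) if row["rr_label"] else None,
            spo2_label=float(row["spo2_label"]) if row["spo2_label"] else None,
            record_id=row["record_id"],
            unlabeled_rr=not row["rr_label"],
            unlabeled_spo2=not row["spo2_label"],
        ))
    provenance = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", {})
    return SegmentSet(segs, provenance=provenance)
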
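"""Pulse-wave delineation: foot, systolic peak, dicrotic notch, diastolic
peak, and the second-derivative a-e waves.

The detector is tuned for recall of systolic peaks, since the timing ratio
t1/tpi and amplitude statistics dominate the downstream feature set:

* a spectral heart-rate prior (periodogram peak in 0.7-3.5 Hz) sets the
  minimum inter-peak distance (40 % of the estimated beat period);
* systolic peaks are local maxima with prominence >= 30 % of the segment's
  robust amplitude range (5th-95th percentile span);
* the pulse foot (onset) is the minimum between consecutive systolic peaks;
* dicrotic notch and diastolic peak come from sign changes of a smoothed
  first derivative inside the diastolic interval, with a curvature-extremum
  fallback when the derivative never changes sign;
* a-e waves are the first five alternating extrema of a Savitzky-Golay
  smoothed second derivative after the onset.

Amplitudes are measured relative to the preceding onset value, since
filtering does not guarantee a zero baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_io import PPGSegment

__all__ = ["Beat", "PulseFiducials", "UnanalyzableSegment", "detect_pulses", "beat_intervals"]


class UnanalyzableSegment(ValueError):
    """Raised when a segment yields fewer than 3 valid beats."""


@dataclass
class Beat:
    """Landmarks of one pulse, as sample indices into the segment."""

    onset_idx: int
    sys_peak_idx: int
    next_onset_idx: int | None = None  # None for a trailing beat with no successor
    notch_idx: int | None = None
    dia_peak_idx: int | None = None
    a_idx: int | None = None
    b_idx: int | None = None
    c_idx: int | None = None
    d_idx: int | None = None
    e_idx: int | None = None


@dataclass
class PulseFiducials:
    """All valid beats of a segment plus detection bookkeeping."""

    beats: list[Beat]
    fs: float
    n_discarded: int = 0
    hr_est_hz: float | None = None
    segment: PPGSegment | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.beats)


# ---------------------------------------------------------------------------

def _spectral_hr(x: np.ndarray, fs: float) -> float | None:
    """Dominant frequency in the cardiac band 0.7-3.5 Hz, or None."""
    f, p = sps.periodogram(x - np.mean(x), fs=fs, window="hann")
    band = (f >= 0.7) & (f <= 3.5)
    if not np.any(band) or np.all(p[band] == 0):
        return None
    return float(f[band][np.argmax(p[band])])


def _smooth_derivatives(x: np.ndarray, fs: float, window: int = 11, order: int = 3):
    """First/second derivatives via Savitzky-Golay smoothing of differences."""
    window = min(window if window % 2 == 1 else window + 1, x.size - (1 - x.size % 2))
    if window <= order + 1:
        d1 = np.gradient(x) * fs
        return d1, np.gradient(d1) * fs
    d1 = sps.savgol_filter(x, window, order, deriv=1, delta=1.0 / fs)
    d2 = sps.savgol_filter(x, window, order, deriv=2, delta=1.0 / fs)
    return d1, d2


def detect_pulses(segment: PPGSegment, *, prominence_frac: float = 0.30,
                  sg_window: int = 11, sg_order: int = 3) -> PulseFiducials:
    """Delineate every pulse in a preprocessed segment.

    Raises :exc:`UnanalyzableSegment` when fewer than 3 beats satisfy the
    ordering invariants (onset < systolic peak < next onset, positive systolic
    amplitude).
    """
    x = segment.samples
    fs = segment.fs
    lo, hi = np.percentile(x, [5, 95])
    robust_range = hi - lo
    if robust_range <= 0:
        raise UnanalyzableSegment("segment has no amplitude variation")

    hr = _spectral_hr(x, fs)
    if hr is None:
        hr = 1.2  # fall back to a nominal 72 bpm prior
    min_dist = max(1, int(round(0.4 / hr * fs)))
    peaks, _ = sps.find_peaks(x, prominence=prominence_frac * robust_range,
                              distance=min_dist)
    if peaks.size < 3:
        raise UnanalyzableSegment(
            f"only {peaks.size} systolic peak(s) found; need >= 3 beats")

    # onsets: minimum between consecutive systolic peaks
    onsets = np.empty(peaks.size - 1, dtype=int)
    for i in range(peaks.size - 1):
        lo_i, hi_i = peaks[i], peaks[i + 1]
        onsets[i] = lo_i + int(np.argmin(x[lo_i:hi_i]))

    d1, d2 = _smooth_derivatives(x, fs, sg_window, sg_order)

    beats: list[Beat] = []
    discarded = 0
    # leading beat: onset searched in a window before the first peak
    first_onset = None
    back = int(round(0.45 / hr * fs))
    j0 = max(0, peaks[0] - back)
    if peaks[0] - j0 >= 2:
        first_onset = j0 + int(np.argmin(x[j0:peaks[0]]))
    all_onsets = ([first_onset] if first_onset is not None else [None]) + list(onsets)
    for i in range(peaks.size):
        onset = all_onsets[i]
        nxt = int(onsets[i]) if i < onsets.size else None   # trailing beat is open
        peak = int(peaks[i])
        if onset is None or not (onset < peak < (nxt if nxt is not None else x.size)) \
                or x[peak] <= x[onset]:
            discarded += 1
            continue
        beat = Beat(onset_idx=int(onset), sys_peak_idx=peak, next_onset_idx=nxt)
        if nxt is not None:
            _find_diastolic(beat, x, d1, d2)
            _find_abcde(beat, d2)
        beats.append(beat)

    if len(beats) < 3:
        raise UnanalyzableSegment(
            f"only {len(beats)} valid beat(s) after ordering checks")
    return PulseFiducials(beats=beats, fs=fs, n_discarded=discarded,
                          hr_est_hz=hr, segment=segment)


def _find_diastolic(beat: Beat, x: np.ndarray, d1: np.ndarray, d2: np.ndarray) -> None:
    """Dicrotic notch (local min) and diastolic peak inside the diastolic
    interval, from first-derivative zero crossings; curvature fallback."""
    a, b = beat.sys_peak_idx + 1, beat.next_onset_idx
    if b - a < 4:
        return
    seg_d1 = d1[a:b]
    sign = np.sign(seg_d1)
    # notch: derivative crosses - to + (signal local minimum)
    up = np.flatnonzero((sign[:-1] <= 0) & (sign[1:] > 0))
    if up.size:
        notch = a + int(up[0]) + 1
        beat.notch_idx = notch
        # diastolic peak: next + to - crossing after the notch
        rel = notch - a
        down = np.flatnonzero((sign[rel:-1] > 0) & (sign[rel + 1:] <= 0))
        if down.size:
            cand = notch + int(down[0]) + 1
            if cand < b:
                beat.dia_peak_idx = cand
    else:
        # no derivative sign change (hump merged into the decay): fall back to
        # interior curvature landmarks — the notch is the first local maximum
        # of d2 after the peak, the diastolic shoulder the following local
        # minimum of d2
        seg_d2 = d2[a:b]
        maxima, _ = sps.find_peaks(seg_d2)
        if maxima.size:
            notch = a + int(maxima[0])
            beat.notch_idx = notch
            minima, _ = sps.find_peaks(-seg_d2[maxima[0]:])
            if minima.size:
                beat.dia_peak_idx = notch + int(minima[0])


def _find_abcde(beat: Beat, d2: np.ndarray) -> None:
    """First five alternating extrema of d2 after the onset: a,c,e maxima and
    b,d minima."""
    a0, b0 = beat.onset_idx, beat.next_onset_idx
    seg = d2[a0:b0]
    if seg.size < 5:
        return
    maxima, _ = sps.find_peaks(seg)
    minima, _ = sps.find_peaks(-seg)
    extrema = sorted([(int(i), True) for i in maxima] + [(int(i), False) for i in minima])
    want_max = True
    found: list[int] = []
    for idx, is_max in extrema:
        if is_max == want_max:
            found.append(a0 + idx)
            want_max = not want_max
            if len(found) == 5:
                break
    for name, idx in zip(("a_idx", "b_idx", "c_idx", "d_idx", "e_idx"), found):
        setattr(beat, name, idx)


# ---------------------------------------------------------------------------

def _cross_time(x: np.ndarray, i0: int, i1: int, level: float, fs: float,
                rising: bool) -> float | None:
    """Linearly interpolated time (s) where x crosses ``level`` in [i0, i1]."""
    seg = x[i0:i1 + 1]
    if rising:
        hits = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
        j = hits[-1] if hits.size else None     # last upward crossing before peak
    else:
        hits = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
        j = hits[0] if hits.size else None      # first downward crossing after peak
    if j is None:
        return None
    y0, y1 = seg[j], seg[j + 1]
    frac = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
    return (i0 + j + frac) / fs


def beat_intervals(fid: PulseFiducials) -> pd.DataFrame:
    """Per-beat timing/amplitude table.

    Columns: ``t1`` (onset to systolic peak, s), ``tpi`` (onset to next onset,
    s), ``t1_tpi_ratio``, rise/fall times, widths at 25/50/75 % of the
    systolic amplitude (linear interpolation of threshold crossings on each
    side of the peak), amplitudes relative to the onset baseline, the
    diastolic/systolic amplitude ratio and notch timing ratio.  Landmarks that
    could not be detected, or width levels never crossed (clipped beats),
    yield NaN for that beat.
    """
    if len(fid.beats) < 1:
        raise ValueError("no beats to tabulate")
    seg = fid.segment
    if seg is None:
        raise ValueError("fiducials carry no segment samples")
    x, fs = seg.samples, fid.fs
    d1, d2 = _smooth_derivatives(x, fs)
    rows = []
    for beat in fid.beats:
        onset, peak, nxt = beat.onset_idx, beat.sys_peak_idx, beat.next_onset_idx
        base = x[onset]
        sys_amp = x[peak] - base
        t1 = (peak - onset) / fs
        tpi = (nxt - onset) / fs if nxt is not None else np.nan
        fall_end = nxt if nxt is not None else x.size - 1
        row = {
            "onset_s": onset / fs,
            "t1": t1,
            "tpi": tpi,
            "t1_tpi_ratio": t1 / tpi if tpi > 0 else np.nan,
            "sys_amp": sys_amp,
            "dia_amp": x[beat.dia_peak_idx] - base if beat.dia_peak_idx is not None else np.nan,
            "notch_amp": x[beat.notch_idx] - base if beat.notch_idx is not None else np.nan,
            "rise_time": t1,
            "fall_time": (fall_end - peak) / fs if nxt is not None else np.nan,
        }
        row["dia_sys_amp_ratio"] = row["dia_amp"] / sys_amp if sys_amp > 0 else np.nan
        row["notch_time_ratio"] = ((beat.notch_idx - onset) / fs / tpi
                                   if beat.notch_idx is not None and tpi > 0 else np.nan)
        for frac, name in ((0.25, "width25"), (0.50, "width50"), (0.75, "width75")):
            level = base + frac * sys_amp
            t_up = _cross_time(x, onset, peak, level, fs, rising=True)
            t_dn = _cross_time(x, peak, fall_end, level, fs, rising=False)
            row[name] = (t_dn - t_up) if (t_up is not None and t_dn is not None) else np.nan
        for wave in "abcde":
            idx = getattr(beat, f"{wave}_idx")
            row[f"{wave}_amp"] = d2[idx] if idx is not None else np.nan
        a_amp = row["a_amp"]
        if np.isfinite(a_amp) and a_amp != 0:
            for wave in "bcde":
                row[f"{wave}_a_ratio"] = row[f"{wave}_amp"] / a_amp
            row["aging_index"] = (row["b_amp"] - row["c_amp"] - row["d_amp"]
                                  - row["e_amp"]) / a_amp
            row["mod_aging_index"] = (row["b_amp"] - row["c_amp"] - row["d_amp"]) / a_amp
        else:
            for wave in "bcde":
                row[f"{wave}_a_ratio"] = np.nan
            row["aging_index"] = np.nan
            row["mod_aging_index"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    # single-beat edge case is handled upstream (detector requires >= 3 beats),
    # but tabulation itself tolerates any count >= 1
    return df
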
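"""The fixed 107-feature catalog and per-segment extraction.

Groups, with counts chosen so the catalog totals exactly 107 (contract-
enforced at import time):

* time (39): mean / SD / variance over beats of 13 pulse timing & amplitude
  quantities (systolic/diastolic/notch amplitudes, t1, tpi, t1/tpi, rise and
  fall times, widths at 25/50/75 % of the systolic amplitude, the
  diastolic/systolic amplitude ratio and notch timing ratio);
* derivative (22): mean / SD over beats of the second-derivative a-e wave
  amplitudes, their b/a..e/a ratios, and two aging indices;
* frequency (17): maximum-magnitude frequency, dominant frequency and
  magnitude in the cardiac (0.7-3.5 Hz) and respiratory (0.05-0.6 Hz) bands,
  the top-3 spectral peaks, relative band powers (respiratory / cardiac /
  harmonic 3.5-10 Hz), spectral centroid and spectral entropy;
* statistical (29): moments, robust spread, entropy, zero-crossing rate and
  Hjorth parameters of the segment, plus moment sets of its first and second
  differences.

Conventions (stated because they are often left implicit): skewness and
kurtosis are population moments, kurtosis non-excess (a Gaussian scores 3, a
sine 1.5); Shannon entropy uses a 16-bin amplitude histogram spanning the
segment's min-max with base-2 logs; the periodogram uses a Hann window on the
mean-removed segment, zero-padded for a fine frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .fiducials import PulseFiducials, beat_intervals
from .signal_io import PPGSegment, SegmentSet

__all__ = [
    "FeatureDescriptor",
    "FeatureVector",
    "FeatureMatrix",
    "FeatureScaler",
    "feature_catalog",
    "feature_names",
    "extract_features",
    "build_matrix",
    "CATALOG_VERSION",
]

CATALOG_VERSION = "1.0"

RESP_BAND = (0.05, 0.6)      # Hz — respiratory modulation
CARDIAC_BAND = (0.7, 3.5)    # Hz — heart-rate fundamentals
HARMONIC_BAND = (3.5, 10.0)  # Hz — cardiac harmonics


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    group: str       # time | derivative | frequency | statistical
    units: str
    definition: str


_TIME_QUANTITIES = [
    ("sys_amp", "au", "systolic peak amplitude above onset baseline"),
    ("dia_amp", "au", "diastolic peak amplitude above onset baseline"),
    ("notch_amp", "au", "dicrotic notch amplitude above onset baseline"),
    ("t1", "s", "onset to systolic peak time"),
    ("tpi", "s", "pulse interval, onset to next onset"),
    ("t1_tpi_ratio", "-", "systolic peak time over pulse interval"),
    ("rise_time", "s", "onset to systolic peak rise time"),
    ("fall_time", "s", "systolic peak to next onset fall time"),
    ("width25", "s", "pulse width at 25% of systolic amplitude"),
    ("width50", "s", "pulse width at 50% of systolic amplitude"),
    ("width75", "s", "pulse width at 75% of systolic amplitude"),
    ("dia_sys_amp_ratio", "-", "diastolic over systolic amplitude"),
    ("notch_time_ratio", "-", "notch time over pulse interval"),
]

_DERIV_QUANTITIES = [
    ("a_amp", "au/s^2", "second-derivative a-wave amplitude"),
    ("b_amp", "au/s^2", "second-derivative b-wave amplitude"),
    ("c_amp", "au/s^2", "second-derivative c-wave amplitude"),
    ("d_amp", "au/s^2", "second-derivative d-wave amplitude"),
    ("e_amp", "au/s^2", "second-derivative e-wave amplitude"),
    ("b_a_ratio", "-", "b/a wave ratio"),
    ("c_a_ratio", "-", "c/a wave ratio"),
    ("d_a_ratio", "-", "d/a wave ratio"),
    ("e_a_ratio", "-", "e/a wave ratio"),
    ("aging_index", "-", "(b-c-d-e)/a"),
    ("mod_aging_index", "-", "(b-c-d)/a"),
]

_FREQ_FEATURES = [
    ("max_frequency", "Hz", "frequency of the global spectral maximum"),
    ("max_frequency_magnitude", "au^2/Hz", "PSD at the global spectral maximum"),
    ("cardiac_dominant_frequency", "Hz", "dominant frequency in 0.7-3.5 Hz"),
    ("cardiac_dominant_magnitude", "au^2/Hz", "PSD at the cardiac dominant frequency"),
    ("resp_dominant_frequency", "Hz", "dominant frequency in 0.05-0.6 Hz"),
    ("resp_dominant_magnitude", "au^2/Hz", "PSD at the respiratory dominant frequency"),
    ("spectral_peak1_freq", "Hz", "frequency of the largest PSD peak"),
    ("spectral_peak1_mag", "au^2/Hz", "magnitude of the largest PSD peak"),
    ("spectral_peak2_freq", "Hz", "frequency of the 2nd largest PSD peak"),
    ("spectral_peak2_mag", "au^2/Hz", "magnitude of the 2nd largest PSD peak"),
    ("spectral_peak3_freq", "Hz", "frequency of the 3rd largest PSD peak"),
    ("spectral_peak3_mag", "au^2/Hz", "magnitude of the 3rd largest PSD peak"),
    ("resp_band_power", "-", "fraction of power in 0.05-0.6 Hz"),
    ("cardiac_band_power", "-", "fraction of power in 0.7-3.5 Hz"),
    ("harmonic_band_power", "-", "fraction of power in 3.5-10 Hz"),
    ("spectral_centroid", "Hz", "power-weighted mean frequency"),
    ("spectral_entropy", "bits", "Shannon entropy of the normalized PSD"),
]

_STAT_SIG = ["mean", "median", "sd", "var", "skewness", "kurtosis", "rms",
             "iqr", "mad", "entropy", "zcr"]
_STAT_D1 = ["mean", "sd", "var", "skewness", "kurtosis", "rms", "iqr", "mad"]
_STAT_D2 = ["sd", "var", "skewness", "kurtosis", "rms", "iqr", "mad", "zcr"]


def feature_catalog() -> list[FeatureDescriptor]:
    """The ordered, versioned catalog of exactly 107 features."""
    cat: list[FeatureDescriptor] = []
    for name, units, defn in _TIME_QUANTITIES:
        for stat in ("mean", "sd", "var"):
            u = units if stat != "var" else (units + "^2" if units not in ("-",) else "-")
            cat.append(FeatureDescriptor(f"{name}_{stat}", "time", u,
                                         f"{stat} over beats of {defn}"))
    for name, units, defn in _DERIV_QUANTITIES:
        for stat in ("mean", "sd"):
            cat.append(FeatureDescriptor(f"{name}_{stat}", "derivative", units,
                                         f"{stat} over beats of {defn}"))
    for name, units, defn in _FREQ_FEATURES:
        cat.append(FeatureDescriptor(name, "frequency", units, defn))
    for stat in _STAT_SIG:
        cat.append(FeatureDescriptor(f"sig_{stat}", "statistical", "au",
                                     f"segment {stat}"))
    cat.append(FeatureDescriptor("hjorth_mobility", "statistical", "-",
                                 "SD of first difference over SD of signal"))
    cat.append(FeatureDescriptor("hjorth_complexity", "statistical", "-",
                                 "mobility of first difference over signal mobility"))
    for stat in _STAT_D1:
        cat.append(FeatureDescriptor(f"d1_{stat}", "statistical", "au/s",
                                     f"first-derivative {stat}"))
    for stat in _STAT_D2:
        cat.append(FeatureDescriptor(f"d2_{stat}", "statistical", "au/s^2",
                                     f"second-derivative {stat}"))
    return cat


_CATALOG = feature_catalog()
_NAMES = [d.name for d in _CATALOG]
if len(_CATALOG) != 107 or len(set(_NAMES)) != 107:
    raise AssertionError(
        f"feature catalog contract violated: {len(_CATALOG)} entries, "
        f"{len(set(_NAMES))} unique names (need 107)")


def feature_names() -> list[str]:
    return list(_NAMES)


@dataclass
class FeatureVector:
    """The 107 ordered feature values for one segment (NaN = missing)."""

    values: np.ndarray
    segment_provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != 107:
            raise ValueError(f"feature vector must have 107 entries, got {self.values.size}")

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=_NAMES)


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------

def _moments(x: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    out["mean"] = float(np.mean(x))
    out["median"] = float(np.median(x))
    out["sd"] = float(np.std(x))
    out["var"] = float(np.var(x))
    sd = out["sd"]
    out["skewness"] = float(spstats.skew(x, bias=True)) if sd > 0 else 0.0
    out["kurtosis"] = float(spstats.kurtosis(x, fisher=False, bias=True)) if sd > 0 else np.nan
    out["rms"] = float(np.sqrt(np.mean(x * x)))
    out["iqr"] = float(np.subtract(*np.percentile(x, [75, 25])))
    out["mad"] = float(np.median(np.abs(x - np.median(x))))
    return out


def _shannon_entropy(x: np.ndarray, bins: int = 16) -> float:
    """Base-2 entropy of the amplitude histogram over the min-max span."""
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def _zero_crossing_rate(x: np.ndarray) -> float:
    """Crossings of the mean level per sample (scale and offset invariant)."""
    centered = x - np.mean(x)
    signs = np.sign(centered)
    signs[signs == 0] = 1
    return float(np.count_nonzero(np.diff(signs)) / max(1, x.size - 1))


def _hjorth(x: np.ndarray) -> tuple[float, float]:
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v0, v1, v2 = np.var(x), np.var(d1), np.var(d2)
    mobility = float(np.sqrt(v1 / v0)) if v0 > 0 else np.nan
    complexity = (float(np.sqrt(v2 / v1) / mobility)
                  if v1 > 0 and mobility and np.isfinite(mobility) and mobility > 0
                  else np.nan)
    return mobility, complexity


# ---------------------------------------------------------------------------
# Frequency-domain helpers
# ---------------------------------------------------------------------------

def _psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nfft = max(x.size, 1 << 15)   # zero-pad for a fine frequency grid
    f, p = sps.periodogram(x - np.mean(x), fs=fs, window="hann", nfft=nfft)
    return f, p


def _band_dominant(f: np.ndarray, p: np.ndarray, band: tuple[float, float]):
    m = (f >= band[0]) & (f <= band[1])
    if not np.any(m) or np.all(p[m] == 0):
        return np.nan, np.nan
    i = np.argmax(p[m])
    return float(f[m][i]), float(p[m][i])


def _frequency_features(x: np.ndarray, fs: float) -> dict[str, float]:
    f, p = _psd(x, fs)
    out: dict[str, float] = {}
    total = float(p.sum())
    if total <= 0:
        return {name: np.nan for name, _, _ in _FREQ_FEATURES}
    imax = int(np.argmax(p))
    out["max_frequency"] = float(f[imax])
    out["max_frequency_magnitude"] = float(p[imax])
    for band, key in ((CARDIAC_BAND, "cardiac"), (RESP_BAND, "resp")):
        fd, md = _band_dominant(f, p, band)
        out[f"{key}_dominant_frequency"] = fd
        out[f"{key}_dominant_magnitude"] = md
    peaks, props = sps.find_peaks(p, height=0.0)
    order = np.argsort(props["peak_heights"])[::-1][:3]
    top = peaks[order]
    for rank in range(3):
        if rank < top.size:
            out[f"spectral_peak{rank + 1}_freq"] = float(f[top[rank]])
            out[f"spectral_peak{rank + 1}_mag"] = float(p[top[rank]])
        else:
            out[f"spectral_peak{rank + 1}_freq"] = np.nan
            out[f"spectral_peak{rank + 1}_mag"] = np.nan
    for band, key in ((RESP_BAND, "resp"), (CARDIAC_BAND, "cardiac"),
                      (HARMONIC_BAND, "harmonic")):
        m = (f >= band[0]) & (f <= band[1])
        out[f"{key}_band_power"] = float(p[m].sum() / total)
    out["spectral_centroid"] = float((f * p).sum() / total)
    q = p[p > 0] / total
    out["spectral_entropy"] = float(-np.sum(q * np.log2(q)))
    return out


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_features(segment: PPGSegment,
                     fiducials: PulseFiducials | None = None) -> FeatureVector:
    """Compute all 107 features for one (preprocessed) segment.

    ``fiducials=None`` marks the segment unanalyzable: every beat-derived
    (time and derivative group) feature is missing, while frequency and
    statistical features are still computed from the raw samples.
    """
    x = segment.samples
    if x.size == 0:
        return FeatureVector(np.full(107, np.nan))
    values: dict[str, float] = {}

    # --- beat-derived groups ---
    if fiducials is not None and len(fiducials.beats) >= 1:
        table = beat_intervals(fiducials)
        for name, _, _ in _TIME_QUANTITIES:
            col = table[name].to_numpy(dtype=float)
            values.update(_beat_stats(name, col, with_var=True))
        for name, _, _ in _DERIV_QUANTITIES:
            col = table[name].to_numpy(dtype=float)
            values.update(_beat_stats(name, col, with_var=False))
    else:
        for name, _, _ in _TIME_QUANTITIES:
            values.update({f"{name}_mean": np.nan, f"{name}_sd": np.nan,
                           f"{name}_var": np.nan})
        for name, _, _ in _DERIV_QUANTITIES:
            values.update({f"{name}_mean": np.nan, f"{name}_sd": np.nan})

    # --- frequency group ---
    values.update(_frequency_features(x, segment.fs))

    # --- statistical group ---
    sig = _moments(x)
    for stat in _STAT_SIG:
        if stat == "entropy":
            values["sig_entropy"] = _shannon_entropy(x)
        elif stat == "zcr":
            values["sig_zcr"] = _zero_crossing_rate(x)
        else:
            values[f"sig_{stat}"] = sig[stat]
    mob, comp = _hjorth(x)
    values["hjorth_mobility"] = mob
    values["hjorth_complexity"] = comp
    d1 = np.diff(x) * segment.fs
    d2 = np.diff(x, 2) * segment.fs ** 2
    m1 = _moments(d1)
    for stat in _STAT_D1:
        values[f"d1_{stat}"] = m1[stat]
    m2 = _moments(d2)
    for stat in _STAT_D2:
        values[f"d2_{stat}"] = m2[stat] if stat != "zcr" else _zero_crossing_rate(d2)

    vec = np.array([values[name] for name in _NAMES], dtype=float)
    return FeatureVector(vec, segment_provenance={
        "record_id": segment.record_id, "start_time": segment.start_time,
        "catalog_version": CATALOG_VERSION,
    })


def _beat_stats(name: str, col: np.ndarray, *, with_var: bool) -> dict[str, float]:
    ok = col[np.isfinite(col)]   # beats with undetectable landmarks are excluded
    out: dict[str, float] = {}
    if ok.size == 0:
        out[f"{name}_mean"] = np.nan
        out[f"{name}_sd"] = np.nan
        if with_var:
            out[f"{name}_var"] = np.nan
        return out
    out[f"{name}_mean"] = float(np.mean(ok))
    out[f"{name}_sd"] = float(np.std(ok))
    if with_var:
        out[f"{name}_var"] = float(np.var(ok))
    return out


# ---------------------------------------------------------------------------
# Matrix assembly and train-only scaling
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Stacked feature vectors with aligned labels."""

    X: pd.DataFrame                  # n x 107, columns = catalog names
    labels: pd.DataFrame             # rr_label / spo2_label per row

    def __post_init__(self) -> None:
        if list(self.X.columns) != _NAMES:
            raise ValueError("feature matrix columns must match the catalog order")
        if len(self.X) != len(self.labels):
            raise ValueError("label/row count mismatch")

    @property
    def mostly_missing_columns(self) -> list[str]:
        frac = self.X.isna().mean()
        return list(frac[frac > 0.5].index)

    def to_csv(self, path) -> None:
        out = pd.concat([self.X.reset_index(drop=True),
                         self.labels.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        label_cols = [c for c in df.columns if c not in _NAMES]
        return cls(X=df[_NAMES], labels=df[label_cols])


def build_matrix(segments: SegmentSet | list[PPGSegment],
                 vectors: list[FeatureVector]) -> FeatureMatrix:
    """Stack one FeatureVector per segment, aligning labels by position."""
    segs = list(segments)
    if len(segs) != len(vectors):
        raise ValueError(f"{len(segs)} segments but {len(vectors)} feature vectors")
    X = pd.DataFrame([v.values for v in vectors], columns=_NAMES)
    labels = pd.DataFrame({
        "rr_label": [np.nan if s.rr_label is None else s.rr_label for s in segs],
        "spo2_label": [np.nan if s.spo2_label is None else s.spo2_label for s in segs],
        "record_id": [s.record_id for s in segs],
        "start_time": [s.start_time for s in segs],
    })
    return FeatureMatrix(X=X, labels=labels)


class FeatureScaler:
    """Median imputation + per-column z-scoring, fit on training rows only.

    Stores the training medians, means and SDs so validation/test rows are
    transformed with training parameters — never their own.
    """

    def __init__(self) -> None:
        self.medians_: np.ndarray | None = None
        self.means_: np.ndarray | None = None
        self.sds_: np.ndarray | None = None

    def fit(self, X: pd.DataFrame | np.ndarray) -> "FeatureScaler":
        A = np.asarray(X, dtype=float)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            self.medians_ = np.nanmedian(A, axis=0)
        self.medians_ = np.where(np.isfinite(self.medians_), self.medians_, 0.0)
        filled = np.where(np.isfinite(A), A, self.medians_)
        self.means_ = filled.mean(axis=0)
        self.sds_ = filled.std(axis=0)
        return self

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if self.medians_ is None:
            raise RuntimeError("scaler is not fitted")
        A = np.asarray(X, dtype=float)
        filled = np.where(np.isfinite(A), A, self.medians_)
        sds = np.where(self.sds_ > 0, self.sds_, 1.0)
        return (filled - self.means_) / sds

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)
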
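"""Labeled synthetic PPG with respiration- and SpO2-linked structure.

Each segment is a train of two-Gaussian beats (systolic bump + diastolic
hump) carrying the three respiratory modulations the pipeline exploits:

* frequency modulation — instantaneous heart rate hr*(1 + fm*sin(2*pi*f_R*t))
  with f_R = rr/60 Hz;
* amplitude modulation — per-beat gain A_k = 1 + am*sin(2*pi*f_R*t_k);
* baseline wander    — bw*sin(2*pi*f_R*t) added to the waveform.

SpO2 is linked to pulse morphology through a declared surrogate (a
single-channel simulator cannot encode true two-wavelength oximetry): the
diastolic-to-systolic amplitude ratio rho = 0.30 + 0.02*(100 - spo2) and a
systolic width inflated by (1 + 0.01*(100 - spo2)).  The mapping is learnable
but not trivial; it is a test scaffold, not a physiological claim.

White Gaussian noise is added at a configurable SNR and sporadic
low-frequency Gaussian bumps emulate motion artifacts.  Ground-truth beat
landmarks are located numerically on the clean waveform so detector accuracy
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import PPGSegment, SegmentSet

__all__ = ["SynthConfig", "SynthTruth", "generate_segment", "generate_corpus"]


@dataclass(frozen=True)
class SynthConfig:
    fs: float = 125.0
    duration_s: float = 32.0
    hr_bpm: float = 75.0
    rr_bpm: float = 15.0            # study population range [5, 25]
    spo2_pct: float = 97.0          # study population range [84, 100]
    am: float = 0.10                # amplitude-modulation depth
    fm: float = 0.03                # frequency-modulation depth
    bw: float = 0.15                # baseline-wander amplitude (pulse = 1)
    sigma_sys_frac: float = 0.11    # systolic Gaussian width / beat period
    sigma_dia_frac: float = 0.20    # diastolic Gaussian width / beat period
    peak_frac: float = 0.30         # systolic peak offset / beat period
    dia_frac: float = 0.55          # diastolic hump offset / beat period
    noise_snr_db: float | None = 25.0   # None = noise-free
    artifact_rate_per_min: float = 0.5
    artifact_amplitude: float = 1.5
    artifact_width_s: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0 or self.hr_bpm <= 0:
            raise ValueError("fs, duration_s and hr_bpm must be positive")
        if not (0 < self.rr_bpm <= 60):
            raise ValueError(f"rr_bpm out of range: {self.rr_bpm}")
        if not (0 < self.spo2_pct <= 100):
            raise ValueError(f"spo2_pct out of range: {self.spo2_pct}")
        for name in ("am", "fm", "bw"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")


@dataclass
class SynthTruth:
    """Programmed ground truth for one synthetic segment."""

    onset_times: np.ndarray      # s, numerically located feet of the clean waveform
    sys_peak_times: np.ndarray   # s, numerically located systolic peaks
    beat_amplitudes: np.ndarray  # per-beat AM gain A_k (aligned with sys_peak_times)
    rr_bpm: float
    spo2_pct: float
    clean: np.ndarray = field(repr=False, default=None)  # pre-noise, pre-artifact

    def __post_init__(self) -> None:
        if np.any(np.diff(self.sys_peak_times) <= 0):
            raise ValueError("landmark times must be strictly increasing")


def _beat_times(cfg: SynthConfig, t_lo: float, t_hi: float) -> np.ndarray:
    """Beat anchor times: integer crossings of the cardiac phase
    phi(t) = (hr/60) * [t - fm*(cos(2 pi f_R t) - 1)/(2 pi f_R)]."""
    f_hr = cfg.hr_bpm / 60.0
    f_r = cfg.rr_bpm / 60.0
    grid = np.linspace(t_lo, t_hi, int((t_hi - t_lo) * cfg.fs * 4) + 2)
    phi = f_hr * (grid - cfg.fm * (np.cos(2 * np.pi * f_r * grid) - 1.0) / (2 * np.pi * f_r))
    k_lo, k_hi = int(np.ceil(phi[0])), int(np.floor(phi[-1]))
    ks = np.arange(k_lo, k_hi + 1, dtype=float)
    return np.interp(ks, phi, grid)


def generate_segment(config: SynthConfig) -> tuple[PPGSegment, SynthTruth]:
    """Generate one labeled synthetic segment plus its ground truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.fs * cfg.duration_s))
    t = np.arange(n) / cfg.fs
    period = 60.0 / cfg.hr_bpm
    f_r = cfg.rr_bpm / 60.0

    rho = 0.30 + 0.02 * (100.0 - cfg.spo2_pct)
    sig_s = cfg.sigma_sys_frac * period * (1.0 + 0.01 * (100.0 - cfg.spo2_pct))
    sig_d = cfg.sigma_dia_frac * period
    tau1 = cfg.peak_frac * period
    tau2 = cfg.dia_frac * period

    # beats whose Gaussians can reach into [0, duration)
    margin = 2.0 * period + 5.0 * sig_d
    tk = _beat_times(cfg, -margin, cfg.duration_s + margin)
    amp = 1.0 + cfg.am * np.sin(2 * np.pi * f_r * tk)

    dt_s = (t[None, :] - (tk + tau1)[:, None]) / sig_s
    dt_d = (t[None, :] - (tk + tau2)[:, None]) / sig_d
    pulses = amp[:, None] * (np.exp(-0.5 * dt_s ** 2) + rho * np.exp(-0.5 * dt_d ** 2))
    clean = pulses.sum(axis=0) + cfg.bw * np.sin(2 * np.pi * f_r * t)

    # numerically locate true landmarks on the clean waveform
    peak_nom = tk + tau1
    in_seg = (peak_nom >= 0) & (peak_nom < cfg.duration_s)
    peak_times, onset_times, amps = [], [], []
    for k in np.flatnonzero(in_seg):
        i0 = max(0, int((tk[k] + tau1 - 0.5 * period) * cfg.fs))
        i1 = min(n, int((tk[k] + tau1 + 0.5 * period) * cfg.fs) + 1)
        if i1 - i0 < 3:
            continue
        ip = i0 + int(np.argmax(clean[i0:i1]))
        j0 = max(0, int((tk[k] - 0.45 * period) * cfg.fs))
        if ip - j0 < 2:
            continue
        io = j0 + int(np.argmin(clean[j0:ip]))
        peak_times.append(ip / cfg.fs)
        onset_times.append(io / cfg.fs)
        amps.append(amp[k])

    x = clean.copy()
    if cfg.noise_snr_db is not None:
        ac_rms = float(np.std(clean))
        noise_sd = ac_rms * 10.0 ** (-cfg.noise_snr_db / 20.0)
        x = x + rng.normal(0.0, noise_sd, size=n)
    n_art = rng.poisson(cfg.artifact_rate_per_min * cfg.duration_s / 60.0)
    for _ in range(n_art):
        center = rng.uniform(0.0, cfg.duration_s)
        sign = rng.choice([-1.0, 1.0])
        x = x + sign * cfg.artifact_amplitude * np.exp(
            -0.5 * ((t - center) / cfg.artifact_width_s) ** 2)

    seg = PPGSegment(samples=x, fs=cfg.fs, start_time=0.0,
                     rr_label=cfg.rr_bpm, spo2_label=cfg.spo2_pct,
                     record_id=f"synth-{cfg.seed}")
    truth = SynthTruth(
        onset_times=np.asarray(onset_times),
        sys_peak_times=np.asarray(peak_times),
        beat_amplitudes=np.asarray(amps),
        rr_bpm=cfg.rr_bpm, spo2_pct=cfg.spo2_pct, clean=clean,
    )
    return seg, truth


def generate_corpus(
    n: int,
    *,
    rr_range: tuple[float, float] = (5.0, 25.0),
    spo2_range: tuple[float, float] = (84.0, 100.0),
    hr_range: tuple[float, float] = (55.0, 95.0),
    seed: int = 0,
    base_config: SynthConfig | None = None,
) -> tuple[SegmentSet, list[SynthTruth]]:
    """n segments with RR / SpO2 / HR drawn uniformly from the given ranges.

    Per-segment seeds derive from the master seed, so corpora are fully
    reproducible and two corpora with the same seed share labels exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_config or SynthConfig()
    rng = np.random.default_rng(seed)
    rr = rng.uniform(*rr_range, size=n)
    spo2 = rng.uniform(*spo2_range, size=n)
    hr = rng.uniform(*hr_range, size=n)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    segments, truths = [], []
    for i in range(n):
        cfg = replace(base, rr_bpm=float(rr[i]), spo2_pct=float(spo2[i]),
                      hr_bpm=float(hr[i]), seed=int(child_seeds[i]))
        seg, truth = generate_segment(cfg)
        seg = replace(seg, record_id=f"synth-{seed}-{i:04d}")
        segments.append(seg)
        truths.append(truth)
    segset = SegmentSet(segments, provenance={
        "generator": "ppgvitals.synthetic", "n": n, "seed": seed,
        "rr_range": rr_range, "spo2_range": spo2_range, "hr_range": hr_range,
    })
    return segset, truths
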
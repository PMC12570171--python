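"""P-wave analysis of multi-lead ECG recordings.

The pipeline mirrors standard clinical P-wave workflows: zero-phase
low-pass/notch preprocessing, segmentation into 15-s epochs, R-peak
detection (Pan–Tompkins style), extraction of a 300-ms pre-QRS window for
every beat, correlation-based template selection and beat averaging per
lead, threshold delineation of the averaged P wave, and finally a
65-element feature vector: 5 global features (P-wave duration, PR
interval, P-terminal force in V1, FWHM, P axis) plus 5 morphological
features for each of the 12 leads (area, peak count, maximum amplitude,
Shannon entropy, sample entropy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

STANDARD_LEADS = ["I", "II", "III", "aVR", "aVL", "aVF",
                  "V1", "V2", "V3", "V4", "V5", "V6"]

LOCAL_FEATURE_NAMES = ["area", "n_peaks", "max_amplitude", "entropy",
                       "sample_entropy"]
GLOBAL_FEATURE_NAMES = ["p_duration", "pr_interval", "ptfv1", "fwhm", "p_axis"]


class EpochUnusableError(RuntimeError):
    """Raised when an epoch yields no usable beats."""


@dataclass
class EcgRecording:
    """Multichannel ECG: ``samples`` is (leads, time) in mV."""

    samples: np.ndarray
    fs: float
    lead_names: list[str]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.lead_names):
            raise ValueError("lead_names length must match number of rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.fs != 1000.0:
            warnings.warn(f"expected fs=1000 Hz, got {self.fs}", stacklevel=2)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        return self.samples[self.lead_names.index(name)]


@dataclass
class PwaveConfig:
    """Tunable parameters of the P-wave pipeline (times in ms unless noted)."""

    epoch_len_s: float = 15.0
    corr_threshold: float = 0.9
    window_pre_r_ms: float = 350.0
    window_len_ms: float = 300.0
    lp_cutoff_hz: float = 100.0
    lp_order: int = 5
    lp_ripple_db: float = 0.5
    notch_hz: float | None = 50.0
    notch_q: float = 30.0
    max_lag_ms: float = 50.0
    delineation_threshold_frac: float = 0.05
    baseline_ms: float = 40.0
    delineation_smooth_ms: float = 21.0
    delineation_snr_gate: float = 3.0
    delineation_min_run_ms: float = 10.0
    delineation_dispersion_tol_ms: float = 40.0
    entropy_bins: int = 10
    sampen_m: int = 2
    sampen_r_frac: float = 0.2
    peak_prominence_frac: float = 0.10
    r_refractory_ms: float = 200.0

    def __post_init__(self) -> None:
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must be in (0, 1]")
        if self.window_len_ms > self.window_pre_r_ms:
            raise ValueError("window_len_ms must not exceed window_pre_r_ms")


@dataclass
class PwaveTemplate:
    """Per-lead averaged P-wave windows for one epoch (leads x samples, mV)."""

    data: np.ndarray
    fs: float
    lead_names: list[str]
    epoch_index: int = 0
    n_beats_used: np.ndarray = field(default_factory=lambda: np.array([]))
    n_beats_discarded: np.ndarray = field(default_factory=lambda: np.array([]))
    template_correlations: list[np.ndarray] = field(default_factory=list)


@dataclass
class Delineation:
    onset_ms: np.ndarray          # per lead, NaN for flat leads
    offset_ms: np.ndarray
    peak_ms: np.ndarray
    baseline: np.ndarray          # per-lead baseline level, mV
    global_onset_ms: float
    global_offset_ms: float


@dataclass
class PwaveFeatures:
    """5 global + 12x5 local features; ``to_series`` flattens to 65 values."""

    p_duration: float
    pr_interval: float
    ptfv1: float | None
    fwhm: float
    p_axis: float
    local: pd.DataFrame           # index = lead, columns = LOCAL_FEATURE_NAMES

    def to_series(self, leads: list[str] = STANDARD_LEADS) -> pd.Series:
        vals = {"p_duration": self.p_duration, "pr_interval": self.pr_interval,
                "ptfv1": np.nan if self.ptfv1 is None else self.ptfv1,
                "fwhm": self.fwhm, "p_axis": self.p_axis}
        for lead in leads:
            for f in LOCAL_FEATURE_NAMES:
                key = f"{f}_{lead}"
                if lead in self.local.index:
                    vals[key] = self.local.loc[lead, f]
                else:
                    vals[key] = np.nan
        return pd.Series(vals)


# ---------------------------------------------------------------------------
# preprocessing & epoching

def preprocess(rec: EcgRecording, cfg: PwaveConfig | None = None) -> EcgRecording:
    """Notch out mains interference and low-pass filter, both zero-phase.

    The low-pass is a Chebyshev-I design (order ``lp_order``, passband
    ripple ``lp_ripple_db``) applied forward-backward so fiducial times are
    not shifted.
    """
    cfg = cfg or PwaveConfig()
    if cfg.lp_cutoff_hz >= rec.fs / 2:
        raise ValueError(
            f"low-pass cutoff {cfg.lp_cutoff_hz} Hz must be below the "
            f"Nyquist frequency {rec.fs / 2} Hz")
    x = rec.samples
    if cfg.notch_hz is not None and cfg.notch_hz < rec.fs / 2:
        b, a = sps.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.fs)
        x = sps.filtfilt(b, a, x, axis=1)
    sos = sps.cheby1(cfg.lp_order, cfg.lp_ripple_db, cfg.lp_cutoff_hz,
                     btype="low", fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    return replace(rec, samples=x)


def segment_epochs(rec: EcgRecording,
                   cfg: PwaveConfig | None = None) -> list[EcgRecording]:
    """Split into consecutive non-overlapping epochs; the remainder is dropped."""
    cfg = cfg or PwaveConfig()
    n_per = int(round(cfg.epoch_len_s * rec.fs))
    if rec.n_samples < n_per:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s is shorter than the "
            f"minimum of {cfg.epoch_len_s:.0f} s required for one epoch")
    n_epochs = rec.n_samples // n_per
    return [replace(rec, samples=rec.samples[:, k * n_per:(k + 1) * n_per])
            for k in range(n_epochs)]


# ---------------------------------------------------------------------------
# R peaks

def detect_r_peaks(epoch: EcgRecording,
                   cfg: PwaveConfig | None = None) -> np.ndarray:
    """R-peak times (ms from epoch start), Pan–Tompkins style.

    Band-pass (5–15 Hz) to emphasise the QRS, differentiate, square,
    integrate over a 150-ms moving window, then pick peaks with a 200-ms
    refractory period and refine each to the local extremum of the
    band-passed signal.
    """
    cfg = cfg or PwaveConfig()
    fs = epoch.fs
    lead = (epoch.lead("II") if "II" in epoch.lead_names
            else epoch.samples.mean(axis=0))
    if np.ptp(lead) < 1e-9:
        return np.array([])
    sos = sps.butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, lead)
    sq = np.gradient(bp) ** 2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    height = 0.2 * np.percentile(integ, 99.5)
    if height <= 0:
        return np.array([])
    locs, _ = sps.find_peaks(integ, height=height,
                             distance=int(round(cfg.r_refractory_ms / 1000 * fs)))
    # refine to the extremum of |band-passed| signal near each detection
    half = int(round(0.075 * fs))
    refined = []
    for p in locs:
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    times = np.unique(np.asarray(refined)) / fs * 1000.0
    # enforce refractory after refinement
    keep = [0]
    for i in range(1, len(times)):
        if times[i] - times[keep[-1]] >= cfg.r_refractory_ms:
            keep.append(i)
    return times[keep] if len(times) else times


# ---------------------------------------------------------------------------
# windows & template

def extract_candidate_pwaves(epoch: EcgRecording, r_times_ms: np.ndarray,
                             cfg: PwaveConfig | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat windows [R-350 ms, R-50 ms), shape (n_beats, n_leads, n_win).

    Beats whose window would leave the epoch are dropped.  Returns the
    window stack and the indices of the retained beats.
    """
    cfg = cfg or PwaveConfig()
    fs = epoch.fs
    n_win = int(round(cfg.window_len_ms / 1000 * fs))
    starts = np.round((np.asarray(r_times_ms) - cfg.window_pre_r_ms)
                      / 1000 * fs).astype(int)
    ok = (starts >= 0) & (starts + n_win <= epoch.n_samples)
    wins = np.stack([epoch.samples[:, s:s + n_win] for s in starts[ok]]) \
        if ok.any() else np.zeros((0, epoch.samples.shape[0], n_win))
    return wins, np.nonzero(ok)[0]


def _best_lag_corr(a: np.ndarray, b: np.ndarray, max_lag: int
                   ) -> tuple[float, int]:
    """Max normalized cross-correlation of two windows over lags within
    ``±max_lag`` samples, and the lag attaining it.

    The correlation at lag ``s`` is sum_t a[t+s] b[t] over the overlap,
    normalized by the overlap norms; computed for all lags at once.
    """
    a = a - a.mean()
    b = b - b.mean()
    n = len(a)
    max_lag = min(max_lag, n - 1)
    full = sps.correlate(a, b, mode="full")
    lags = np.arange(-max_lag, max_lag + 1)
    num = full[lags + n - 1]
    ca = np.concatenate(([0.0], np.cumsum(a * a)))
    cb = np.concatenate(([0.0], np.cumsum(b * b)))
    na2 = np.where(lags >= 0, ca[n] - ca[np.clip(lags, 0, n)],
                   ca[np.clip(n + lags, 0, n)])
    nb2 = np.where(lags >= 0, cb[np.clip(n - lags, 0, n)],
                   cb[n] - cb[np.clip(-lags, 0, n)])
    den = np.sqrt(na2 * nb2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 1e-15, num / den, -np.inf)
    k = int(np.argmax(r))
    if not np.isfinite(r[k]):
        return -1.0, 0
    return float(r[k]), int(lags[k])


def build_template(windows: np.ndarray, cfg: PwaveConfig | None = None,
                   fs: float = 1000.0,
                   lead_names: list[str] | None = None,
                   epoch_index: int = 0) -> PwaveTemplate:
    """Correlation-selected, lag-aligned beat average, independently per lead.

    For each lead every window is scored by its mean best-lag correlation
    with the others; the window with the highest mean is the candidate
    template, windows correlating < ``corr_threshold`` with it are
    discarded, and the survivors are aligned at their best lag and averaged.
    """
    cfg = cfg or PwaveConfig()
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3 or windows.shape[0] < 2:
        raise ValueError("need at least 2 windows of shape (n_leads, n_samples)")
    if np.ptp(windows) < 1e-12:
        raise EpochUnusableError(
            f"epoch {epoch_index}: all candidate windows are flat")
    n_beats, n_leads, n_win = windows.shape
    lead_names = lead_names or [f"lead{k}" for k in range(n_leads)]
    max_lag = int(round(cfg.max_lag_ms / 1000 * fs))

    data = np.full((n_leads, n_win), np.nan)
    used = np.zeros(n_leads, dtype=int)
    discarded = np.zeros(n_leads, dtype=int)
    corrs_all: list[np.ndarray] = []
    for li in range(n_leads):
        W = windows[:, li, :]
        R = np.eye(n_beats)
        L = np.zeros((n_beats, n_beats), dtype=int)
        for i in range(n_beats):
            for j in range(i + 1, n_beats):
                r, lag = _best_lag_corr(W[i], W[j], max_lag)
                R[i, j] = R[j, i] = r
                L[i, j], L[j, i] = lag, -lag
        mean_r = (R.sum(axis=1) - 1.0) / max(n_beats - 1, 1)
        cand = int(np.argmax(mean_r))
        corr_to_cand = R[cand].copy()
        keep = corr_to_cand >= cfg.corr_threshold
        keep[cand] = True
        corrs_all.append(corr_to_cand)
        used[li] = int(keep.sum())
        discarded[li] = n_beats - used[li]
        if used[li] == 0:
            continue
        acc = np.full((int(keep.sum()), n_win), np.nan)
        for k, bi in enumerate(np.nonzero(keep)[0]):
            # lag maximizes sum cand[t+lag]*beat[t], so cand[i] ~ beat[i-lag]
            lag = L[cand, bi]
            w = np.full(n_win, np.nan)
            if lag >= 0:
                w[lag:] = W[bi, :n_win - lag]
            else:
                w[:n_win + lag] = W[bi, -lag:]
            acc[k] = w
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            data[li] = np.nanmean(acc, axis=0)
    if int(used.sum()) == 0:
        raise EpochUnusableError(
            f"epoch {epoch_index}: all beats discarded in every lead")
    return PwaveTemplate(data=data, fs=fs, lead_names=lead_names,
                         epoch_index=epoch_index, n_beats_used=used,
                         n_beats_discarded=discarded,
                         template_correlations=corrs_all)


# ---------------------------------------------------------------------------
# delineation & features

def delineate(template: PwaveTemplate,
              cfg: PwaveConfig | None = None) -> Delineation:
    """Threshold delineation of the averaged P wave.

    Per lead, the template is lightly smoothed (Savitzky–Golay, order 2,
    ``delineation_smooth_ms`` span), the baseline is the median of the
    first ``baseline_ms`` of the window, and onset/offset are the
    first/last samples whose absolute deviation from baseline exceeds
    ``delineation_threshold_frac`` of the lead's peak deviation.  Flat
    leads, and leads whose threshold would sit below
    ``delineation_snr_gate`` times the residual noise level (estimated
    from the baseline segment), are excluded from the global extremes —
    otherwise one noisy low-amplitude lead inflates the global duration
    to the full window.  The global onset (offset) is the earliest
    (latest) surviving per-lead value.
    """
    cfg = cfg or PwaveConfig()
    fs = template.fs
    nb = int(round(cfg.baseline_ms / 1000 * fs))
    n_leads, n_win = template.data.shape
    span = int(round(cfg.delineation_smooth_ms / 1000 * fs)) | 1
    onset = np.full(n_leads, np.nan)
    offset = np.full(n_leads, np.nan)
    peak = np.full(n_leads, np.nan)
    base = np.full(n_leads, np.nan)
    snr_ok = np.zeros(n_leads, dtype=bool)
    for li in range(n_leads):
        x = template.data[li]
        if np.any(np.isnan(x)):
            continue
        if span >= 5 and n_win > span:
            x = sps.savgol_filter(x, span, 2)
        b = float(np.median(x[:nb]))
        noise_sd = float(np.std(x[:nb]))
        dev = np.abs(x - b)
        pk = float(dev.max())
        if pk < 1e-9:
            continue   # flat lead: excluded from global extremes
        thr = cfg.delineation_threshold_frac * pk
        # debounce: only above-threshold runs of at least min_run_ms count,
        # so isolated noise excursions cannot set the onset or offset
        min_run = max(1, int(round(cfg.delineation_min_run_ms / 1000 * fs)))
        above = dev >= thr
        edges = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        long_runs = (ends - starts) >= min_run
        if not long_runs.any():
            continue
        onset[li] = starts[long_runs][0] / fs * 1000.0
        offset[li] = (ends[long_runs][-1] - 1) / fs * 1000.0
        peak[li] = int(np.argmax(dev)) / fs * 1000.0
        base[li] = b
        snr_ok[li] = thr >= cfg.delineation_snr_gate * noise_sd
    if np.all(np.isnan(onset)):
        raise ValueError("flat template: no lead could be delineated")
    use = snr_ok if snr_ok.any() else np.isfinite(onset)
    # cross-lead consistency: physiological inter-lead P dispersion is a few
    # tens of ms, so leads whose delineation strays far beyond the median
    # interval carry template artifacts, not signal
    tol = cfg.delineation_dispersion_tol_ms
    med_on = float(np.nanmedian(onset[use]))
    med_off = float(np.nanmedian(offset[use]))
    with np.errstate(invalid="ignore"):
        consistent = use & (onset >= med_on - tol) & (offset <= med_off + tol)
    if consistent.any():
        use = consistent
    return Delineation(onset_ms=onset, offset_ms=offset, peak_ms=peak,
                       baseline=base,
                       global_onset_ms=float(np.nanmin(onset[use])),
                       global_offset_ms=float(np.nanmax(offset[use])))


def _signed_dev(x: np.ndarray, baseline: float) -> np.ndarray:
    """Deviation from baseline, flipped so the dominant excursion is positive."""
    d = x - baseline
    return d if abs(d.max()) >= abs(d.min()) else -d


def global_features(template: PwaveTemplate, delin: Delineation,
                    cfg: PwaveConfig | None = None,
                    qrs_onset_ms: float | None = None) -> dict:
    """P-wave duration, PR interval, PTFV1, FWHM and frontal-plane P axis.

    ``qrs_onset_ms`` is the QRS-onset time on the window clock; by default
    the end of the 300-ms window (i.e. R - 50 ms) is used as a proxy.
    """
    cfg = cfg or PwaveConfig()
    fs = template.fs
    dt = 1000.0 / fs
    n_win = template.data.shape[1]
    if qrs_onset_ms is None:
        qrs_onset_ms = n_win * dt
    p_duration = delin.global_offset_ms - delin.global_onset_ms
    pr_interval = qrs_onset_ms - delin.global_onset_ms

    # PTFV1: signed area of the terminal negative deflection in V1
    ptfv1: float | None
    if "V1" in template.lead_names:
        li = template.lead_names.index("V1")
        if np.isnan(delin.onset_ms[li]):
            ptfv1 = 0.0
        else:
            i0 = int(round(delin.onset_ms[li] / dt))
            i1 = int(round(delin.offset_ms[li] / dt))
            seg = template.data[li, i0:i1 + 1] - delin.baseline[li]
            neg = np.nonzero(seg < 0)[0]
            if len(neg) and neg[-1] == len(seg) - 1:
                # walk back to the start of the terminal negative run
                j = len(seg) - 1
                while j > 0 and seg[j - 1] < 0:
                    j -= 1
                ptfv1 = float(np.trapezoid(seg[j:], dx=dt))
            else:
                ptfv1 = 0.0
    else:
        ptfv1 = None

    # FWHM on the dominant lead (largest peak deviation)
    devs = []
    for li in range(template.data.shape[0]):
        if np.isnan(delin.onset_ms[li]):
            devs.append(-np.inf)
        else:
            devs.append(np.nanmax(np.abs(template.data[li] - delin.baseline[li])))
    dom = int(np.argmax(devs))
    d = _signed_dev(template.data[dom], delin.baseline[dom])
    fwhm = float(np.sum(d > 0.5 * d.max()) * dt)

    # P axis from net areas in leads I and aVF
    p_axis = np.nan
    if "I" in template.lead_names and "aVF" in template.lead_names:
        areas = {}
        for name in ("I", "aVF"):
            li = template.lead_names.index(name)
            if np.isnan(delin.onset_ms[li]):
                areas[name] = np.nan
                continue
            i0 = int(round(delin.onset_ms[li] / dt))
            i1 = int(round(delin.offset_ms[li] / dt))
            areas[name] = float(np.trapezoid(
                template.data[li, i0:i1 + 1] - delin.baseline[li], dx=dt))
        if np.isfinite(areas["I"]) and np.isfinite(areas["aVF"]):
            p_axis = float(np.degrees(np.arctan2(areas["aVF"], areas["I"])))

    return {"p_duration": p_duration, "pr_interval": pr_interval,
            "ptfv1": ptfv1, "fwhm": fwhm, "p_axis": p_axis}


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_frac: float = 0.2) -> float:
    """Sample entropy: -ln(A/B) with template length m, tolerance r
    (default ``r_frac`` times the SD), Chebyshev distance, self-matches
    excluded.  NaN when no template pairs match."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if r is None:
        r = r_frac * float(np.std(x))
    if n <= m + 1 or r <= 0:
        return np.nan

    def count(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        iu = np.triu_indices(len(emb), k=1)
        return int(np.sum(d[iu] <= r))

    B = count(m)
    A = count(m + 1)
    if B == 0 or A == 0:
        return np.nan
    return float(-np.log(A / B))


def local_features(lead_signal: np.ndarray, onset_ms: float, offset_ms: float,
                   baseline: float, fs: float = 1000.0,
                   cfg: PwaveConfig | None = None) -> dict:
    """Area, peak count, max amplitude, Shannon entropy and sample entropy
    of the delineated P segment of one lead."""
    cfg = cfg or PwaveConfig()
    nanrow = {f: np.nan for f in LOCAL_FEATURE_NAMES}
    if not np.isfinite(onset_ms) or not np.isfinite(offset_ms) \
            or offset_ms <= onset_ms:
        return nanrow
    dt = 1000.0 / fs
    i0, i1 = int(round(onset_ms / dt)), int(round(offset_ms / dt))
    seg = np.asarray(lead_signal[i0:i1 + 1], dtype=float) - baseline
    if len(seg) < 2:
        return nanrow
    area = float(np.trapezoid(seg, dx=dt))
    max_amp = float(np.max(np.abs(seg)))
    if max_amp < 1e-12:
        n_peaks = 0
    else:
        pk, _ = sps.find_peaks(seg, prominence=cfg.peak_prominence_frac * max_amp)
        n_peaks = int(len(pk))
    # Shannon entropy (nats) of the amplitude histogram; a zero-range
    # (constant) segment occupies a single bin -> entropy 0
    if np.ptp(seg) < 1e-15:
        entropy = 0.0
    else:
        counts, _ = np.histogram(seg, bins=cfg.entropy_bins)
        p = counts[counts > 0] / counts.sum()
        entropy = float(-np.sum(p * np.log(p)))
    sampen = sample_entropy(seg, m=cfg.sampen_m, r_frac=cfg.sampen_r_frac)
    return {"area": area, "n_peaks": n_peaks, "max_amplitude": max_amp,
            "entropy": entropy, "sample_entropy": sampen}


def epoch_features(template: PwaveTemplate,
                   cfg: PwaveConfig | None = None) -> PwaveFeatures:
    """Full 65-value feature set for one epoch's averaged P waves."""
    cfg = cfg or PwaveConfig()
    delin = delineate(template, cfg)
    g = global_features(template, delin, cfg)
    rows = {}
    for li, name in enumerate(template.lead_names):
        rows[name] = local_features(template.data[li], delin.onset_ms[li],
                                    delin.offset_ms[li], delin.baseline[li]
                                    if np.isfinite(delin.baseline[li]) else 0.0,
                                    fs=template.fs, cfg=cfg)
    local = pd.DataFrame.from_dict(rows, orient="index")[LOCAL_FEATURE_NAMES]
    return PwaveFeatures(p_duration=g["p_duration"],
                         pr_interval=g["pr_interval"], ptfv1=g["ptfv1"],
                         fwhm=g["fwhm"], p_axis=g["p_axis"], local=local)


def average_over_epochs(features: list[PwaveFeatures],
                        leads: list[str] = STANDARD_LEADS
                        ) -> tuple[pd.Series, pd.Series]:
    """Patient-level features: NaN-skipping mean across epochs.

    Returns the averaged 65-value series and the per-feature count of
    epochs that contributed.
    """
    if len(features) == 0:
        raise ValueError("no valid epochs to average")
    table = pd.DataFrame([f.to_series(leads) for f in features])
    return table.mean(axis=0, skipna=True), table.notna().sum(axis=0)


def process_recording(rec: EcgRecording, cfg: PwaveConfig | None = None
                      ) -> tuple[pd.Series, dict]:
    """End-to-end pipeline for one patient: preprocess, epoch, template,
    delineate, feature-extract, average.  Returns (features, QC dict)."""
    cfg = cfg or PwaveConfig()
    filtered = preprocess(rec, cfg)
    epochs = segment_epochs(filtered, cfg)
    feats: list[PwaveFeatures] = []
    qc = {"n_epochs": len(epochs), "n_epochs_valid": 0,
          "n_beats_used": 0, "n_beats_discarded": 0}
    for k, ep in enumerate(epochs):
        r = detect_r_peaks(ep, cfg)
        if len(r) < 2:
            continue
        wins, _ = extract_candidate_pwaves(ep, r, cfg)
        if len(wins) < 2:
            continue
        try:
            tpl = build_template(wins, cfg, fs=ep.fs,
                                 lead_names=ep.lead_names, epoch_index=k)
            feats.append(epoch_features(tpl, cfg))
        except (EpochUnusableError, ValueError):
            continue
        qc["n_epochs_valid"] += 1
        qc["n_beats_used"] += int(tpl.n_beats_used.max())
        qc["n_beats_discarded"] += int(tpl.n_beats_discarded.max())
    if not feats:
        raise EpochUnusableError(f"patient {rec.patient_id}: no usable epochs")
    avg, counts = average_over_epochs(feats, rec.lead_names)
    qc["feature_epoch_counts"] = counts
    return avg, qc
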
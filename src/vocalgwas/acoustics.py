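"""Estimation of f0 contours and formant tracks from audio.

Pitch is tracked with a windowed, normalized autocorrelation (Boersma-style
lag-domain normalization by the window autocorrelation), with sex-specific
search ranges (60-220 Hz male, 100-300 Hz female) and window lengths
(60/40 ms), parabolic peak interpolation, and a voicing threshold on the
normalized peak. Contours are refined by linear interpolation of missing
frames, a 5-point running median, and removal of outliers beyond
k x scaled-MAD from the contour median, in that order.

Formants are estimated by Burg linear prediction after resampling to
twice the sex-specific maximum formant frequency (5000 Hz male, 5500 Hz
female) and first-difference pre-emphasis, with 25 ms frames every 10 ms.
Pole candidates with bandwidth < 400 Hz inside (50 Hz, max formant) are
sorted ascending into F1..F5. Summaries are taken over frames whose
linear RMS intensity exceeds half the utterance maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal
from statsmodels.regression.linear_model import burg

from .audio import AudioSegment, EmptyAudioError

SEX_PITCH_RANGE = {"male": (60.0, 220.0), "female": (100.0, 300.0)}
SEX_PITCH_WINDOW = {"male": 0.060, "female": 0.040}
SEX_MAX_FORMANT = {"male": 5000.0, "female": 5500.0}

VOICING_THRESHOLD = 0.45  # normalized autocorrelation peak magnitude
MAD_K = 3.0
MAD_SCALE = 1.4826  # consistency factor for Gaussian data
LPC_ORDER = 10  # 2 poles per formant x 5 formants
MAX_CANDIDATE_BANDWIDTH = 400.0
PREEMPHASIS_HZ = 50.0
FORMANT_WINDOW_S = 0.025
FORMANT_STEP_S = 0.010
N_FORMANTS = 5


@dataclass
class PitchContour:
    """Per-frame f0 (NaN where unvoiced/missing) on a strictly increasing
    frame-time grid."""

    frame_times: np.ndarray
    f0: np.ndarray  # Hz, NaN = unvoiced or removed
    voiced: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def values(self) -> np.ndarray:
        """Retained (voiced, non-missing) f0 values."""
        return self.f0[~np.isnan(self.f0)]


@dataclass
class PitchSummary:
    f0_median: float
    f0_sd: float
    f0_skew: float
    n_frames: int


@dataclass
class FormantTrack:
    frame_times: np.ndarray
    formants: np.ndarray  # (n_frames, N_FORMANTS), NaN = missing
    intensity: np.ndarray  # per-frame linear RMS


@dataclass
class FormantSummary:
    """Median and SD of F1-F4 over intensity-gated frames (Hz)."""

    medians: np.ndarray  # length 4, NaN where unavailable
    sds: np.ndarray
    n_frames: int


def trim_silence(seg: AudioSegment, threshold_db: float = -25.0,
                 min_run_ms: float = 100.0) -> AudioSegment:
    """Drop low-energy edges and internal pauses longer than min_run_ms.

    Frame RMS (10 ms frames) is compared against the loudest frame;
    frames more than |threshold_db| below it are silent. Edge silence is
    always removed; internal silent runs are removed only when longer
    than ``min_run_ms`` (short gaps are part of normal phonation).
    """
    frame = max(1, int(round(0.010 * seg.rate)))
    n_frames = seg.samples.size // frame
    if n_frames == 0:
        return seg
    x = seg.samples[: n_frames * frame].reshape(n_frames, frame)
    rms = np.sqrt(np.mean(x ** 2, axis=1))
    peak = rms.max()
    if peak <= 0:
        raise EmptyAudioError("input is fully silent")
    silent = 20.0 * np.log10(np.maximum(rms, 1e-12) / peak) < threshold_db
    if silent.all():
        raise EmptyAudioError("input is fully silent at the given threshold")

    keep = np.ones(n_frames, dtype=bool)
    min_run = max(1, int(round(min_run_ms / 10.0)))
    run_start = None
    for i in range(n_frames + 1):
        is_sil = silent[i] if i < n_frames else False
        if is_sil and run_start is None:
            run_start = i
        elif not is_sil and run_start is not None:
            run_len = i - run_start
            at_edge = run_start == 0 or i == n_frames
            if at_edge or run_len >= min_run:
                keep[run_start:i] = False
            run_start = None

    mask = np.repeat(keep, frame)
    tail = seg.samples[n_frames * frame:]
    samples = np.concatenate([seg.samples[: n_frames * frame][mask], tail])
    if samples.size == 0:
        raise EmptyAudioError("trimming removed all audio")
    return seg.with_samples(samples)


def _autocorr_fft(frame: np.ndarray) -> np.ndarray:
    n = frame.size
    nfft = 1 << (2 * n - 1).bit_length()
    spec = np.fft.rfft(frame, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    return ac


def estimate_f0_contour(seg: AudioSegment, sex: str,
                        window_s: float | None = None,
                        overlap_s: float = 0.010,
                        voicing_threshold: float = VOICING_THRESHOLD) -> PitchContour:
    """Sliding-window normalized-autocorrelation pitch tracking.

    The hop is window - overlap (the overlap read literally as the
    shared duration between consecutive windows). Frames whose best
    normalized peak falls below the voicing threshold, or whose
    frequency falls outside the sex-specific range, are unvoiced.
    """
    f_min, f_max = SEX_PITCH_RANGE[sex]
    window_s = SEX_PITCH_WINDOW[sex] if window_s is None else window_s
    win = int(round(window_s * seg.rate))
    hop = max(1, win - int(round(overlap_s * seg.rate)))
    if seg.samples.size < win:
        raise ValueError("segment shorter than one analysis window")

    lag_min = int(math.floor(seg.rate / f_max))
    lag_max = int(math.ceil(seg.rate / f_min))
    taper = np.hanning(win)
    # Lag-domain normalization: autocorrelation of the window itself.
    win_ac = _autocorr_fft(taper)
    win_ac = win_ac / win_ac[0]

    times, f0s, voiced = [], [], []
    for start in range(0, seg.samples.size - win + 1, hop):
        frame = seg.samples[start: start + win]
        frame = (frame - frame.mean()) * taper
        ac = _autocorr_fft(frame)
        if ac[0] <= 0:
            times.append((start + win / 2) / seg.rate)
            f0s.append(np.nan)
            voiced.append(False)
            continue
        r = ac / ac[0]
        hi = min(lag_max + 1, win - 1)
        r_norm = r[: hi].copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            r_norm = np.where(win_ac[: hi] > 1e-6, r_norm / win_ac[: hi], 0.0)
        # Candidate peaks = local maxima in the lag search range; an
        # octave cost (0.05 per octave below the range ceiling) breaks
        # ties in favor of shorter lags, suppressing subharmonic errors.
        interior = np.arange(max(lag_min, 1), min(hi - 1, r_norm.size - 1))
        is_peak = (r_norm[interior] >= r_norm[interior - 1]) & (
            r_norm[interior] > r_norm[interior + 1]
        )
        cands = interior[is_peak & (r_norm[interior] >= voicing_threshold)]
        f0 = np.nan
        ok = cands.size > 0
        if ok:
            scores = r_norm[cands] - 0.05 * np.log2((seg.rate / cands) ** -1 * f_max)
            k = int(cands[np.argmax(scores)])
            peak = r_norm[k]
        if ok:
            # Parabolic interpolation around the peak lag.
            y0, y1, y2 = r_norm[k - 1], r_norm[k], r_norm[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            lag = k + float(np.clip(delta, -1, 1))
            cand = seg.rate / lag
            if f_min <= cand <= f_max:
                f0 = cand
            else:
                ok = False
        times.append((start + win / 2) / seg.rate)
        f0s.append(f0)
        voiced.append(bool(ok))
    return PitchContour(np.asarray(times), np.asarray(f0s), np.asarray(voiced))


def refine_contour(c: PitchContour, mad_k: float = MAD_K) -> PitchContour:
    """Interpolate -> 5-point median filter -> MAD outlier removal.

    Interior missing values are linearly interpolated (edges stay
    missing); the running median uses nearest-edge padding; values more
    than ``mad_k`` scaled MADs from the contour median are set missing.
    """
    if c.values.size == 0:
        raise ValueError("contour has no voiced frames")
    f0 = c.f0.copy()
    good = ~np.isnan(f0)
    idx = np.arange(f0.size)
    first, last = idx[good][0], idx[good][-1]
    interior = (idx >= first) & (idx <= last)
    f0[interior] = np.interp(idx[interior], idx[good], f0[good])

    smoothed = f0.copy()
    smoothed[interior] = ndimage.median_filter(
        f0[interior], size=5, mode="nearest"
    )

    vals = smoothed[~np.isnan(smoothed)]
    med = np.median(vals)
    mad = MAD_SCALE * np.median(np.abs(vals - med))
    out = smoothed.copy()
    # mad == 0 (majority exactly at the median) degenerates to the
    # strict limit of the rule: any deviation from the median is out.
    out[np.abs(smoothed - med) > mad_k * mad] = np.nan
    return PitchContour(c.frame_times, out, ~np.isnan(out))


def summarize_pitch(c: PitchContour) -> PitchSummary | None:
    """Median, sample SD and Fisher-Pearson skewness of retained f0.

    Returns None (a missing-measure marker that propagates to
    completeness QC) when fewer than 3 values remain.
    """
    v = c.values
    if v.size < 3:
        return None
    m = v.mean()
    m2 = np.mean((v - m) ** 2)
    m3 = np.mean((v - m) ** 3)
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    return PitchSummary(
        f0_median=float(np.median(v)),
        f0_sd=float(np.std(v, ddof=1)),
        f0_skew=float(skew),
        n_frames=int(v.size),
    )


def _resample_to(seg: AudioSegment, target_rate: float) -> tuple[np.ndarray, float]:
    if abs(seg.rate - target_rate) < 1e-9:
        return seg.samples, seg.rate
    frac = Fraction(target_rate / seg.rate).limit_denominator(1000)
    x = signal.resample_poly(seg.samples, frac.numerator, frac.denominator)
    actual = seg.rate * frac.numerator / frac.denominator
    return x, actual


def _gaussian_window(n: int) -> np.ndarray:
    # Praat-style Gaussian taper: exp(-48 ((t - 1/2)/T)^2), rescaled to
    # vanish at the edges.
    t = (np.arange(n) + 0.5) / n
    w = np.exp(-48.0 * (t - 0.5) ** 2)
    return (w - math.exp(-12.0)) / (1.0 - math.exp(-12.0))


def estimate_formant_track(seg: AudioSegment, sex: str,
                           max_formant: float | None = None) -> FormantTrack:
    """Burg-LPC formant tracking with sex-specific maximum formant.

    The stated 25 ms window is the effective (half-power) duration of
    the Gaussian taper; the physical analysis window is twice that,
    following Praat's convention. Pre-emphasis is applied to the whole
    resampled signal before framing.
    """
    max_formant = SEX_MAX_FORMANT[sex] if max_formant is None else max_formant
    x, rate = _resample_to(seg, 2.0 * max_formant)
    win = int(round(2.0 * FORMANT_WINDOW_S * rate))
    hop = max(1, int(round(FORMANT_STEP_S * rate)))
    if x.size < win:
        raise ValueError("segment shorter than the formant analysis window")

    alpha = math.exp(-2.0 * math.pi * PREEMPHASIS_HZ / rate)
    pre_all = np.append(x[0] * (1.0 - alpha), x[1:] - alpha * x[:-1])
    taper = _gaussian_window(win)

    times, rows, intens = [], [], []
    for start in range(0, x.size - win + 1, hop):
        frame = x[start: start + win]
        intens.append(float(np.sqrt(np.mean(frame ** 2))))
        pre = pre_all[start: start + win]
        w = (pre - pre.mean()) * taper
        row = np.full(N_FORMANTS, np.nan)
        if np.any(w != 0):
            try:
                ar, _ = burg(w, order=LPC_ORDER, demean=False)
                roots = np.roots(np.concatenate([[1.0], -ar]))
            except (np.linalg.LinAlgError, ValueError):
                roots = np.array([])
            cands = []
            for root in roots:
                if root.imag <= 0:
                    continue
                freq = math.atan2(root.imag, root.real) * rate / (2.0 * math.pi)
                mag = abs(root)
                if mag >= 1.0 or mag <= 0.0:
                    continue
                bw = -math.log(mag) * rate / math.pi
                if 50.0 < freq < max_formant and bw < MAX_CANDIDATE_BANDWIDTH:
                    cands.append(freq)
            for i, f in enumerate(sorted(cands)[:N_FORMANTS]):
                row[i] = f
        rows.append(row)
        times.append((start + win / 2) / rate)
    return FormantTrack(np.asarray(times), np.asarray(rows), np.asarray(intens))


def gate_and_summarize_formants(t: FormantTrack,
                                gate_fraction: float = 0.5) -> FormantSummary | None:
    """Median/SD of F1-F4 over frames with RMS >= gate_fraction x max.

    Each formant is summarized over the gated frames where it is
    present; a formant missing everywhere yields NaN summaries. Returns
    None when no frame passes the gate.
    """
    if t.intensity.size == 0:
        return None
    gate = t.intensity >= gate_fraction * t.intensity.max()
    if not gate.any():
        return None
    sub = t.formants[gate][:, :4]
    medians = np.full(4, np.nan)
    sds = np.full(4, np.nan)
    for i in range(4):
        col = sub[:, i]
        col = col[~np.isnan(col)]
        if col.size:
            medians[i] = np.median(col)
            sds[i] = np.std(col, ddof=1) if col.size > 1 else 0.0
    if np.all(np.isnan(medians)):
        return None
    return FormantSummary(medians=medians, sds=sds, n_frames=int(gate.sum()))
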
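"""Preprocessing: filtering, EMD denoising, burst detection, windowing, RR.

The preprocessing chain applied to a recording before feature extraction:

1. zero-phase Butterworth band-pass: 20-250 Hz for EMG, 0.1-250 Hz for ECG
   (the upper edge is clipped to 0.99 x Nyquist when the sampling rate puts
   250 Hz at or above Nyquist);
2. additional empirical-mode-decomposition (EMD) denoising of the EMG:
   leading intrinsic mode functions whose energies follow the geometric
   decay expected of broadband noise are discarded before reconstruction;
3. cutting of labelled windows: a 5.5 s "pain window" anchored at each
   stimulus onset (4 s plateau + 1.5 s after) and equally long "non-pain
   windows" at the scheduled baseline onsets;
4. Hilbert-envelope burst detection on the band-passed EMG (diagnostic);
5. R-peak detection on the filtered ECG via derivative-energy peak picking
   with a 250 ms refractory period, yielding the RR interval series.

SCL is not band-pass filtered; it is detrended per window where the
frequency-domain features require it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from painfeat.core import LabeledWindow, Recording, StimulusSchedule

log = logging.getLogger(__name__)

EMG_BAND = (20.0, 250.0)
ECG_BAND = (0.1, 250.0)


@dataclass
class RRSeries:
    """Interbeat (RR) intervals in milliseconds plus the beat times."""

    rr_ms: np.ndarray
    beat_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if len(self.beat_times_s) >= 1 and len(self.rr_ms) != len(self.beat_times_s) - 1:
            raise ValueError("need len(rr_ms) == len(beat_times_s) - 1")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")

    @property
    def n_beats(self) -> int:
        return len(self.beat_times_s)

    def in_window(self, t0: float, t1: float) -> "RRSeries":
        """RR intervals whose defining beats both fall in [t0, t1)."""
        m = (self.beat_times_s >= t0) & (self.beat_times_s < t1)
        beats = self.beat_times_s[m]
        if len(beats) < 2:
            return RRSeries(np.empty(0), beats)
        return RRSeries(np.diff(beats) * 1000.0, beats)


def butterworth_bandpass(x: np.ndarray, fs: float, lo_hz: float, hi_hz: float,
                         order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass, length-preserving.

    ``hi_hz`` is clipped to 0.99 x Nyquist with a warning when the requested
    band touches or exceeds Nyquist.
    """
    nyq = fs / 2.0
    if not (0 < lo_hz < hi_hz):
        raise ValueError(f"invalid band ({lo_hz}, {hi_hz})")
    if hi_hz >= nyq:
        clipped = 0.99 * nyq
        warnings.warn(
            f"band edge {hi_hz} Hz >= Nyquist ({nyq} Hz); clipping to {clipped:.1f} Hz",
            stacklevel=2)
        hi_hz = clipped
    if lo_hz >= hi_hz:
        raise ValueError(f"band collapsed after Nyquist clipping: ({lo_hz}, {hi_hz})")
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# empirical mode decomposition
# ---------------------------------------------------------------------------

def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau -> first sample)."""
    d = np.diff(x)
    s = np.sign(d)
    # carry the sign over zero-runs so plateaus register a single extremum;
    # a leading plateau takes the first nonzero sign (boundary plateaus are
    # not extrema in either direction)
    zeros = s == 0
    if zeros.any():
        nz = np.where(~zeros)[0]
        if len(nz) == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        idx = np.where(~zeros, np.arange(len(s)), 0)
        np.maximum.accumulate(idx, out=idx)
        s = s[idx]
        s[: nz[0]] = s[nz[0]]
    flips = np.diff(s)
    maxima = np.where(flips < 0)[0] + 1
    minima = np.where(flips > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through x[idx] with mirrored end conditions."""
    n = len(x)
    # mirror the outermost extrema so the spline does not swing at the edges
    xi = np.concatenate(([-idx[0] - 1], idx, [2 * n - idx[-1] - 1])).astype(float)
    yi = np.concatenate(([x[idx[0]]], x[idx], [x[idx[-1]]]))
    return CubicSpline(xi, yi)(np.arange(n))


def emd(x: np.ndarray, max_imf: int = 8, max_sift: int = 6,
        sd_thresh: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Empirical mode decomposition via standard sifting.

    Returns ``(imfs, residual)`` where ``imfs`` has shape (k, n).  Sifting of
    each mode stops on the Cauchy-type criterion SD < ``sd_thresh`` or after
    ``max_sift`` iterations; decomposition stops when fewer than two maxima
    or minima remain or ``max_imf`` modes were extracted.
    """
    x = np.asarray(x, dtype=float)
    residual = x.copy()
    imfs = []
    for _ in range(max_imf):
        maxima, minima = _local_extrema(residual)
        if len(maxima) < 2 or len(minima) < 2:
            break
        h = residual
        for _ in range(max_sift):
            mx, mn = _local_extrema(h)
            if len(mx) < 2 or len(mn) < 2:
                break
            mean_env = 0.5 * (_envelope(h, mx) + _envelope(h, mn))
            h_new = h - mean_env
            denom = np.sum(h ** 2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_thresh:
                break
        imfs.append(h)
        residual = residual - h
    return np.asarray(imfs), residual


def _noise_imf_count(energies: np.ndarray, sig_ratio: float = 0.1) -> int:
    """Number of leading IMFs attributable to broadband noise.

    Broadband noise spreads over the leading modes with monotonically
    decaying energies (roughly geometric), whereas a narrowband signal
    concentrates in one mode and breaks the decay.  Two guards:

    * if E2/E1 < ``sig_ratio`` the first mode is itself signal-dominated
      (its energy decays far faster than any noise cascade) — discard
      nothing;
    * otherwise discard the leading modes up to the first energy increase
      (the first signal-bearing mode); a fully monotone cascade discards
      only the first mode (conservative: at most the top octave goes).
    """
    k = len(energies)
    if k < 2 or energies[0] <= 0:
        return 0
    if energies[1] / energies[0] < sig_ratio:
        return 0
    for i in range(1, k):
        if energies[i] > energies[i - 1]:
            return i  # modes 0..i-1 are the noise cascade
    return 1


def emd_denoise(x: np.ndarray, fs: float, max_imf: int = 5,
                sig_ratio: float = 0.1) -> np.ndarray:
    """EMD-based denoising: drop leading noise-attributed IMFs, reconstruct.

    The reconstruction subtracts only the discarded leading modes from the
    original signal, so only the first ``max_imf`` modes are ever sifted —
    noise occupies the leading modes, and everything below passes through
    inside the implicit residual.  On decomposition failure (no oscillatory
    modes, e.g. a constant input) the signal is returned unchanged with a
    logged warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise ValueError("emd_denoise needs at least 64 samples")
    try:
        imfs, _ = emd(x, max_imf=max_imf)
    except Exception as exc:  # pragma: no cover - defensive
        log.warning("EMD failed (%s); passing signal through", exc)
        return x.copy()
    if len(imfs) == 0:
        log.warning("EMD produced no modes; passing signal through")
        return x.copy()
    energies = np.sum(imfs ** 2, axis=1)
    n_drop = _noise_imf_count(energies, sig_ratio=sig_ratio)
    n_drop = min(n_drop, len(imfs) - 1)  # never discard every mode
    if n_drop == 0:
        return x.copy()
    return x - np.sum(imfs[:n_drop], axis=0)


# ---------------------------------------------------------------------------
# burst detection
# ---------------------------------------------------------------------------

def detect_bursts_hilbert(x: np.ndarray, fs: float, k: float = 3.5,
                          min_dur_s: float = 0.1, smooth_s: float = 0.05
                          ) -> list[tuple[float, float]]:
    """EMG burst detection from the smoothed Hilbert (analytic) envelope.

    The envelope is smoothed with a ``smooth_s`` moving average; samples
    where it exceeds mu_baseline + k * sigma_baseline for at least
    ``min_dur_s`` form a burst.  Baseline statistics are the median and the
    MAD-based robust sigma of the envelope, so bursts themselves do not
    inflate the threshold.  Returns ordered, non-overlapping
    ``(onset_s, offset_s)`` pairs (possibly empty).
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0 or np.all(x == 0):
        return []
    env = np.abs(sps.hilbert(x))
    w = max(int(round(smooth_s * fs)), 1)
    env = np.convolve(env, np.ones(w) / w, mode="same")

    mu = float(np.median(env))
    sd = 1.4826 * float(np.median(np.abs(env - mu)))
    if sd == 0:
        return []
    above = env > mu + k * sd

    bursts: list[tuple[float, float]] = []
    min_n = max(int(round(min_dur_s * fs)), 1)
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    for a, b in zip(starts, ends):
        if b - a >= min_n:
            bursts.append((a / fs, b / fs))
    return bursts


# ---------------------------------------------------------------------------
# windowing and RR detection
# ---------------------------------------------------------------------------

def cut_windows(recording: Recording, schedule: StimulusSchedule,
                window_s: float = 5.5) -> list[LabeledWindow]:
    """Cut onset-anchored pain windows and baseline non-pain windows.

    The standard protocol yields 100 windows per subject (20 x B, T1..T4).
    Windows that would run past the end of the recording are dropped with a
    logged warning.
    """
    fs = recording.fs
    n_win = int(round(window_s * fs))
    n_total = recording.n_samples
    out: list[LabeledWindow] = []
    items = [(ev.level, ev.onset_s) for ev in schedule.events]
    items += [("B", b) for b in schedule.baseline_windows]
    for label, onset in sorted(items, key=lambda it: it[1]):
        i0 = int(round(onset * fs))
        if i0 + n_win > n_total:
            log.warning("window %s@%.2fs exceeds recording end; dropped", label, onset)
            continue
        segs = {recording.channel_role[name]: arr[i0:i0 + n_win]
                for name, arr in recording.channels.items()}
        out.append(LabeledWindow(subject_id=recording.subject_id, class_label=label,
                                 segments=segs, fs=fs, onset_s=onset, window_s=window_s))
    return out


def detect_rr(ecg: np.ndarray, fs: float, refractory_s: float = 0.25,
              smooth_s: float = 0.02, rel_height: float = 0.3) -> RRSeries:
    """R-peak detection by derivative-energy peak picking.

    The squared first difference is smoothed (``smooth_s`` moving average)
    and peaks above ``rel_height`` x max with a ``refractory_s`` minimum
    separation are taken as beats.  Fewer than two beats yields an empty
    series (downstream RR features then carry sentinels).
    """
    x = np.asarray(ecg, dtype=float)
    if len(x) < 3:
        return RRSeries(np.empty(0), np.empty(0))
    e = np.diff(x) ** 2
    w = max(int(round(smooth_s * fs)), 1)
    e = np.convolve(e, np.ones(w) / w, mode="same")
    top = e.max()
    if top <= 0:
        return RRSeries(np.empty(0), np.empty(0))
    peaks, _ = sps.find_peaks(e, height=rel_height * top,
                              distance=max(int(round(refractory_s * fs)), 1))
    if len(peaks) < 2:
        return RRSeries(np.empty(0), peaks / fs)
    # refine each beat to the ECG extremum near the energy peak
    half = max(int(round(0.05 * fs)), 1)
    beats = []
    for p in peaks:
        a, b = max(p - half, 0), min(p + half + 1, len(x))
        beats.append(a + int(np.argmax(np.abs(x[a:b]))))
    beat_t = np.unique(np.asarray(beats)) / fs
    if len(beat_t) < 2:
        return RRSeries(np.empty(0), beat_t)
    return RRSeries(np.diff(beat_t) * 1000.0, beat_t)


@dataclass
class PreprocessedSubject:
    """Filtered windows + full-recording RR series for one subject."""

    windows: list[LabeledWindow]
    rr: RRSeries
    burst_counts: dict[str, int] = field(default_factory=dict)


def preprocess_subject(recording: Recording, schedule: StimulusSchedule,
                       window_s: float = 5.5, emd_windows: bool = True,
                       detect_bursts: bool = False,
                       keep_classes: tuple[str, ...] | None = None
                       ) -> PreprocessedSubject:
    """Run the full preprocessing chain on one subject.

    EMG channels are band-passed 20-250 Hz then EMD-denoised per window;
    the ECG is band-passed 0.1-250 Hz (upper edge clipped below Nyquist)
    before R-peak detection.  SCL passes through unfiltered.
    """
    fs = recording.fs
    filtered: dict[str, np.ndarray] = {}
    burst_counts: dict[str, int] = {}
    for name, x in recording.channels.items():
        role = recording.channel_role[name]
        if role.startswith("emg"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                y = butterworth_bandpass(x, fs, *EMG_BAND)
            if detect_bursts:
                burst_counts[role] = len(detect_bursts_hilbert(y, fs))
            filtered[name] = y
        elif role == "ecg":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                filtered[name] = butterworth_bandpass(x, fs, *ECG_BAND)
        else:  # scl: no band-pass
            filtered[name] = np.asarray(x, dtype=float)

    rec_f = Recording(subject_id=recording.subject_id, fs=fs,
                      channels=filtered, channel_role=dict(recording.channel_role))
    windows = cut_windows(rec_f, schedule, window_s=window_s)
    if keep_classes is not None:
        windows = [w for w in windows if w.class_label in keep_classes]
    if emd_windows:
        for win in windows:
            for role in ("emg_zyg", "emg_cor", "emg_tra"):
                if role in win.segments:
                    win.segments[role] = emd_denoise(win.segments[role], fs)
    rr = detect_rr(rec_f.by_role("ecg"), fs)
    return PreprocessedSubject(windows=windows, rr=rr, burst_counts=burst_counts)
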
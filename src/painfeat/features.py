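"""The 159-dimensional feature space over seven mathematical groups.

Each of the four waveform channels (zygomaticus, corrugator and trapezius
EMG, skin conductance level) contributes 39 features:

========== ===========================================================
group      features (count)
========== ===========================================================
amplitude  peak, p2p, rms, mean of local maxima/minima, MAV and the
           MAV of the first/second differences, raw and on the
           standardized segment (10)
frequency  zero crossings, mode/mean/median frequency, bandwidth,
           central frequency (6)
stationar. four aggregates of the stationarity degree DS plus the
           dispersion of subsegment means and stds (6)
entropy    approximate, fuzzy, sample, Shannon, spectral (5)
linearity  polynomial and linear lag-dependence values (2)
variabil.  variance, std, range, semi-interquartile range (4)
similarity four coherence aggregates vs. the subject's mean baseline
           signal, Pearson correlation, mutual information (6)
========== ===========================================================

The ECG contributes three heart-rate-variability features (meanRR, RMSSD,
slopeRR), for 4 x 39 + 3 = 159 in total, with printed group sums
40/24/24/20/8/19/24.  Similarity features compare each window against the
element-wise mean of the subject's baseline (non-pain) windows; afterwards
every feature is z-transformed per person.

Degenerate inputs (constant segments, empty spectra, too few beats) yield
NaN sentinels; columns containing sentinels are removed by the static
pruning stage of feature selection.  All logarithms are natural, so entropy
and mutual-information values are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from painfeat.core import LabeledWindow, ConfigError
from painfeat.preprocess import RRSeries, _local_extrema

SENTINEL = float("nan")

#: role -> display name used in feature identifiers
CHANNEL_DISPLAY = {
    "emg_zyg": "Zygomaticus",
    "emg_cor": "Corrugator",
    "emg_tra": "Trapezius",
    "scl": "SCL",
}
WAVEFORM_ROLES = tuple(CHANNEL_DISPLAY)

AMPLITUDE_NAMES = (
    "Peak", "PeakToPeak", "RootMeanSquare", "MeanOfLocalMaxima",
    "MeanOfLocalMinima", "MeanAbsoluteValue", "MeanAbsoluteValueFirstDiff",
    "MeanAbsoluteValueFirstDiffNorm", "MeanAbsoluteValueSecondDiff",
    "MeanAbsoluteValueSecondDiffNorm",
)
FREQUENCY_NAMES = (
    "ZeroCrossings", "ModeFrequency", "Bandwidth", "CentralFrequency",
    "MeanFrequency", "MedianFrequency",
)
STATIONARITY_NAMES = (
    "MedianOfStationarityDegree", "FrequencyWeightedStationarityDegree",
    "AreaOfStationarityDegree", "PowerWeightedAreaOfStationarityDegree",
    "StandardDeviationOfMeanVector", "StandardDeviationOfStdVector",
)
ENTROPY_NAMES = ("Approximate", "Fuzzy", "Sample", "Shannon", "Spectral")
LINEARITY_NAMES = ("PolynomialLagDependenceValues", "LagDependenceValues")
VARIABILITY_NAMES = ("Variance", "StandardDeviation", "Range", "SemiInterquartileRange")
SIMILARITY_NAMES = (
    "CoherenceAtMedianFrequency", "CoherenceMean", "CoherencePowerWeightedMean",
    "CoherencePowerWeightedArea", "Correlation", "MutualInformation",
)
RR_NAMES = ("MeanRR", "RMSSD", "SlopeRR")


@dataclass
class FeatureConfig:
    """Tunable parameters of the feature operators.

    Defaults are standard literature values (the feature definitions
    themselves do not prescribe them): embedding dimension m=2 and tolerance
    r = 0.2 x std for the template entropies, fuzzy exponent 2, 16 histogram
    bins, 256-sample spectral segments with 50 % overlap, 0.5 s subsegments
    for the stationarity dispersion features, and a maximum lag of 10 for
    the lag-dependence values.  Template entropies are evaluated on a
    coarse-grained copy of the segment of at most ``entropy_max_n`` (256) samples
    (non-overlapping block averages), keeping the O(N^2) template matching
    tractable at the full window length.
    """

    entropy_m: int = 2
    entropy_r_frac: float = 0.2
    fuzzy_n: float = 2.0
    hist_bins: int = 16
    spectral_nperseg: int = 256
    spectral_overlap: float = 0.5
    stationarity_ti_s: float = 0.5
    lag_k: int = 10
    entropy_max_n: int = 256
    #: if True, central frequency uses the printed half-difference
    #: (fh - fl)/2 instead of the band-edge mean (fh + fl)/2
    cf_printed_variant: bool = False


@dataclass
class BaselineReference:
    """Per-subject mean of the baseline (non-pain) windows, self-excluded.

    Every window — baseline or pain — is compared against a leave-one-out
    mean over the subject's baseline windows.  A baseline window excludes
    itself: comparing a segment against an average containing itself would
    give every baseline row a spurious positive self-similarity that the
    per-person z-transform then amplifies into an artifactual class
    separator.  A pain window excludes one baseline window too (rotating,
    keyed on the window onset), so both classes see references of
    identical construction — the same averaging count, hence the same
    residual-noise level — and similarity features carry only genuine
    stimulus-locked dissimilarity.
    """

    subject_id: str
    segments: dict[str, np.ndarray]          # plain mean over B windows
    _stacks: dict[str, np.ndarray] | None = None  # (n_b, n_samples) per role
    _b_onsets: tuple[float, ...] = ()

    @classmethod
    def from_windows(cls, windows: list[LabeledWindow]) -> "BaselineReference":
        b_wins = [w for w in windows if w.class_label == "B"]
        if not b_wins:
            raise ConfigError("no baseline windows to build the reference from")
        roles = [r for r in b_wins[0].segments if r in WAVEFORM_ROLES]
        stacks = {r: np.stack([w.segments[r] for w in b_wins]) for r in roles}
        segs = {r: stacks[r].mean(axis=0) for r in roles}
        return cls(subject_id=b_wins[0].subject_id, segments=segs,
                   _stacks=stacks, _b_onsets=tuple(w.onset_s for w in b_wins))

    def reference_for(self, window: LabeledWindow, role: str) -> np.ndarray | None:
        """Leave-one-out reference segment for a window."""
        if role not in self.segments:
            return None
        n = len(self._b_onsets) if self._stacks is not None else 0
        if n < 2:
            return self.segments[role]
        if window.class_label == "B" and window.onset_s in self._b_onsets:
            drop = self._b_onsets.index(window.onset_s)
        else:
            drop = int(round(window.onset_s * 1000)) % n
        stack = self._stacks[role]
        return (stack.sum(axis=0) - stack[drop]) / (n - 1)


# ---------------------------------------------------------------------------
# amplitude
# ---------------------------------------------------------------------------

def amplitude_features(x: np.ndarray) -> dict[str, float]:
    """Ten amplitude descriptors of a segment."""
    x = np.asarray(x, dtype=float)
    out: dict[str, float] = {}
    out["Peak"] = float(np.max(x))
    out["PeakToPeak"] = float(np.max(x) - np.min(x))
    out["RootMeanSquare"] = float(np.sqrt(np.mean(x ** 2)))
    maxima, minima = _local_extrema(x)
    out["MeanOfLocalMaxima"] = float(np.mean(x[maxima])) if len(maxima) else SENTINEL
    out["MeanOfLocalMinima"] = float(np.mean(x[minima])) if len(minima) else SENTINEL
    out["MeanAbsoluteValue"] = float(np.mean(np.abs(x)))
    if len(x) < 3:
        for k in AMPLITUDE_NAMES[6:]:
            out[k] = SENTINEL
        return out
    sd = np.std(x)
    z = (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)
    out["MeanAbsoluteValueFirstDiff"] = float(np.mean(np.abs(np.diff(x))))
    out["MeanAbsoluteValueFirstDiffNorm"] = float(np.mean(np.abs(np.diff(z))))
    out["MeanAbsoluteValueSecondDiff"] = float(np.mean(np.abs(np.diff(x, 2))))
    out["MeanAbsoluteValueSecondDiffNorm"] = float(np.mean(np.abs(np.diff(z, 2))))
    return out


# ---------------------------------------------------------------------------
# frequency
# ---------------------------------------------------------------------------

def frequency_features(x: np.ndarray, fs: float,
                       cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Zero crossings plus five descriptors of the magnitude spectrum.

    The segment is mean-removed; the one-sided magnitude of its discrete
    Fourier transform defines the mode, mean and median frequencies and the
    -3 dB (0.707 x max) bandwidth.  The central frequency is the mean of the
    band edges (fh + fl)/2 by default.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    x = x - np.mean(x)
    zc = int(np.sum(x[:-1] * x[1:] < 0))
    out: dict[str, float] = {"ZeroCrossings": float(zc)}
    if len(x) < 32:
        for k in FREQUENCY_NAMES[1:]:
            out[k] = SENTINEL
        return out
    X = np.abs(np.fft.rfft(x))
    f = np.fft.rfftfreq(len(x), d=1.0 / fs)
    tot = X.sum()
    if tot <= 0:
        for k in FREQUENCY_NAMES[1:]:
            out[k] = SENTINEL
        return out
    kmax = int(np.argmax(X))
    out["ModeFrequency"] = float(f[kmax])
    thr = X[kmax] / math.sqrt(2.0)
    above = np.where(X >= thr)[0]
    fl, fh = float(f[above[0]]), float(f[above[-1]])
    out["Bandwidth"] = fh - fl
    out["CentralFrequency"] = (fh - fl) / 2 if cfg.cf_printed_variant else (fh + fl) / 2
    out["MeanFrequency"] = float(np.sum(X * f) / tot)
    cum = np.cumsum(X)
    out["MedianFrequency"] = float(f[int(np.searchsorted(cum, cum[-1] / 2.0))])
    return out


# ---------------------------------------------------------------------------
# stationarity
# ---------------------------------------------------------------------------

def _spectrogram(x: np.ndarray, fs: float, cfg: FeatureConfig):
    nper = min(cfg.spectral_nperseg, len(x))
    nover = int(nper * cfg.spectral_overlap)
    return sps.spectrogram(x, fs=fs, nperseg=nper, noverlap=nover,
                           window="hann", scaling="density", mode="psd")


def stationarity_features(x: np.ndarray, fs: float,
                          cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Aggregates of the stationarity degree DS plus subsegment dispersion.

    DS(w) = mean over frames t of (1 - H(w,t)/h(w))^2, where H is the
    spectrogram and h(w) its time average (the whole-segment spectral
    density); a stationary process keeps H close to h at every frequency.
    The four aggregates are the median of DS, the frequency-weighted mean
    sum(w DS)/sum(w), the area sum(DS) dw and the power-weighted area
    sum(h DS) dw / sum(h).  The dispersion features split the segment into
    ``stationarity_ti_s``-second parts and take the standard deviation of
    the per-part means ("me") and of the per-part standard deviations
    ("sd").
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    out = {k: SENTINEL for k in STATIONARITY_NAMES}

    n_sub = int(len(x) // max(int(round(cfg.stationarity_ti_s * fs)), 1))
    if n_sub >= 1:
        parts = np.array_split(x[: n_sub * (len(x) // n_sub)], n_sub)
        out["StandardDeviationOfMeanVector"] = float(np.std([p.mean() for p in parts]))
        out["StandardDeviationOfStdVector"] = float(np.std([p.std() for p in parts]))

    f, t, H = _spectrogram(x, fs, cfg)
    if H.shape[1] < 4:
        return out
    h = H.mean(axis=1)
    valid = h > 0
    if not np.any(valid):
        return out
    ds = np.zeros_like(h)
    ds[valid] = np.mean((1.0 - H[valid] / h[valid, None]) ** 2, axis=1)
    fv, dsv, hv = f[valid], ds[valid], h[valid]
    df = f[1] - f[0] if len(f) > 1 else 1.0
    out["MedianOfStationarityDegree"] = float(np.median(dsv))
    wsum = fv.sum()
    out["FrequencyWeightedStationarityDegree"] = (
        float(np.sum(fv * dsv) / wsum) if wsum > 0 else SENTINEL)
    out["AreaOfStationarityDegree"] = float(np.sum(dsv) * df)
    out["PowerWeightedAreaOfStationarityDegree"] = float(np.sum(hv * dsv) * df / hv.sum())
    return out


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def _coarse_grain(x: np.ndarray, max_n: int) -> np.ndarray:
    """Non-overlapping block averages so the result has <= max_n samples."""
    n = len(x)
    if max_n <= 0 or n <= max_n:
        return x
    q = int(math.ceil(n / max_n))
    n_blocks = n // q
    return x[: n_blocks * q].reshape(n_blocks, q).mean(axis=1)


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """All length-m templates as rows (shape (N - m + 1, m))."""
    from numpy.lib.stride_tricks import sliding_window_view
    return sliding_window_view(x, m)


def _cheb_dists(a: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev distance matrix of template rows.

    Accumulates the coordinate-wise maximum in place instead of building an
    (n, n, m) intermediate.
    """
    col = a[:, 0:1]
    d = np.abs(col - col.T)
    for k in range(1, a.shape[1]):
        col = a[:, k:k + 1]
        np.maximum(d, np.abs(col - col.T), out=d)
    return d


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                        r_frac: float = 0.2) -> float:
    """ApEn(m, r) with self-matches included (the standard convention).

    phi_m = mean_i ln C_i^m(r), C_i^m the fraction of templates within
    Chebyshev distance r of template i; ApEn = phi_m - phi_{m+1}.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        return SENTINEL
    if r is None:
        sd = np.std(x)
        if sd == 0:
            return 0.0
        r = r_frac * sd

    def phi_full(mm: int) -> float:
        a = _embed(x, mm)
        d = _cheb_dists(a)
        c = np.mean(d <= r, axis=1)
        return float(np.mean(np.log(c)))

    return phi_full(m) - phi_full(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_frac: float = 0.2) -> float:
    """SampEn(m, r): -ln(A/B), self-matches excluded (Richman & Moorman)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        return SENTINEL
    if r is None:
        sd = np.std(x)
        if sd == 0:
            return 0.0
        r = r_frac * sd
    tm = _embed(x, m)[: n - m]
    tm1 = _embed(x, m + 1)
    dm = _cheb_dists(tm)
    dm1 = _cheb_dists(tm1)
    iu = np.triu_indices(n - m, k=1)
    b = int(np.sum(dm[iu] <= r))
    a = int(np.sum(dm1[iu] <= r))
    if a == 0 or b == 0:
        return SENTINEL
    return float(-math.log(a / b))


def fuzzy_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                  r_frac: float = 0.2, n_fuzzy: float = 2.0) -> float:
    """FuzzyEn(m, r, n): exponential similarity on baseline-removed templates.

    Each template has its own mean subtracted; similarity between templates
    is exp(-(d/r)^n) with d the Chebyshev distance, averaged over distinct
    pairs; FuzzyEn = ln(phi_m / phi_{m+1}).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        return SENTINEL
    if r is None:
        sd = np.std(x)
        if sd == 0:
            return 0.0
        r = r_frac * sd

    def phi(mm: int) -> float:
        a = _embed(x, mm)[: n - m]
        a = a - a.mean(axis=1, keepdims=True)
        d = _cheb_dists(a)
        iu = np.triu_indices(len(a), k=1)
        return float(np.mean(np.exp(-((d[iu] / r) ** n_fuzzy))))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        return SENTINEL
    return float(math.log(p_m / p_m1))


def shannon_entropy(x: np.ndarray, bins: int = 16) -> float:
    """Histogram (plug-in) Shannon entropy in nats; 0 for a constant."""
    x = np.asarray(x, dtype=float)
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def spectral_entropy(x: np.ndarray, fs: float,
                     cfg: FeatureConfig | None = None) -> float:
    """Normalized entropy of the spectral density estimate, in [0, 1]."""
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    nper = min(cfg.spectral_nperseg, len(x))
    f, p = sps.welch(x, fs=fs, nperseg=nper,
                     noverlap=int(nper * cfg.spectral_overlap))
    tot = p.sum()
    if tot <= 0 or len(p) < 2:
        return SENTINEL
    q = p[p > 0] / tot
    return float(-np.sum(q * np.log(q)) / math.log(len(p)))


# ---------------------------------------------------------------------------
# linearity
# ---------------------------------------------------------------------------

def lag_dependence_features(x: np.ndarray, K: int = 10) -> dict[str, float]:
    """Mean lag-dependence values over lags 1..K.

    For each lag k, x(t) is regressed on x(t-k) with a linear (ldf) and a
    quadratic (pldf, the nonlinear variant) fit; the per-lag statistic is
    sqrt(max(R0, 0)) with R0 = (SST - SSR)/SST, and the feature averages it
    over lags.  Lags with a singular fit are skipped.
    """
    x = np.asarray(x, dtype=float)
    vals_lin, vals_quad = [], []
    for k in range(1, K + 1):
        if len(x) <= k + 2:
            break
        y, z = x[k:], x[:-k]
        yc = y - y.mean()
        sst = float(yc @ yc)
        if sst == 0 or np.ptp(z) == 0:
            continue
        # closed-form least squares on the centered designs [z] and [z, z^2]
        zc = z - z.mean()
        z2 = z * z
        z2c = z2 - z2.mean()
        szz, szy = float(zc @ zc), float(zc @ yc)
        vals_lin.append(math.sqrt(max(min(szy * szy / (szz * sst), 1.0), 0.0)))
        g11, g12, g22 = szz, float(zc @ z2c), float(z2c @ z2c)
        b1, b2 = szy, float(z2c @ yc)
        det = g11 * g22 - g12 * g12
        if abs(det) < 1e-12 * max(g11 * g22, 1e-300):
            continue
        beta1 = (g22 * b1 - g12 * b2) / det
        beta2 = (g11 * b2 - g12 * b1) / det
        ss_model = beta1 * b1 + beta2 * b2
        vals_quad.append(math.sqrt(max(min(ss_model / sst, 1.0), 0.0)))
    return {
        "PolynomialLagDependenceValues": float(np.mean(vals_quad)) if vals_quad else SENTINEL,
        "LagDependenceValues": float(np.mean(vals_lin)) if vals_lin else SENTINEL,
    }


# ---------------------------------------------------------------------------
# variability
# ---------------------------------------------------------------------------

def variability_features(x: np.ndarray) -> dict[str, float]:
    """Unbiased variance, std, range and semi-interquartile range."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return {k: SENTINEL for k in VARIABILITY_NAMES}
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "Variance": float(np.var(x, ddof=1)),
        "StandardDeviation": float(np.std(x, ddof=1)),
        "Range": float(np.ptp(x)),
        "SemiInterquartileRange": float((q3 - q1) / 2.0),
    }


def rr_features(rr_ms: np.ndarray) -> dict[str, float]:
    """meanRR, RMSSD and the OLS slope of RR against beat index (ms)."""
    rr = np.asarray(rr_ms, dtype=float)
    if len(rr) < 3:
        return {k: SENTINEL for k in RR_NAMES}
    d = np.diff(rr)
    return {
        "MeanRR": float(np.mean(rr)),
        "RMSSD": float(np.sqrt(np.sum(d ** 2) / (len(rr) - 1))),
        "SlopeRR": float(np.polyfit(np.arange(len(rr)), rr, 1)[0]),
    }


# ---------------------------------------------------------------------------
# similarity (vs. the subject's mean baseline signal)
# ---------------------------------------------------------------------------

def coherence_features(x: np.ndarray, y: np.ndarray, fs: float,
                       cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Aggregates of the magnitude-squared coherence between x and y.

    C(f) = |Sxy|^2 / (Sxx Syy), estimated with averaged overlapping
    windows.  Aggregates: C at the power-median frequency of x, the plain
    mean, the power-weighted mean sum(Sxx C)/sum(Sxx), and the
    power-weighted area sum(Sxx C) df / sum(Sxx) df.  All lie in [0, 1].
    Fewer than 4 averaging windows yields sentinels (the coherence of a
    single window is identically 1).
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nper = min(cfg.spectral_nperseg, len(x))
    nover = int(nper * cfg.spectral_overlap)
    step = nper - nover
    n_seg = 1 + max(len(x) - nper, 0) // step
    if n_seg < 4:
        return {k: SENTINEL for k in SIMILARITY_NAMES[:4]}
    kw = dict(fs=fs, nperseg=nper, noverlap=nover)
    f, sxy = sps.csd(x, y, **kw)
    _, sxx = sps.welch(x, **kw)
    _, syy = sps.welch(y, **kw)
    denom = sxx * syy
    valid = denom > 0
    if not np.any(valid):
        return {k: SENTINEL for k in SIMILARITY_NAMES[:4]}
    c = np.zeros(len(f))
    c[valid] = np.clip(np.abs(sxy[valid]) ** 2 / denom[valid], 0.0, 1.0)
    fv, cv, pv = f[valid], c[valid], sxx[valid]

    cum = np.cumsum(pv)
    i_med = int(np.searchsorted(cum, cum[-1] / 2.0))
    psum = pv.sum()
    pond = float(np.sum(pv * cv) / psum) if psum > 0 else SENTINEL
    return {
        "CoherenceAtMedianFrequency": float(cv[i_med]),
        "CoherenceMean": float(np.mean(cv)),
        "CoherencePowerWeightedMean": pond,
        "CoherencePowerWeightedArea": pond,  # uniform df: area == weighted mean
    }


def similarity_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between a window and the mean baseline segment."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return SENTINEL
    return float(np.corrcoef(x, y)[0, 1])


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 16) -> float:
    """Histogram mutual information I(A,B) = H(A) + H(B) - H(A,B), in nats."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def _h(counts: np.ndarray) -> float:
        p = counts[counts > 0] / counts.sum()
        return float(-np.sum(p * np.log(p)))

    cx, ex = np.histogram(x, bins=bins)
    cy, ey = np.histogram(y, bins=bins)
    cxy, _, _ = np.histogram2d(x, y, bins=[ex, ey])
    return _h(cx) + _h(cy) - _h(cxy.ravel())


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def standard_feature_names(roles: tuple[str, ...] = WAVEFORM_ROLES,
                           include_ecg: bool = True) -> list[str]:
    """Canonical column order of the feature matrix (159 under defaults)."""
    names: list[str] = []
    for role in roles:
        ch = CHANNEL_DISPLAY[role]
        for group, feats in (("Amplitude", AMPLITUDE_NAMES),
                             ("Frequency", FREQUENCY_NAMES),
                             ("Stationarity", STATIONARITY_NAMES),
                             ("Entropy", ENTROPY_NAMES),
                             ("Linearity", LINEARITY_NAMES),
                             ("Variability", VARIABILITY_NAMES),
                             ("Similarity", SIMILARITY_NAMES)):
            names += [f"{ch}_{group}_{f}" for f in feats]
    if include_ecg:
        names += [f"ECG_Variability_{f}" for f in RR_NAMES]
    return names


def feature_group_counts(names: list[str]) -> dict[str, int]:
    """Feature count per mathematical group (ECG RR features -> variability)."""
    counts: dict[str, int] = {}
    for n in names:
        group = n.split("_")[1].lower()
        counts[group] = counts.get(group, 0) + 1
    return counts


def extract_feature_vector(window: LabeledWindow, baseline_ref: BaselineReference,
                           rr: RRSeries, cfg: FeatureConfig | None = None
                           ) -> dict[str, float]:
    """All features of one labelled window, in canonical order."""
    cfg = cfg or FeatureConfig()
    fs = window.fs
    missing = set(WAVEFORM_ROLES) - set(window.segments)
    if missing:
        raise ConfigError(f"window is missing waveform channels: {sorted(missing)}")
    has_ecg = "ecg" in window.segments
    vec: dict[str, float] = {}
    for role in WAVEFORM_ROLES:
        ch = CHANNEL_DISPLAY[role]
        x = np.asarray(window.segments[role], dtype=float)
        ref = baseline_ref.reference_for(window, role)
        if ref is None:
            raise ConfigError(f"baseline reference missing channel {role}")
        # SCL: detrend before the frequency-domain operators
        x_spec = sps.detrend(x) if role == "scl" else x
        xe = _coarse_grain(x, cfg.entropy_max_n)

        amp = amplitude_features(x)
        frq = frequency_features(x_spec, fs, cfg)
        sta = stationarity_features(x_spec, fs, cfg)
        ent = {
            "Approximate": approximate_entropy(xe, cfg.entropy_m, r_frac=cfg.entropy_r_frac),
            "Fuzzy": fuzzy_entropy(xe, cfg.entropy_m, r_frac=cfg.entropy_r_frac,
                                   n_fuzzy=cfg.fuzzy_n),
            "Sample": sample_entropy(xe, cfg.entropy_m, r_frac=cfg.entropy_r_frac),
            "Shannon": shannon_entropy(x, cfg.hist_bins),
            "Spectral": spectral_entropy(x_spec, fs, cfg),
        }
        lin = lag_dependence_features(x, cfg.lag_k)
        var = variability_features(x)
        sim = coherence_features(x_spec, sps.detrend(ref) if role == "scl" else ref,
                                 fs, cfg)
        sim["Correlation"] = similarity_correlation(x, ref)
        sim["MutualInformation"] = mutual_information(x, ref, cfg.hist_bins)

        for group, vals in (("Amplitude", amp), ("Frequency", frq),
                            ("Stationarity", sta), ("Entropy", ent),
                            ("Linearity", lin), ("Variability", var),
                            ("Similarity", sim)):
            for fname, v in vals.items():
                vec[f"{ch}_{group}_{fname}"] = v

    if has_ecg:
        t0 = window.onset_s
        rr_win = rr.in_window(t0, t0 + window.window_s)
        for fname, v in rr_features(rr_win.rr_ms).items():
            vec[f"ECG_Variability_{fname}"] = v
    return vec


def extract_features(subjects, cfg: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature matrix over preprocessed subjects.

    ``subjects`` iterates over objects with ``windows`` (list of
    :class:`~painfeat.core.LabeledWindow`) and ``rr`` (full-recording
    :class:`~painfeat.preprocess.RRSeries`) attributes, one per subject.
    Returns a DataFrame with ``subject_id``, ``class_label`` and the feature
    columns in canonical order.
    """
    cfg = cfg or FeatureConfig()
    rows = []
    for subj in subjects:
        if not subj.windows:
            continue
        ref = BaselineReference.from_windows(subj.windows)
        for win in subj.windows:
            vec = extract_feature_vector(win, ref, subj.rr, cfg)
            rows.append({"subject_id": win.subject_id,
                         "class_label": win.class_label, **vec})
    return pd.DataFrame(rows)


def znorm_per_person(m: pd.DataFrame) -> pd.DataFrame:
    """Z-transform every feature column within each subject.

    Non-degenerate columns end up with per-subject mean 0 and sd 1;
    zero-variance columns become all zeros (flagged static downstream).
    """
    out = m.copy()
    feats = [c for c in m.columns if c not in ("subject_id", "class_label")]

    def _z(g: pd.DataFrame) -> pd.DataFrame:
        mu = g.mean()
        sd = g.std(ddof=0)
        z = (g - mu) / sd.replace(0.0, np.nan)
        static = sd.index[sd == 0.0]
        z[static] = 0.0
        return z

    out[feats] = m.groupby("subject_id", group_keys=False, sort=False)[feats].apply(_z)
    return out
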
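"""Time- and frequency-domain feature battery for 1-minute EGG windows.

Seventeen time-domain features (distribution moments, RMS, line length,
five entropies, Lempel-Ziv complexity, Hjorth mobility/complexity,
Petrosian fractal dimension, Hurst exponent) and ten frequency-domain
features derived from a Welch PSD on a 0.1 cpm grid (dominant frequency
and power, PMMP, spectral entropy, three gastric band powers, PSD crest
factor, median and mean power frequency).

Conventions chosen for this battery:

* population (1/N) moments; excess (Fisher) kurtosis;
* mode of a continuous signal = midpoint of the fullest of 64 equal-width
  histogram bins;
* ApEn per Pincus (self-matches included), SampEn per Richman & Moorman
  (self-matches excluded), both with Chebyshev distance and r = 0.2 * SD;
* permutation and SVD entropies normalized to [0, 1];
* LZ76 exhaustive-parsing phrase count on the median-binarized sequence;
* Hurst via Anis-Lloyd-Peters corrected rescaled range over dyadic
  window sizes (the uncorrected R/S slope is biased upward at the window
  lengths used here);
* frequencies reported in cycles per minute (cpm); spectral features are
  computed over the 0.6-30 cpm passband; the gastric bands 3-8, 8-11 and
  11-15 cpm correspond to brady-, normo- and tachygastria.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .preprocessing import CleanWindow

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "PSDEstimate",
    "FEATURE_NAMES",
    "statistical_moments",
    "rms",
    "line_length",
    "approx_entropy",
    "sample_entropy",
    "permutation_entropy",
    "svd_entropy",
    "lempel_ziv",
    "hjorth_params",
    "petrosian_fd",
    "hurst_exponent",
    "welch_psd",
    "dominant_freq_power",
    "pmmp",
    "spectral_entropy",
    "band_powers",
    "psd_crest_factor",
    "median_frequency",
    "mean_power_frequency",
    "extract_features",
    "build_feature_table",
]


@dataclass
class FeatureConfig:
    apen_m: int = 2
    apen_r_factor: float = 0.2
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    perm_order: int = 3
    perm_delay: int = 1
    svd_order: int = 3
    svd_delay: int = 1
    psd_resolution_cpm: float = 0.1
    psd_window: str = "hann"
    df_band_cpm: tuple = (0.6, 30.0)
    bands_cpm: tuple = ((3.0, 8.0), (8.0, 11.0), (11.0, 15.0))

    def __post_init__(self) -> None:
        self.df_band_cpm = tuple(self.df_band_cpm)
        self.bands_cpm = tuple(tuple(b) for b in self.bands_cpm)
        if self.psd_resolution_cpm <= 0:
            raise ValueError("psd_resolution_cpm must be positive")
        flat = [e for b in self.bands_cpm for e in b]
        if flat != sorted(flat):
            raise ValueError("bands_cpm must be disjoint and ordered")


@dataclass
class PSDEstimate:
    freqs_cpm: np.ndarray
    power: np.ndarray  # uV^2 per cpm
    resolution_cpm: float


#: fixed column order of the feature battery (17 time + 10 frequency)
FEATURE_NAMES = [
    "mean", "variance", "mode", "median", "skewness", "kurtosis",
    "rms", "line_length", "apen", "sampen", "pren", "svden", "lz",
    "hjorth_mobility", "hjorth_complexity", "pfd", "hurst",
    "df", "dp", "pmmp", "spen", "bp1", "bp2", "bp3",
    "crest_factor", "mf", "mpf",
]


# ----------------------------------------------------------------------
# time domain
# ----------------------------------------------------------------------

def statistical_moments(x: np.ndarray):
    """(mean, variance, mode, median, skewness, kurtosis).

    Population moments; skewness = standardized third moment; kurtosis =
    excess.  Mode = midpoint of the fullest of 64 equal-width histogram
    bins.  A zero-variance input returns 0 for the standardized moments.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    mean = float(x.mean())
    var = float(x.var())
    median = float(np.median(x))
    if var == 0.0:
        warnings.warn("zero-variance window: skewness/kurtosis set to 0")
        return mean, 0.0, mean, median, 0.0, 0.0
    counts, edges = np.histogram(x, bins=64)
    i = int(np.argmax(counts))
    mode = float(0.5 * (edges[i] + edges[i + 1]))
    skew = float(spstats.skew(x, bias=True))
    kurt = float(spstats.kurtosis(x, fisher=True, bias=True))
    return mean, var, mode, median, skew, kurt


def rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(x * x)))


def line_length(x: np.ndarray) -> float:
    """Sum of absolute first differences (approximates Katz's fractal
    dimension and tracks signal amplitude/roughness)."""
    x = np.asarray(x, dtype=float)
    return float(np.abs(np.diff(x)).sum())


def _embed(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    n = len(x) - (order - 1) * delay
    if n <= 0:
        raise ValueError("signal too short for this embedding")
    idx = np.arange(n)[:, None] + np.arange(order)[None, :] * delay
    return x[idx]


def _chebyshev_matches(emb: np.ndarray, r: float) -> np.ndarray:
    """Boolean match matrix under max-norm distance <= r."""
    d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
    return d <= r


def approx_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Approximate entropy (Pincus): phi(m) - phi(m+1), self-matches
    included, tolerance r = r_factor * SD, Chebyshev distance."""
    x = np.asarray(x, dtype=float)
    if len(x) < m + 2:
        raise ValueError("signal too short for ApEn")
    r = r_factor * x.std()
    if r == 0:
        warnings.warn("zero-variance window: ApEn set to 0")
        return 0.0

    def phi(mm: int) -> float:
        emb = _embed(x, mm, 1)
        c = _chebyshev_matches(emb, r).mean(axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy (Richman & Moorman): -ln(A/B) over the first N-m
    templates, self-matches excluded.  Returns +inf if no m+1 matches."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValueError("signal too short for SampEn")
    r = r_factor * x.std()
    if r == 0:
        warnings.warn("zero-variance window: SampEn set to 0")
        return 0.0
    emb_m = _embed(x, m, 1)[: n - m]
    emb_m1 = _embed(x, m + 1, 1)
    mb = _chebyshev_matches(emb_m, r)
    ma = _chebyshev_matches(emb_m1, r)
    k = len(emb_m1)
    b = (mb.sum() - len(emb_m)) / 2.0  # off-diagonal pairs
    a = (ma.sum() - k) / 2.0
    if b == 0 or a == 0:
        logger.warning("SampEn degenerate: no template matches, returning inf")
        return math.inf
    return float(-np.log(a / b))


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy in [0, 1]; ties broken by index
    order (stable argsort)."""
    x = np.asarray(x, dtype=float)
    if len(x) < (order - 1) * delay + 2:
        raise ValueError("signal too short for permutation entropy")
    emb = _embed(x, order, delay)
    patterns = np.argsort(emb, axis=1, kind="stable")
    # encode each ordinal pattern as an integer in base `order`
    codes = (patterns * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(math.factorial(order)))


def svd_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized singular-spectrum entropy of the delay-embedded
    trajectory matrix, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    emb = _embed(x, order, delay)
    s = np.linalg.svd(emb, compute_uv=False)
    total = s.sum()
    if total == 0:
        return 0.0
    p = s / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(order))


def lempel_ziv(x: np.ndarray, normalize: bool = False) -> float:
    """LZ76 exhaustive-parsing phrase count of the median-binarized signal.

    Binarization: x >= median -> 1.  With ``normalize`` the count is scaled
    by log2(n)/n (asymptotic phrase count of a random sequence).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    bits = (x >= np.median(x)).astype(np.uint8).tobytes()
    n = len(bits)
    phrases = 0
    i = 0
    while i < n:
        j = i + 1
        # grow the phrase while it can be copied from the prior text; the
        # first non-reproducible (innovation) symbol closes the phrase
        while j < n and bits[i:j] in bits[: j - 1]:
            j += 1
        phrases += 1
        i = j
    if normalize:
        return phrases * math.log2(n) / n
    return float(phrases)


def hjorth_params(x: np.ndarray) -> tuple[float, float]:
    """(mobility, complexity) from first-difference derivatives.

    Complexity tends to 1 for a pure sine sampled well above its frequency.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    v0 = x.var()
    if v0 == 0:
        warnings.warn("zero-variance window: Hjorth parameters set to 0")
        return 0.0, 0.0
    d1 = np.diff(x)
    d2 = np.diff(d1)
    mobility = math.sqrt(d1.var() / v0)
    v1 = d1.var()
    if v1 == 0:
        return mobility, 0.0
    complexity = math.sqrt(d2.var() / v1) / mobility
    return float(mobility), float(complexity)


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from derivative sign changes:

        PFD = log10(N) / (log10(N) + log10(N / (N + 0.4 * Nd)))

    with N the window length and Nd the number of sign changes of the
    first difference (zero differences carry the previous sign).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    d = np.diff(x)
    s = np.sign(d)
    # zeros inherit the previous nonzero sign
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    nz = s[s != 0]
    n_delta = int(np.count_nonzero(nz[1:] * nz[:-1] < 0))
    log_n = math.log10(n)
    return log_n / (log_n + math.log10(n / (n + 0.4 * n_delta)))


def _expected_rs(n: int) -> float:
    """Anis-Lloyd-Peters expected R/S of iid data for window length n."""
    i = np.arange(1, n)
    s = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        return (n - 0.5) / n * s / math.sqrt(math.pi * n / 2.0)
    return (n - 0.5) / n * s / math.sqrt(math.pi * n / 2.0)


def hurst_exponent(x: np.ndarray) -> float:
    """Corrected rescaled-range (R/S) Hurst estimate.

    R/S is averaged over non-overlapping segments at dyadic window sizes
    between 16 and n/2; H = 0.5 + slope of log(R/S) - log E[R/S] against
    log window size, the Anis-Lloyd-Peters small-sample correction.
    White noise gives H near 0.5, a random walk near 1.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 samples for the Hurst estimate")
    if x.std() == 0:
        raise ValueError("constant signal: Hurst exponent undefined")
    sizes = []
    w = 16
    while w <= n // 2:
        sizes.append(w)
        w *= 2
    log_w, log_ratio = [], []
    for w in sizes:
        k = n // w
        segs = x[: k * w].reshape(k, w)
        dev = segs - segs.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        s = segs.std(axis=1)
        ok = s > 0
        if not np.any(ok):
            continue
        rs = float(np.mean(r[ok] / s[ok]))
        log_w.append(math.log(w))
        log_ratio.append(math.log(rs) - math.log(_expected_rs(w)))
    if len(log_w) < 2:
        raise ValueError("too few valid window sizes for the Hurst estimate")
    slope = np.polyfit(log_w, log_ratio, 1)[0]
    return float(0.5 + slope)


# ----------------------------------------------------------------------
# frequency domain
# ----------------------------------------------------------------------

def welch_psd(
    x: np.ndarray, fs_hz: float, config: FeatureConfig | None = None
) -> PSDEstimate:
    """Welch PSD of a window on a fixed cycles-per-minute grid.

    Single segment (the whole window) with a Hann taper, zero-padded so
    the grid spacing equals ``psd_resolution_cpm``; for a 60 s window the
    native resolution is 1 cpm, so the default 0.1 cpm grid is an
    interpolation of the spectrum, not extra information.
    """
    cfg = config or FeatureConfig()
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    res_hz = cfg.psd_resolution_cpm / 60.0
    nfft = round(fs_hz / res_hz)
    if nfft < len(x):
        warnings.warn(
            "requested resolution coarser than native: no zero padding"
        )
        nfft = len(x)
    freqs_hz, pxx = sps.welch(
        x, fs=fs_hz, window=cfg.psd_window, nperseg=len(x), noverlap=0,
        nfft=nfft, detrend=False, scaling="density",
    )
    return PSDEstimate(
        freqs_cpm=freqs_hz * 60.0,
        power=pxx / 60.0,  # uV^2/Hz -> uV^2/cpm
        resolution_cpm=float((freqs_hz[1] - freqs_hz[0]) * 60.0),
    )


def _band_mask(psd: PSDEstimate, band: tuple[float, float]) -> np.ndarray:
    return (psd.freqs_cpm >= band[0]) & (psd.freqs_cpm <= band[1])


def dominant_freq_power(
    psd: PSDEstimate, df_band_cpm: tuple[float, float] = (0.6, 30.0)
) -> tuple[float, float]:
    """Dominant frequency (cpm) and its power within the search band;
    ties resolve to the lowest frequency (argmax of the first maximum)."""
    mask = _band_mask(psd, df_band_cpm)
    if not np.any(mask):
        raise ValueError("dominant-frequency band contains no grid points")
    f, p = psd.freqs_cpm[mask], psd.power[mask]
    i = int(np.argmax(p))
    return float(f[i]), float(p[i])


def pmmp(psd: PSDEstimate, df_band_cpm: tuple[float, float] = (0.6, 30.0)) -> float:
    """Percentage of in-band PSD bins strictly above DP/4."""
    mask = _band_mask(psd, df_band_cpm)
    p = psd.power[mask]
    if len(p) == 0:
        raise ValueError("empty band")
    dp = p.max()
    return float(100.0 * np.count_nonzero(p > dp / 4.0) / len(p))


def spectral_entropy(
    psd: PSDEstimate, band_cpm: tuple[float, float] = (0.6, 30.0)
) -> float:
    """Shannon entropy of the normalized in-band PSD, scaled to [0, 1]."""
    p = psd.power[_band_mask(psd, band_cpm)]
    total = p.sum()
    if total <= 0:
        raise ValueError("zero in-band power")
    q = p / total
    q = q[q > 0]
    if len(q) == 1:
        return 0.0
    return float(-np.sum(q * np.log(q)) / np.log(len(p)))


def band_powers(
    psd: PSDEstimate,
    bands_cpm=((3.0, 8.0), (8.0, 11.0), (11.0, 15.0)),
    total_band_cpm: tuple[float, float] = (0.6, 30.0),
) -> tuple[float, float, float]:
    """Relative band powers (brady/normo/tachygastria by default),
    normalized by the total passband power."""
    total = psd.power[_band_mask(psd, total_band_cpm)].sum()
    if total <= 0:
        raise ValueError("zero passband power")
    return tuple(
        float(psd.power[_band_mask(psd, b)].sum() / total) for b in bands_cpm
    )


def psd_crest_factor(
    psd: PSDEstimate, band_cpm: tuple[float, float] = (0.6, 30.0)
) -> float:
    """max/RMS of the in-band PSD: 1 for a flat spectrum, sqrt(#bins) for
    a single spike."""
    p = psd.power[_band_mask(psd, band_cpm)]
    r = np.sqrt(np.mean(p * p))
    if r == 0:
        raise ValueError("zero in-band power")
    return float(p.max() / r)


def median_frequency(
    psd: PSDEstimate, band_cpm: tuple[float, float] = (0.6, 30.0)
) -> float:
    """Smallest grid frequency at which cumulative in-band power reaches
    half the total."""
    mask = _band_mask(psd, band_cpm)
    f, p = psd.freqs_cpm[mask], psd.power[mask]
    total = p.sum()
    if total <= 0:
        raise ValueError("zero in-band power")
    i = int(np.searchsorted(np.cumsum(p), 0.5 * total))
    return float(f[min(i, len(f) - 1)])


def mean_power_frequency(
    psd: PSDEstimate, band_cpm: tuple[float, float] = (0.6, 30.0)
) -> float:
    """Power-weighted mean frequency over the passband."""
    mask = _band_mask(psd, band_cpm)
    f, p = psd.freqs_cpm[mask], psd.power[mask]
    total = p.sum()
    if total <= 0:
        raise ValueError("zero in-band power")
    return float(np.sum(f * p) / total)


# ----------------------------------------------------------------------
# assembly
# ----------------------------------------------------------------------

def extract_features(
    window: CleanWindow, config: FeatureConfig | None = None
) -> dict:
    """Compute the full feature battery for one clean window.

    Returns an ordered mapping of the 27 named features plus the window's
    ``removed_pct`` and metadata.  Degenerate (near-constant) windows fall
    back to the documented defaults instead of failing; a zero-variance
    Hurst estimate falls back to 0.5 (no long-range memory).
    """
    cfg = config or FeatureConfig()
    x = window.samples
    try:
        mean, var, mode, median, skew, kurt = statistical_moments(x)
        mob, comp = hjorth_params(x)
        try:
            hurst = hurst_exponent(x)
        except ValueError:
            warnings.warn("degenerate window: Hurst set to 0.5")
            hurst = 0.5
        sampen = sample_entropy(x, cfg.sampen_m, cfg.sampen_r_factor)
        if math.isinf(sampen):
            sampen = 0.0  # no irregularity detectable
        psd = welch_psd(x, window.fs_hz, cfg)
        if psd.power[_band_mask(psd, cfg.df_band_cpm)].sum() <= 0:
            raise ValueError("zero passband power")
        df, dp = dominant_freq_power(psd, cfg.df_band_cpm)
        bp1, bp2, bp3 = band_powers(psd, cfg.bands_cpm, cfg.df_band_cpm)
        feats = {
            "mean": mean, "variance": var, "mode": mode, "median": median,
            "skewness": skew, "kurtosis": kurt,
            "rms": rms(x), "line_length": line_length(x),
            "apen": approx_entropy(x, cfg.apen_m, cfg.apen_r_factor),
            "sampen": sampen,
            "pren": permutation_entropy(x, cfg.perm_order, cfg.perm_delay),
            "svden": svd_entropy(x, cfg.svd_order, cfg.svd_delay),
            "lz": lempel_ziv(x),
            "hjorth_mobility": mob, "hjorth_complexity": comp,
            "pfd": petrosian_fd(x), "hurst": hurst,
            "df": df, "dp": dp,
            "pmmp": pmmp(psd, cfg.df_band_cpm),
            "spen": spectral_entropy(psd, cfg.df_band_cpm),
            "bp1": bp1, "bp2": bp2, "bp3": bp3,
            "crest_factor": psd_crest_factor(psd, cfg.df_band_cpm),
            "mf": median_frequency(psd, cfg.df_band_cpm),
            "mpf": mean_power_frequency(psd, cfg.df_band_cpm),
        }
    except ValueError as err:
        if "zero passband power" not in str(err):
            raise ValueError(
                f"feature extraction failed for window "
                f"{window.session_id}@{window.start_time_s:.0f}s: {err}"
            ) from err
        # fully degenerate spectrum: spectral features default to 0
        warnings.warn("degenerate window: spectral features set to 0")
        base = {name: 0.0 for name in FEATURE_NAMES}
        mean, var, mode, median, skew, kurt = statistical_moments(x)
        base.update(
            mean=mean, variance=var, mode=mode, median=median,
            skewness=skew, kurtosis=kurt, rms=rms(x),
            line_length=line_length(x), pfd=petrosian_fd(x), hurst=0.5,
        )
        feats = {name: base[name] for name in FEATURE_NAMES}
    feats["removed_pct"] = window.removed_pct
    feats["label"] = window.label
    feats["subject_id"] = window.subject_id
    feats["session_id"] = window.session_id
    feats["stim_freq_hz"] = window.stim_freq_hz
    return feats


def build_feature_table(windows, config: FeatureConfig | None = None):
    """Feature DataFrame over a list of windows, columns in battery order
    followed by removed_pct and metadata."""
    import pandas as pd

    rows = [extract_features(w, config) for w in windows]
    cols = FEATURE_NAMES + [
        "removed_pct", "label", "subject_id", "session_id", "stim_freq_hz"
    ]
    return pd.DataFrame(rows, columns=cols)
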
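"""Nonlinear sway measures: RMS, sample entropy, Lyapunov exponent, DFA.

All four estimators operate on a single preprocessed acceleration component
(100 Hz, 5,000 samples at the default configuration):

* RMS — magnitude of sway, reported in mm·s⁻².
* Sample entropy (SEn) — negative natural log of the conditional probability
  that templates matching for M samples (Chebyshev distance within
  r = r_frac·SD, self-matches excluded) also match for M + 1.
* Largest Lyapunov exponent (LyE) — mean exponential divergence rate of
  initially nearby delay-embedded trajectories (Rosenstein's method), with
  the delay from the first minimum of the average mutual information and
  the dimension from false-nearest-neighbor analysis; slope taken over the
  first linear region of the divergence curve and converted to bits·s⁻¹.
* alpha-DFA — slope of log F(n) versus log n from first-order detrended
  fluctuation analysis, restricted to box sizes equivalent to the 2-10 Hz
  band (10-50 samples at 100 Hz) to target proprioceptive-loop timescales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sstats

from swaylab.io_config import RunConfig, logger
from swaylab.preprocess import CleanSignal

__all__ = [
    "SEnParams",
    "EmbeddingParams",
    "DFAParams",
    "ComplexityProfile",
    "rms",
    "sample_entropy",
    "sample_entropy_counts",
    "select_sen_params",
    "average_mutual_information",
    "first_minimum",
    "false_nearest_neighbors",
    "select_m",
    "reconstruct",
    "lyapunov_rosenstein",
    "divergence_curve",
    "dfa",
    "dfa_band_to_scales",
    "complexity_profile",
]


@dataclass
class SEnParams:
    M: int = 3
    r_frac: float = 0.07

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError(f"template length M must be >= 1, got {self.M}")
        if not (0 < self.r_frac < 1):
            raise ValueError(f"r_frac must lie in (0, 1), got {self.r_frac}")


@dataclass
class EmbeddingParams:
    m: int = 4
    tau: int = 17

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"embedding dimension must be >= 2, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"delay must be >= 1, got {self.tau}")


@dataclass
class DFAParams:
    n_min: int = 10
    n_max: int = 50
    n_scales: int = 10
    detrend_order: int = 1

    def __post_init__(self) -> None:
        if not (4 <= self.n_min < self.n_max):
            raise ValueError(f"require 4 <= n_min < n_max, got {self.n_min}, {self.n_max}")
        if self.n_scales < 4:
            raise ValueError(f"need at least 4 scales, got {self.n_scales}")


@dataclass
class ComplexityProfile:
    """Per-trial, per-axis sway measures."""

    rms: float  # mm·s⁻²
    sen: float  # dimensionless (reported "bit")
    lye: float  # bits·s⁻¹
    alpha_dfa: float

    def __post_init__(self) -> None:
        if np.isfinite(self.alpha_dfa) and not (0.2 < self.alpha_dfa < 2.0):
            logger.warning("alpha-DFA %.3f outside the typical (0.2, 2.0) range", self.alpha_dfa)


def rms(signal: CleanSignal | np.ndarray, unit_scale: float = 1000.0) -> float:
    """Root mean square of the signal, scaled (default m·s⁻² → mm·s⁻²)."""
    x = signal.samples if isinstance(signal, CleanSignal) else np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sqrt(np.mean(x**2)) * unit_scale)


# ---------------------------------------------------------------------------
# sample entropy


def sample_entropy_counts(x: np.ndarray, M: int, r: float) -> tuple[int, int]:
    """Template-match counts (A, B) underlying sample entropy.

    B counts unordered pairs of M-length templates within Chebyshev distance
    ``r`` (inclusive); A counts the subset whose (M+1)-length extensions
    also match.  Both counts run over the first N − M templates (those with
    an extension), excluding self-pairs.  Counting uses k-d trees under the
    infinity norm, which is exact and far faster than the O(N²) scan.
    """
    from scipy.spatial import cKDTree

    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= M + 1:
        raise ValueError(f"need more than M+1={M + 1} samples, got {n}")
    templates = sliding_window_view(x, M + 1)  # (n - M, M + 1)
    nt = templates.shape[0]
    tree_m = cKDTree(np.ascontiguousarray(templates[:, :M]))
    tree_m1 = cKDTree(np.ascontiguousarray(templates))
    # count_neighbors returns ordered pairs including self-pairs
    b = (int(tree_m.count_neighbors(tree_m, r, p=np.inf)) - nt) // 2
    a = (int(tree_m1.count_neighbors(tree_m1, r, p=np.inf)) - nt) // 2
    return a, b


def sample_entropy(x: np.ndarray, params: SEnParams | None = None) -> float:
    """Sample entropy −ln(A/B); +inf (with a warning) when no extension matches.

    The tolerance is ``params.r_frac`` times the series SD; a constant
    series (SD = 0) is rejected.
    """
    params = params or SEnParams()
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("sample entropy is undefined for a constant signal")
    a, b = sample_entropy_counts(x, params.M, params.r_frac * sd)
    if b == 0:
        raise ValueError("no template matches at length M; tolerance too small")
    if a == 0:
        logger.warning("no (M+1)-length matches; sample entropy is +inf")
        return float("inf")
    return float(-np.log(a / b))


def select_sen_params(
    records: list[np.ndarray],
    M_grid: list[int],
    r_grid: list[float],
) -> SEnParams:
    """Choose (M, r_frac) minimising the relative error of the SEn estimate.

    For each candidate the conditional probability CP = A/B is computed per
    record, its sampling error approximated by the binomial surrogate
    sigma = sqrt(CP(1−CP)/B), and the efficiency metric
    max(sigma/CP, sigma/(CP·|ln CP|)) taken.  The candidate minimising the
    median metric across records wins; ties resolve to the smaller M, then
    the larger r.
    """
    if not records or not M_grid or not r_grid:
        raise ValueError("need at least one record and non-empty grids")
    best: tuple[float, int, float] | None = None
    for M in M_grid:
        for r_frac in r_grid:
            metrics = []
            for rec in records:
                rec = np.asarray(rec, dtype=float)
                sd = float(np.std(rec))
                if sd == 0:
                    metrics.append(np.inf)
                    continue
                a, b = sample_entropy_counts(rec, M, r_frac * sd)
                if b == 0 or a == 0 or a == b:
                    metrics.append(np.inf)
                    continue
                cp = a / b
                sigma = np.sqrt(cp * (1 - cp) / b)
                metrics.append(max(sigma / cp, sigma / (cp * abs(np.log(cp)))))
            med = float(np.median(metrics))
            key = (med, M, -r_frac)
            if best is None or key < best:
                best = key
    if best is None or not np.isfinite(best[0]):
        raise ValueError("all candidate (M, r) pairs are degenerate on these records")
    return SEnParams(M=best[1], r_frac=-best[2])


# ---------------------------------------------------------------------------
# state-space reconstruction helpers


def reconstruct(x: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """Delay-embed a scalar series into m dimensions: rows [x_t, x_{t+τ}, ...]."""
    x = np.asarray(x, dtype=float)
    m, tau = params.m, params.tau
    n_vec = x.size - (m - 1) * tau
    if n_vec < 1:
        raise ValueError(f"series of {x.size} samples too short for m={m}, tau={tau}")
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :] * tau
    return x[idx]


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    if m == 1:
        return np.asarray(x, dtype=float)[:, None]
    return reconstruct(x, EmbeddingParams(m=m, tau=tau))


def average_mutual_information(
    x: np.ndarray, max_lag: int, n_bins: int | None = None
) -> np.ndarray:
    """AMI(τ) for τ = 0..max_lag from an equiprobable-bin 2-D histogram (nats).

    Bin count defaults to ceil(N^(1/3)); equiprobable marginal bins are
    obtained by rank transformation, which makes the estimate invariant to
    monotone rescaling of the signal.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_lag >= n // 2:
        raise ValueError(f"max_lag must be < N/2 = {n // 2}")
    if np.std(x) == 0:
        raise ValueError("AMI is undefined for a constant signal")
    n_bins = n_bins or int(np.ceil(n ** (1 / 3)))
    # tie-aware average ranks keep equal samples in one bin (strictly
    # periodic signals repeat values exactly)
    ranks = sstats.rankdata(x, method="average") - 0.5
    bins = np.clip((ranks * n_bins / n).astype(np.int64), 0, n_bins - 1)
    ami = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = bins[: n - lag]
        b = bins[lag:]
        joint = np.bincount(a * n_bins + b, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
        p = joint / joint.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        ami[lag] = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    return ami


def first_minimum(ami: np.ndarray, smooth: int = 5) -> int:
    """First local minimum of an AMI curve indexed from lag 0.

    Returns the smallest τ ≥ 1 with AMI(τ) < AMI(τ−1) and AMI(τ) ≤ AMI(τ+1),
    evaluated after a ``smooth``-point moving average — histogram AMI
    estimates carry sampling jitter that otherwise triggers spurious early
    minima on plateau-shaped curves.  Noise-like curves may have no
    interior minimum; the fallback is the first lag dropping below
    AMI(1)/e, else lag 1, each with a warning.
    """
    ami = np.asarray(ami, dtype=float)
    if smooth > 1 and ami.size > smooth + 2:
        kernel = np.ones(smooth) / smooth
        curve = np.convolve(ami, kernel, mode="valid")
        offset = smooth // 2
    else:
        curve, offset = ami, 0
    for tau in range(1, curve.size - 1):
        if curve[tau] < curve[tau - 1] and curve[tau] <= curve[tau + 1]:
            return tau + offset
    below = np.flatnonzero(ami[1:] < ami[1] / np.e)
    if below.size:
        logger.warning("no AMI local minimum; falling back to 1/e drop at lag %d", below[0] + 1)
        return int(below[0] + 1)
    logger.warning("no AMI minimum or 1/e drop; defaulting to lag 1")
    return 1


def false_nearest_neighbors(
    x: np.ndarray,
    tau: int,
    m_max: int,
    rtol: float = 15.0,
    atol: float = 2.0,
    _chunk: int = 512,
) -> np.ndarray:
    """Fraction of false nearest neighbors for m = 1..m_max (Kennel criteria).

    A neighbor pair at dimension m is false when the extra (m+1)-th
    coordinate inflates its distance by more than ``rtol``, or when the
    inflated distance exceeds ``atol`` times the series SD (loneliness
    criterion for sparse data).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if (m_max) * tau >= n // 2:
        raise ValueError(f"m_max={m_max}, tau={tau} leave too few delay vectors (N={n})")
    r_a = float(np.std(x))
    fractions = np.empty(m_max)
    for m in range(1, m_max + 1):
        n_vec = n - m * tau  # restrict to vectors whose (m+1)-th coordinate exists
        emb = _embed(x, m, tau)[:n_vec]
        extra = x[m * tau : m * tau + n_vec]
        nn = _nearest_neighbors(emb, theiler=0, _chunk=_chunk)
        d = np.sqrt(((emb - emb[nn]) ** 2).sum(axis=1))
        e = np.abs(extra - extra[nn])
        valid = d > 0
        ratio_false = e[valid] / d[valid] > rtol
        lonely = np.sqrt(d[valid] ** 2 + e[valid] ** 2) / r_a > atol
        fractions[m - 1] = float(np.mean(ratio_false | lonely))
    return fractions


def select_m(fractions: np.ndarray, threshold: float = 0.01) -> int:
    """Smallest embedding dimension whose FNN fraction drops below threshold."""
    below = np.flatnonzero(np.asarray(fractions) < threshold)
    if below.size == 0:
        logger.warning("FNN fraction never dropped below %.2g; returning m_max", threshold)
        return len(fractions)
    return int(below[0] + 1)


def _nearest_neighbors(points: np.ndarray, theiler: int, _chunk: int = 512) -> np.ndarray:
    """Index of each point's nearest Euclidean neighbor, excluding indices
    within the Theiler window and zero-distance duplicates where possible."""
    n = points.shape[0]
    sq = (points**2).sum(axis=1)
    nn = np.empty(n, dtype=np.int64)
    idx = np.arange(n)
    for start in range(0, n, _chunk):
        block = points[start : start + _chunk]
        d2 = sq[start : start + _chunk, None] - 2 * block @ points.T + sq[None, :]
        rows = np.arange(block.shape[0])[:, None]
        mask = np.abs((start + rows) - idx[None, :]) <= theiler
        d2[mask] = np.inf
        d2[d2 <= 0] = np.inf  # exact duplicates give log(0); prefer a distinct neighbor
        nn[start : start + _chunk] = d2.argmin(axis=1)
    return nn


def divergence_curve(
    x: np.ndarray,
    params: EmbeddingParams,
    n_steps: int,
    theiler: int | None = None,
) -> np.ndarray:
    """Rosenstein mean log2 divergence ⟨log2 d_j(i)⟩ for i = 0..n_steps.

    Each delay vector is paired with its nearest neighbor outside the
    Theiler window (default (m−1)·τ); pairs are dropped once either
    trajectory runs off the end of the series.
    """
    emb = reconstruct(np.asarray(x, dtype=float), params)
    n = emb.shape[0]
    if theiler is None:
        theiler = (params.m - 1) * params.tau
    if n <= n_steps + 1:
        raise ValueError(f"only {n} delay vectors; need more than n_steps={n_steps}")
    nn = _nearest_neighbors(emb, theiler)
    curve = np.full(n_steps + 1, np.nan)
    base = np.arange(n)
    for i in range(n_steps + 1):
        ok = (base + i < n) & (nn + i < n)
        if not ok.any():
            break
        d = np.sqrt(((emb[base[ok] + i] - emb[nn[ok] + i]) ** 2).sum(axis=1))
        d = d[d > 0]
        if d.size == 0:
            continue
        curve[i] = float(np.mean(np.log2(d)))
    if np.isnan(curve).all():
        raise ValueError("no valid neighbor pairs for the divergence curve")
    return curve


def lyapunov_rosenstein(
    x: np.ndarray,
    params: EmbeddingParams,
    fit_lo: int = 0,
    fit_hi: int = 75,
    fs: float = 100.0,
    theiler: int | None = None,
) -> float:
    """Largest Lyapunov exponent in bits·s⁻¹.

    Least-squares slope of the mean log2 divergence curve over steps
    [fit_lo, fit_hi] (both endpoints included), multiplied by the sampling
    frequency.
    """
    if not (0 <= fit_lo < fit_hi):
        raise ValueError(f"require 0 <= fit_lo < fit_hi, got ({fit_lo}, {fit_hi})")
    curve = divergence_curve(x, params, fit_hi, theiler=theiler)
    steps = np.arange(fit_lo, fit_hi + 1)
    y = curve[fit_lo : fit_hi + 1]
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("divergence curve too short for the requested fit range")
    slope = np.polyfit(steps[ok], y[ok], 1)[0]
    return float(slope * fs)


# ---------------------------------------------------------------------------
# detrended fluctuation analysis


def dfa(x: np.ndarray, params: DFAParams | None = None, return_fluctuations: bool = False):
    """Scaling exponent alpha from first-order detrended fluctuation analysis.

    The mean-centred series is integrated; for each of ``n_scales``
    log-spaced box sizes the profile is split into non-overlapping boxes
    from the start (trailing remainder discarded), a per-box linear trend
    removed, and F(n) computed as the root mean squared residual.  Alpha is
    the OLS slope of log F(n) versus log n.
    """
    params = params or DFAParams()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 * params.n_max:
        raise ValueError(f"need N >= 4·n_max = {4 * params.n_max}, got {n}")
    profile = np.cumsum(x - x.mean())
    scales = np.unique(
        np.round(
            np.logspace(np.log10(params.n_min), np.log10(params.n_max), params.n_scales)
        ).astype(int)
    )
    scales = scales[(scales >= 4) & (scales <= n // 4)]
    if scales.size < 4:
        raise ValueError(f"fewer than 4 usable scales in [{params.n_min}, {params.n_max}]")
    fluct = np.empty(scales.size)
    for k, size in enumerate(scales):
        n_boxes = n // size
        boxes = profile[: n_boxes * size].reshape(n_boxes, size)
        t = np.arange(size, dtype=float)
        design = np.column_stack([t, np.ones(size)])
        coef, *_ = np.linalg.lstsq(design, boxes.T, rcond=None)
        resid = boxes.T - design @ coef
        fluct[k] = np.sqrt(np.mean(resid**2))
    alpha = float(np.polyfit(np.log(scales), np.log(fluct), 1)[0])
    if return_fluctuations:
        return alpha, scales, fluct
    return alpha


def dfa_band_to_scales(band: tuple[float, float], fs: float, n_samples: int = 5000) -> DFAParams:
    """Map a frequency band to period-equivalent DFA box sizes.

    A box of n samples corresponds to an oscillation at fs/n Hz, so the
    2-10 Hz band at 100 Hz maps to box sizes 10-50.  Bounds are clipped to
    the DFA validity range [4, N/4].
    """
    f_lo, f_hi = band
    if not (0 < f_lo < f_hi <= fs / 2):
        raise ValueError(f"require 0 < f_lo < f_hi <= fs/2, got {band} at fs={fs}")
    n_min = max(4, int(round(fs / f_hi)))
    n_max = min(n_samples // 4, int(round(fs / f_lo)))
    return DFAParams(n_min=n_min, n_max=n_max, n_scales=10, detrend_order=1)


# ---------------------------------------------------------------------------
# per-trial profile


def trial_measures(
    sig: CleanSignal, cfg: RunConfig | None = None, measures: tuple[str, ...] | None = None
) -> dict[str, float]:
    """Selected sway measures with the per-axis parameters from the config.

    Restricting ``measures`` (e.g. to ``("RMS",)``) skips the expensive
    estimators, which matters in large simulation studies.
    """
    cfg = cfg or RunConfig()
    x = sig.samples
    wanted = measures or ("RMS", "SEn", "LyE", "aDFA")
    out: dict[str, float] = {}
    if "RMS" in wanted:
        out["RMS"] = rms(x, cfg.unit_scale)
    if "SEn" in wanted:
        out["SEn"] = sample_entropy(x, SEnParams(M=cfg.sen_M, r_frac=cfg.sen_r_frac[sig.axis]))
    if "LyE" in wanted:
        embed = EmbeddingParams(m=cfg.embed_m, tau=cfg.embed_tau[sig.axis])
        lo, hi = cfg.lye_fit_range
        out["LyE"] = lyapunov_rosenstein(x, embed, fit_lo=lo, fit_hi=hi, fs=sig.fs)
    if "aDFA" in wanted:
        out["aDFA"] = dfa(x, dfa_band_to_scales(cfg.dfa_band, sig.fs, x.size))
    return out


def complexity_profile(sig: CleanSignal, cfg: RunConfig | None = None) -> ComplexityProfile:
    """All four sway measures with the per-axis parameters from the config."""
    vals = trial_measures(sig, cfg)
    return ComplexityProfile(
        rms=vals["RMS"], sen=vals["SEn"], lye=vals["LyE"], alpha_dfa=vals["aDFA"]
    )
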
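"""Raw trial → clean ML/AP acceleration signals.

Pipeline order: integer-factor downsampling with anti-alias filtering,
middle-crop to 50 s, static tilt correction into the anatomical frame,
zero-lag Butterworth bandpass, then a windowed-SD artifact screen on the
resultant horizontal acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from swaylab.io_config import RawRecording, RunConfig, logger

G = 9.81  # m·s⁻²


@dataclass
class CleanSignal:
    """One preprocessed horizontal acceleration component."""

    axis: str  # "ML" or "AP"
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.axis not in ("ML", "AP"):
            raise ValueError(f"axis must be ML or AP, got {self.axis!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("clean signal contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class ArtifactVerdict:
    """Outcome of the fivefold windowed-SD screen."""

    passed: bool
    window_sds: np.ndarray
    ratio: float


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Decimate by an integer factor with an anti-aliasing low-pass.

    A zero-phase 8th-order Chebyshev-I low-pass (0.05 dB ripple, cutoff at
    0.8× the target Nyquist) precedes sample picking, so out-of-band sensor
    noise cannot fold into the sway band.
    """
    x = np.asarray(x, dtype=float)
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs_in/fs_out must be an integer factor, got {fs_in}/{fs_out}")
    q = int(round(factor))
    if q == 1:
        return x.copy()
    return sps.decimate(x, q, ftype="iir", zero_phase=True)


def crop_middle(x: np.ndarray, fs: float, keep_s: float) -> np.ndarray:
    """Return the centred contiguous block of exactly ``keep_s * fs`` samples."""
    x = np.asarray(x)
    n_keep = int(round(keep_s * fs))
    if x.size < n_keep:
        raise ValueError(f"signal of {x.size} samples too short; need {n_keep}")
    start = (x.size - n_keep) // 2
    return x[start : start + n_keep]


def tilt_correct(acc_xyz: np.ndarray, g: float = G) -> tuple[np.ndarray, np.ndarray]:
    """Rotate tri-axial samples into the anatomical frame using static tilt.

    The per-trial mean acceleration is taken as the gravity direction (quiet
    stance assumption).  Two sequential rotations are applied: first about
    the ML axis by the angle that nulls the mean AP component, then about
    the AP axis by the angle that nulls the mean ML component.  The vertical
    axis is discarded; the returned ML and AP series have (numerically) zero
    mean by construction.
    """
    acc = np.asarray(acc_xyz, dtype=float)
    mean = acc.mean(axis=0)
    mag = float(np.linalg.norm(mean))
    if mag == 0.0:
        raise ValueError("zero-magnitude mean acceleration; cannot infer gravity direction")
    if abs(mag - g) > 0.2 * g:
        logger.warning(
            "mean acceleration magnitude %.3f deviates >20%% from g=%.2f; "
            "tilt correction may be unreliable",
            mag,
            g,
        )

    mx, my, mz = mean
    # rotation about X (ML axis) nulling the mean AP (Y) component
    theta_ap = np.arctan2(my, mz)
    c, s = np.cos(theta_ap), np.sin(theta_ap)
    rot_x = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    acc1 = acc @ rot_x.T
    m1 = rot_x @ mean
    # rotation about Y (AP axis) nulling the updated mean ML (X) component
    theta_ml = np.arctan2(m1[0], m1[2])
    c, s = np.cos(theta_ml), np.sin(theta_ml)
    rot_y = np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]])
    acc2 = acc1 @ rot_y.T
    ml = acc2[:, 0] - acc2[:, 0].mean()
    ap = acc2[:, 1] - acc2[:, 1].mean()
    return ml, ap


def bandpass(x: np.ndarray, fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-lag Butterworth bandpass (designed at ``order``, applied forward-backward)."""
    if not (0 < low < high < fs / 2):
        raise ValueError(f"require 0 < low < high < fs/2, got ({low}, {high}) at fs={fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def resultant(ml: np.ndarray, ap: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean magnitude of the horizontal acceleration vector."""
    ml = np.asarray(ml, dtype=float)
    ap = np.asarray(ap, dtype=float)
    if ml.shape != ap.shape:
        raise ValueError(f"length mismatch: {ml.shape} vs {ap.shape}")
    return np.hypot(ml, ap)


def artifact_screen(
    res: np.ndarray,
    fs: float,
    n_windows: int = 5,
    window_s: float = 10.0,
    ratio_max: float = 5.0,
) -> ArtifactVerdict:
    """Windowed-SD abnormality screen on the resultant acceleration.

    The series is split into ``n_windows`` consecutive non-overlapping
    windows; the trial fails iff the largest window SD strictly exceeds
    ``ratio_max`` times the smallest (the boundary value passes).
    """
    res = np.asarray(res, dtype=float)
    win = int(round(window_s * fs))
    if res.size != n_windows * win:
        raise ValueError(f"expected exactly {n_windows * win} samples, got {res.size}")
    sds = res.reshape(n_windows, win).std(axis=1, ddof=0)
    ratio = float(sds.max() / sds.min()) if sds.min() > 0 else np.inf
    return ArtifactVerdict(passed=not (sds.max() > ratio_max * sds.min()), window_sds=sds, ratio=ratio)


def preprocess_trial(
    rec: RawRecording, cfg: RunConfig | None = None
) -> tuple[CleanSignal, CleanSignal, ArtifactVerdict]:
    """Full preprocessing of one trial.

    Order: downsample each sensor axis → crop to the middle ``crop_s``
    seconds → tilt-correct into ML/AP → bandpass → artifact screen on the
    resultant of the filtered pair.  A failing verdict flags the trial; it
    is never silently dropped here.
    """
    cfg = cfg or RunConfig()
    down = np.column_stack(
        [downsample(rec.acc_xyz[:, i], rec.fs_in, cfg.fs_target) for i in range(3)]
    )
    cropped = np.column_stack(
        [crop_middle(down[:, i], cfg.fs_target, cfg.crop_s) for i in range(3)]
    )
    ml, ap = tilt_correct(cropped)
    low, high = cfg.band
    # a finite window of a zero-DC process still has a sample mean of order
    # SD/sqrt(cycles at the low cutoff); remove it to honour the zero-mean
    # contract of the clean signal
    ml_f = bandpass(ml, cfg.fs_target, low, high, cfg.filter_order)
    ap_f = bandpass(ap, cfg.fs_target, low, high, cfg.filter_order)
    ml_f -= ml_f.mean()
    ap_f -= ap_f.mean()
    verdict = artifact_screen(
        resultant(ml_f, ap_f),
        cfg.fs_target,
        cfg.artifact_windows,
        cfg.artifact_window_s,
        cfg.artifact_ratio,
    )
    if not verdict.passed:
        logger.warning(
            "trial %s failed the windowed-SD screen (ratio %.2f > %.1f)",
            rec.trial_id,
            verdict.ratio,
            cfg.artifact_ratio,
        )
    return (
        CleanSignal("ML", cfg.fs_target, ml_f),
        CleanSignal("AP", cfg.fs_target, ap_f),
        verdict,
    )
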
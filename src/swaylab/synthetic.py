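"""Synthetic sway signals and cohorts.

The generator emulates the measurement model of the study: a trunk-worn
IMU sampling tri-axial acceleration at 500 Hz for 60 s while a child
stands quietly.  Horizontal sway is modelled as band-limited colored noise
(controllable spectral exponent beta → long-range correlation), mixed with
a low-frequency oscillation (controllable regularity) and a broadband
white measurement-noise floor (controllable local divergence), scaled to a
target RMS and embedded into a tilted sensor frame carrying gravity.

Cohorts impose multiplicative group (YO vs YN) and condition (firm vs
foam) effects on the knobs — not on the measures — so recovering the
imposed structure through the full pipeline is a genuine inverse problem.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from swaylab.io_config import CONDITIONS, GROUPS, VISITS, RawRecording

G = 9.81

#: spectral support of the colored sway core (Hz); kept inside the 0.3-10 Hz
#: analysis band so the preprocessing chain preserves its amplitude
SWAY_BAND = (0.5, 8.0)


@dataclass
class SwayKnobs:
    """Control knobs of one simulated trial.

    beta — spectral exponent of the colored core (power ∝ f^−beta); raising
    it strengthens long-range correlation (higher alpha-DFA), makes the
    signal more repeatable (lower SEn) and steepens the divergence curve
    from its lower starting distance (higher LyE);
    periodic_weight — fraction of sway variance from a low-frequency
    oscillation (more weight → more regular → lower SEn, higher alpha);
    amp — target RMS of the horizontal sway in m·s⁻²;
    noise_floor — SD of the broadband white sensor noise in m·s⁻²; its
    in-band residue adds irregularity (raises SEn) and lifts the early
    divergence curve, flattening the Rosenstein slope (lowers LyE);
    tilt_deg — static (pitch, roll) of the sensor in degrees;
    ap_gain — AP amplitude relative to ML;
    osc_freq — oscillation frequency in Hz.
    """

    beta: float = 1.3
    periodic_weight: float = 0.25
    amp: float = 0.045
    noise_floor: float = 0.02
    tilt_deg: tuple[float, float] = (3.0, 1.5)
    ap_gain: float = 1.1
    osc_freq: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.beta <= 2):
            raise ValueError(f"beta must lie in [0, 2], got {self.beta}")
        if not (0 <= self.periodic_weight <= 1):
            raise ValueError(f"periodic_weight must lie in [0, 1], got {self.periodic_weight}")
        if self.amp <= 0:
            raise ValueError(f"amp must be positive, got {self.amp}")
        if self.noise_floor < 0:
            raise ValueError(f"noise_floor must be non-negative, got {self.noise_floor}")

    def scaled(self, factors: dict[str, float]) -> "SwayKnobs":
        """New knobs with multiplicative factors applied (beta/weight clipped)."""
        values = dataclasses.asdict(self)
        for key, factor in factors.items():
            if key not in values:
                raise KeyError(f"unknown knob {key!r}")
            if factor <= 0:
                raise ValueError(f"factor for {key!r} must be positive, got {factor}")
            values[key] = values[key] * factor
        values["beta"] = float(np.clip(values["beta"], 0.0, 2.0))
        values["periodic_weight"] = float(np.clip(values["periodic_weight"], 0.0, 1.0))
        values["tilt_deg"] = tuple(values["tilt_deg"])
        return SwayKnobs(**values)


@dataclass
class CohortSpec:
    """Design of a synthetic 2 (group) × 2 (condition) × 2 (visit) cohort.

    ``group_effects`` multiply the YO arm's knobs, ``condition_effects``
    the foam trials'.  Subjects get log-normal between-subject knob spread
    (SD ``between_subject_sd`` on the log scale) and each visit a shared
    log-normal retest jitter (SD ``visit_jitter_sd``), which makes
    test-retest ICCs land in a fair-to-excellent range.
    """

    n_per_group: int = 19
    base: SwayKnobs = field(default_factory=SwayKnobs)
    group_effects: dict = field(
        default_factory=lambda: {
            "periodic_weight": 1.5,
            "beta": 1.12,
            "ap_gain": 1.2,
        }
    )
    condition_effects: dict = field(
        default_factory=lambda: {
            "amp": 1.5,
            "periodic_weight": 1.25,
            "beta": 1.06,
        }
    )
    between_subject_sd: float = 0.15
    visit_jitter_sd: float = 0.06
    duration_s: float = 60.0
    fs: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError(f"need n_per_group >= 2, got {self.n_per_group}")
        for name, effects in [("group_effects", self.group_effects), ("condition_effects", self.condition_effects)]:
            for key, factor in effects.items():
                if factor <= 0:
                    raise ValueError(f"{name}[{key!r}] must be positive, got {factor}")


def gen_colored_noise(
    n: int,
    beta: float,
    seed: int | np.random.Generator = 0,
    fs: float = 1.0,
    band: tuple[float, float] | None = None,
) -> np.ndarray:
    """Unit-variance colored noise via spectral synthesis.

    Fourier amplitudes are set proportional to f^(−beta/2) with uniform
    random phases; beta = 0 reduces to white noise.  An optional ``band``
    (Hz at sampling rate ``fs``) zeroes all components outside it.
    """
    if n < 64:
        raise ValueError(f"need n >= 64, got {n}")
    if not (0 <= beta <= 2):
        raise ValueError(f"beta must lie in [0, 2], got {beta}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    if band is not None:
        lo, hi = band
        amp[(freqs < lo) | (freqs > hi)] = 0.0
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate spectrum: no energy in the requested band")
    return (x - x.mean()) / sd


def gen_oracle_signals(
    kind: str, n: int, params: dict | None = None, seed: int = 0
) -> np.ndarray:
    """Exactly-known fixture signals for the estimators.

    kinds: ``sine`` (params f, fs, amplitude), ``logistic_map`` (r = 4,
    seeded x0, 100-step burn-in), ``periodic_pattern`` (a fixed pattern
    tiled), ``brown`` (cumulative sum of white noise).
    """
    if n < 100:
        raise ValueError(f"need n >= 100, got {n}")
    params = params or {}
    rng = np.random.default_rng(seed)
    if kind == "sine":
        f = params.get("f", 1.0)
        fs = params.get("fs", 100.0)
        amplitude = params.get("amplitude", 1.0)
        t = np.arange(n) / fs
        return amplitude * np.sin(2 * np.pi * f * t + params.get("phase", 0.0))
    if kind == "logistic_map":
        r = params.get("r", 4.0)
        x = float(rng.uniform(0.05, 0.95))
        out = np.empty(n)
        for _ in range(100):
            x = r * x * (1 - x)
        for i in range(n):
            x = r * x * (1 - x)
            out[i] = x
        return out
    if kind == "periodic_pattern":
        pattern = np.asarray(params.get("pattern", [0.0, 1.0, 2.0, 1.0]), dtype=float)
        return np.tile(pattern, int(np.ceil(n / pattern.size)))[:n]
    if kind == "brown":
        return np.cumsum(rng.standard_normal(n))
    raise ValueError(f"unknown oracle signal kind {kind!r}")


def gen_sway_trial(
    knobs: SwayKnobs,
    duration_s: float = 60.0,
    fs: float = 500.0,
    seed: int | np.random.Generator = 0,
    *,
    subject_id: str = "S01",
    group: str = "YN",
    condition: str = "firm",
    visit: int = 1,
) -> RawRecording:
    """One tri-axial 60 s quiet-stance trial at the acquisition rate.

    Horizontal sway per axis = sqrt(1−w)·colored core + sqrt(w)·oscillation
    (both unit variance), scaled to the target RMS, plus the white noise
    floor; the AP axis is ``ap_gain`` times larger.  The three body-frame
    axes (ML, AP, vertical = g) are rotated by the static sensor tilt.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    w = knobs.periodic_weight
    t = np.arange(n) / fs

    def horizontal(gain: float) -> np.ndarray:
        core = gen_colored_noise(n, knobs.beta, rng, fs=fs, band=SWAY_BAND)
        osc = np.sqrt(2.0) * np.sin(2 * np.pi * knobs.osc_freq * t + rng.uniform(0, 2 * np.pi))
        sway = np.sqrt(1 - w) * core + np.sqrt(w) * osc
        return gain * knobs.amp * sway + knobs.noise_floor * rng.standard_normal(n)

    ml = horizontal(1.0)
    ap = horizontal(knobs.ap_gain)
    body = np.column_stack([ml, ap, np.full(n, G)])

    pitch, roll = np.deg2rad(knobs.tilt_deg)
    c, s = np.cos(pitch), np.sin(pitch)
    rot_x = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    c, s = np.cos(roll), np.sin(roll)
    rot_y = np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]])
    sensor = body @ (rot_x @ rot_y).T

    return RawRecording(
        subject_id=subject_id,
        group=group,
        condition=condition,
        visit=visit,
        fs_in=fs,
        acc_xyz=sensor,
    )


def gen_cohort(spec: CohortSpec) -> tuple[list[RawRecording], pd.DataFrame]:
    """Full synthetic cohort plus the ground-truth knob table.

    Returns ``n_per_group × 2 groups × 2 conditions × 2 visits`` recordings
    and a truth table joining 1:1 with them on (subject, condition, visit).
    Subjects are matched across groups by index (YO01 ↔ YN01), mirroring
    the matched-pairs recruitment.
    """
    root = np.random.SeedSequence(spec.seed)
    recordings: list[RawRecording] = []
    truth_rows: list[dict] = []
    jitter_knobs = ["beta", "periodic_weight", "amp", "noise_floor"]

    for group in GROUPS:
        for s_idx in range(spec.n_per_group):
            subject_id = f"{group}{s_idx + 1:02d}"
            ss = np.random.SeedSequence(
                spec.seed, spawn_key=(GROUPS.index(group), s_idx)
            )
            rng = np.random.default_rng(ss)
            subject_factors = {
                k: float(np.exp(rng.normal(0, spec.between_subject_sd))) for k in jitter_knobs
            }
            visit_factors = {
                v: {k: float(np.exp(rng.normal(0, spec.visit_jitter_sd))) for k in jitter_knobs}
                for v in VISITS
            }
            for condition in CONDITIONS:
                for visit in VISITS:
                    knobs = spec.base
                    if group == "YO":
                        knobs = knobs.scaled(spec.group_effects)
                    if condition == "foam":
                        knobs = knobs.scaled(spec.condition_effects)
                    knobs = knobs.scaled(subject_factors).scaled(visit_factors[visit])
                    rec = gen_sway_trial(
                        knobs,
                        duration_s=spec.duration_s,
                        fs=spec.fs,
                        seed=np.random.default_rng(rng.integers(2**31)),
                        subject_id=subject_id,
                        group=group,
                        condition=condition,
                        visit=visit,
                    )
                    recordings.append(rec)
                    row = {
                        "subject": subject_id,
                        "group": group,
                        "condition": condition,
                        "visit": visit,
                    }
                    row.update(
                        {k: v for k, v in dataclasses.asdict(knobs).items() if k != "tilt_deg"}
                    )
                    truth_rows.append(row)
    return recordings, pd.DataFrame(truth_rows)
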
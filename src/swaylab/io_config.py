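"""IMU text-export I/O, study-table serialisation and run configuration.

The acquisition device stores each trial as a delimited text file with one
sample per row and one column per accelerometer axis.  The exact export
schema (axis order, delimiter, header) varies between firmware versions, so
a small :class:`Dialect` mapping absorbs it.  All internal accelerations are
in m·s⁻²; RMS values are reported ×1000 as mm·s⁻².
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("swaylab")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

GROUPS = ("YO", "YN")
CONDITIONS = ("firm", "foam")
VISITS = (1, 2)
AXES = ("ML", "AP")
MEASURES = ("RMS", "SEn", "LyE", "aDFA")

#: fixed header of every study-table CSV written by :func:`write_measures`
TABLE_COLUMNS = ["subject", "group", "condition", "visit", "axis", "measure", "value", "units"]

MEASURE_UNITS = {"RMS": "mm.s-2", "SEn": "bit", "LyE": "bit.s-1", "aDFA": ""}


@dataclass
class RawRecording:
    """One 60 s tri-axial acceleration trial plus its study metadata.

    ``acc_xyz`` rows are samples; columns are sensor X (ML), Y (AP) and
    Z (vertical, carrying gravity when the sensor is level).
    """

    subject_id: str
    group: str
    condition: str
    visit: int
    fs_in: float
    acc_xyz: np.ndarray  # shape (n, 3), m·s⁻²

    def __post_init__(self) -> None:
        self.acc_xyz = np.asarray(self.acc_xyz, dtype=float)
        if self.acc_xyz.ndim != 2 or self.acc_xyz.shape[1] != 3:
            raise ValueError("acc_xyz must have shape (n_samples, 3)")
        if self.fs_in <= 0:
            raise ValueError("fs_in must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if int(self.visit) not in VISITS:
            raise ValueError(f"visit must be 1 or 2, got {self.visit!r}")
        self.visit = int(self.visit)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n / fs_in)."""
        return self.acc_xyz.shape[0] / self.fs_in

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}_{self.condition}_v{self.visit}"


@dataclass
class RunConfig:
    """All fixed constants of the analysis, with the published defaults.

    Defaults: 500 Hz acquisition down-sampled to 100 Hz, middle 50 s kept
    (5,000 samples), 4th-order zero-lag Butterworth bandpass 0.3-10 Hz,
    artifact screen of five 10 s windows with a fivefold SD rule, SEn with
    M = 3 and r = 0.07·SD (ML) / 0.06·SD (AP), delay embedding with m = 4
    and tau = 17 (ML) / 20 (AP) samples, Lyapunov fit over divergence steps
    0-75, DFA over the box sizes matching 2-10 Hz, ICC poor-reliability
    gate at 0.40 and alpha level 0.05.
    """

    fs_target: float = 100.0
    crop_s: float = 50.0
    band: tuple[float, float] = (0.3, 10.0)
    filter_order: int = 4
    sen_M: int = 3
    sen_r_frac: dict = field(default_factory=lambda: {"ML": 0.07, "AP": 0.06})
    embed_m: int = 4
    embed_tau: dict = field(default_factory=lambda: {"ML": 17, "AP": 20})
    lye_fit_range: tuple[int, int] = (0, 75)
    dfa_band: tuple[float, float] = (2.0, 10.0)
    artifact_windows: int = 5
    artifact_window_s: float = 10.0
    artifact_ratio: float = 5.0
    bootstrap_B: int = 10_000
    seed: int = 0
    icc_poor_threshold: float = 0.40
    alpha_level: float = 0.05
    unit_scale: float = 1000.0  # m·s⁻² → mm·s⁻²

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high):
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")
        if high >= self.fs_target / 2:
            raise ValueError(
                f"band high {high} Hz violates the Nyquist limit {self.fs_target / 2} Hz"
            )
        if self.artifact_ratio <= 1:
            raise ValueError(f"artifact_ratio must exceed 1, got {self.artifact_ratio}")
        if self.sen_M < 1:
            raise ValueError(f"sen_M must be >= 1, got {self.sen_M}")
        if self.crop_s <= 0 or self.fs_target <= 0:
            raise ValueError("crop_s and fs_target must be positive")
        if self.filter_order < 1:
            raise ValueError(f"filter_order must be >= 1, got {self.filter_order}")
        f_lo, f_hi = self.dfa_band
        if not (0 < f_lo < f_hi <= self.fs_target / 2):
            raise ValueError(f"dfa_band must satisfy 0 < lo < hi <= Nyquist, got {self.dfa_band}")

    @property
    def n_samples(self) -> int:
        """Samples per clean signal (5,000 at defaults)."""
        return int(round(self.crop_s * self.fs_target))

    def rng(self, *stream: object) -> np.random.Generator:
        """Named sub-stream generator so every random draw traces to ``seed``.

        Stream names are hashed with CRC32 (stable across processes, unlike
        built-in ``hash``) so identical runs are bit-reproducible.
        """
        key = tuple(zlib.crc32(str(s).encode()) for s in stream)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))


@dataclass
class Dialect:
    """Column layout of a delimited IMU export."""

    delimiter: str = "\t"
    columns: tuple[int, int, int] = (0, 1, 2)  # file columns for (X/ML, Y/AP, Z/vertical)
    skip_header: int = 0
    unit_factor: float = 1.0  # multiply file values to obtain m·s⁻²


def read_imu_text(
    path: str | Path,
    dialect: Dialect | None = None,
    *,
    subject_id: str,
    group: str,
    condition: str,
    visit: int,
    fs_in: float = 500.0,
    bad_row_tolerance: float = 0.01,
) -> RawRecording:
    """Read a delimited one-sample-per-row acceleration export.

    Non-numeric or non-finite rows are dropped with a logged count; if they
    exceed ``bad_row_tolerance`` (fraction of all rows) the file is rejected
    with the offending line numbers named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"IMU file not found: {path}")
    dialect = dialect or Dialect()

    raw = pd.read_csv(
        path,
        sep=dialect.delimiter,
        header=None,
        skiprows=dialect.skip_header,
        engine="python",
        comment="#",
    )
    if raw.empty:
        raise ValueError(f"no samples in {path}")
    needed = max(dialect.columns) + 1
    if raw.shape[1] < needed:
        raise ValueError(
            f"{path}: expected at least {needed} columns "
            f"(dialect columns {dialect.columns}), found {raw.shape[1]}"
        )
    cols = raw.iloc[:, list(dialect.columns)].apply(pd.to_numeric, errors="coerce")
    good = np.isfinite(cols.to_numpy(dtype=float)).all(axis=1)
    n_bad = int((~good).sum())
    if n_bad:
        bad_lines = (np.flatnonzero(~good) + 1 + dialect.skip_header).tolist()
        if n_bad > bad_row_tolerance * len(good):
            raise ValueError(
                f"{path}: {n_bad} malformed rows exceed tolerance "
                f"{bad_row_tolerance:.1%}; lines {bad_lines[:20]}"
                + ("..." if n_bad > 20 else "")
            )
        logger.warning("%s: dropped %d malformed rows (lines %s)", path, n_bad, bad_lines[:20])
    acc = cols.to_numpy(dtype=float)[good] * dialect.unit_factor
    if acc.shape[0] == 0:
        raise ValueError(f"no samples in {path}")
    return RawRecording(
        subject_id=subject_id,
        group=group,
        condition=condition,
        visit=visit,
        fs_in=fs_in,
        acc_xyz=acc,
    )


def write_recording(rec: RawRecording, path: str | Path, dialect: Dialect | None = None) -> None:
    """Write a recording in the same text dialect :func:`read_imu_text` consumes."""
    dialect = dialect or Dialect()
    out = np.empty_like(rec.acc_xyz)
    out[:, list(dialect.columns)] = rec.acc_xyz / dialect.unit_factor
    np.savetxt(path, out, delimiter=dialect.delimiter, fmt="%.9g")


def write_measures(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format study table as CSV with the fixed header.

    Missing values are written as the literal ``NA``; the file round-trips
    losslessly through :func:`read_measures`.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty study table")
    out = table.copy()
    if "units" not in out.columns:
        out["units"] = out["measure"].map(MEASURE_UNITS).fillna("")
    missing = [c for c in TABLE_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"study table lacks required columns: {missing}")
    out = out[TABLE_COLUMNS]
    out.to_csv(path, index=False, na_rep="NA", float_format="%.12g")


def read_measures(path: str | Path) -> pd.DataFrame:
    """Read a study table written by :func:`write_measures`."""
    df = pd.read_csv(
        path,
        na_values=["NA"],
        keep_default_na=False,
        dtype={"subject": str, "group": str, "condition": str, "axis": str, "measure": str, "units": str},
    )
    df["visit"] = df["visit"].astype(int)
    df["value"] = df["value"].astype(float)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is not a study table; missing columns {missing}")
    return df


# fields that the YAML config may override, with bounds checked in RunConfig
_TUPLE_FIELDS = {"band", "lye_fit_range", "dfa_band"}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file, falling back to defaults.

    Unknown keys raise; every out-of-range value raises with the field and
    bound named (via RunConfig validation).  The full effective configuration
    is echoed to the log.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded:
            if not isinstance(loaded, dict):
                raise ValueError(f"config {path} must be a mapping")
            data.update(loaded)
    if overrides:
        data.update(overrides)

    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(data):
        data[key] = tuple(data[key])
    cfg = RunConfig(**data)
    logger.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg


def profiles_to_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble per-trial measure dicts into a long-format study table."""
    df = pd.DataFrame(list(rows))
    df["units"] = df["measure"].map(MEASURE_UNITS).fillna("")
    return df[TABLE_COLUMNS]
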
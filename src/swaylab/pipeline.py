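"""Study orchestration: preprocess → complexity → reliability → inference.

Trials failing the windowed-SD artifact screen exclude their whole subject
(mirroring the recruitment-level exclusion of corrupted signals), and the
subject's matched control in the other group is dropped with them so the
design stays balanced.  The reliability gate removes measure × axis
combinations with any poor ICC cell from inferential testing; their
descriptives are still reported.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from swaylab.complexity import trial_measures
from swaylab.io_config import (
    AXES,
    MEASURES,
    Dialect,
    RawRecording,
    RunConfig,
    logger,
    profiles_to_table,
    read_imu_text,
    write_measures,
)
from swaylab.preprocess import preprocess_trial
from swaylab.stats import (
    icc_1_1,
    log1_transform,
    mixed_anova_2x2x2,
    posthoc_pairwise_bh,
    reliability_gate,
)


@dataclass
class PipelineResult:
    table: pd.DataFrame  # long-format study table (descriptives, all subjects kept)
    icc: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    manifest: dict
    excluded_measures: list = field(default_factory=list)


def load_cohort_dir(input_dir: str | Path, dialect: Dialect | None = None) -> list[RawRecording]:
    """Read a cohort from a directory of trial text files plus metadata.csv.

    metadata.csv columns: subject, group, condition, visit, file, fs.
    """
    input_dir = Path(input_dir)
    meta_path = input_dir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.csv in {input_dir}")
    meta = pd.read_csv(meta_path, dtype={"subject": str})
    required = {"subject", "group", "condition", "visit", "file"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata.csv lacks columns {sorted(missing)}")
    recordings = []
    for row in meta.itertuples(index=False):
        recordings.append(
            read_imu_text(
                input_dir / row.file,
                dialect,
                subject_id=row.subject,
                group=row.group,
                condition=row.condition,
                visit=int(row.visit),
                fs_in=float(getattr(row, "fs", 500.0)),
            )
        )
    return recordings


def _matched_partner(subject_id: str) -> str:
    """Matched control of a subject under the YO01 ↔ YN01 pairing convention."""
    if subject_id.startswith("YO"):
        return "YN" + subject_id[2:]
    if subject_id.startswith("YN"):
        return "YO" + subject_id[2:]
    return ""


def run_pipeline(
    recordings: list[RawRecording],
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
    measures: tuple[str, ...] = MEASURES,
) -> PipelineResult:
    """Run the complete analysis on an in-memory cohort.

    Returns the study table, the ICC grid, the ANOVA and post-hoc reports
    (per retained measure × axis) and a manifest recording every input's
    artifact verdict and every exclusion with its reason.
    """
    cfg = cfg or RunConfig()
    if not recordings:
        raise ValueError("empty cohort")

    inputs_manifest = []
    excluded_subjects: dict[str, str] = {}
    clean: dict[str, dict] = {}
    for rec in recordings:
        ml, ap, verdict = preprocess_trial(rec, cfg)
        inputs_manifest.append(
            {
                "trial": rec.trial_id,
                "subject": rec.subject_id,
                "verdict": "pass" if verdict.passed else "fail",
                "sd_ratio": round(verdict.ratio, 4),
            }
        )
        if not verdict.passed:
            excluded_subjects.setdefault(
                rec.subject_id,
                f"trial {rec.trial_id} failed the windowed-SD screen "
                f"(ratio {verdict.ratio:.2f} > {cfg.artifact_ratio:.1f})",
            )
        clean[rec.trial_id] = {"rec": rec, "ML": ml, "AP": ap}

    # whole-subject exclusion cascades to the matched control
    for subject, reason in list(excluded_subjects.items()):
        partner = _matched_partner(subject)
        if partner and partner not in excluded_subjects and any(
            e["subject"] == partner for e in inputs_manifest
        ):
            excluded_subjects[partner] = f"matched control of excluded subject {subject}"

    rows = []
    for entry in clean.values():
        rec = entry["rec"]
        for axis in AXES:
            values = trial_measures(entry[axis], cfg, measures)
            for measure in measures:
                rows.append(
                    {
                        "subject": rec.subject_id,
                        "group": rec.group,
                        "condition": rec.condition,
                        "visit": rec.visit,
                        "axis": axis,
                        "measure": measure,
                        "value": values[measure],
                    }
                )
    table = profiles_to_table(rows)

    analysis = table[~table["subject"].isin(excluded_subjects)].copy()
    if analysis.empty:
        raise ValueError("empty cohort after artifact exclusions")
    analysis.loc[~np.isfinite(analysis["value"]), "value"] = np.nan

    icc_df = compute_icc_grid(analysis)
    excluded_measures = reliability_gate(icc_df, cfg.icc_poor_threshold)

    anova_reports, posthoc_reports = [], []
    for measure in measures:
        for axis in AXES:
            if (measure, axis) in excluded_measures:
                continue
            sub = analysis[(analysis["measure"] == measure) & (analysis["axis"] == axis)].copy()
            if sub["value"].isna().any():
                bad = sub.loc[sub["value"].isna(), "subject"].unique().tolist()
                logger.warning(
                    "%s/%s: missing values for subjects %s; skipping inference",
                    measure,
                    axis,
                    bad,
                )
                continue
            sub["value"] = log1_transform(sub["value"].to_numpy())
            anova = mixed_anova_2x2x2(sub)
            significant = (anova["p"] < cfg.alpha_level).any()
            posthoc = (
                posthoc_pairwise_bh(sub, anova, cfg.alpha_level)
                if significant
                else pd.DataFrame()
            )
            anova.insert(0, "axis", axis)
            anova.insert(0, "measure", measure)
            anova_reports.append(anova)
            if len(posthoc):
                posthoc.insert(0, "axis", axis)
                posthoc.insert(0, "measure", measure)
                posthoc_reports.append(posthoc)

    anova_df = pd.concat(anova_reports, ignore_index=True) if anova_reports else pd.DataFrame()
    posthoc_df = pd.concat(posthoc_reports, ignore_index=True) if posthoc_reports else pd.DataFrame()

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "inputs": inputs_manifest,
        "excluded_subjects": [
            {"subject": s, "reason": r} for s, r in sorted(excluded_subjects.items())
        ],
        "excluded_measures": [
            {"measure": m, "axis": a, "reason": "ICC at or below poor threshold"}
            for m, a in excluded_measures
        ],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": [],
    }

    result = PipelineResult(
        table=table,
        icc=icc_df,
        anova=anova_df,
        posthoc=posthoc_df,
        manifest=manifest,
        excluded_measures=excluded_measures,
    )
    if out_dir is not None:
        write_reports(result, out_dir)
    return result


def compute_icc_grid(table: pd.DataFrame) -> pd.DataFrame:
    """ICC(1,1) per measure × axis × group × condition across the two visits."""
    rows = []
    for (measure, axis, group, condition), sub in table.groupby(
        ["measure", "axis", "group", "condition"]
    ):
        cell = sub.pivot_table(index="subject", columns="visit", values="value")
        if cell.shape[1] != 2 or cell.dropna().shape[0] < 3:
            raise ValueError(
                f"ICC needs both visits for >= 3 subjects in {measure}/{axis}/{group}/{condition}"
            )
        paired = cell.dropna()
        icc, band = icc_1_1(paired[1].to_numpy(), paired[2].to_numpy())
        rows.append(
            {
                "measure": measure,
                "axis": axis,
                "group": group,
                "condition": condition,
                "icc": icc,
                "band": band,
            }
        )
    return pd.DataFrame(rows)


def write_reports(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write the study table, ICC grid, per measure × axis ANOVA/post-hoc
    reports and the manifest under ``out_dir``; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    p = out_dir / "measures.csv"
    write_measures(result.table, p)
    paths.append(p)

    p = out_dir / "icc.csv"
    result.icc.to_csv(p, index=False, float_format="%.6g")
    paths.append(p)

    if len(result.anova):
        for (measure, axis), sub in result.anova.groupby(["measure", "axis"]):
            p = out_dir / f"anova_{measure}_{axis}.csv"
            sub.to_csv(p, index=False, float_format="%.6g")
            paths.append(p)
    if len(result.posthoc):
        for (measure, axis), sub in result.posthoc.groupby(["measure", "axis"]):
            p = out_dir / f"posthoc_{measure}_{axis}.csv"
            sub.to_csv(p, index=False, float_format="%.6g")
            paths.append(p)

    result.manifest["outputs"] = [str(x) for x in paths]
    p = out_dir / "manifest.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=False)
    paths.append(p)
    return paths
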
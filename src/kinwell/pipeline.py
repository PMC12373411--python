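"""End-to-end cohort pipeline: simulate or ingest, compute, report.

Stage order mirrors the study's analysis: sensor streams -> kinematic metrics;
weekly questionnaires -> well-being classification and trends; daily logs ->
nutrition trends; pre/post surveys -> paired tests and effect sizes; finally
group-stratified metric trends combining the first two.

Every run writes a ``manifest.json`` listing each output file with its SHA-256
content hash: identical (config, seed, inputs) produce identical manifests.
Partial outputs are removed if a stage fails.  Only deidentified participant
ids ever appear in logs or outputs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import imu, nutrition, stats, synthetic, wellbeing
from .config import CohortConfig, PeakDetectionConfig
from .errors import InputError

log = logging.getLogger(__name__)

INGEST_FILES = ("sensors.csv", "mhcsf.csv", "nutrition.csv", "survey.csv")

_CSV_KW = dict(index=False, lineterminator="\n", encoding="utf-8")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: CohortConfig) -> str:
    doc = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(doc).hexdigest()


def run_pipeline(
    config: CohortConfig,
    out_dir: str | Path,
    mode: str = "simulate",
    input_dir: str | Path | None = None,
    peak_cfg: PeakDetectionConfig | None = None,
    study_start: _dt.date = synthetic.DEFAULT_STUDY_START,
    classification_basis: str = "week1",
    write_raw: bool = True,
) -> dict:
    """Execute the full pipeline and return the output manifest.

    ``mode="simulate"`` generates the cohort from ``config``;
    ``mode="ingest"`` reads the four input CSVs (sensors, mhcsf, nutrition,
    survey) from ``input_dir``.
    """
    if mode not in ("simulate", "ingest"):
        raise InputError(f"mode must be 'simulate' or 'ingest', got {mode!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peak_cfg = peak_cfg or PeakDetectionConfig()
    written: list[Path] = []

    def write_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, **_CSV_KW)
        written.append(path)
        log.info("wrote %s (%d rows)", path, len(df))

    try:
        # --- stage 1: obtain inputs -------------------------------------
        weights: dict[str, float] = {}
        if mode == "simulate":
            roster = synthetic.simulate_participants(config)
            weights = dict(zip(roster["participant_id"], roster["weight_kg"]))
            frames, _ = synthetic.simulate_cohort_imu(config, roster)
            mhcsf_df = synthetic.simulate_mhcsf_weekly(config, roster)
            nutrition_df = synthetic.simulate_nutrition_log(config, roster, study_start)
            survey_wide = synthetic.simulate_survey_prepost(config, roster)
            survey_df = synthetic.survey_to_long(survey_wide)
            if write_raw:
                write_csv(roster, "participants.csv")
                write_csv(synthetic.frames_to_dataframe(frames), "sensors.csv")
                write_csv(mhcsf_df.drop(columns=["true_group"]), "mhcsf.csv")
                write_csv(nutrition_df, "nutrition.csv")
                write_csv(survey_df, "survey.csv")
        else:
            src = Path(input_dir or out)
            missing = [f for f in INGEST_FILES if not (src / f).exists()]
            if missing:
                raise InputError(f"missing input file(s) in {src}: {missing}")
            frames = synthetic.dataframe_to_frames(pd.read_csv(src / "sensors.csv"))
            mhcsf_df = pd.read_csv(src / "mhcsf.csv")
            nutrition_df = pd.read_csv(src / "nutrition.csv")
            survey_df = pd.read_csv(src / "survey.csv")
            roster_path = src / "participants.csv"
            if roster_path.exists():
                roster = pd.read_csv(roster_path)
                weights = dict(zip(roster["participant_id"], roster["weight_kg"]))

        # --- stage 2: kinematic metrics ---------------------------------
        metrics_df = imu.cohort_metrics_table(frames, peak_cfg, weights=weights)
        write_csv(metrics_df, "metrics.csv")

        # --- stage 3: well-being classification and trends --------------
        classes_df = wellbeing.classification_table(mhcsf_df)
        write_csv(classes_df, "wellbeing.csv")
        wb_trends = wellbeing.weekly_group_trends(mhcsf_df, classification_basis)
        write_csv(wb_trends, "wellbeing_trends.csv")
        groups = wellbeing.participant_groups(mhcsf_df, "week1")

        # --- stage 4: nutrition trends -----------------------------------
        nut_trends = nutrition.aggregate_nutrition_weekly(
            nutrition_df, study_start, weeks=config.weeks
        )
        write_csv(nut_trends, "nutrition_trends.csv")

        # --- stage 5: pre/post survey statistics -------------------------
        summaries = stats.summarize_items(survey_df)
        survey_table = stats.summaries_to_table(summaries)
        write_csv(survey_table, "survey_summary.csv")

        # --- stage 6: group-stratified metric trends ----------------------
        trends, changes = stats.metric_group_trends(metrics_df, groups)
        write_csv(trends, "metric_trends.csv")
        write_csv(changes, "metric_changes.csv")

        # --- summary & manifest -------------------------------------------
        summary = {
            "n_participants": int(mhcsf_df["participant_id"].nunique()),
            "weeks": int(config.weeks),
            "survey_items": {
                row["item_id"]: {
                    k: (None if pd.isna(row[k]) else float(row[k]))
                    for k in ("t_stat", "p_value", "cohens_d")
                }
                for _, row in survey_table.iterrows()
            },
            "metric_percent_change": {
                f"{r['group']}/{r['metric']}": (
                    None if pd.isna(r["percent_change"]) else float(r["percent_change"])
                )
                for _, r in changes.iterrows()
            },
            "nutrition_weekly_mean": {
                f"week{int(r['week'])}/{r['metric']}": (
                    None if pd.isna(r["mean"]) else round(float(r["mean"]), 4)
                )
                for _, r in nut_trends.iterrows()
            },
        }
        summary_path = out / "summary.json"
        summary_path.write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        written.append(summary_path)

        manifest = {
            "mode": mode,
            "seed": int(config.seed),
            "config_hash": _config_hash(config),
            "files": {p.name: _sha256(p) for p in sorted(written)},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        (out / "manifest.json").unlink(missing_ok=True)
        raise
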
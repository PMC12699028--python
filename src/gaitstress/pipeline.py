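"""End-to-end orchestration: simulate/load -> extract -> score -> test.

A :class:`RunConfig` carries every stage parameter; :func:`run_pipeline`
executes the full analysis deterministically (fixed config + seed implies
byte-identical output tables) and writes feature tables, score tables,
statistics reports, SPM fields and a run log into the output directory.

Stage order for gait extraction follows the package's fixed convention:
low-pass filter the full trajectory first (zero-phase Butterworth), then
drop the 30 s familiarization window, so filter edge transients never sit
inside the analysis window.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import (
    DEFAULT_STRIDE_TIME_BOUNDS,
    GaitEvents,
    InsufficientStridesError,
    StrideSet,
    ankle_hip_distance,
    detect_heel_strikes,
    segment_strides,
)
from .keypoints import (
    CortisolSeries,
    KeypointSeries,
    QuestionnaireResponse,
    filter_trajectories,
    read_cortisol,
    read_keypoints,
    read_questionnaires,
    trim_familiarization,
)
from .kinematics import (
    ANGLE_SIGNALS,
    bout_features,
    build_feature_table,
    exclude_nonfunctional_arm_strides,
    joint_angles,
)
from .simulate import CohortData, CohortSpec, default_control_group, default_omc_group, simulate_cohort
from .stats import MixedAnova, RepeatedMeasuresAnova, SpmTTest, gated_pairwise
from .stats.anova import DegenerateModelError
from .stress import cortisol_feature_table, score_table

__all__ = ["RunConfig", "RunResult", "run_pipeline", "extract_gait"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


@dataclass
class RunConfig:
    """Fully serializable run configuration.

    Either ``input_dir`` (a dataset in the package's documented file
    formats) or ``simulate_n_per_group`` (generate a synthetic cohort)
    must be set.
    """

    input_dir: str | None = None
    simulate_n_per_group: int | None = None
    simulate_duration_s: float = 240.0
    seed: int = 0
    # gait-stage parameters
    trim_seconds: float = 30.0
    cutoff_hz: float = 10.0
    filter_order: int = 2
    offset_frames: int = 1
    min_period_s: float | None = None
    grf_threshold_n: float = 20.0
    stride_time_bounds: tuple[float, float] = DEFAULT_STRIDE_TIME_BOUNDS
    elbow_interior_threshold_deg: float = 80.0
    forward: str = "+x"
    # statistics
    alpha: float = 0.05
    spm_permutations: int = 0  # 0 disables the permutation cross-check
    out_dir: str = "gaitstress_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stride_time_bounds" in payload:
            payload["stride_time_bounds"] = tuple(payload["stride_time_bounds"])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stride_time_bounds"] = list(self.stride_time_bounds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class RunResult:
    """All result tables of one pipeline run."""

    features: pd.DataFrame
    cortisol: pd.DataFrame
    scores: pd.DataFrame
    anova: pd.DataFrame
    pairwise: pd.DataFrame
    spm: dict[str, "pd.DataFrame"]
    log: dict


def extract_gait(
    series: KeypointSeries, config: RunConfig
) -> tuple[dict[str, StrideSet], GaitEvents, dict[str, int]]:
    """Run the gait stage on one trial: filter, trim, events, angles, strides.

    Returns the per-signal stride sets (arm signals already cleaned of
    non-functional strides), the detected events, and per-stage counts.
    """
    filtered = filter_trajectories(series, config.cutoff_hz, config.filter_order)
    trimmed = trim_familiarization(filtered, config.trim_seconds)
    dist = ankle_hip_distance(trimmed, side="left")
    events = detect_heel_strikes(
        dist,
        trimmed.fps,
        config.min_period_s,
        config.offset_frames,
        participant_id=series.participant_id,
        bout=series.bout,
    )
    angles = joint_angles(trimmed, forward=config.forward)
    stride_sets: dict[str, StrideSet] = {}
    for name in ANGLE_SIGNALS:
        stride_sets[name] = segment_strides(
            angles[name],
            events,
            signal_name=name,
            stride_time_bounds=config.stride_time_bounds,
        )
    stride_sets, excluded = exclude_nonfunctional_arm_strides(
        stride_sets, config.elbow_interior_threshold_deg
    )
    counts = {
        "events": events.n_events,
        "strides": next(iter(stride_sets.values())).n_strides + int(excluded.sum()),
        "dropped": next(iter(stride_sets.values())).dropped,
        "arm_excluded": int(excluded.sum()),
    }
    return stride_sets, events, counts


def _gait_stage(cohort_kp: dict[str, dict[str, KeypointSeries]], groups: dict[str, str], config: RunConfig):
    per_bout: dict[str, dict[str, dict[str, float]]] = {}
    mean_waves: dict[tuple[str, str, str], np.ndarray] = {}
    counts: dict[str, dict] = {}
    for pid, bouts in cohort_kp.items():
        per_bout[pid] = {}
        counts[pid] = {}
        for bout, series in bouts.items():
            try:
                stride_sets, events, c = extract_gait(series, config)
            except (InsufficientStridesError, ValueError) as exc:
                raise StageError(f"gait extraction failed for {pid}/{bout}: {exc}") from exc
            per_bout[pid][bout] = bout_features(stride_sets)
            counts[pid][bout] = c
            for name in ("hip_flexion", "knee_flexion"):
                mean_waves[(pid, bout, name)] = stride_sets[name].mean_waveform()
    features = build_feature_table(per_bout, groups)
    return features, mean_waves, counts


def _stats_stage(
    features: pd.DataFrame,
    cortisol_table: pd.DataFrame,
    scores: pd.DataFrame,
    mean_waves: dict[tuple[str, str, str], np.ndarray],
    config: RunConfig,
    rng: np.random.Generator,
):
    anova_rows, pairwise_rows, spm_tables = [], [], {}
    groups = sorted(cortisol_table["group"].unique())
    if len(groups) != 2:
        raise StageError(f"statistics stage expects two groups, got {groups}")
    g_omc = "OMC" if "OMC" in groups else groups[0]
    g_ctl = [g for g in groups if g != g_omc][0]

    # --- cortisol: mixed ANOVA on baseline-adjusted samples S0..S5 -------
    long_rows = []
    for _, r in cortisol_table.iterrows():
        long_rows.append(dict(participant=r["participant"], group=r["group"], sample="S0", value=0.0))
        for i in range(1, 6):
            long_rows.append(
                dict(participant=r["participant"], group=r["group"], sample=f"S{i}", value=r[f"adj_S{i}"])
            )
    cort_long = pd.DataFrame(long_rows)
    res = MixedAnova(cort_long, "value", "sample", "participant", "group").fit()
    for _, r in res.table.iterrows():
        anova_rows.append({"analysis": "cortisol_adjusted", **r.to_dict()})

    # pairwise comparisons need n >= 3 per sample for the normality gate;
    # smaller runs (smoke tests) skip them and note it in the log
    pairwise_ok = cortisol_table.groupby("group").size().min() >= 3

    # cortisol feature group: max-increase group comparison
    if pairwise_ok:
        a = cortisol_table.loc[cortisol_table["group"] == g_omc, "max_increase_nmol_l"].to_numpy()
        b = cortisol_table.loc[cortisol_table["group"] == g_ctl, "max_increase_nmol_l"].to_numpy()
        pr = gated_pairwise(a, b, paired=False, m_comparisons=1, label="max_increase OMC vs control")
        pairwise_rows.append({"feature_group": "cortisol", **dataclasses.asdict(pr)})

    # --- questionnaires ---------------------------------------------------
    score_cols = [
        "PANAS_positive",
        "PANAS_negative",
        "SSSQ_distress",
        "SSSQ_self_evaluation",
        "SSSQ_total",
    ]
    pre_post = scores[scores["timepoint"].isin(["Q-pre", "Q-post"])]
    for col in score_cols:
        sub = pre_post[["participant", "group", "timepoint", col]].dropna()
        try:
            res = MixedAnova(sub, col, "timepoint", "participant", "group").fit()
        except DegenerateModelError:
            log.warning("skipping %s pre/post ANOVA: zero error variance", col)
            continue
        for _, r in res.table.iterrows():
            anova_rows.append({"analysis": f"{col} pre/post", **r.to_dict()})
        omc3 = scores[(scores["group"] == g_omc)][["participant", "timepoint", col]].dropna()
        if omc3["timepoint"].nunique() == 3:
            try:
                res3 = RepeatedMeasuresAnova(omc3, col, "timepoint", "participant").fit()
            except DegenerateModelError:
                log.warning("skipping %s OMC timecourse ANOVA: zero error variance", col)
                res3 = None
            if res3 is not None:
                for _, r in res3.table.iterrows():
                    anova_rows.append({"analysis": f"{col} OMC timecourse", **r.to_dict()})
        if omc3["timepoint"].nunique() == 3 and pairwise_ok:
            # post-hoc pairwise within the instrument's feature group
            wide = omc3.pivot(index="participant", columns="timepoint", values=col)
            pairs = [("Q-pre", "Q-marker"), ("Q-marker", "Q-post"), ("Q-pre", "Q-post")]
            for t0, t1 in pairs:
                pr = gated_pairwise(
                    wide[t1].to_numpy(),
                    wide[t0].to_numpy(),
                    paired=True,
                    m_comparisons=len(pairs),
                    label=f"{col} {t1} vs {t0}",
                )
                group_name = "PANAS" if col.startswith("PANAS") else "SSSQ"
                pairwise_rows.append({"feature_group": group_name, **dataclasses.asdict(pr)})

    # --- discrete gait features ------------------------------------------
    feat_cols = [c for c in features.columns if c not in ("participant", "group")]
    valid_cols = [c for c in feat_cols if features[c].notna().all()] if pairwise_ok else []
    for col in valid_cols:
        a = features.loc[features["group"] == g_omc, col].to_numpy()
        b = features.loc[features["group"] == g_ctl, col].to_numpy()
        pr = gated_pairwise(
            a, b, paired=False, m_comparisons=len(valid_cols), label=f"{col} OMC vs control"
        )
        pairwise_rows.append({"feature_group": "gait", **dataclasses.asdict(pr)})

    # --- SPM on lower-limb waveforms --------------------------------------
    pids_by_group = {
        g: sorted(cortisol_table.loc[cortisol_table["group"] == g, "participant"])
        for g in (g_omc, g_ctl)
    }
    for bout in ("slow", "fast"):
        for name in ("hip_flexion", "knee_flexion"):
            try:
                ga = np.vstack([mean_waves[(p, bout, name)] for p in pids_by_group[g_omc]])
                gb = np.vstack([mean_waves[(p, bout, name)] for p in pids_by_group[g_ctl]])
            except KeyError as exc:
                raise StageError(f"missing waveform for SPM: {exc}") from exc
            model = SpmTTest(ga, gb, alpha=config.alpha)
            if config.spm_permutations > 0:
                spm = model.fit_with_permutation(config.spm_permutations, rng)
            else:
                spm = model.fit()
            in_cluster = np.zeros(spm.t_field.size, dtype=bool)
            for c in spm.clusters:
                in_cluster[c.start_node : c.end_node + 1] = True
            spm_tables[f"{name}_{bout}"] = pd.DataFrame(
                {
                    "node": np.arange(spm.t_field.size),
                    "t": spm.t_field,
                    "threshold": spm.critical_threshold,
                    "in_cluster": in_cluster,
                }
            )
    return pd.DataFrame(anova_rows), pd.DataFrame(pairwise_rows), spm_tables


def _load_dataset(input_dir: Path):
    cortisol = read_cortisol(input_dir / "cortisol.csv")
    questionnaires = read_questionnaires(input_dir / "questionnaires.csv")
    groups = {c.participant_id: c.group for c in cortisol}
    kp: dict[str, dict[str, KeypointSeries]] = {}
    for f in sorted(input_dir.glob("*_keypoints.csv")):
        pid, bout = f.stem.rsplit("_keypoints", 1)[0].rsplit("_", 1)
        kp.setdefault(pid, {})[bout] = read_keypoints(f, participant_id=pid, bout=bout)
    if not kp:
        raise StageError(f"no *_keypoints.csv files found in {input_dir}")
    return kp, cortisol, questionnaires, groups


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all artifacts to ``out_dir``."""
    rng = np.random.default_rng(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None:
        kp, cortisol, questionnaires, groups = _load_dataset(Path(config.input_dir))
    elif config.simulate_n_per_group is not None:
        spec = CohortSpec(
            omc=default_omc_group(config.simulate_n_per_group),
            control=default_control_group(config.simulate_n_per_group),
            duration_s=config.simulate_duration_s,
            seed=config.seed,
        )
        cohort = simulate_cohort(spec)
        kp = {p.participant_id: p.keypoints for p in cohort.participants}
        cortisol = [p.cortisol for p in cohort.participants]
        questionnaires = [q for p in cohort.participants for q in p.questionnaires]
        groups = {p.participant_id: p.group for p in cohort.participants}
    else:
        raise StageError("config must set input_dir or simulate_n_per_group")

    features, mean_waves, counts = _gait_stage(kp, groups, config)
    cortisol_table = cortisol_feature_table(cortisol)
    scores = score_table(questionnaires)
    anova, pairwise, spm_tables = _stats_stage(
        features, cortisol_table, scores, mean_waves, config, rng
    )

    features.to_csv(out / "gait_features.csv", index=False)
    cortisol_table.to_csv(out / "cortisol_features.csv", index=False)
    scores.to_csv(out / "questionnaire_scores.csv", index=False)
    anova.to_csv(out / "anova.csv", index=False)
    pairwise.to_csv(out / "pairwise.csv", index=False)
    for name, tbl in spm_tables.items():
        tbl.to_csv(out / f"spm_{name}.csv", index=False)
    config.to_yaml(out / "config.yaml")
    run_log = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()},
        "n_participants": len(kp),
        "stride_counts": counts,
        "responders": int(cortisol_table["responder"].sum()),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return RunResult(features, cortisol_table, scores, anova, pairwise, spm_tables, run_log)
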
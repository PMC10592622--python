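"""Session-level orchestration and group comparisons.

``analyze_session`` runs the full pipeline on in-memory objects:
smoothing -> walking bouts -> strides/phase -> per-unit phase, speed and
start/stop coding -> optogenetic tagging -> gait summary.  ``run_session``
wraps it with file I/O driven by a YAML/JSON config, and ``compare_groups``
reproduces the group-contrast layout: vector-length factor comparisons,
angle comparisons via the angular permutation test (Bonferroni over limbs),
and t-tests on modulation indices, speed scores and gait metrics.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import bouts as bt
from . import events as ev
from . import kinematics as kin
from . import phase as ph
from . import tagging as tg
from .circstats import angular_permutation_test
from .types import LIMBS, LaserProtocol, PoseTrack, SpikeTrain, StrideTable

__all__ = ["SessionConfig", "analyze_session", "run_session", "compare_groups"]


@dataclass
class SessionConfig:
    """Every analysis constant, surfaced with its default."""

    kinematics: kin.KinematicsConfig = field(default_factory=kin.KinematicsConfig)
    speed_high: float = 50.0
    speed_low: float = 20.0
    min_motion_bout: float = 0.3
    jitter_iter: int = 100
    jitter_halfwidth: float = 0.5
    outlier_cutoff: float = 0.9
    speed_shuffle_iter: int = 100
    perm_iter: int = 1000
    alpha: float = 0.05
    tagging_test: str = "ttest"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        kcfg = kin.KinematicsConfig(**d.pop("kinematics", {}))
        return cls(kinematics=kcfg, **d)


def analyze_session(
    track: PoseTrack,
    spike_trains: Optional[list[SpikeTrain]] = None,
    genotype: str = "",
    group: str = "",
    config: Optional[SessionConfig] = None,
) -> dict:
    """Run every stage on one session; returns a structured report.

    The report carries the stride table, gait summary, motion bouts, and a
    per-unit table with phase tuning per limb, coupling class, speed score,
    start/stop results and tag label.  Without spike trains the report is
    kinematics-only.
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(config.seed)
    table: StrideTable = kin.segment_strides(track, config.kinematics)
    speed = kin.body_speed(track)
    motion = bt.detect_motion_bouts(
        speed,
        track.frame_rate,
        high=config.speed_high,
        low=config.speed_low,
        min_duration=config.min_motion_bout,
    )
    init_rate = bt.initiation_rate(motion, track.duration)
    summary = kin.gait_summary(table, track, initiation_rate_per_min=init_rate)

    report = {
        "strides": table.strides,
        "stride_table": table,
        "bouts": motion,
        "gait_summary": summary,
        "group": group,
        "genotype": genotype,
        "config": config,
    }
    if not spike_trains:
        return report

    unit_rows = []
    tunings_all = []
    for st in spike_trains:
        tunings = {}
        for limb in LIMBS:
            t = ph.phase_tuning(
                st,
                table.phase[limb],
                track.frame_rate,
                limb=limb,
                n_iter=config.jitter_iter,
                jitter_halfwidth=config.jitter_halfwidth,
                rng=rng,
            )
            t.unit_id = st.unit_id
            tunings[limb] = t
            tunings_all.append(t)
        profile = ph.limb_coupling_profile(tunings)
        speed_tuning = ev.speed_coding(
            st, speed, track.frame_rate, n_iter=config.speed_shuffle_iter, rng=rng
        )
        start = ev.start_stop_test(st, motion, "start", alpha=config.alpha)
        stop = ev.start_stop_test(st, motion, "stop", alpha=config.alpha)
        tag = None
        if st.protocol is not None and st.waveforms is not None:
            tag = tg.classify_unit(st, st.protocol, genotype, test=config.tagging_test)
        best = profile["limb_preference"][0]
        unit_rows.append(
            {
                "unit_id": st.unit_id,
                "group": group,
                "genotype": genotype,
                "session_rate_hz": st.session_rate(),
                "coupling_class": profile["coupling_class"],
                "n_significant_limbs": len(profile["significant_limbs"]),
                "phase_coding": len(profile["significant_limbs"]) > 0,
                "best_limb": best,
                "best_vector_length": tunings[best].vector_length,
                "best_vector_angle_deg": tunings[best].vector_angle,
                "speed_score": speed_tuning.score,
                "speed_coding": speed_tuning.significant,
                "mi_start": start.modulation_index,
                "mi_stop": stop.modulation_index,
                "start_coding": start.significant,
                "stop_coding": stop.significant,
                "tag_label": tag.label if tag else "untagged",
                "tagged": bool(tag.tagged) if tag else False,
            }
        )

    units = pd.DataFrame(unit_rows)
    tuning_table = ph.tuning_summary(tunings_all)
    tuning_table, excluded = ph.exclude_outliers(tuning_table, config.outlier_cutoff)
    units["outlier"] = units["unit_id"].isin(excluded)
    venn = {}
    for row in units[~units["outlier"]].itertuples():
        cats = frozenset(
            ev.coding_categories(
                row.phase_coding, row.speed_coding, row.start_coding, row.stop_coding
            )
        )
        key = "+".join(sorted(cats)) if cats else "none"
        venn[key] = venn.get(key, 0) + 1
    report.update(
        {
            "units": units,
            "tunings": tuning_table,
            "excluded_units": excluded,
            "venn_categories": venn,
        }
    )
    return report


def _load_spike_train(entry: dict, session_end: float) -> SpikeTrain:
    times = pd.read_csv(entry["path"])["spike_time_s"].to_numpy()
    protocol = None
    waveforms = None
    first_laser = None
    if "laser_path" in entry:
        pulses = pd.read_csv(entry["laser_path"])["pulse_time_s"].to_numpy()
        protocol = LaserProtocol(pulses)
        first_laser = float(pulses[0])
    if "waveforms_path" in entry:
        import h5py

        with h5py.File(entry["waveforms_path"], "r") as f:
            waveforms = f[entry.get("waveforms_key", "waveforms")][...]
    return SpikeTrain(
        unit_id=str(entry.get("unit_id", Path(entry["path"]).stem)),
        spike_times=times,
        session_end=session_end,
        first_laser_time=first_laser,
        waveforms=waveforms,
        protocol=protocol,
    )


def run_session(config: dict | str | Path, outdir: Optional[str | Path] = None) -> dict:
    """File-driven session analysis.

    ``config`` is a YAML/JSON path or dict naming the pose file (``pose``,
    CSV or HDF5), optional per-unit spike entries (``spikes``: list of
    {unit_id, path, laser_path, waveforms_path}), ``genotype``, ``group``,
    and analysis-parameter overrides under ``parameters``.  Writes stride,
    bout and unit tables plus a JSON summary into ``outdir`` when given.
    """
    if not isinstance(config, dict):
        text = Path(config).read_text()
        config = yaml.safe_load(text)
    if "pose" not in config:
        raise ValueError("config must name a 'pose' file")
    pose_path = Path(config["pose"])
    if pose_path.suffix in (".h5", ".hdf5"):
        track = PoseTrack.from_hdf5(pose_path)
    else:
        track = PoseTrack.from_csv(
            pose_path,
            frame_rate=config.get("frame_rate", 80.0),
            pixel_scale=config.get("pixel_scale", 0.3),
        )
    cfg = SessionConfig.from_dict(config.get("parameters", {}))
    spikes = [
        _load_spike_train(e, track.duration) for e in config.get("spikes", [])
    ]
    report = analyze_session(
        track,
        spikes,
        genotype=config.get("genotype", ""),
        group=config.get("group", ""),
        config=cfg,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report["strides"].to_csv(outdir / "strides.csv", index=False)
        bt.bouts_to_frame(report["bouts"]).to_csv(outdir / "motion_bouts.csv", index=False)
        with open(outdir / "gait_summary.json", "w") as f:
            json.dump(report["gait_summary"], f, indent=2, default=float)
        if "units" in report:
            report["units"].to_csv(outdir / "units.csv", index=False)
            report["tunings"].to_csv(outdir / "tunings.csv", index=False)
            with open(outdir / "venn_categories.json", "w") as f:
                json.dump(report["venn_categories"], f, indent=2)
        with open(outdir / "parameters.json", "w") as f:
            json.dump(asdict(cfg), f, indent=2, default=str)
    return report


def compare_groups(
    tunings: pd.DataFrame,
    units: Optional[pd.DataFrame] = None,
    group_col: str = "group",
    n_iter: int = 1000,
    seed: Optional[int] = None,
) -> dict:
    """Group contrasts on phase-coupling and coding statistics.

    ``tunings`` is a long per-unit x per-limb table with columns
    [unit_id, limb, vector_length, vector_angle_deg, ``group_col``].
    Vector lengths are compared with a two-way factor layout
    (group x limb, ordinary ANOVA via statsmodels) and, as the
    repeated-measures-robust view, a two-sample t-test on per-unit mean
    lengths.  Preferred angles are compared per limb with the angular
    permutation test, Bonferroni-corrected over the four limbs.  Optional
    ``units`` (one row per unit) adds t-tests on modulation indices and
    speed scores.
    """
    groups = sorted(tunings[group_col].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ga, gb = groups
    rng = np.random.default_rng(seed)
    out: dict = {"groups": groups}

    # vector length: group x limb factor layout
    df = tunings.rename(columns={group_col: "grp"})
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("vector_length ~ C(grp) * C(limb)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    per_unit = df.groupby(["unit_id", "grp"])["vector_length"].mean().reset_index()
    va = per_unit.loc[per_unit["grp"] == ga, "vector_length"]
    vb = per_unit.loc[per_unit["grp"] == gb, "vector_length"]
    tt = stats.ttest_ind(va, vb)
    out["vector_length"] = {
        "mean": {ga: float(va.mean()), gb: float(vb.mean())},
        "sem": {ga: float(va.sem()), gb: float(vb.sem())},
        "anova_group_p": float(anova.loc["C(grp)", "PR(>F)"]),
        "anova_table": anova,
        "ttest_p": float(tt.pvalue),
    }

    # preferred angle per limb: angular permutation test, Bonferroni over limbs
    limbs = sorted(df["limb"].unique())
    angle_results = {}
    for limb in limbs:
        sub = df[(df["limb"] == limb) & np.isfinite(df["vector_angle_deg"])]
        aa = sub.loc[sub["grp"] == ga, "vector_angle_deg"].to_numpy()
        bb = sub.loc[sub["grp"] == gb, "vector_angle_deg"].to_numpy()
        if len(aa) == 0 or len(bb) == 0:
            continue
        res = angular_permutation_test(
            aa, bb, n_iter=n_iter, n_comparisons=len(limbs), rng=rng
        )
        angle_results[limb] = {
            "distance": res.distance,
            "p_value": res.p_value,
            "significant": res.significant,
        }
    out["vector_angle"] = angle_results

    if units is not None:
        scalars = {}
        for col in ("mi_start", "mi_stop", "speed_score"):
            if col not in units.columns:
                continue
            xa = units.loc[units[group_col] == ga, col].dropna()
            xb = units.loc[units[group_col] == gb, col].dropna()
            if len(xa) > 1 and len(xb) > 1:
                r = stats.ttest_ind(xa, xb)
                scalars[col] = {
                    "mean": {ga: float(xa.mean()), gb: float(xb.mean())},
                    "p_value": float(r.pvalue),
                    "significant": bool(r.pvalue < 0.05),
                }
        out["scalar_tests"] = scalars
    return out
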
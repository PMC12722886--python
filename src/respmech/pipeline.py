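"""End-to-end orchestration: trial -> per-cycle features -> group battery.

:func:`run_trial` executes the whole per-trial chain — volumetry, breath
segmentation, COM/COP, joint angles, iEMG and respiration-posture coupling —
over every annotated movement cycle and aggregates cycle values into trial
means ("mean values across trials/cycles represent performance").  A failed
or missing stage is recorded in ``notes`` and never aborts the rest of the
trial.

:func:`run_battery` takes the long-format participant table (one trial-mean
value per participant x outcome), routes each outcome through the two-group
comparison battery and renders a summary table with per-family FDR-adjusted
q-values and effect sizes with CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import breath as breath_mod
from . import chestwall, coupling, emg as emg_mod, group_stats, posture
from .mocap_io import TrialBundle

__all__ = ["PipelineConfig", "TrialFeatures", "run_trial", "run_battery"]

#: joint -> (proximal segment, distal segment); segments name marker triads
JOINT_CHAIN = {"hip": ("pelvis", "thigh"), "knee": ("thigh", "shank"),
               "ankle": ("shank", "foot")}

SEGMENT_TRIADS = {
    "pelvis": ("SACR", "PELVD", "PELVL"),
    "thigh": ("{S}HIP", "{S}KNE", "{S}THI"),
    "shank": ("{S}KNE", "{S}ANK", "{S}SHA"),
    "foot": ("{S}ANK", "{S}TOE", "{S}FOO"),
}


@dataclass
class PipelineConfig:
    """Validated knobs for one pipeline run; unknown keys are rejected."""

    analysis_rate: float = 100.0
    smooth_cutoff_hz: float = 1.0
    refine_cutoff_hz: float = 3.0  # light smoothing for extremum-time refinement
    min_breath_duration_s: float = 1.0
    min_prominence_frac: float = 0.2
    fz_threshold_n: float = 20.0
    # range statistics (ROM, COP displacement) amplify wide-band sensor
    # noise, so angles and COP are zero-phase low-passed first; both cutoffs
    # sit far above the movement bandwidth of slow whole-body exercise
    angle_cutoff_hz: float = 2.0
    cop_cutoff_hz: float = 10.0
    emg_band_hz: tuple[float, float] = (20.0, 450.0)
    max_lag_s: float = 2.0
    fdr_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        from pathlib import Path

        data = yaml.safe_load(Path(source).read_text(encoding="utf-8")) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "emg_band_hz" in data:
            data["emg_band_hz"] = tuple(data["emg_band_hz"])
        return cls(**data)


def _lowpass(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass; NaN runs are bridged and restored."""
    from scipy import signal as sps

    if cutoff >= rate / 2:
        return x
    sos = sps.butter(4, cutoff, btype="low", fs=rate, output="sos")
    x = np.asarray(x, dtype=float)
    flat = x.reshape(x.shape[0], -1).copy()
    for j in range(flat.shape[1]):
        col = flat[:, j]
        bad = ~np.isfinite(col)
        if bad.all():
            continue
        if bad.any():
            idx = np.arange(col.size)
            col = col.copy()
            col[bad] = np.interp(idx[bad], idx[~bad], col[~bad])
        y = sps.sosfiltfilt(sos, col)
        y[bad] = np.nan
        flat[:, j] = y
    return flat.reshape(x.shape)


def default_grid_spec() -> dict:
    text = resources.files("respmech").joinpath("config/chest_grid.yaml").read_text("utf-8")
    return yaml.safe_load(text)


@dataclass
class TrialFeatures:
    """Per-cycle feature table and its per-trial aggregation."""

    per_cycle: pd.DataFrame  # columns: movement, cycle, outcome, value
    trial_means: dict[str, float]
    notes: list[str] = field(default_factory=list)
    stages: dict[str, object] = field(default_factory=dict)

    def to_long(self, participant: str, group: str) -> pd.DataFrame:
        fam = {o: _family_of(o) for o in self.trial_means}
        return pd.DataFrame(
            [
                (o, fam[o], group, participant, v)
                for o, v in self.trial_means.items()
                if np.isfinite(v)
            ],
            columns=["outcome", "family", "group", "participant", "value"],
        )


def _family_of(outcome: str) -> str:
    if "rom" in outcome:
        return "rom"
    if outcome.startswith("cop_"):
        return "cop"
    if outcome.startswith("iemg"):
        return "emg"
    if outcome.startswith("ccf"):
        return "coupling"
    return "respiratory"


def run_trial(
    bundle: TrialBundle,
    config: PipelineConfig | None = None,
    grid_spec: dict | None = None,
    segment_model: posture.SegmentModel | None = None,
) -> TrialFeatures:
    """Execute the full per-trial analysis chain over the annotated cycles."""
    config = config or PipelineConfig()
    notes: list[str] = []
    stages: dict[str, object] = {}
    rows: list[tuple[str, int, str, float]] = []
    cycles = bundle.events.all_cycles()
    if not cycles:
        span = (bundle.time[0], bundle.time[-1])
        cycles = [("trial", 0, float(span[0]), float(span[1]))]
        notes.append("no movement cycles annotated; using the whole trial")

    # --- respiratory chain -------------------------------------------------
    volumes = None
    try:
        grid = chestwall.build_grid(
            bundle.markers.labels, grid_spec or default_grid_spec()
        )
        raw = chestwall.volume_series(bundle.markers, grid)
        volumes = breath_mod.smooth_volume(raw, cutoff=config.smooth_cutoff_hz)
        lightly = breath_mod.smooth_volume(raw, cutoff=config.refine_cutoff_hz)
        stages["volumes"] = volumes
        breaths = breath_mod.segment_breaths(
            volumes,
            min_duration=config.min_breath_duration_s,
            min_prominence_frac=config.min_prominence_frac,
            refine=lightly,
        )
        stages["breaths"] = breaths
        for movement, idx, start, end in cycles:
            s = breath_mod.summarize_respiration(breaths, (start, end))
            rows.append((movement, idx, "inspiratory_time_s", s.mean_Ti))
            rows.append((movement, idx, "expiratory_time_s", s.mean_Te))
            rows.append((movement, idx, "max_respiratory_volume_L", s.max_respiratory_volume))
            for comp, val in s.mean_contributions.items():
                rows.append((movement, idx, f"{comp}_contribution_pct", val))
    except Exception as exc:
        notes.append(f"respiratory stage failed: {type(exc).__name__}: {exc}")

    # --- joint angles ------------------------------------------------------
    for side in ("R", "L"):
        try:
            frames = {}
            for seg, triad in SEGMENT_TRIADS.items():
                names = [m.format(S=side) for m in triad]
                if not all(n in bundle.markers.labels for n in names):
                    raise KeyError(f"missing triad markers for {seg} ({side})")
                frames[seg] = posture.segment_frames(bundle.markers, *names)
            for joint, (prox, dist) in JOINT_CHAIN.items():
                series = posture.cardan_angles(
                    frames[prox], frames[dist], bundle.time, joint=joint, side=side
                )
                series.angles = _lowpass(
                    series.angles, bundle.analysis_rate, config.angle_cutoff_hz
                )
                for movement, idx, start, end in cycles:
                    for plane, value in posture.joint_rom(series, (start, end)).items():
                        rows.append(
                            (movement, idx, f"{joint}_{plane}_rom_deg_{side}", value)
                        )
        except Exception as exc:
            notes.append(f"joint angles ({side}) skipped: {exc}")

    # --- COM + coupling ----------------------------------------------------
    com = None
    try:
        model = segment_model or posture.default_segment_model()
        com = posture.whole_body_com(bundle.markers, model)
        stages["com"] = com
    except Exception as exc:
        notes.append(f"COM stage failed: {exc}")
    if com is not None and volumes is not None:
        try:
            cycle_list = [(m, i, s, e) for m, i, s, e in cycles]
            results = coupling.coupling_battery(
                volumes, com, cycle_list, max_lag_s=config.max_lag_s
            )
            stages["coupling"] = results
            for r in results:
                rows.append(
                    (r.cycle[0], r.cycle[1], f"ccf_{r.axis.lower()}", r.ccf)
                )
        except Exception as exc:
            notes.append(f"coupling stage failed: {exc}")

    # --- COP ---------------------------------------------------------------
    if bundle.plate is not None:
        try:
            cop = posture.cop_from_forceplate(bundle.plate, config.fz_threshold_n)
            rate = bundle.plate.rate
            cop.cop_x = _lowpass(cop.cop_x, rate, config.cop_cutoff_hz)
            cop.cop_y = _lowpass(cop.cop_y, rate, config.cop_cutoff_hz)
            stages["cop"] = cop
            for movement, idx, start, end in cycles:
                rx, ry = posture.cop_displacement(cop, (start, end))
                rows.append((movement, idx, "cop_range_x_m", rx))
                rows.append((movement, idx, "cop_range_y_m", ry))
        except Exception as exc:
            notes.append(f"COP stage failed: {exc}")
    else:
        notes.append("no force-plate record; COP block missing")

    # --- iEMG --------------------------------------------------------------
    if bundle.emg is not None and bundle.emg.channels:
        try:
            clean = emg_mod.preprocess_emg(bundle.emg, band=config.emg_band_hz)
            clean.reference_peak = bundle.emg.reference_peak
            for movement, idx, start, end in cycles:
                for channel in clean.channels:
                    ref = clean.reference_peak.get(channel)
                    res = emg_mod.integrated_emg(clean, channel, (start, end), ref)
                    rows.append((movement, idx, f"iemg_raw_{channel}", res.iemg_raw))
                    if res.iemg_norm is not None:
                        rows.append((movement, idx, f"iemg_norm_{channel}", res.iemg_norm))
        except Exception as exc:
            notes.append(f"EMG stage failed: {exc}")
    else:
        notes.append("no EMG record; iEMG block missing")

    per_cycle = pd.DataFrame(rows, columns=["movement", "cycle", "outcome", "value"])
    if len(per_cycle):
        means = per_cycle.groupby("outcome")["value"].mean().to_dict()
    else:
        means = {}
    return TrialFeatures(per_cycle=per_cycle, trial_means=means, notes=notes, stages=stages)


# ---------------------------------------------------------------------------
# group battery
# ---------------------------------------------------------------------------


def run_battery(
    table: pd.DataFrame,
    group_a: str = "LP",
    group_b: str = "BP",
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group battery over a long-format participant table.

    ``table`` needs columns ``outcome, family, group, participant, value``
    (one trial-mean value per participant).  Returns a tidy report sorted by
    family with columns ``family, outcome, lp_desc, bp_desc, route, effect,
    ci_low, ci_high, p, q, significant``.
    """
    required = {"outcome", "family", "group", "participant", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"feature table lacks columns: {sorted(missing)}")
    samples: dict[str, tuple[group_stats.GroupSample, group_stats.GroupSample]] = {}
    families: dict[str, str] = {}
    for outcome, sub in table.groupby("outcome", sort=False):
        byg = {g: s["value"].to_numpy() for g, s in sub.groupby("group")}
        if group_a not in byg or group_b not in byg:
            continue
        if len(byg[group_a]) < 2 or len(byg[group_b]) < 2:
            continue
        samples[str(outcome)] = (
            group_stats.GroupSample(str(outcome), group_a, byg[group_a]),
            group_stats.GroupSample(str(outcome), group_b, byg[group_b]),
        )
        families[str(outcome)] = str(sub["family"].iloc[0])
    if not samples:
        raise ValueError(f"no outcome has both groups {group_a!r} and {group_b!r}")
    comparisons = group_stats.compare_outcomes(
        samples, families, alpha=alpha, seed=seed
    )
    report = pd.DataFrame(
        [
            {
                "family": c.family,
                "outcome": c.outcome,
                "lp_desc": c.desc_a,
                "bp_desc": c.desc_b,
                "route": c.route,
                "effect": c.effect_size,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p": c.p,
                "q": c.q,
                "significant": c.significant,
            }
            for c in comparisons
        ]
    )
    return report.sort_values(["family", "outcome"], kind="stable").reset_index(drop=True)


def render_report_markdown(report: pd.DataFrame, title: str = "Group comparison") -> str:
    """Markdown rendering of the battery report, flagging q < 0.05 rows."""
    lines = [f"# {title}", ""]
    header = "| family | outcome | group A | group B | effect (95% CI) | p | q | |"
    lines += [header, "|" + "---|" * 8]
    for _, r in report.iterrows():
        flag = "**sig**" if r["significant"] else ""
        eff = f"{r['effect']:.2f} ({r['ci_low']:.2f}, {r['ci_high']:.2f})"
        lines.append(
            f"| {r['family']} | {r['outcome']} | {r['lp_desc']} | {r['bp_desc']} "
            f"| {eff} | {r['p']:.3g} | {r['q']:.3g} | {flag} |"
        )
    lines.append("")
    return "\n".join(lines)
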
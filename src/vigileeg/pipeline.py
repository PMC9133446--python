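"""End-to-end study orchestration.

Simulates a two-group (BLT vs TAU) pre/post design, runs the vigilance
chain per recording, and applies the full statistical battery, producing
a report shaped like the study's results table (paired tests per group,
2×2 mixed ANOVA, baseline equivalence, stability tests, BDI-II
correlations, descriptives).

Two simulation modes:

* ``"trajectory"`` (default) — draw latent stage sequences from the
  Markov chain and score them directly.  This is the mode for
  statistical experiments (type-I error, power/sign recovery), where
  thousands of recordings are needed and the signal-rendering /
  classification path has already been validated separately.
* ``"full"`` — render multichannel EEG, preprocess (filter, ICA,
  artifact screening) and classify, then score the classified sequence.

A treatment effect is modelled as a tilt of the stationary stage mix
toward wakefulness (0/A1/A2/A3 mass multiplied by ``exp(shift)``) at the
post timepoint; per-participant arousal traits are random tilts shared
by both timepoints, which induces the within-subject correlation a
paired design exploits.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, stats
from .classifier import classify_recording
from .preprocess import preprocess
from .stages import STAGE_A1, STAGE_B23, STAGES, WAKE_STAGES
from .synth import (
    DEFAULT_STATIONARY,
    SimulationConfig,
    default_transition_matrix,
    sample_stage_trajectory,
    synthesize_recording,
)

GROUPS = ("BLT", "TAU")
TIMEPOINTS = ("pre", "post")
OUTCOMES = {"A1": STAGE_A1, "B23": STAGE_B23, "mean_vigilance": None}


@dataclass
class StudyConfig:
    """Design and generator settings of one simulated study."""

    n_blt: int = 9
    n_tau: int = 10
    duration: float = 1200.0
    mode: str = "trajectory"
    seed: int = 0
    #: post-timepoint wake-mass tilt (log multiplier) per group; positive
    #: values raise arousal after treatment.
    arousal_shift: dict = field(default_factory=lambda: {"BLT": 0.0, "TAU": 0.0})
    #: SD of the per-participant arousal trait (log multiplier).
    trait_sd: float = 0.15
    bdi_mean: float = 31.5
    bdi_sd: float = 11.0
    #: correlation between simulated BDI-II and B2/3 occurrence.
    bdi_b23_correlation: float = -0.5
    sesoi: float | None = None
    stationary: dict = field(default_factory=lambda: dict(DEFAULT_STATIONARY))
    stickiness: float = 0.95
    sim_overrides: dict = field(default_factory=dict)
    run_ica: bool = True
    out_dir: str | None = None

    def validate(self) -> None:
        if min(self.n_blt, self.n_tau) < 2:
            raise ValueError("each group needs at least 2 participants")
        if self.mode not in ("trajectory", "full"):
            raise ValueError("mode must be 'trajectory' or 'full'")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclass
class StudyReport:
    """Participant-level summaries plus the inferential battery."""

    participants: pd.DataFrame
    results: dict
    descriptives: pd.DataFrame
    config: StudyConfig


def tilt_stationary(stationary: dict, shift: float) -> dict:
    """Multiply the wake-stage mass by exp(shift) and renormalize."""
    out = {
        s: p * (np.exp(shift) if s in WAKE_STAGES else 1.0)
        for s, p in stationary.items()
    }
    total = sum(out.values())
    return {s: p / total for s, p in out.items()}


def _simulate_labels(config: StudyConfig, stationary: dict, seed: int) -> list[str]:
    sim = SimulationConfig(
        duration=config.duration,
        transition_matrix=default_transition_matrix(
            stationary, config.stickiness
        ),
        seed=seed,
        **config.sim_overrides,
    )
    if config.mode == "trajectory":
        return sample_stage_trajectory(sim)
    traj = sample_stage_trajectory(sim)
    rec, _ = synthesize_recording(traj, sim)
    cleaned, table = preprocess(rec, run_ica=config.run_ica, ica_seed=seed % (2**31))
    staged = classify_recording(cleaned, table)
    return staged["stage"].tolist()


def run_study(config: StudyConfig) -> StudyReport:
    """Simulate the cohort, summarize every recording, run the battery."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    pid = 0
    for group, n in (("BLT", config.n_blt), ("TAU", config.n_tau)):
        shift = float(config.arousal_shift.get(group, 0.0))
        for _ in range(n):
            pid += 1
            trait = rng.normal(0.0, config.trait_sd)
            for timepoint in TIMEPOINTS:
                total_shift = trait + (shift if timepoint == "post" else 0.0)
                pi = tilt_stationary(config.stationary, total_shift)
                seed = int(rng.integers(0, 2**31 - 1))
                try:
                    labels = _simulate_labels(config, pi, seed)
                    summary = metrics.summarize(labels)
                except Exception as exc:
                    raise RuntimeError(
                        f"participant {pid} ({group}, {timepoint}): {exc}"
                    ) from exc
                row = {
                    "id": pid,
                    "group": group,
                    "timepoint": timepoint,
                    "mean_vigilance": summary.mean_vigilance,
                    "stability": summary.stability_index,
                    "n_artifact_free": summary.n_artifact_free,
                }
                for stage in STAGES:
                    row[stage] = summary.occurrence[stage]
                rows.append(row)
    participants = pd.DataFrame(rows)
    participants["A1"] = participants[STAGE_A1]
    participants["B23"] = participants[STAGE_B23]

    # simulated BDI-II scores, correlated with B2/3 occurrence
    rho = config.bdi_b23_correlation
    bdi = []
    for timepoint in TIMEPOINTS:
        sub = participants[participants["timepoint"] == timepoint]
        z = stats_zscore(sub["B23"].to_numpy())
        noise = rng.standard_normal(len(sub))
        latent = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * noise
        scores = np.clip(
            np.rint(config.bdi_mean + config.bdi_sd * latent), 0, 63
        )
        bdi.append(pd.Series(scores, index=sub.index))
    participants["bdi"] = pd.concat(bdi)

    results, descriptives = analyze(participants, sesoi=config.sesoi)
    report = StudyReport(
        participants=participants,
        results=results,
        descriptives=descriptives,
        config=config,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        participants.to_csv(out / "participants.csv", index=False)
        descriptives.to_csv(out / "descriptives.csv")
        (out / "report.txt").write_text(format_report(report))
    return report


def stats_zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _wide(participants: pd.DataFrame, outcome: str) -> pd.DataFrame:
    return participants.pivot_table(
        index=["id", "group"], columns="timepoint", values=outcome
    ).reset_index()


def analyze(participants: pd.DataFrame, sesoi: float | None = None):
    """Statistical battery on a participant summary table.

    Expects long format with columns id, group, timepoint, A1, B23,
    mean_vigilance, stability, bdi.
    """
    results: dict[str, object] = {}
    n_by_group = {
        g: participants[participants["group"] == g]["id"].nunique()
        for g in GROUPS
    }
    if sesoi is None:
        sesoi = stats.mde_t(
            stats.PowerSpec(
                family="two-sample", n1=n_by_group["BLT"], n2=n_by_group["TAU"]
            )
        )
    results["sesoi"] = sesoi

    for outcome in OUTCOMES:
        wide = _wide(participants, outcome)
        for group in GROUPS:
            sub = wide[wide["group"] == group]
            diffs = (sub["pre"] - sub["post"]).to_numpy()
            key = f"paired_t[{group},{outcome}]"
            try:
                results[key] = stats.paired_t(diffs, name=key)
            except ValueError as exc:
                results[key] = str(exc)
        try:
            anova = stats.mixed_anova_2x2(
                participants, dv=outcome, subject="id",
                between="group", within="timepoint",
            )
            results[f"anova_time[{outcome}]"] = anova["time"]
            results[f"anova_interaction[{outcome}]"] = anova["interaction"]
        except Exception as exc:  # degenerate simulated data
            results[f"anova_time[{outcome}]"] = str(exc)
            results[f"anova_interaction[{outcome}]"] = str(exc)
        pre = wide[wide["group"] == "BLT"]["pre"].to_numpy()
        tau_pre = wide[wide["group"] == "TAU"]["pre"].to_numpy()
        try:
            results[f"baseline[{outcome}]"] = stats.equivalence_check(
                pre, tau_pre, sesoi=sesoi
            )
        except ValueError as exc:
            results[f"baseline[{outcome}]"] = str(exc)

    stab = _wide(participants, "stability")
    for group in GROUPS:
        sub = stab[stab["group"] == group]
        diffs = (sub["pre"] - sub["post"]).to_numpy()
        key = f"wilcoxon_stability[{group}]"
        try:
            results[key] = stats.wilcoxon_signed_rank(diffs)
        except ValueError as exc:
            results[key] = str(exc)
    stab = stab.assign(diff=stab["pre"] - stab["post"])
    crosstab = pd.crosstab(stab["group"], stab["diff"])
    try:
        results["chi2_stability"] = stats.chi_square_crosstab(crosstab.to_numpy())
    except ValueError as exc:
        results["chi2_stability"] = str(exc)

    for timepoint in TIMEPOINTS:
        sub = participants[participants["timepoint"] == timepoint]
        try:
            results[f"pearson_bdi_b23[{timepoint}]"] = stats.pearson_r(
                sub["bdi"].to_numpy(), sub["B23"].to_numpy()
            )
        except ValueError as exc:
            results[f"pearson_bdi_b23[{timepoint}]"] = str(exc)

    descriptives = (
        participants.groupby(["group", "timepoint"])[list(OUTCOMES)]
        .agg(["mean", "std"])
        .reindex(
            pd.MultiIndex.from_product([GROUPS, TIMEPOINTS]),
        )
    )
    return results, descriptives


def format_report(report: StudyReport) -> str:
    """Deterministic plain-text report: paired tests, ANOVA, descriptives."""
    buf = io.StringIO()
    w = buf.write
    res = report.results
    w("Effect of time on EEG vigilance level\n")
    w("=====================================\n\n")
    w("Paired t-tests (pre - post)\n")
    w(f"{'group':<5} {'measure':<15} {'t':>8} {'df':>4} {'p':>7} {'dz':>7}\n")
    for group in GROUPS:
        for outcome in OUTCOMES:
            r = res.get(f"paired_t[{group},{outcome}]")
            if isinstance(r, stats.TestResult):
                w(
                    f"{group:<5} {outcome:<15} {r.statistic:>8.3f} "
                    f"{r.df:>4.0f} {r.p_value:>7.3f} {r.effect_size:>7.3f}\n"
                )
            else:
                w(f"{group:<5} {outcome:<15} {r}\n")
    w("\nMixed ANOVA (within: time; between: group)\n")
    w(f"{'measure':<15} {'effect':<12} {'F':>8} {'p':>7} {'d(=2f)':>7}\n")
    for outcome in OUTCOMES:
        for eff, key in (("time", "anova_time"), ("time*group", "anova_interaction")):
            r = res.get(f"{key}[{outcome}]")
            if isinstance(r, stats.TestResult):
                w(
                    f"{outcome:<15} {eff:<12} {r.statistic:>8.3f} "
                    f"{r.p_value:>7.3f} {r.effect_size:>7.3f}\n"
                )
            else:
                w(f"{outcome:<15} {eff:<12} {r}\n")
    w("\nBaseline equivalence (SESOI d = %.3f)\n" % res["sesoi"])
    for outcome in OUTCOMES:
        r = res.get(f"baseline[{outcome}]")
        if isinstance(r, stats.TestResult):
            lo, hi = r.ci
            verdict = "EQUIVALENT" if r.extra["equivalent"] else "not equivalent"
            w(
                f"{outcome:<15} t={r.statistic:.3f} d={r.effect_size:.3f} "
                f"CI=({lo:.3f}, {hi:.3f}) -> {verdict}\n"
            )
        else:
            w(f"{outcome:<15} {r}\n")
    w("\nDescriptives (mean / SD per group and timepoint)\n")
    desc = report.descriptives
    widths = {o: max(9, len(o) + 3) for o in OUTCOMES}
    w(f"{'group':<5} {'time':<5}")
    for outcome, width in widths.items():
        w(f" {outcome + '.m':>{width}} {outcome + '.sd':>{width}}")
    w("\n")
    for (group, timepoint), row in desc.iterrows():
        w(f"{group:<5} {timepoint:<5}")
        for outcome, width in widths.items():
            w(
                f" {row[(outcome, 'mean')]:>{width}.3f}"
                f" {row[(outcome, 'std')]:>{width}.3f}"
            )
        w("\n")
    return buf.getvalue()
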
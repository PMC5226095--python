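"""End-to-end pseudo-experiment orchestration.

Builds per-subject trial schedules (six blocks, one per coloration x speed
combination, each holding every group size equally often; six flagged
practice trials first), runs the swarm simulator and synthetic observer
over every scheduled trial, computes the tracking-error records, and runs
the full mixed-model analysis ladder. Everything is a pure function of the
run configuration and master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import mixed_model, observer_synth
from .observer_synth import ObserverParams, TrialSpec
from .swarm_sim import COLORATIONS, PAPER_GROUP_SIZES

SPEED_CONDS = ("constant", "variable")


@dataclass(frozen=True)
class ExperimentSchedule:
    """One subject's full presentation order, practice trials first."""

    subject_id: int
    trials: tuple[TrialSpec, ...]

    @property
    def n_practice(self) -> int:
        return sum(t.is_practice for t in self.trials)

    @property
    def n_test(self) -> int:
        return len(self.trials) - self.n_practice


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pseudo-experiment run.

    Defaults reproduce the study design: 15 subjects, 4 group sizes x
    3 colorations x 2 speed conditions x 14 replicates = 336 test trials
    per subject, preceded by 6 practice trials that are flagged and
    excluded from analysis.
    """

    subjects: int = 15
    reps_per_cell: int = 14
    n_levels: tuple[int, ...] = PAPER_GROUP_SIZES
    colorations: tuple[str, ...] = COLORATIONS
    speed_conds: tuple[str, ...] = SPEED_CONDS
    n_practice: int = 6
    practice_cell: tuple[int, str, str] = (10, "trinary", "constant")
    observer: ObserverParams = field(default_factory=ObserverParams)
    trial_kwargs: dict = field(default_factory=dict)
    master_seed: int = 0

    @property
    def trials_per_subject(self) -> int:
        return (
            len(self.n_levels)
            * len(self.colorations)
            * len(self.speed_conds)
            * self.reps_per_cell
        )


def build_schedule(
    config: RunConfig, subject_id: int, rng: np.random.Generator | None = None
) -> ExperimentSchedule:
    """Randomized block/trial order for one subject.

    Blocks are the coloration x speed combinations in a per-subject random
    order; within each block the group-size x replicate list is shuffled
    independently. Practice trials come first and are flagged.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence((config.master_seed, 7777, subject_id))
        )
    blocks = list(product(config.colorations, config.speed_conds))
    block_order = rng.permutation(len(blocks))

    trials: list[TrialSpec] = []
    n_p, col_p, sp_p = config.practice_cell
    for j in range(config.n_practice):
        trials.append(
            TrialSpec(n_p, col_p, sp_p, is_practice=True, block=-1, trial=j)
        )
    for b_pos, b_idx in enumerate(block_order):
        coloration, speed_cond = blocks[b_idx]
        cells = [
            (n, r) for n in config.n_levels for r in range(config.reps_per_cell)
        ]
        order = rng.permutation(len(cells))
        for t_pos, c_idx in enumerate(order):
            n, _rep = cells[c_idx]
            trials.append(
                TrialSpec(
                    n, coloration, speed_cond,
                    is_practice=False, block=b_pos, trial=t_pos,
                )
            )
    return ExperimentSchedule(subject_id=subject_id, trials=tuple(trials))


@dataclass
class ExperimentResult:
    records: pd.DataFrame  # includes flagged practice rows
    analysis: dict
    figure2: pd.DataFrame
    config: RunConfig


def run_experiment(config: RunConfig, outdir: str | Path | None = None) -> ExperimentResult:
    """Simulate, synthesize, measure and analyse the whole experiment."""
    schedules = [
        build_schedule(config, s).trials for s in range(config.subjects)
    ]
    records = observer_synth.generate_dataset(
        schedules=schedules,
        params=config.observer,
        master_seed=config.master_seed,
        trial_kwargs=config.trial_kwargs,
    )
    analysis = analyze_records(records)
    figure2 = summarize_figure2_analogue(records)
    result = ExperimentResult(
        records=records, analysis=analysis, figure2=figure2, config=config
    )
    if outdir is not None:
        write_artifacts(result, Path(outdir))
    return result


def analyze_records(records: pd.DataFrame) -> dict:
    """The full inference ladder on one record table.

    Deviance tests for polynomial order and each interaction; per-subject
    coefficient contrasts (speed pair on linear and quadratic group-size
    terms; coloration pairs on the linear term); and the post hoc
    speed-by-coloration ratios at 30 items.
    """
    ladder = mixed_model.deviance_ladder(records)
    contrasts = {
        "speed_quadratic": mixed_model.subject_contrast(
            records, term="n^2", factor="speed", pair=("constant", "variable")
        ),
        "speed_linear": mixed_model.subject_contrast(
            records, term="n^1", factor="speed", pair=("constant", "variable")
        ),
        "coloration_linear_parallel_vs_orthogonal": mixed_model.subject_contrast(
            records, term="n^1", factor="coloration", pair=("parallel", "orthogonal")
        ),
        "coloration_linear_parallel_vs_trinary": mixed_model.subject_contrast(
            records, term="n^1", factor="coloration", pair=("parallel", "trinary")
        ),
        "coloration_linear_orthogonal_vs_trinary": mixed_model.subject_contrast(
            records, term="n^1", factor="coloration", pair=("orthogonal", "trinary")
        ),
    }
    oddity = {
        "orthogonal_vs_trinary": mixed_model.oddity_ratio_at_n(
            records, 30, ("orthogonal", "trinary")
        ),
        "parallel_vs_trinary": mixed_model.oddity_ratio_at_n(
            records, 30, ("parallel", "trinary")
        ),
    }
    return {"ladder": ladder, "contrasts": contrasts, "oddity": oddity}


def summarize_figure2_analogue(records: pd.DataFrame) -> pd.DataFrame:
    """Condition means of log error with within-subject 95% CIs.

    Subject-mean centring (Cousineau) with the Morey cell-count
    correction: each subject's cell means are shifted by (grand mean -
    subject mean) before computing between-subject SDs, and CI half-widths
    are scaled by sqrt(C / (C - 1)) for C condition cells.
    """
    df = records.copy()
    if "is_practice" in df:
        df = df.loc[~df["is_practice"].astype(bool)]
    cell_cols = ["coloration", "speed_cond", "n_agents"]
    cell = (
        df.groupby(["subject_id"] + cell_cols, observed=True)["log_error"]
        .mean()
        .reset_index()
    )
    missing = cell.groupby("subject_id").size()
    n_cells = cell[cell_cols].drop_duplicates().shape[0]
    if (missing != n_cells).any():
        bad = missing[missing != n_cells].index.tolist()
        raise ValueError(f"subjects with missing condition cells: {bad}")

    grand = cell["log_error"].mean()
    subj_mean = cell.groupby("subject_id")["log_error"].transform("mean")
    cell["centred"] = cell["log_error"] - subj_mean + grand

    n_subj = cell["subject_id"].nunique()
    morey = np.sqrt(n_cells / (n_cells - 1.0))
    tcrit = stats.t.ppf(0.975, n_subj - 1)

    out = (
        cell.groupby(cell_cols, observed=True)
        .agg(
            mean_log_error=("log_error", "mean"),
            sd_centred=("centred", "std"),
        )
        .reset_index()
    )
    half = tcrit * out["sd_centred"] * morey / np.sqrt(n_subj)
    out["ci_low"] = out["mean_log_error"] - half
    out["ci_high"] = out["mean_log_error"] + half
    out["n_subjects"] = n_subj
    return out.drop(columns="sd_centred").sort_values(cell_cols).reset_index(drop=True)


def plot_figure2(summary: pd.DataFrame, path: str | Path) -> None:
    """Three-panel condition-means plot (one panel per coloration;
    solid = constant speed, dashed = variable)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colorations = sorted(summary["coloration"].unique())
    fig, axes = plt.subplots(1, len(colorations), figsize=(4 * len(colorations), 3.5),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, col in zip(axes, colorations):
        for speed, ls in (("constant", "-"), ("variable", "--")):
            d = summary[(summary["coloration"] == col) & (summary["speed_cond"] == speed)]
            d = d.sort_values("n_agents")
            ax.errorbar(
                d["n_agents"], d["mean_log_error"],
                yerr=[d["mean_log_error"] - d["ci_low"], d["ci_high"] - d["mean_log_error"]],
                fmt="o" + ls, capsize=3, label=speed,
            )
        ax.set_title(col)
        ax.set_xlabel("number of squares")
    axes[0].set_ylabel("mean log error (log px)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------


def analysis_to_dict(analysis: dict) -> dict:
    """Plain-JSON view of the `analyze_records` output."""
    ladder = analysis["ladder"]
    out: dict = {"deviance_tests": {}, "fits": {}, "contrasts": {}, "oddity_ratios": {}}
    for name, t in ladder["tests"].items():
        out["deviance_tests"][name] = {"chisq": t.chisq, "df": t.df, "p": t.p}
    for name, f in ladder["fits"].items():
        out["fits"][name] = {
            "loglik": f.loglik,
            "sigma_u2": f.sigma_u2,
            "sigma_e2": f.sigma_e2,
            "n_params": f.n_params,
            "coefficients": dict(zip(f.column_names, f.beta.tolist())),
            "se": dict(zip(f.column_names, f.se.tolist())),
        }
    for name, c in analysis["contrasts"].items():
        out["contrasts"][name] = {
            "estimate": c.estimate, "t": c.t_stat, "df": c.df, "p": c.p
        }
    for name, o in analysis["oddity"].items():
        out["oddity_ratios"][name] = {
            "ratio": o.ratio, "ci_low": o.ci_low, "ci_high": o.ci_high
        }
    return out


def write_artifacts(result: ExperimentResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(outdir / "records.csv", index=False)
    (outdir / "model_summary.json").write_text(
        json.dumps(analysis_to_dict(result.analysis), indent=2)
    )
    result.figure2.to_csv(outdir / "figure2_analogue.csv", index=False)
    plot_figure2(result.figure2, outdir / "figure2_analogue.png")
    cfg = dataclasses.asdict(result.config)
    cfg["observer"] = dataclasses.asdict(result.config.observer)
    (outdir / "run_log.json").write_text(json.dumps(cfg, indent=2, default=str))


def load_run_config(path: str | Path) -> RunConfig:
    """Read a flat ``key = value`` config file mirroring RunConfig.

    Observer parameters use an ``observer.`` prefix; unknown keys are
    rejected. Example line: ``observer.pursuit_gain = 0.4``.
    """
    run_kw: dict = {}
    obs_kw: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key.startswith("observer."):
            obs_kw[key[len("observer."):]] = _coerce(val)
        else:
            run_kw[key] = _coerce(val)
    valid_run = {f.name for f in dataclasses.fields(RunConfig)}
    valid_obs = {f.name for f in dataclasses.fields(ObserverParams)}
    for k in run_kw:
        if k not in valid_run - {"observer"}:
            raise ValueError(f"unknown RunConfig key: {k!r}")
    for k in obs_kw:
        if k not in valid_obs:
            raise ValueError(f"unknown observer key: {k!r}")
    if obs_kw:
        run_kw["observer"] = ObserverParams(**obs_kw)
    return RunConfig(**run_kw)


def _coerce(val: str):
    try:
        return int(val)
    except ValueError:
        pass
    try:
        return float(val)
    except ValueError:
        pass
    if val.lower() in ("true", "false"):
        return val.lower() == "true"
    if "," in val:
        return tuple(_coerce(v.strip()) for v in val.split(","))
    return val
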
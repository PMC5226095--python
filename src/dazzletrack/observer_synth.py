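"""Synthetic observer: a stand-in for human participants.

No human tracking data are available for this task, so two generators
provide analysis-ready data with known ground truth:

* a *mechanistic* observer (`generate_cursor_trace`, `generate_dataset`)
  that pursues the target with lag, proportional gain and motor jitter,
  and occasionally swaps the identity it believes it is tracking — more
  often when the local swarm is dense (confusion effect), less often when
  the target's instantaneous speed is odd relative to the group (oddity
  effect), and with a coloration-dependent offset (dazzle effect);

* a *direct* sampler (`generate_logerror_dataset`) from the analysis
  model itself — log error = X beta + subject intercept + residual — which
  gives exact ground truth for estimator and calibration tests.

Default parameters are calibrated so the mechanistic observer reproduces,
qualitatively, the empirical pattern of the tracking literature: error
rising and decelerating with group size, lower error when speeds vary, and
a steeper group-size slope for motion-parallel stripes. They are properties
of this synthetic observer, not estimates of human parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import swarm_sim, tracking_metrics
from .swarm_sim import Trajectory, TrialConfig

NEIGHBOUR_RADIUS_PX = 64.0  # local-density neighbourhood around the tracked item


class TrialSpec(NamedTuple):
    """One scheduled trial: factor levels plus bookkeeping."""

    n_agents: int
    coloration: str
    speed_cond: str
    is_practice: bool = False
    block: int = 0
    trial: int = 0


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the mechanistic synthetic observer.

    Pursuit: each frame the cursor moves ``pursuit_gain`` of the way toward
    the ``lag_ms``-lagged position of the currently tracked item, plus
    isotropic Gaussian jitter of SD ``motor_sd`` px per axis.

    Identity swaps: each frame the tracked identity switches to the item
    nearest the cursor (other than the current one) with probability
    ``logistic(swap_base + swap_density_gain * density
    + coloration_gain[coloration] - oddity_gain * |z_speed(target)|)``
    where ``density`` counts items within 64 px of the tracked item and
    ``z_speed`` standardizes the target's speed within the group (0 when
    the group speed SD is 0, e.g. constant-speed trials).

    ``subject_sd`` is the SD of a per-subject multiplicative error offset
    (additive on the log scale); ``resid_sd`` is used only by the direct
    log-error sampler.
    """

    lag_ms: float = 100.0
    pursuit_gain: float = 0.35
    motor_sd: float = 3.0
    swap_base: float = -6.0
    swap_density_gain: float = 0.35
    coloration_gain: dict = field(
        default_factory=lambda: {"orthogonal": 0.0, "parallel": 0.7, "trinary": 0.0}
    )
    oddity_gain: float = 1.0
    subject_sd: float = 0.15
    resid_sd: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.pursuit_gain <= 1.0):
            raise ValueError("pursuit_gain must lie in (0, 1]")
        for name in ("motor_sd", "subject_sd", "resid_sd", "oddity_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lag_ms < 0:
            raise ValueError("lag_ms must be >= 0")


@dataclass
class CursorTrace:
    """Synthetic cursor positions and believed identity, on the frame grid."""

    times_ms: np.ndarray
    xy: np.ndarray  # (n_frames, 2)
    tracked_id: np.ndarray  # (n_frames,)

    def sampled(self, traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
        """Cursor positions on the trial's 10 ms recording grid."""
        idx = traj.sample_indices()
        return self.times_ms[idx], self.xy[idx]


def _logistic(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit  # overflow-safe, expit(-inf) = 0

    return expit(x)


def generate_cursor_trace(
    trajectory: Trajectory,
    params: ObserverParams,
    rng: np.random.Generator,
) -> CursorTrace:
    """Run the mechanistic observer over one trial."""
    xy, tracked = _cursor_batch([trajectory], params, [rng])
    return CursorTrace(times_ms=trajectory.times_ms, xy=xy[0], tracked_id=tracked[0])


def _cursor_batch(
    trajectories: Sequence[Trajectory],
    params: ObserverParams,
    rngs: Sequence[np.random.Generator],
):
    """Vectorized observer over same-shape trials.

    Noise is pre-drawn per trial from that trial's generator, so results
    are identical whether a trial is run alone or in a batch.
    """
    cap = swarm_sim.MAX_BATCH
    if len(trajectories) > cap:
        xs, ts = [], []
        for i in range(0, len(trajectories), cap):
            xy_i, tid_i = _cursor_batch(trajectories[i : i + cap], params, rngs[i : i + cap])
            xs.append(xy_i)
            ts.append(tid_i)
        return np.concatenate(xs), np.concatenate(ts)

    B = len(trajectories)
    cfg = trajectories[0].config
    n_f, A = trajectories[0].x.shape
    lag = int(round(params.lag_ms * cfg.frame_rate / 1000.0))
    colorations = [t.config.coloration for t in trajectories]

    # frame-major stacks: per-frame slices are contiguous in the hot loop
    P = np.empty((n_f, B, A, 2))
    P0 = np.empty((B, A, 2))
    targets = np.empty(B, dtype=int)
    jitter = np.empty((n_f, B, 2))
    u_swap = np.empty((n_f, B))
    z_t = np.zeros((n_f, B))
    for b, (t, rng) in enumerate(zip(trajectories, rngs)):
        P[:, b, :, 0] = t.x
        P[:, b, :, 1] = t.y
        P0[b, :, 0] = t.x0
        P0[b, :, 1] = t.y0
        targets[b] = t.target_index
        jitter[:, b] = (
            rng.normal(0.0, params.motor_sd, size=(n_f, 2))
            if params.motor_sd > 0
            else np.zeros((n_f, 2))
        )
        u_swap[:, b] = rng.uniform(size=n_f)
        if A > 1:
            sd = t.speed.std(axis=1)
            dev = np.abs(t.speed[:, t.target_index] - t.speed.mean(axis=1))
            z_t[:, b] = np.divide(dev, sd, out=np.zeros(n_f), where=sd > 0)

    color_off = np.array([params.coloration_gain.get(c, 0.0) for c in colorations])

    rows = np.arange(B)
    cursor = P0[rows, targets].copy()
    tracked = targets.copy()
    out_xy = np.empty((n_f, B, 2))
    out_id = np.empty((n_f, B), dtype=int)

    # preallocated scratch: the frame loop must not churn fresh arrays
    pull = np.empty((B, 2))
    diff = np.empty((B, A, 2))
    d2 = np.empty((B, A))
    r2 = NEIGHBOUR_RADIUS_PX**2
    base_logit = params.swap_base + color_off  # (B,)

    with swarm_sim._gc_paused():
        for k in range(n_f):
            lagged = P0 if k - lag < 0 else P[k - lag]
            np.subtract(lagged[rows, tracked], cursor, out=pull)
            pull *= params.pursuit_gain
            cursor += pull
            cursor += jitter[k]
            out_xy[k] = cursor
            out_id[k] = tracked

            if A > 1:
                here = P[k]  # (B, A, 2)
                np.subtract(here, here[rows, tracked][:, None, :], out=diff)
                np.multiply(diff, diff, out=diff)
                np.add(diff[:, :, 0], diff[:, :, 1], out=d2)
                density = (d2 < r2).sum(axis=1) - 1
                logit = (
                    base_logit
                    + params.swap_density_gain * density
                    - params.oddity_gain * z_t[k]
                )
                swap = u_swap[k] < _logistic(logit)
                if np.any(swap):
                    idx = np.nonzero(swap)[0]
                    d_cursor = np.linalg.norm(here[idx] - cursor[idx, None, :], axis=2)
                    d_cursor[np.arange(len(idx)), tracked[idx]] = np.inf
                    tracked[idx] = d_cursor.argmin(axis=1)

    xy = np.ascontiguousarray(out_xy.transpose(1, 0, 2))
    tid = np.ascontiguousarray(out_id.T)
    return xy, tid


# ---------------------------------------------------------------------------
# dataset generators
# ---------------------------------------------------------------------------


def _trial_rngs(master_seed: int, subject_id: int, trial_uid: int):
    """Deterministic (swarm, observer) generators for one scheduled trial."""
    ss = np.random.SeedSequence((master_seed, subject_id, trial_uid))
    kids = ss.spawn(2)
    return np.random.default_rng(kids[0]), np.random.default_rng(kids[1])


def generate_dataset(
    schedule: Sequence[TrialSpec] | None = None,
    subjects: int = 15,
    params: ObserverParams | None = None,
    master_seed: int = 0,
    trial_kwargs: dict | None = None,
    schedules: Sequence[Sequence[TrialSpec]] | None = None,
) -> pd.DataFrame:
    """Simulate the whole pseudo-experiment with the mechanistic observer.

    Either one ``schedule`` shared by all ``subjects`` or an explicit
    per-subject list ``schedules``. Order effects are not modelled; a
    per-subject random intercept N(0, subject_sd^2) scales errors
    multiplicatively. Returns one row per (subject, trial) with practice
    trials flagged, not dropped.
    """
    params = params or ObserverParams()
    trial_kwargs = trial_kwargs or {}
    if schedules is None:
        if schedule is None:
            raise ValueError("pass either schedule or schedules")
        schedules = [schedule] * subjects
    subjects = len(schedules)

    intercept_rng = np.random.default_rng(np.random.SeedSequence((master_seed, 54321)))
    u_subj = (
        intercept_rng.normal(0.0, params.subject_sd, size=subjects)
        if params.subject_sd > 0
        else np.zeros(subjects)
    )

    # batch trials across subjects/replicates by identical simulation shape
    jobs: dict[tuple, list[tuple[int, int, TrialSpec]]] = {}
    for s in range(subjects):
        for uid, spec in enumerate(schedules[s]):
            key = (spec.n_agents, spec.speed_cond, spec.coloration)
            jobs.setdefault(key, []).append((s, uid, spec))

    rows = []
    for (n_agents, speed_cond, coloration), items in jobs.items():
        cfg = swarm_sim.trial_config_for(
            n_agents, coloration, speed_cond, **trial_kwargs
        )
        swarm_rngs, obs_rngs = [], []
        for s, uid, _ in items:
            r_sw, r_ob = _trial_rngs(master_seed, s, uid)
            swarm_rngs.append(r_sw)
            obs_rngs.append(r_ob)
        trajs = swarm_sim._simulate_batch(cfg, swarm_rngs)
        xy, _ = _cursor_batch(trajs, params, obs_rngs)

        idx = trajs[0].sample_indices()
        times = trajs[0].times_ms
        tgt = np.empty((len(items), len(idx), 2))
        for b, t in enumerate(trajs):
            _, tser = t.target_series()
            tgt[b] = tser
        err = tracking_metrics.batch_mean_error(tgt, xy[:, idx], times[idx])

        for b, (s, uid, spec) in enumerate(items):
            raw = float(err[b])
            log_e = float(np.log(raw) + u_subj[s])
            rows.append(
                {
                    "subject_id": s,
                    "block": spec.block,
                    "trial": spec.trial,
                    "n_agents": spec.n_agents,
                    "coloration": spec.coloration,
                    "speed_cond": spec.speed_cond,
                    "is_practice": spec.is_practice,
                    "mean_error_px": float(np.exp(log_e)),
                    "log_error": log_e,
                }
            )

    df = pd.DataFrame(rows).sort_values(["subject_id", "block", "trial"])
    return df.reset_index(drop=True)


def balanced_factor_table(
    subjects: int = 15,
    reps: int = 14,
    n_levels: Sequence[int] = (1, 10, 30, 50),
    colorations: Sequence[str] = ("orthogonal", "parallel", "trinary"),
    speed_conds: Sequence[str] = ("constant", "variable"),
) -> pd.DataFrame:
    """Fully crossed factor table: subjects x n x coloration x speed x reps.

    Defaults give the study's 15 subjects x 336 trials."""
    idx = pd.MultiIndex.from_product(
        [range(subjects), n_levels, colorations, speed_conds, range(reps)],
        names=["subject_id", "n_agents", "coloration", "speed_cond", "rep"],
    )
    return idx.to_frame(index=False)


def generate_logerror_dataset(
    factors: pd.DataFrame,
    terms: Sequence[str],
    beta: Sequence[float],
    subject_sd: float,
    resid_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample log errors directly from the analysis model.

    ``log_error = X beta + u_subject + eps`` with X the fixed-effects
    matrix built from ``terms`` (see `mixed_model.build_design`),
    u ~ N(0, subject_sd^2) per subject, eps ~ N(0, resid_sd^2) per row.
    """
    from . import mixed_model  # deferred: mixed_model does not import us

    records = factors.copy()
    records["log_error"] = 0.0
    design = mixed_model.build_design(records, terms)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (design.X.shape[1],):
        raise ValueError(
            f"beta has {beta.shape[0] if beta.ndim else 0} entries; "
            f"design has {design.X.shape[1]} columns {design.column_names}"
        )
    lin = design.X @ beta
    subj_codes, _ = pd.factorize(records["subject_id"])
    n_subj = subj_codes.max() + 1
    u = rng.normal(0.0, subject_sd, size=n_subj) if subject_sd > 0 else np.zeros(n_subj)
    eps = rng.normal(0.0, resid_sd, size=len(records)) if resid_sd > 0 else 0.0
    records["log_error"] = lin + u[subj_codes] + eps
    records["mean_error_px"] = np.exp(records["log_error"])
    if "is_practice" not in records:
        records["is_practice"] = False
    return records
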
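"""Protocol simulation: blocks of perturbation trials driven by the staircase.

One *block* is five minutes of perturbed walking in the real experiment; here
it is a fixed-or-drawn number of trials (the real design produced variable
counts with a floor of 25).  Each trial perturbs a randomly chosen belt by the
staircase's currently recommended speed difference, collects the observer's
left-or-right judgement, feeds correctness back into the posterior and records
the running estimate and credible width.  The last estimate of a block is that
block's just-noticeable difference (JND).  A full *study* runs four blocks per
participant: two with the perturbed belt sped up, two with it slowed down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ParseError, ProtocolError
from .observers import DIRECTIONS, TrialRecord, VirtualObserver, simulate_trial
from .quest import (
    QuestParams,
    credible_width,
    make_quest,
    next_intensity,
    replay_block,
    threshold_estimate,
    update,
)

__all__ = [
    "ProtocolConfig",
    "BlockResult",
    "StudyResult",
    "run_block",
    "run_study",
    "write_trial_log",
    "read_trial_log",
    "replay_study",
]

TRIAL_LOG_COLUMNS = [
    "participant",
    "block",
    "trial",
    "direction",
    "side",
    "intensity_mps",
    "response",
    "correct",
    "steps_to_response",
]

#: trial window used for steps-to-response vs JND correlations: late enough
#: that every participant is near threshold, early enough that no block (floor
#: 25 trials) has ended.
LATE_TRIAL_WINDOW = (16, 25)


@dataclass(frozen=True)
class ProtocolConfig:
    """Trial-level protocol constants of the split-belt task."""

    baseline_speed: float = 1.0       # m/s, both belts between perturbations
    ramp_rate: float = 3.0            # m/s^2 belt (de)acceleration magnitude
    max_perturbed_steps: int = 12
    response_window_steps: int = 10
    prompt_after_steps: int = 3
    post_response_steps: int = 2
    baseline_gap_steps: tuple[int, int] = (6, 9)
    trials_per_block: int | tuple[int, int] = (25, 35)
    blocks: tuple[str, ...] = ("increase", "decrease", "increase", "decrease")
    clamp: tuple[float, float] = (0.005, 0.9)
    swing_duration_s: float = 0.4     # upper bound on swing-phase duration

    def __post_init__(self) -> None:
        if not (self.prompt_after_steps < self.response_window_steps <= self.max_perturbed_steps):
            raise ParameterError(
                "need prompt_after_steps < response_window_steps <= max_perturbed_steps, got "
                f"{self.prompt_after_steps}, {self.response_window_steps}, {self.max_perturbed_steps}"
            )
        lo, hi = self.clamp
        if not (0.0 < lo < hi < self.baseline_speed):
            raise ParameterError(f"clamp must lie within (0, baseline_speed), got {self.clamp}")
        # the perturbed belt must reach its target speed within one swing
        # phase, otherwise the walker feels the ramp rather than the speed step
        if hi / self.ramp_rate > self.swing_duration_s:
            raise ProtocolError(
                f"ramp infeasible: clamp_hi/ramp_rate = {hi / self.ramp_rate:.3f} s exceeds the "
                f"{self.swing_duration_s} s swing-phase bound"
            )
        g0, g1 = self.baseline_gap_steps
        if not (0 < g0 <= g1):
            raise ParameterError(f"baseline_gap_steps must be a positive range, got {self.baseline_gap_steps}")
        for d in self.blocks:
            if d not in DIRECTIONS:
                raise ParameterError(f"block direction must be one of {DIRECTIONS}, got {d!r}")

    def draw_trials(self, rng: np.random.Generator) -> int:
        t = self.trials_per_block
        if isinstance(t, int):
            n = t
        else:
            lo, hi = int(t[0]), int(t[1])
            if lo > hi:
                raise ProtocolError(f"trials_per_block range reversed: {t}")
            n = int(rng.integers(lo, hi + 1))
        if n < 1:
            raise ProtocolError(f"trials_per_block must be >= 1, got {n}")
        return n


@dataclass(frozen=True)
class BlockResult:
    """One block: trial records plus trial-wise estimate/width trajectories."""

    direction: str
    trials: tuple[TrialRecord, ...]
    estimate_trajectory: np.ndarray   # m/s, one entry per trial
    ci_width_trajectory: np.ndarray   # m/s, 95% credible widths
    final_jnd: float                  # m/s, last estimate of the block

    def __post_init__(self) -> None:
        n = len(self.trials)
        if len(self.estimate_trajectory) != n or len(self.ci_width_trajectory) != n:
            raise ParameterError("trajectory lengths must equal the trial count")
        if n and self.final_jnd != self.estimate_trajectory[-1]:
            raise ParameterError("final_jnd must equal the last trajectory entry")


@dataclass(frozen=True)
class StudyResult:
    """A simulated (or replayed) study: per-block results and the summary table.

    ``table`` has one row per participant x direction x block repetition with
    final JNDs (m/s and % of baseline speed), steps-to-response means (overall
    and over the late-trial window, non-responses excluded) and trial counts.
    ``blocks`` maps (participant, block_index) to the :class:`BlockResult`.
    """

    table: pd.DataFrame
    blocks: dict = field(default_factory=dict)
    baseline_speed: float = 1.0

    def participant_means(self) -> pd.DataFrame:
        """Per participant x direction: mean of the two block-final JNDs."""
        g = self.table.groupby(["participant", "direction"], as_index=False).agg(
            jnd_mps=("final_jnd_mps", "mean"),
            jnd_pct=("final_jnd_pct", "mean"),
            steps=("mean_steps", "mean"),
            steps_late=("mean_steps_late", "mean"),
        )
        return g


def run_block(
    observer: VirtualObserver,
    direction: str,
    quest_params: QuestParams,
    protocol: ProtocolConfig,
    rng: np.random.Generator,
    n_trials: int | None = None,
) -> BlockResult:
    """Simulate one block of staircase-driven perturbation trials."""
    if n_trials is None:
        n_trials = protocol.draw_trials(rng)
    if n_trials < 1:
        raise ProtocolError(f"cannot run an empty block (n_trials={n_trials})")
    state = make_quest(quest_params)
    trials: list[TrialRecord] = []
    estimates: list[float] = []
    widths: list[float] = []
    for _ in range(n_trials):
        intensity = next_intensity(state, protocol.clamp)
        side = "left" if rng.random() < 0.5 else "right"
        rec = simulate_trial(observer, intensity, direction, side, rng)
        state = update(state, intensity, rec.correct)
        trials.append(rec)
        estimates.append(threshold_estimate(state))
        widths.append(credible_width(state))
    return BlockResult(
        direction=direction,
        trials=tuple(trials),
        estimate_trajectory=np.asarray(estimates),
        ci_width_trajectory=np.asarray(widths),
        final_jnd=estimates[-1],
    )


def block_order(participant: int, protocol: ProtocolConfig) -> tuple[str, ...]:
    """Direction sequence for one participant.

    Directions alternate; which direction comes first is counterbalanced by
    participant parity (the original randomization is not knowable, so this
    deterministic counterbalancing is recorded in the run manifest).
    """
    order = protocol.blocks
    if participant % 2 == 1:
        swap = {"increase": "decrease", "decrease": "increase"}
        order = tuple(swap[d] for d in order)
    return order


def run_study(
    population: list[VirtualObserver],
    quest_params: QuestParams | None = None,
    protocol: ProtocolConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> StudyResult:
    """Run the four-block protocol for every observer in the population."""
    if not population:
        raise ParameterError("population must be non-empty")
    quest_params = quest_params or QuestParams()
    protocol = protocol or ProtocolConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    blocks: dict = {}
    for pid, observer in enumerate(population):
        rep_count = {d: 0 for d in DIRECTIONS}
        for bidx, direction in enumerate(block_order(pid, protocol), start=1):
            block = run_block(observer, direction, quest_params, protocol, rng)
            rep_count[direction] += 1
            blocks[(pid, bidx)] = block
            rows.append(_summarize_block(pid, bidx, rep_count[direction], block, protocol))
    table = pd.DataFrame(rows)
    return StudyResult(table=table, blocks=blocks, baseline_speed=protocol.baseline_speed)


def _summarize_block(pid: int, bidx: int, rep: int, block: BlockResult, protocol: ProtocolConfig) -> dict:
    steps = [t.steps_to_response for t in block.trials if t.responded]
    lo, hi = LATE_TRIAL_WINDOW
    late = [
        t.steps_to_response
        for i, t in enumerate(block.trials, start=1)
        if t.responded and lo <= i <= hi
    ]
    return {
        "participant": pid,
        "block": bidx,
        "direction": block.direction,
        "block_rep": rep,
        "n_trials": len(block.trials),
        "final_jnd_mps": block.final_jnd,
        "final_jnd_pct": 100.0 * block.final_jnd / protocol.baseline_speed,
        "mean_steps": float(np.mean(steps)) if steps else np.nan,
        "mean_steps_late": float(np.mean(late)) if late else np.nan,
        "n_nonresponse": sum(not t.responded for t in block.trials),
    }


def write_trial_log(study: StudyResult, path) -> None:
    """Write the per-trial log as CSV (full float precision; replayable)."""
    rows = []
    for (pid, bidx), block in sorted(study.blocks.items()):
        for tidx, t in enumerate(block.trials, start=1):
            rows.append(
                (pid, bidx, tidx, t.direction, t.side, t.intensity_mps, t.response,
                 int(t.correct), t.steps_to_response)
            )
    pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS).to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Raises :class:`ParseError` naming the missing column or the first
    offending row for non-numeric numeric cells.
    """
    df = pd.read_csv(path, dtype={"direction": str, "side": str, "response": str},
                     float_precision="round_trip")
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"trial log missing required columns: {missing}")
    for col in ("participant", "block", "trial", "intensity_mps", "correct", "steps_to_response"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ParseError(f"non-numeric value in column {col!r} at data row {row}")
        df[col] = coerced
    return df


def replay_study(
    log: pd.DataFrame,
    quest_params: QuestParams | None = None,
    protocol: ProtocolConfig | None = None,
) -> StudyResult:
    """Rebuild a :class:`StudyResult` from a trial log by re-running the posterior.

    Estimate and credible-width trajectories (and hence final JNDs) are
    recomputed from the logged intensities and correctness flags, so a replay
    of a freshly written log reproduces the original study exactly.
    """
    quest_params = quest_params or QuestParams()
    protocol = protocol or ProtocolConfig()
    rows = []
    blocks: dict = {}
    for pid, part in log.groupby("participant", sort=True):
        rep_count = {d: 0 for d in DIRECTIONS}
        for bidx, blk in part.groupby("block", sort=True):
            blk = blk.sort_values("trial")
            direction = str(blk["direction"].iloc[0])
            if direction not in DIRECTIONS:
                raise ParseError(f"unknown direction {direction!r} in trial log")
            trials = tuple(
                TrialRecord(
                    direction=str(r.direction),
                    side=str(r.side),
                    intensity_mps=float(r.intensity_mps),
                    response=str(r.response),
                    correct=bool(r.correct),
                    steps_to_response=int(r.steps_to_response),
                )
                for r in blk.itertuples()
            )
            estimates, widths, _ = replay_block(
                [(t.intensity_mps, t.correct) for t in trials], quest_params
            )
            block = BlockResult(
                direction=direction,
                trials=trials,
                estimate_trajectory=estimates,
                ci_width_trajectory=widths,
                final_jnd=float(estimates[-1]),
            )
            rep_count[direction] += 1
            blocks[(int(pid), int(bidx))] = block
            rows.append(_summarize_block(int(pid), int(bidx), rep_count[direction], block, protocol))
    table = pd.DataFrame(rows)
    return StudyResult(table=table, blocks=blocks, baseline_speed=protocol.baseline_speed)
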
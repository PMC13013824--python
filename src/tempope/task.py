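"""Pavlovian catch-trial task schedules and event tables.

The task is a passive reward-learning paradigm with two interleaved trial
types: a *juice* cue predicting an oral juice bolus and a *visual* cue
predicting a neutral visual outcome, each after a short consistent delay
(2-4 s).  A first run establishes the cue-outcome timing; in a second run,
occasional *catch* trials unexpectedly extend the delay to 8-10 s, producing
a negative temporal prediction error (outcome absent at the expected time)
followed by a positive one (outcome delivered at an unexpected time).

This module generates randomized schedules honoring the placement rules
(catch trials confined to the latter 75% of run-2 trials; every catch trial
of a type followed by at least one normal trial of that type before the next
catch of that type), validates them, and expands them into BIDS-style event
tables with the five event classes used by the first-level models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("juice", "visual")
EVENT_CLASSES = (
    "cue",
    "expected_outcome",
    "expected_absence",
    "unexpected_absence",
    "unexpected_outcome",
)

#: gap between outcome offset and the modeled "expected absence" window (s)
EXPECTED_ABSENCE_LAG = 2.0
#: gap between cue offset and the modeled "unexpected absence" window (s),
#: i.e. the very end of the typical outcome-delivery window
UNEXPECTED_ABSENCE_LAG = 4.0


class ScheduleConstraintError(ValueError):
    """Raised when the requested schedule constraints cannot be satisfied."""


@dataclass(frozen=True)
class TrialSpec:
    """A single trial with all event times in seconds from run start."""

    run_index: int
    trial_index: int
    condition: str
    is_catch: bool
    cue_onset: float
    cue_outcome_delay: float
    cue_duration: float = 1.0
    outcome_duration: float = 1.0
    juice_shift: float = 0.5

    @property
    def shift(self) -> float:
        return self.juice_shift if self.condition == "juice" else 0.0

    @property
    def cue_offset(self) -> float:
        return self.cue_onset + self.cue_duration

    @property
    def outcome_onset(self) -> float:
        return self.cue_offset + self.cue_outcome_delay + self.shift

    @property
    def trial_end(self) -> float:
        """End of the last modeled event of this trial."""
        if self.is_catch:
            return self.outcome_onset + self.outcome_duration
        return (
            self.outcome_onset
            + EXPECTED_ABSENCE_LAG
            + self.outcome_duration
        )


@dataclass
class ScheduleConfig:
    """Trial counts, delay ranges and pacing of the two task runs."""

    run1_normal_per_condition: int = 27
    run2_normal_per_condition: int = 26
    run2_catch_per_condition: int = 10
    normal_delay_range: tuple[float, float] = (2.0, 4.0)
    catch_delay_range: tuple[float, float] = (8.0, 10.0)
    delay_grid: float = 0.5
    iti_range: tuple[float, float] = (4.0, 8.0)
    cue_duration: float = 1.0
    outcome_duration: float = 1.0
    juice_shift: float = 0.5
    initial_rest: float = 10.0
    final_rest: float = 10.0
    catch_fraction: float = 0.75  # catch trials live in this latter fraction
    max_consecutive_same_condition: int = 4
    spacing_across_types: bool = False

    def validate(self) -> None:
        if min(
            self.run1_normal_per_condition,
            self.run2_normal_per_condition,
            self.run2_catch_per_condition,
        ) < 0:
            raise ValueError("trial counts must be non-negative")
        for lo, hi in (self.normal_delay_range, self.catch_delay_range):
            if not (0 < lo <= hi):
                raise ValueError("delay ranges must be positive and ordered")
        lo, hi = self.iti_range
        if not (0 < lo <= hi):
            raise ValueError("ITI range must be positive and ordered")


@dataclass
class TaskSchedule:
    subject_id: str
    runs: list[list[TrialSpec]]
    run_durations: list[float]
    seed: int
    config: ScheduleConfig = field(default_factory=ScheduleConfig)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def trials(self, condition: str | None = None):
        for run in self.runs:
            for t in run:
                if condition is None or t.condition == condition:
                    yield t

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, np.bool_):
                return bool(v)
            return v

        return {
            "subject_id": self.subject_id,
            "seed": int(self.seed),
            "config": plain(dataclasses.asdict(self.config)),
            "run_durations": [float(d) for d in self.run_durations],
            "runs": [
                [plain(dataclasses.asdict(t)) for t in run] for run in self.runs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSchedule":
        cfg = ScheduleConfig(**d["config"])
        runs = [[TrialSpec(**t) for t in run] for run in d["runs"]]
        return cls(
            subject_id=d["subject_id"],
            runs=runs,
            run_durations=list(d["run_durations"]),
            seed=int(d["seed"]),
            config=cfg,
        )


def _grid_choice(rng: np.random.Generator, lo: float, hi: float, grid: float) -> float:
    """Uniform draw on a regular grid within [lo, hi]."""
    n = int(round((hi - lo) / grid)) + 1
    return lo + grid * rng.integers(0, n)


def _condition_order(
    rng: np.random.Generator, n_per_condition: dict[str, int], max_run: int
) -> list[str]:
    """Random interleaving with no more than ``max_run`` consecutive repeats."""
    for _ in range(2000):
        seq: list[str] = []
        remaining = dict(n_per_condition)
        ok = True
        while any(remaining.values()):
            avail = [c for c, n in remaining.items() if n > 0]
            tail = seq[-max_run:]
            if len(tail) == max_run and len(set(tail)) == 1 and tail[0] in avail:
                avail = [c for c in avail if c != tail[0]]
            if not avail:
                ok = False
                break
            weights = np.array([remaining[c] for c in avail], dtype=float)
            c = str(rng.choice(avail, p=weights / weights.sum()))
            seq.append(c)
            remaining[c] -= 1
        if ok:
            return seq
    raise ScheduleConstraintError(
        "could not interleave conditions under the max-consecutive rule"
    )


def _assign_catches(
    rng: np.random.Generator,
    order: list[str],
    n_catch: dict[str, int],
    catch_fraction: float,
    across_types: bool,
) -> list[bool]:
    """Choose catch positions in the latter ``catch_fraction`` of the run.

    Within each condition's subsequence, catch trials must be non-adjacent so
    that at least one normal trial of the same type separates consecutive
    catches of that type.  In strict mode the non-adjacency is additionally
    enforced on the global trial sequence.
    """
    n = len(order)
    first_ok = int(np.floor((1.0 - catch_fraction) * n))
    # quick feasibility check per condition
    for cond, k in n_catch.items():
        slots = [i for i, c in enumerate(order) if c == cond]
        eligible = [j for j, i in enumerate(slots) if i >= first_ok]
        if k > 0 and (len(eligible) < 2 * k - 1):
            raise ScheduleConstraintError(
                f"latter-{catch_fraction:.0%}/spacing rule infeasible for "
                f"condition {cond!r}: need {k} non-adjacent catch slots among "
                f"{len(eligible)} eligible positions"
            )
    for _ in range(5000):
        is_catch = [False] * n
        ok = True
        for cond, k in n_catch.items():
            slots = [i for i, c in enumerate(order) if c == cond]
            eligible_within = [j for j, i in enumerate(slots) if i >= first_ok]
            if k == 0:
                continue
            # uniform non-adjacent k-subset of the eligible tail via the
            # standard combinatorial bijection (choose from m-k+1, spread)
            m = len(eligible_within)
            base = np.sort(rng.choice(m - k + 1, size=k, replace=False))
            picked = [eligible_within[b + j] for j, b in enumerate(base)]
            for j in picked:
                is_catch[slots[j]] = True
        if ok and across_types:
            # strict mode: between successive catches (any type) there must be
            # a normal trial of the earlier catch's type
            catches = [i for i, f in enumerate(is_catch) if f]
            for a, b in zip(catches, catches[1:]):
                sep = [
                    i
                    for i in range(a + 1, b)
                    if order[i] == order[a] and not is_catch[i]
                ]
                if not sep:
                    ok = False
                    break
        if ok:
            return is_catch
    raise ScheduleConstraintError(
        "could not place catch trials under the latter-75%/spacing rules"
    )


def generate_schedule(
    config: ScheduleConfig | None = None,
    seed: int = 0,
    subject_id: str = "sub-001",
) -> TaskSchedule:
    """Generate a two-run schedule satisfying all placement constraints.

    Deterministic: identical ``(config, seed)`` yields an identical schedule.
    """
    cfg = config or ScheduleConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    runs: list[list[TrialSpec]] = []
    durations: list[float] = []
    for run_index in (1, 2):
        if run_index == 1:
            counts = {c: cfg.run1_normal_per_condition for c in CONDITIONS}
            catch_counts = {c: 0 for c in CONDITIONS}
        else:
            counts = {
                c: cfg.run2_normal_per_condition + cfg.run2_catch_per_condition
                for c in CONDITIONS
            }
            catch_counts = {c: cfg.run2_catch_per_condition for c in CONDITIONS}
        order = _condition_order(rng, counts, cfg.max_consecutive_same_condition)
        if any(catch_counts.values()):
            flags = _assign_catches(
                rng, order, catch_counts, cfg.catch_fraction, cfg.spacing_across_types
            )
        else:
            flags = [False] * len(order)

        trials: list[TrialSpec] = []
        t = cfg.initial_rest
        for idx, (cond, catch) in enumerate(zip(order, flags)):
            lo, hi = cfg.catch_delay_range if catch else cfg.normal_delay_range
            delay = _grid_choice(rng, lo, hi, cfg.delay_grid)
            trial = TrialSpec(
                run_index=run_index,
                trial_index=idx,
                condition=cond,
                is_catch=catch,
                cue_onset=t,
                cue_outcome_delay=delay,
                cue_duration=cfg.cue_duration,
                outcome_duration=cfg.outcome_duration,
                juice_shift=cfg.juice_shift,
            )
            trials.append(trial)
            iti = _grid_choice(rng, cfg.iti_range[0], cfg.iti_range[1], cfg.delay_grid)
            t = trial.trial_end + iti
        runs.append(trials)
        durations.append(trials[-1].trial_end + cfg.final_rest if trials else 0.0)

    return TaskSchedule(
        subject_id=subject_id,
        runs=runs,
        run_durations=durations,
        seed=int(seed),
        config=cfg,
    )


def validate_schedule(
    schedule: TaskSchedule, config: ScheduleConfig | None = None
) -> list[str]:
    """Return a list of human-readable constraint violations (empty if valid)."""
    cfg = config or schedule.config
    report: list[str] = []
    for run_i, run in enumerate(schedule.runs, start=1):
        n = len(run)
        if run_i == 1:
            expect = {c: (cfg.run1_normal_per_condition, 0) for c in CONDITIONS}
        else:
            expect = {
                c: (cfg.run2_normal_per_condition, cfg.run2_catch_per_condition)
                for c in CONDITIONS
            }
        for cond in CONDITIONS:
            n_norm = sum(
                1 for t in run if t.condition == cond and not t.is_catch
            )
            n_catch = sum(1 for t in run if t.condition == cond and t.is_catch)
            if (n_norm, n_catch) != expect[cond]:
                report.append(
                    f"run {run_i}: condition {cond} has {n_norm} normal / "
                    f"{n_catch} catch trials, expected {expect[cond]}"
                )
        first_ok = int(np.floor((1.0 - cfg.catch_fraction) * n))
        prev_end = -np.inf
        last_catch_pos: dict[str, int] = {}
        for t in run:
            if t.run_index != run_i:
                report.append(f"trial {t.trial_index}: wrong run_index")
            lo, hi = (
                cfg.catch_delay_range if t.is_catch else cfg.normal_delay_range
            )
            if not (lo <= t.cue_outcome_delay <= hi):
                report.append(
                    f"run {run_i} trial {t.trial_index}: delay "
                    f"{t.cue_outcome_delay} outside [{lo}, {hi}]"
                )
            if t.is_catch and run_i == 1:
                report.append(
                    f"run 1 trial {t.trial_index}: catch trials not allowed in run 1"
                )
            if t.is_catch and t.trial_index < first_ok:
                report.append(
                    f"run {run_i} trial {t.trial_index}: catch trial before "
                    f"position {first_ok} violates latter-"
                    f"{cfg.catch_fraction:.0%} rule"
                )
            if t.cue_onset <= prev_end:
                report.append(
                    f"run {run_i} trial {t.trial_index}: overlaps previous trial"
                )
            prev_end = t.trial_end
            if t.is_catch:
                if t.condition in last_catch_pos:
                    prev_pos = last_catch_pos[t.condition]
                    n_between = sum(
                        1
                        for u in run[prev_pos + 1 : t.trial_index]
                        if u.condition == t.condition and not u.is_catch
                    )
                    if n_between < 1:
                        report.append(
                            f"run {run_i} trial {t.trial_index}: catch trial of "
                            f"type {t.condition} not preceded by a normal trial "
                            f"of that type since trial {prev_pos} (spacing rule)"
                        )
                last_catch_pos[t.condition] = t.trial_index
    return report


def schedule_to_events(schedule: TaskSchedule) -> pd.DataFrame:
    """Expand a schedule into the five-class event table.

    Normal trials yield cue, expected_outcome and expected_absence rows;
    catch trials yield cue, unexpected_absence and unexpected_outcome rows.
    The juice outcome shift (default 0.5 s) is already folded into onsets.
    """
    violations = validate_schedule(schedule)
    if violations:
        raise ValueError(
            "invalid schedule:\n" + "\n".join(violations)
        )
    rows = []

    def add(t: TrialSpec, event_class: str, onset: float, duration: float):
        rows.append(
            {
                "onset": round(onset, 6),
                "duration": duration,
                "trial_type": f"{event_class}_{t.condition}",
                "event_class": event_class,
                "condition": t.condition,
                "run_index": t.run_index,
                "trial_index": t.trial_index,
                "modulator": np.nan,
            }
        )

    for t in schedule.trials():
        add(t, "cue", t.cue_onset, t.cue_duration)
        if t.is_catch:
            add(
                t,
                "unexpected_absence",
                t.cue_offset + UNEXPECTED_ABSENCE_LAG + t.shift,
                1.0,
            )
            add(t, "unexpected_outcome", t.outcome_onset, t.outcome_duration)
        else:
            add(t, "expected_outcome", t.outcome_onset, t.outcome_duration)
            add(
                t,
                "expected_absence",
                t.outcome_onset + EXPECTED_ABSENCE_LAG,
                1.0,
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["run_index", "onset"], kind="stable").reset_index(
        drop=True
    )


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])
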
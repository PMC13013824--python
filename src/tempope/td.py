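"""Temporal-difference learning over the task timeline.

Each condition (juice / visual) is modeled by an independent TD(0) learner
with a complete-serial-compound (tapped delay line) stimulus representation:
one indicator feature per post-cue time bin up to a fixed horizon.  The
learner predicts, for every time bin within a trial, the total discounted
future reward to the end of the trial; the prediction error

    delta(t) = r(t) + gamma * V(t) - V(t - 1)

(the TD error of the transition into bin ``t``) drives the weight update
``w[x(t-1)] += alpha * delta``.  After the typical cue-outcome delay is
learned, outcome delivery at the expected time generates no PE, delivery at
an unexpected (late) time generates a positive PE, and outcome absence at
the expected time generates a negative PE — the signals sampled as
parametric modulators in the model-based first-level analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .task import TaskSchedule

#: event classes at which PEs are sampled as modulators
SAMPLED_CLASSES = (
    "cue",
    "expected_outcome",
    "unexpected_outcome",
    "unexpected_absence",
)


@dataclass
class TDParams:
    """Learning-rule and state-representation parameters.

    alpha : learning rate in (0, 1]
    gamma : per-bin temporal discount in (0, 1]
    dt : time-bin width (s)
    horizon : post-cue extent of the tapped delay line (s); must cover the
        longest cue-to-outcome span (catch delay + outcome duration)
    reward_magnitude : reward delivered at each outcome onset (a.u.)
    """

    alpha: float = 0.2
    gamma: float = 0.95
    dt: float = 0.5
    horizon: float = 12.0
    reward_magnitude: float = 1.0

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")


@dataclass
class TDTrace:
    """Time-binned value and prediction-error traces for one condition."""

    condition: str
    dt: float
    time_bins: np.ndarray
    value: np.ndarray
    pe: np.ndarray
    weights_final: np.ndarray
    run_offsets: list[float] = field(default_factory=list)

    def bin_of(self, run_index: int, onset: float) -> int:
        """Bin containing an event onset (floor convention)."""
        t = self.run_offsets[run_index - 1] + onset
        b = int(np.floor(t / self.dt))
        if not (0 <= b < len(self.pe)):
            raise ValueError(
                f"event time {onset:.2f} s (run {run_index}) outside trace support"
            )
        return b


class TemporalDifferenceModel(BaseEstimator):
    """TD(0) learner with a complete-serial-compound representation.

    Parameters mirror :class:`TDParams`.  ``carry_across_runs`` keeps the
    learned value weights across the run boundary (learning in run 1 sets up
    the run-2 temporal expectations that the catch trials violate).
    """

    def __init__(
        self,
        alpha: float = 0.2,
        gamma: float = 0.95,
        dt: float = 0.5,
        horizon: float = 12.0,
        reward_magnitude: float = 1.0,
        carry_across_runs: bool = True,
    ):
        self.alpha = alpha
        self.gamma = gamma
        self.dt = dt
        self.horizon = horizon
        self.reward_magnitude = reward_magnitude
        self.carry_across_runs = carry_across_runs

    # ------------------------------------------------------------------
    def _params(self) -> TDParams:
        p = TDParams(
            alpha=self.alpha,
            gamma=self.gamma,
            dt=self.dt,
            horizon=self.horizon,
            reward_magnitude=self.reward_magnitude,
        )
        p.validate()
        return p

    def fit(self, schedule: TaskSchedule, condition: str = "juice"):
        """Simulate learning over the full (concatenated-run) timeline."""
        params = self._params()
        cfg = schedule.config
        # the delay line must reach the latest possible reward bin
        max_span = (
            cfg.cue_duration
            + cfg.catch_delay_range[1]
            + cfg.juice_shift
            + params.dt
        )
        if params.horizon < max_span:
            raise ValueError(
                f"horizon {params.horizon} s shorter than the longest "
                f"cue-to-outcome span ({max_span} s)"
            )
        dt = params.dt
        run_offsets = [0.0]
        for d in schedule.run_durations[:-1]:
            run_offsets.append(run_offsets[-1] + d)
        total = run_offsets[-1] + schedule.run_durations[-1]
        n = int(np.ceil(total / dt)) + 1
        n_taps = int(np.round(params.horizon / dt))

        # active tap per bin (-1 = no cue feature); later cues reset the line
        active = np.full(n, -1, dtype=np.int64)
        reward = np.zeros(n)
        run_start_bins = [int(np.floor(o / dt)) for o in run_offsets]
        for t in schedule.trials(condition):
            off = run_offsets[t.run_index - 1]
            c0 = int(np.floor((off + t.cue_onset) / dt))
            j_hi = min(n_taps, n - c0)
            active[c0 : c0 + j_hi] = np.arange(j_hi)
            rb = int(np.floor((off + t.outcome_onset) / dt))
            if rb < n:
                reward[rb] += params.reward_magnitude

        w = np.zeros(n_taps)
        value = np.zeros(n)
        pe = np.zeros(n)
        v_prev = 0.0
        reset_bins = set(run_start_bins[1:]) if not self.carry_across_runs else set()
        for t in range(n):
            if t in reset_bins:
                w[:] = 0.0
                v_prev = 0.0
            v_t = w[active[t]] if active[t] >= 0 else 0.0
            delta = reward[t] + params.gamma * v_t - v_prev
            pe[t] = delta
            # each cue onset starts a new episode: the transition into it
            # produces the (positive) cue-arrival PE but does not credit the
            # pre-cue state, so value never bootstraps across trials
            if t > 0 and active[t - 1] >= 0 and active[t] != 0:
                w[active[t - 1]] += params.alpha * delta
            value[t] = w[active[t]] if active[t] >= 0 else 0.0
            v_prev = value[t]

        self.condition_ = condition
        self.trace_ = TDTrace(
            condition=condition,
            dt=dt,
            time_bins=np.arange(n) * dt,
            value=value,
            pe=pe,
            weights_final=w.copy(),
            run_offsets=run_offsets,
        )
        return self

    def sample(self, events: pd.DataFrame) -> pd.DataFrame:
        """Sample the PE trace at the modeled event onsets of this condition."""
        return sample_pes(self.trace_, events)


def simulate_td(
    schedule: TaskSchedule, condition: str, params: TDParams | None = None
) -> TDTrace:
    """Functional wrapper around :class:`TemporalDifferenceModel`."""
    p = params or TDParams()
    model = TemporalDifferenceModel(
        alpha=p.alpha,
        gamma=p.gamma,
        dt=p.dt,
        horizon=p.horizon,
        reward_magnitude=p.reward_magnitude,
    )
    return model.fit(schedule, condition).trace_


def trace_to_frame(trace: TDTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {"time": trace.time_bins, "value": trace.value, "pe": trace.pe}
    )


def write_trace_tsv(trace: TDTrace, path) -> None:
    trace_to_frame(trace).to_csv(path, sep="\t", index=False)


def plot_trace(trace: TDTrace, path=None):
    """Value/PE time-course plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(10, 4))
    ax1.plot(trace.time_bins, trace.value, lw=0.5)
    ax1.set_ylabel("V(t)")
    ax2.plot(trace.time_bins, trace.pe, lw=0.5, color="C3")
    ax2.set_ylabel("delta(t)")
    ax2.set_xlabel("time (s)")
    fig.suptitle(f"TD trace ({trace.condition})")
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig


def sample_pes(trace: TDTrace, events: pd.DataFrame) -> pd.DataFrame:
    """PE samples at cue onsets, outcome deliveries and unexpected absences.

    Returns one row per modeled event of the trace's condition with columns
    (event_class, condition, run_index, trial_index, time, pe_value).
    """
    sel = events[
        (events["condition"] == trace.condition)
        & (events["event_class"].isin(SAMPLED_CLASSES))
    ].reset_index(drop=True)
    offsets = np.array(
        [trace.run_offsets[r - 1] for r in sel["run_index"].astype(int)]
    )
    bins = np.floor((offsets + sel["onset"].to_numpy()) / trace.dt).astype(int)
    if bins.size and (bins.min() < 0 or bins.max() >= len(trace.pe)):
        bad = sel.iloc[int(np.argmax((bins < 0) | (bins >= len(trace.pe))))]
        raise ValueError(
            f"event time {bad['onset']:.2f} s (run {int(bad['run_index'])}) "
            "outside trace support"
        )
    return pd.DataFrame(
        {
            "event_class": sel["event_class"],
            "condition": sel["condition"],
            "run_index": sel["run_index"].astype(int),
            "trial_index": sel["trial_index"].astype(int),
            "time": sel["onset"].astype(float),
            "pe_value": trace.pe[bins],
        }
    )
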
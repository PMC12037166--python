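"""Forward simulation of multi-session ROI BOLD data with known ground truth.

The generator emulates a block-design visuomotor experiment: four task
sessions in which 12 s task blocks alternate with 12 s replay-observation
blocks, plus a 6 min resting-state run before and after training.  Each
condition evokes a fixed multivoxel pattern whose time course is the block
boxcar convolved with a canonical double-gamma HRF.  Rest runs are AR(1)
noise plus slow drift, into which task-pattern "reactivation" events can
be planted at known onsets.  Behavioral tracking error is generated from a
linear-Gaussian model coupled to the planted reactivation increase, so the
full cohort has a known reactivation-behavior correlation.

Design constants (TR 3 s, 174/122 scans per task/rest run, 3 discarded
volumes, 10 blocks per condition, 12 s blocks) are the defaults of
:class:`SimConfig`; every stochastic draw is a pure function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .core import (
    REPLAY,
    TASK,
    BlockEvents,
    ConfigurationError,
    RoiTimeSeries,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticSubject",
    "canonical_hrf",
    "condition_regressor",
    "make_block_events",
    "simulate_task_session",
    "simulate_rest_session",
    "simulate_behavior",
    "simulate_subject",
    "simulate_cohort",
    "window_overlap_fraction",
    "coupling_for_target_r",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """All parameters of the synthetic experiment.

    Defaults reproduce the emulated acquisition: TR 3 s, four task sessions
    of 174 scans with 10 task + 10 replay blocks of 12 s, two rest sessions
    of 122 scans (~6 min), first three scans of every run discarded.

    ``pattern_amplitude`` and ``noise_sd`` are in the same (percent-signal
    scale) per-voxel units; their ratio controls decodability.  Only a
    minority of the anatomical ROI carries condition information, as in
    real multivoxel data: each condition pattern is supported on a random
    ``responsive_fraction`` subset of voxels.  Patterns are stored with
    unit Euclidean norm and rescaled by ``sqrt(n_responsive)`` inside the
    forward model, so ``pattern_amplitude`` is the RMS activation of a
    responsive voxel regardless of ROI size.  ``behavior_coupling`` is in
    tracking-error units per percentage point of reactivation increase.

    The inter-block and initial fixation intervals are not part of the
    emulated acquisition protocol (only total scan counts are); the layout
    here (9 s initial fixation, 6 s gaps, trailing fixation) is an explicit
    assumption chosen so that all onsets fall on TR boundaries.
    """

    n_voxels: int = 200
    tr_s: float = 3.0
    n_task_sessions: int = 4
    blocks_per_condition: int = 10
    block_duration_s: float = 12.0
    inter_block_gap_s: float = 6.0
    initial_fixation_s: float = 9.0
    task_scans: int = 174
    rest_scans: int = 122
    discard_volumes: int = 3
    pattern_amplitude: float = 1.0
    responsive_fraction: float = 0.1
    pattern_correlation: float = 0.0
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 2.0
    drift_period_s: float = 300.0
    n_react_events_pre: int = 0
    n_react_events_post: int = 6
    react_event_duration_s: float = 12.0
    behavior_baseline_mean: float = 40.0
    behavior_baseline_sd: float = 5.0
    behavior_learning_step: float = 3.0
    behavior_session4_decrement: float = 5.0
    behavior_coupling: float = 0.5
    behavior_noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming any violated constraint."""
        if self.n_voxels < 1:
            raise ConfigurationError("n_voxels must be >= 1")
        if self.tr_s <= 0:
            raise ConfigurationError("tr_s must be positive")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ConfigurationError("ar1_coef must lie in [0, 1)")
        if not (0.0 < self.responsive_fraction <= 1.0):
            raise ConfigurationError("responsive_fraction must lie in (0, 1]")
        if self.discard_volumes >= min(self.task_scans, self.rest_scans):
            raise ConfigurationError("discard_volumes must be smaller than every run")
        needed = self.blocks_per_condition * 2 * (
            self.block_duration_s + self.inter_block_gap_s
        )
        if self.task_scans * self.tr_s < needed:
            raise ConfigurationError(
                f"design overflow: task run of {self.task_scans * self.tr_s:.0f} s "
                f"cannot hold {self.blocks_per_condition} blocks/condition "
                f"({needed:.0f} s required)"
            )
        for name in ("block_duration_s", "inter_block_gap_s", "initial_fixation_s"):
            value = getattr(self, name)
            if abs(value / self.tr_s - round(value / self.tr_s)) > 1e-9:
                raise ConfigurationError(f"{name}={value} is not a multiple of tr_s")

    @property
    def n_responsive(self) -> int:
        """Voxels per condition pattern support (at least 1)."""
        return max(1, int(round(self.responsive_fraction * self.n_voxels)))

    @property
    def block_len_volumes(self) -> int:
        return int(round(self.block_duration_s / self.tr_s))

    @property
    def event_len_volumes(self) -> int:
        return int(round(self.react_event_duration_s / self.tr_s))

    @property
    def retained_rest_volumes(self) -> int:
        return self.rest_scans - self.discard_volumes


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for parameter-recovery checks.

    ``rest_event_onsets`` are volume indices in *post-discard* (retained)
    indexing.  ``true_reactivation_fraction`` is the fraction of length-4
    step-1 sliding windows of the retained rest run that overlap any planted
    event, computed by window enumeration.
    """

    pattern_task: np.ndarray
    pattern_replay: np.ndarray
    pattern_correlation: float
    rest_event_onsets: dict = field(default_factory=dict)
    true_reactivation_fraction: dict = field(default_factory=dict)
    true_behavior_improvement: float = 0.0


@dataclass(frozen=True)
class SyntheticSubject:
    """One simulated participant: task runs + events, both rests, behavior."""

    subject_id: str
    group: str
    task_sessions: tuple  # of (RoiTimeSeries, BlockEvents)
    rest_pre: RoiTimeSeries
    rest_post: RoiTimeSeries
    behavior: np.ndarray  # tracking error per task session, all positive
    truth: GroundTruth


# ---------------------------------------------------------------------------
# HRF and block layout


def canonical_hrf(
    tr_s: float,
    *,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    peak_dispersion_s: float = 1.0,
    undershoot_dispersion_s: float = 1.0,
    peak_undershoot_ratio: float = 6.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel, sampled at the TR.

    Difference of two gamma densities in the standard (SPM-convention)
    parameterization: response delay 6 s, undershoot delay 16 s, unit
    dispersions, peak:undershoot ratio 6, 32 s support.  The sampled kernel
    is rescaled so its maximum is exactly 1.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    n = int(math.floor(length_s / tr_s)) + 1
    t = np.arange(n) * tr_s
    peak = _stats.gamma.pdf(t, peak_delay_s / peak_dispersion_s, scale=peak_dispersion_s)
    under = _stats.gamma.pdf(
        t, undershoot_delay_s / undershoot_dispersion_s, scale=undershoot_dispersion_s
    )
    h = peak - under / peak_undershoot_ratio
    return h / h.max()


def make_block_events(
    config: SimConfig, session_index: int = 0, seed: int | None = None
) -> BlockEvents:
    """Alternating task/replay block table for one task session.

    Layout: ``initial_fixation_s`` of fixation, then task and replay blocks
    of ``block_duration_s`` alternating, separated by ``inter_block_gap_s``
    of fixation, remainder of the run as trailing fixation.  All onsets are
    integer multiples of the TR.  The layout is deterministic; ``seed`` is
    accepted for signature uniformity and ignored.
    """
    config.validate()
    period = config.block_duration_s + config.inter_block_gap_s
    onsets, conditions = [], []
    for k in range(config.blocks_per_condition):
        task_onset = config.initial_fixation_s + 2 * k * period
        onsets.extend([task_onset, task_onset + period])
        conditions.extend([TASK, REPLAY])
    end_s = onsets[-1] + config.block_duration_s
    run_s = config.task_scans * config.tr_s
    if end_s > run_s:
        raise ConfigurationError(
            f"design overflow: last block ends at {end_s:.0f} s but the run "
            f"is only {run_s:.0f} s (task_scans={config.task_scans})"
        )
    durations = np.full(len(onsets), config.block_duration_s)
    return BlockEvents(
        np.array(onsets), durations, tuple(conditions), session_id=f"task-{session_index + 1}"
    )


def condition_regressor(
    events: BlockEvents, condition: str, n_volumes: int, tr_s: float
) -> np.ndarray:
    """HRF-convolved boxcar for one condition, sampled at the TR.

    The boxcar covers volumes whose acquisition time falls inside a block
    (onset inclusive, offset exclusive); convolution is truncated to the run.
    """
    box = np.zeros(n_volumes)
    for onset, duration, cond in events:
        if cond != condition:
            continue
        start = int(round(onset / tr_s))
        stop = int(round((onset + duration) / tr_s))
        box[start : min(stop, n_volumes)] = 1.0
    return np.convolve(box, canonical_hrf(tr_s))[:n_volumes]


# ---------------------------------------------------------------------------
# noise, patterns, sessions


def _ar1_noise(rng: np.random.Generator, n_volumes: int, n_voxels: int,
               coef: float, innovation_sd: float) -> np.ndarray:
    """Independent per-voxel AR(1) series, zero-initialized."""
    eps = rng.normal(0.0, innovation_sd, size=(n_volumes, n_voxels))
    if coef == 0.0:
        return eps
    return _signal.lfilter([1.0], [1.0, -coef], eps, axis=0)


def _drift(config: SimConfig, n_volumes: int) -> np.ndarray:
    """Shared slow drift: cosine of the configured period plus a linear trend.

    The linear component ramps over +/- half the drift amplitude across the
    run so that ``drift_amplitude = 0`` silences both terms.
    """
    t = np.arange(n_volumes) * config.tr_s
    cos = config.drift_amplitude * np.cos(2 * np.pi * t / config.drift_period_s)
    if n_volumes > 1:
        lin = config.drift_amplitude * (t / t[-1] - 0.5)
    else:
        lin = np.zeros(1)
    return cos + lin


def make_patterns(config: SimConfig, rng: np.random.Generator) -> tuple:
    """Unit-norm sparse task and replay patterns with controlled correlation.

    Each condition pattern has Gaussian weights on an independent random
    subset of ``n_responsive`` voxels (the condition-informative minority
    of the ROI) and zeros elsewhere.  The replay pattern is Gram-Schmidt
    orthogonalized against the task pattern and then mixed back to reach
    ``pattern_correlation`` (default 0: fully orthogonal, so decodability
    is controlled by the amplitude/noise ratio alone).
    """
    V, k = config.n_voxels, config.n_responsive

    def sparse_draw() -> np.ndarray:
        p = np.zeros(V)
        support = rng.choice(V, size=k, replace=False)
        p[support] = rng.normal(size=k)
        return p / np.linalg.norm(p)

    p_task = sparse_draw()
    raw = sparse_draw()
    orth = raw - (raw @ p_task) * p_task
    orth /= np.linalg.norm(orth)
    r = config.pattern_correlation
    p_replay = r * p_task + math.sqrt(1.0 - r**2) * orth
    return p_task, p_replay


def _pattern_scale(config: SimConfig) -> float:
    """Forward-model pattern scale: ``pattern_amplitude * sqrt(n_responsive)``.

    Patterns are stored with unit Euclidean norm over their responsive
    support, so a responsive voxel's RMS weight is ``1/sqrt(n_responsive)``;
    multiplying by ``sqrt(n_responsive)`` makes ``pattern_amplitude`` the
    RMS activation of a responsive voxel in percent-signal units, directly
    comparable to ``noise_sd`` and independent of the ROI size.
    """
    return config.pattern_amplitude * math.sqrt(config.n_responsive)


def simulate_task_session(
    config: SimConfig, truth: GroundTruth, events: BlockEvents, seed
) -> RoiTimeSeries:
    """One task run: pattern x HRF-convolved boxcars + AR(1) noise + drift."""
    rng = np.random.default_rng(seed)
    T = config.task_scans
    reg_task = condition_regressor(events, TASK, T, config.tr_s)
    reg_replay = condition_regressor(events, REPLAY, T, config.tr_s)
    clean = _pattern_scale(config) * (
        np.outer(reg_task, truth.pattern_task)
        + np.outer(reg_replay, truth.pattern_replay)
    )
    noise = _ar1_noise(rng, T, config.n_voxels, config.ar1_coef, config.noise_sd)
    data = clean + noise + _drift(config, T)[:, None]
    return RoiTimeSeries(data, config.tr_s, session_id=events.session_id)


def _draw_nonoverlapping_onsets(
    rng: np.random.Generator, n_events: int, n_retained: int, event_len: int
) -> np.ndarray:
    """Uniform draw of sorted, non-overlapping event onsets (retained indices).

    Uses the standard bijection between non-overlapping placements and
    combinations: pick ``n`` distinct auxiliary positions, then re-inflate
    by ``event_len - 1`` per preceding event.  Exact-uniform over all
    feasible onset sets.
    """
    if n_events == 0:
        return np.array([], dtype=int)
    m = n_retained - event_len - (n_events - 1) * (event_len - 1)
    if m + 1 < n_events:
        raise ConfigurationError(
            f"cannot place {n_events} non-overlapping {event_len}-volume events "
            f"in {n_retained} retained volumes"
        )
    z = np.sort(rng.choice(m + 1, size=n_events, replace=False))
    return z + np.arange(n_events) * (event_len - 1)


def simulate_rest_session(
    config: SimConfig, truth: GroundTruth, n_events: int, seed, session_id: str = "rest"
) -> tuple:
    """One rest run with ``n_events`` planted task-pattern reactivations.

    Baseline is AR(1) noise plus drift.  Each event adds the task pattern
    modulated by an HRF-convolved 12 s boxcar (the same forward model as
    the task blocks, so planted events look hemodynamically realistic to
    the decoder).  Returns ``(series, onsets)`` with onsets as retained
    (post-discard) volume indices.
    """
    rng = np.random.default_rng(seed)
    config.validate()
    T = config.rest_scans
    L = config.event_len_volumes
    n_ret = config.retained_rest_volumes
    if n_events * L > n_ret:
        raise ConfigurationError(
            f"{n_events} events of {L} volumes exceed the {n_ret} retained rest volumes"
        )
    onsets = _draw_nonoverlapping_onsets(rng, n_events, n_ret, L)
    box = np.zeros(T)
    for o in onsets:
        start = config.discard_volumes + o
        box[start : start + L] = 1.0
    reg = np.convolve(box, canonical_hrf(config.tr_s))[:T]
    data = (
        _ar1_noise(rng, T, config.n_voxels, config.ar1_coef, config.noise_sd)
        + _drift(config, T)[:, None]
        + _pattern_scale(config) * np.outer(reg, truth.pattern_task)
    )
    return RoiTimeSeries(data, config.tr_s, session_id=session_id), onsets


def window_overlap_fraction(
    onsets, event_len: int, n_volumes: int, window_len: int = 4, step: int = 1
) -> float:
    """Fraction of sliding windows that overlap any planted event.

    Windows start at ``0, step, 2*step, ...`` over ``n_volumes`` retained
    volumes; a window overlaps an event iff their volume ranges intersect.
    """
    starts = np.arange(0, n_volumes - window_len + 1, step)
    if starts.size == 0:
        return 0.0
    hit = np.zeros(starts.size, dtype=bool)
    for o in np.asarray(onsets, dtype=int):
        hit |= (starts <= o + event_len - 1) & (starts + window_len - 1 >= o)
    return float(hit.mean())


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(
    config: SimConfig, true_fraction_increase_pp: float, seed
) -> np.ndarray:
    """Per-session tracking errors for one subject (4 values, positive).

    Sessions 1-3 scatter around a subject-specific baseline with a fixed
    learning decrement (session 1 worst, session 3 best); session 4 equals
    the baseline minus a fixed offline decrement minus
    ``behavior_coupling * true_fraction_increase_pp``, plus Gaussian noise.
    With zero noise and unit coupling, improvement (mean of sessions 1-3
    minus session 4) exceeds the fixed decrement by exactly the planted
    reactivation increase.
    """
    rng = np.random.default_rng(seed)
    baseline = rng.normal(config.behavior_baseline_mean, config.behavior_baseline_sd)
    sessions = np.empty(4)
    for s in (1, 2, 3):
        sessions[s - 1] = (
            baseline
            + config.behavior_learning_step * (2 - s)
            + rng.normal(0.0, config.behavior_noise_sd)
        )
    sessions[3] = (
        baseline
        - config.behavior_session4_decrement
        - config.behavior_coupling * true_fraction_increase_pp
        + rng.normal(0.0, config.behavior_noise_sd)
    )
    return np.maximum(sessions, 1e-3)


def coupling_for_target_r(
    target_r: float, fraction_increase_sd_pp: float, behavior_noise_sd: float
) -> float:
    """Coupling slope giving a population reactivation-improvement correlation.

    Improvement = const + c * df + (mean noise of sessions 1-3) - noise_4,
    whose noise variance is (4/3) * behavior_noise_sd**2, hence
    ``R = c * sd(df) / sqrt(c**2 sd(df)**2 + (4/3) noise**2)`` solved for c.
    """
    if not (0.0 < abs(target_r) < 1.0):
        raise ValueError("target_r must lie strictly between -1 and 1 (nonzero)")
    return (
        math.sqrt(4.0 / 3.0)
        * behavior_noise_sd
        * target_r
        / (fraction_increase_sd_pp * math.sqrt(1.0 - target_r**2))
    )


# ---------------------------------------------------------------------------
# subjects and cohorts


def simulate_subject(config: SimConfig, subject_id: str, seed, group: str = "right-hand") -> SyntheticSubject:
    """One full subject: patterns, task runs, both rests, behavior, truth.

    All randomness is derived from ``seed`` via a spawned seed sequence so
    that subjects are bit-reproducible and mutually independent.
    """
    config.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(config.n_task_sessions + 4)
    p_task, p_replay = make_patterns(config, np.random.default_rng(children[0]))
    truth = GroundTruth(p_task, p_replay, config.pattern_correlation)

    task_sessions = []
    for s in range(config.n_task_sessions):
        events = make_block_events(config, session_index=s)
        series = simulate_task_session(config, truth, events, children[1 + s])
        task_sessions.append((series.with_(subject_id=subject_id), events))

    n = config.n_task_sessions
    onsets, fractions = {}, {}
    rests = {}
    for key, n_events, child in (
        ("pre", config.n_react_events_pre, children[n + 1]),
        ("post", config.n_react_events_post, children[n + 2]),
    ):
        series, ons = simulate_rest_session(
            config, truth, n_events, child, session_id=f"rest-{key}"
        )
        rests[key] = series.with_(subject_id=subject_id)
        onsets[key] = ons
        fractions[key] = window_overlap_fraction(
            ons,
            config.event_len_volumes,
            config.retained_rest_volumes,
            window_len=config.block_len_volumes,
        )

    df_pp = 100.0 * (fractions["post"] - fractions["pre"])
    behavior = simulate_behavior(config, df_pp, children[n + 3])
    truth = replace(
        truth,
        rest_event_onsets=onsets,
        true_reactivation_fraction=fractions,
        true_behavior_improvement=config.behavior_session4_decrement
        + config.behavior_coupling * df_pp,
    )
    return SyntheticSubject(
        subject_id=subject_id,
        group=group,
        task_sessions=tuple(task_sessions),
        rest_pre=rests["pre"],
        rest_post=rests["post"],
        behavior=behavior,
        truth=truth,
    )


def simulate_cohort(
    config: SimConfig,
    n_subjects: int,
    react_rate_post: int | None = None,
    seed: int = 0,
) -> list:
    """Independent subjects with alternating group labels.

    ``react_rate_post`` overrides ``config.n_react_events_post`` for the
    whole cohort.  Per-subject seeds are spawned deterministically from the
    master seed.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if react_rate_post is not None:
        config = replace(config, n_react_events_post=react_rate_post)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    groups = ("right-hand", "left-hand")
    return [
        simulate_subject(config, f"sub-{i + 1:02d}", children[i], group=groups[i % 2])
        for i in range(n_subjects)
    ]
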
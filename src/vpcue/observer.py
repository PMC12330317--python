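"""Generative observer model and cohort simulator.

The observer forms noisy unimodal estimates of target position — visual with
SD ``sigma_v``, proprioceptive with SD ``sigma_p`` — and combines them on
bimodal (VP) trials with a fixed visual weight ``w_v`` that, by default, is
the minimum-variance weight sigma_p^2 / (sigma_p^2 + sigma_v^2).  Reporting
with the indicator hand adds isotropic motor noise ``sigma_m``.

When the two cues conflict, each unimodal map recalibrates a little on every
VP trial, in proportion to the *perceived* conflict and inversely to its own
weight: the proprioceptive bias moves by ``eta * w_v`` of the conflict and
the visual bias by ``eta * (1 - w_v)``, so the less-trusted modality
recalibrates more.  Signs are chosen so that positive accumulated biases
produce overshoot of P targets and undershoot of V targets, the behavioural
signature of recalibration toward the displaced cue.

The cohort simulator layers participant heterogeneity, group-level cTBS
effects (Expt. 2), and synthetic SAI neurophysiology whose post/pre change is
linearly coupled to the participant's measured proprioceptive recalibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import estimators
from .sai import DEFAULT_RATE_HZ, MepTrace
from .schedule import BlockSchedule, ScheduleError, TrialSpec, session_blocks

EXPERIMENTS = ("expt1", "expt2", "control")

#: Groove widths (mm) of the grating-orientation test dome set.
GOT_DOME_SET = (0.35, 0.5, 0.75, 1.0, 1.2, 1.5, 2.0, 3.0, 4.0, 5.0)
GOT_START_WIDTH = 3.0


class ObserverError(ValueError):
    """Raised for invalid observer or cohort configuration."""


# ---------------------------------------------------------------------------
# Observer parameters and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverParams:
    """Sensory, motor, and recalibration parameters of one observer.

    Units: all SDs in mm (per axis, isotropic); ``eta`` and ``w_v`` unitless.
    Defaults are anchored so that simulated 2D endpoint variances fall in the
    50-92 mm^2 range typical of this task, with ``sigma_m = sigma_p``
    encoding the convention that the indicator hand contributes half of the
    P-trial endpoint variance.
    """

    sigma_p: float = 8.0
    sigma_v: float = 10.0
    sigma_m: float = 8.0
    w_v: float | None = None  # derived minimum-variance weight when None
    eta: float = 0.08
    b_p0: tuple[float, float] = (0.0, 0.0)
    b_v0: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.sigma_p, self.sigma_v, self.sigma_m) < 0:
            raise ObserverError("noise SDs must be non-negative")
        if not 0.0 <= self.eta <= 1.0:
            raise ObserverError("eta must lie in [0, 1]")
        if self.w_v is not None and not 0.0 <= self.w_v <= 1.0:
            raise ObserverError("w_v must lie in [0, 1]")

    @property
    def visual_weight(self) -> float:
        """The effective visual weight (explicit, or minimum-variance)."""
        if self.w_v is not None:
            return self.w_v
        denom = self.sigma_p**2 + self.sigma_v**2
        return 0.5 if denom == 0 else self.sigma_p**2 / denom


@dataclass
class ObserverState:
    """Accumulated recalibration biases, updated only on VP trials."""

    b_p: np.ndarray
    b_v: np.ndarray

    @classmethod
    def from_params(cls, params: ObserverParams) -> "ObserverState":
        return cls(
            b_p=np.array(params.b_p0, dtype=float),
            b_v=np.array(params.b_v0, dtype=float),
        )


# ---------------------------------------------------------------------------
# Single trial and session simulation
# ---------------------------------------------------------------------------

def _trial_core(
    spec: TrialSpec,
    params: ObserverParams,
    b_p: np.ndarray,
    b_v: np.ndarray,
    eps_p: np.ndarray,
    eps_v: np.ndarray,
    eps_m: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Endpoint and updated biases for one trial given pre-drawn noise.

    The conflict that drives recalibration is measured relative to the
    observer's habitual cross-modal discrepancy (the baseline biases): a
    participant whose visual and proprioceptive maps have always disagreed
    by a constant offset does not experience that offset as a conflict, so
    veridical trials leave the biases stable apart from noise.
    """
    w = params.visual_weight
    baseline_gap = -(np.asarray(params.b_v0) + np.asarray(params.b_p0))
    if spec.target_type == "P":
        if spec.p_target is None:
            raise ScheduleError("P trial without a proprioceptive target")
        endpoint = np.asarray(spec.p_target) + b_p + eps_p + eps_m
    elif spec.target_type == "V":
        if spec.v_cue is None:
            raise ScheduleError("V trial without a visual cue")
        endpoint = np.asarray(spec.v_cue) - b_v + eps_v + eps_m
    elif spec.target_type == "VP":
        if spec.p_target is None or spec.v_cue is None:
            raise ScheduleError("VP trial requires both cues")
        est_v = np.asarray(spec.v_cue) - b_v + eps_v
        est_p = np.asarray(spec.p_target) + b_p + eps_p
        endpoint = w * est_v + (1.0 - w) * est_p + eps_m
        conflict = (est_v - est_p) - baseline_gap
        b_p = b_p + params.eta * w * conflict
        b_v = b_v + params.eta * (1.0 - w) * conflict
    else:  # pragma: no cover - TrialSpec validates
        raise ScheduleError(f"unknown target type {spec.target_type!r}")
    return endpoint, b_p, b_v


def simulate_trial(
    spec: TrialSpec,
    params: ObserverParams,
    state: ObserverState,
    rng: np.random.Generator,
) -> tuple[np.ndarray, ObserverState]:
    """Simulate one trial; returns the 2D endpoint and the updated state."""
    eps_p = rng.normal(0.0, params.sigma_p, 2)
    eps_v = rng.normal(0.0, params.sigma_v, 2)
    eps_m = rng.normal(0.0, params.sigma_m, 2)
    endpoint, b_p, b_v = _trial_core(
        spec, params, state.b_p, state.b_v, eps_p, eps_v, eps_m
    )
    return endpoint, ObserverState(b_p=b_p, b_v=b_v)


@dataclass
class SessionResult:
    """Simulated endpoints joined to their trial specs, plus ground truth."""

    trials: pd.DataFrame
    #: block label -> terminal accumulated biases relative to baseline,
    #: the generative ground truth for recalibration in that block.
    terminal_biases: dict[str, dict[str, np.ndarray]]


def simulate_session(
    schedules: list[BlockSchedule],
    params: ObserverParams,
    seed: int | np.random.Generator,
) -> SessionResult:
    """Run the observer over a session's blocks.

    The bias state starts from the observer's constant baseline biases at the
    beginning of every block and is carried trial to trial within a block, so
    each block's terminal bias (relative to baseline) is the generative
    ground truth for that block's recalibration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    terminal: dict[str, dict[str, np.ndarray]] = {}
    b_p0 = np.array(params.b_p0, dtype=float)
    b_v0 = np.array(params.b_v0, dtype=float)
    for block in schedules:
        n = len(block.trials)
        eps_p = rng.normal(0.0, params.sigma_p, (n, 2))
        eps_v = rng.normal(0.0, params.sigma_v, (n, 2))
        eps_m = rng.normal(0.0, params.sigma_m, (n, 2))
        b_p, b_v = b_p0.copy(), b_v0.copy()
        endpoints = np.empty((n, 2))
        for i, spec in enumerate(block.trials):
            endpoints[i], b_p, b_v = _trial_core(
                spec, params, b_p, b_v, eps_p[i], eps_v[i], eps_m[i]
            )
        frame = block.to_frame()
        frame["endpoint_x"] = endpoints[:, 0]
        frame["endpoint_y"] = endpoints[:, 1]
        frames.append(frame)
        label = block.trials[0].block_label
        terminal[label] = {"b_p": b_p - b_p0, "b_v": b_v - b_v0}
    return SessionResult(
        trials=pd.concat(frames, ignore_index=True), terminal_biases=terminal
    )


# ---------------------------------------------------------------------------
# Synthetic SAI neurophysiology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaiCoupling:
    """Linear coupling of the post/pre SAI change to recalibration.

    ``delta_sai = intercept + slope_p * recal_P + slope_v * recal_V + noise``
    (all in % units, recalibration in mm); the coupling is applied only in
    cue-conflict sessions — veridical sessions get intercept + noise.
    """

    intercept: float = 105.94
    slope_p: float = 1.80
    slope_v: float = 0.0
    noise_sd: float = 15.0
    sai_pre_mean: float = 55.0  # baseline inhibition, % of unconditioned
    sai_pre_sd: float = 8.0


def _mep_shape(n_samples: int, rate: float, onset_ms: float = 20.0) -> np.ndarray:
    """Unit damped-sinusoid MEP waveform starting ``onset_ms`` after TMS."""
    t = np.arange(n_samples) / rate * 1_000.0  # ms
    u = t - onset_ms
    shape = np.where(u >= 0, np.exp(-u / 12.0) * np.sin(2 * np.pi * u / 15.0), 0.0)
    return shape


@dataclass
class SaiSimResult:
    traces: list[MepTrace]
    target_delta_sai: float
    target_sai_pre: float
    target_sai_post: float


def simulate_sai(
    delta_yp: float,
    coupling: SaiCoupling,
    rng: np.random.Generator,
    *,
    delta_yv: float = 0.0,
    conflict: bool = True,
    n_cond: int = 20,
    n_uncond: int = 20,
    sai_pre: float | None = None,
    amplitude_jitter: float = 0.15,
    baseline_noise_mv: float = 0.005,
    rate: float = DEFAULT_RATE_HZ,
    duration_ms: float = 100.0,
) -> SaiSimResult:
    """Generate pre/post conditioned and unconditioned MEP traces.

    Unconditioned peak-to-peak amplitudes sit near 1 mV (the test-stimulus
    titration target).  Conditioned amplitudes at each timepoint are scaled
    so that the realised ratio-of-means SAI equals the target exactly before
    baseline EMG noise is added; with ``coupling.noise_sd`` and
    ``baseline_noise_mv`` both zero the quantification pipeline therefore
    recovers the generative delta-SAI to numerical precision.
    """
    if n_cond < 1 or n_uncond < 1:
        raise ObserverError("trace counts must be positive")
    if not all(map(math.isfinite, (coupling.intercept, coupling.slope_p,
                                   coupling.slope_v, coupling.noise_sd))):
        raise ObserverError("coupling parameters must be finite")
    target = coupling.intercept + rng.normal(0.0, coupling.noise_sd) if coupling.noise_sd else coupling.intercept
    if conflict:
        target += coupling.slope_p * delta_yp + coupling.slope_v * delta_yv
    if sai_pre is None:
        sai_pre = float(np.clip(
            rng.normal(coupling.sai_pre_mean, coupling.sai_pre_sd), 20.0, 95.0
        ))
    sai_post = sai_pre * target / 100.0
    n_samples = int(round(duration_ms / 1_000.0 * rate))
    shape = _mep_shape(n_samples, rate)
    shape_p2p = float(shape.max() - shape.min())

    traces: list[MepTrace] = []
    for timepoint, sai_pct in (("pre", sai_pre), ("post", sai_post)):
        sets = {}
        for condition, n, base_amp in (
            ("unconditioned", n_uncond, 1.0),
            ("conditioned", n_cond, sai_pct / 100.0),
        ):
            jitter = np.exp(rng.normal(0.0, amplitude_jitter, n)) if amplitude_jitter else np.ones(n)
            amps = base_amp * jitter
            sets[condition] = amps
        # rescale the conditioned set so the realised ratio of mean
        # peak-to-peak amplitudes hits the target exactly (p2p is linear in
        # amplitude for noiseless traces)
        ratio = sets["conditioned"].mean() / sets["unconditioned"].mean()
        sets["conditioned"] *= (sai_pct / 100.0) / ratio
        for condition, amps in sets.items():
            for a in amps:
                samples = a / shape_p2p * shape
                if baseline_noise_mv:
                    samples = samples + rng.normal(0.0, baseline_noise_mv, n_samples)
                traces.append(
                    MepTrace(samples=samples, rate=rate,
                             condition=condition, timepoint=timepoint)
                )
    return SaiSimResult(
        traces=traces,
        target_delta_sai=float(sai_post / sai_pre * 100.0),
        target_sai_pre=float(sai_pre),
        target_sai_post=float(sai_post),
    )


# ---------------------------------------------------------------------------
# Grating-orientation test (tactile acuity staircase)
# ---------------------------------------------------------------------------

def simulate_got(
    true_threshold: float,
    lapse: float = 0.02,
    seed: int | np.random.Generator = 0,
    dome_set: tuple[float, ...] = GOT_DOME_SET,
    start_width: float = GOT_START_WIDTH,
    spread: float | None = None,
    max_trials: int = 10_000,
) -> float:
    """Adaptive grating-orientation staircase; returns the observed threshold.

    Two-alternative orientation report: six consecutive correct responses at
    a width step down to the next smaller dome, any error steps up.  The
    probability of a correct report rises from chance (0.5) to ``1 - lapse``
    as the groove width exceeds ``true_threshold``.  The observed threshold
    is the smallest width passed; an observer who never passes any width is
    scored at the largest dome.
    """
    if len(dome_set) == 0:
        raise ObserverError("dome set must be non-empty")
    if not 0.0 <= lapse < 0.5:
        raise ObserverError("lapse must lie in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    widths = sorted(dome_set)
    from scipy.stats import norm

    s = spread if spread is not None else max(0.25 * true_threshold, 1e-9)

    def p_correct(width: float) -> float:
        return 0.5 + (0.5 - lapse) * norm.cdf((width - true_threshold) / s)

    idx = min(range(len(widths)), key=lambda i: abs(widths[i] - start_width))
    passed: set[int] = set()
    streak = 0
    for _ in range(max_trials):
        correct = rng.random() < p_correct(widths[idx])
        if correct:
            streak += 1
            if streak == 6:
                passed.add(idx)
                if idx == 0:
                    break
                idx -= 1
                streak = 0
        else:
            streak = 0
            if idx == len(widths) - 1 or (idx + 1) in passed:
                break
            idx += 1
    return widths[min(passed)] if passed else widths[-1]


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDistributions:
    """Population distributions the per-participant parameters are drawn from.

    Sensory SDs are lognormal around their medians with the given log-SD
    (coefficient of variation for small values); ``sigma_m`` is tied to
    ``sigma_p`` so the indicator hand contributes half of the P endpoint
    variance.  Baseline modality biases are the participant's idiosyncratic
    constant offsets when estimating V vs P targets.

    Each participant's visual weight starts from the minimum-variance value
    implied by their sigmas and receives independent spread ``w_v_sd``
    (weighting in this task also reflects attentional and strategic factors
    beyond the noise ratio).  Weighting spread trades proprioceptive against
    visual recalibration across participants while learning-rate spread
    (``eta_sd``) moves both together; the defaults let weighting dominate,
    reproducing the robust empirical inverse relation between visual and
    proprioceptive recalibration across a cohort.
    """

    sigma_p_median: float = 8.0
    sigma_v_median: float = 10.0
    sigma_log_sd: float = 0.2
    w_v_sd: float = 0.15
    eta_mean: float = 0.08
    eta_sd: float = 0.02
    eta_bounds: tuple[float, float] = (0.01, 0.30)
    bias_sd: float = 10.0

    def draw(self, rng: np.random.Generator) -> ObserverParams:
        sigma_p = float(np.exp(rng.normal(np.log(self.sigma_p_median), self.sigma_log_sd)))
        sigma_v = float(np.exp(rng.normal(np.log(self.sigma_v_median), self.sigma_log_sd)))
        eta = float(np.clip(rng.normal(self.eta_mean, self.eta_sd), *self.eta_bounds))
        params = ObserverParams(
            sigma_p=sigma_p,
            sigma_v=sigma_v,
            sigma_m=sigma_p,
            eta=eta,
            b_p0=tuple(rng.normal(0.0, self.bias_sd, 2)),
            b_v0=tuple(rng.normal(0.0, self.bias_sd, 2)),
        )
        # materialise the weight (minimum-variance value plus idiosyncratic
        # spread) so later sigma changes (e.g. cTBS) alter noise but not the
        # integration weight
        w_v = float(np.clip(
            params.visual_weight + rng.normal(0.0, self.w_v_sd), 0.05, 0.95
        ))
        return replace(params, w_v=w_v)


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative cTBS after-effects applied after the first block."""

    sigma_p_mult: float = 1.0
    eta_mult: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_p_mult <= 0 or self.eta_mult <= 0:
            raise ObserverError("group multipliers must be positive")

    def apply(self, params: ObserverParams) -> ObserverParams:
        return replace(
            params,
            sigma_p=params.sigma_p * self.sigma_p_mult,
            eta=min(1.0, params.eta * self.eta_mult),
        )


DEFAULT_GROUP_EFFECTS: dict[str, GroupEffect] = {
    "S1": GroupEffect(sigma_p_mult=1.3, eta_mult=1.4),
    "M1": GroupEffect(),
    "Sham": GroupEffect(),
}


@dataclass
class CohortConfig:
    """Design and generative settings for a simulated cohort."""

    experiment: str = "expt1"
    n_per_group: int = 22  # per group for expt2; total N otherwise
    group_effects: dict[str, GroupEffect] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    sai_coupling: SaiCoupling = field(default_factory=SaiCoupling)
    param_dist: ParamDistributions = field(default_factory=ParamDistributions)
    seed: int = 0
    emit_traces: bool = True

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ObserverError(f"unknown experiment {self.experiment!r}")
        if self.n_per_group < 1:
            raise ObserverError("n_per_group must be >= 1")
        for label in self.group_effects:
            if label not in DEFAULT_GROUP_EFFECTS:
                raise ObserverError(f"unknown group label {label!r}")


@dataclass
class CohortResult:
    """Cohort-level output: endpoint tables, ground truth, and MEP traces."""

    trials: pd.DataFrame
    truth: pd.DataFrame
    #: (participant, session) -> MEP traces; populated for expt1 only.
    traces: dict[tuple[int, str], list[MepTrace]]


def _participant_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _block_recal(trials: pd.DataFrame, label: str, total_shift: float) -> dict[str, float]:
    """Estimated recalibration (both modalities, x and y) for one block."""
    return estimators.block_recalibration(trials[trials.block == label], total_shift)


def simulate_cohort(config: CohortConfig) -> CohortResult:
    """Simulate a full cohort of the configured experiment.

    expt1: each participant completes a cue-conflict and a veridical session
    (baseline block + 84-trial second block each) with synthetic SAI
    measured pre/post in both.  expt2: three groups complete veridical 1,
    veridical 2, and a conflict block, with the group's cTBS effect applied
    after veridical 1.  control: a veridical training block followed by the
    84-trial V-only visual-shift block.
    """
    master = np.random.SeedSequence(config.seed)
    if config.experiment == "expt2":
        groups = [g for g in ("M1", "S1", "Sham") if g in config.group_effects]
        roster = [(i, g) for g in groups for i in range(config.n_per_group)]
    else:
        roster = [(i, "all") for i in range(config.n_per_group)]

    trial_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    traces: dict[tuple[int, str], list[MepTrace]] = {}

    for pid, (_, group) in enumerate(roster):
        pseq = master.spawn(1)[0]
        rng = np.random.default_rng(pseq)
        params = config.param_dist.draw(rng)

        if config.experiment == "expt1":
            for session, exp_name, shift in (
                ("conflict", "expt1", 70.0),
                ("veridical", "expt1_veridical", 0.0),
            ):
                blocks = session_blocks(exp_name, _participant_seed(pseq.spawn(1)[0]))
                res = simulate_session(blocks, params, rng)
                second = blocks[1].trials[0].block_label
                recal = _block_recal(res.trials, second, shift)
                sai = simulate_sai(
                    recal["recal_p_y"],
                    config.sai_coupling,
                    rng,
                    delta_yv=recal["recal_v_y"],
                    conflict=(session == "conflict"),
                )
                if config.emit_traces:
                    traces[(pid, session)] = sai.traces
                tb = res.terminal_biases[second]
                frame = res.trials.assign(participant=pid, group=group, session=session)
                trial_frames.append(frame)
                truth_rows.append(
                    {
                        "participant": pid,
                        "group": group,
                        "session": session,
                        "sigma_p": params.sigma_p,
                        "sigma_v": params.sigma_v,
                        "sigma_m": params.sigma_m,
                        "w_v": params.visual_weight,
                        "eta": params.eta,
                        "true_b_p_y": tb["b_p"][1],
                        "true_b_v_y": tb["b_v"][1],
                        **recal,
                        "target_delta_sai": sai.target_delta_sai,
                        "target_sai_pre": sai.target_sai_pre,
                    }
                )

        elif config.experiment == "expt2":
            if group not in config.group_effects:
                raise ObserverError(f"unknown group label {group!r}")
            post_params = config.group_effects[group].apply(params)
            blocks = session_blocks("expt2", _participant_seed(pseq.spawn(1)[0]))
            res_v1 = simulate_session([blocks[0]], params, rng)
            res_post = simulate_session(blocks[1:], post_params, rng)
            all_trials = pd.concat(
                [res_v1.trials, res_post.trials], ignore_index=True
            ).assign(participant=pid, group=group, session="ctbs")
            trial_frames.append(all_trials)
            recal = _block_recal(all_trials, "conflict", 70.0)
            tb = res_post.terminal_biases["conflict"]
            truth_rows.append(
                {
                    "participant": pid,
                    "group": group,
                    "session": "ctbs",
                    "sigma_p": params.sigma_p,
                    "sigma_p_post": post_params.sigma_p,
                    "sigma_v": params.sigma_v,
                    "sigma_m": params.sigma_m,
                    "w_v": params.visual_weight,
                    "eta": params.eta,
                    "eta_post": post_params.eta,
                    "true_b_p_y": tb["b_p"][1],
                    "true_b_v_y": tb["b_v"][1],
                    **recal,
                }
            )

        else:  # control
            blocks = session_blocks("control", _participant_seed(pseq.spawn(1)[0]))
            res = simulate_session(blocks, params, rng)
            frame = res.trials.assign(participant=pid, group=group, session="control")
            trial_frames.append(frame)
            recal = _block_recal(res.trials, "vshift_control", 70.0)
            truth_rows.append(
                {
                    "participant": pid,
                    "group": group,
                    "session": "control",
                    "sigma_p": params.sigma_p,
                    "sigma_v": params.sigma_v,
                    "sigma_m": params.sigma_m,
                    "w_v": params.visual_weight,
                    "eta": params.eta,
                    "recal_v_y": recal["recal_v_y"],
                    "recal_v_x": recal["recal_v_x"],
                }
            )

    return CohortResult(
        trials=pd.concat(trial_frames, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        traces=traces,
    )
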
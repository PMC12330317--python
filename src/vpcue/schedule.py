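"""Trial schedules for the visuo-proprioceptive alignment task.

A session of the alignment task is a sequence of reaching trials in which a
participant indicates the perceived position of a visual cue (V), of their
unseen target fingertip (P), or of both presented together (VP).  During a
cue-conflict block the visual cue is ramped forward (+y, away from the body)
in small per-trial steps until it sits 70 mm ahead of the proprioceptive
target.  The builders here construct those sequences deterministically from a
seed.

Coordinate frame: origin at the body midline at the near edge of the
workspace, +x to the participant's right, +y away from the body; all
positions in mm.  The conflict is applied along +y only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

# Geometry of the workspace (mm).  Five start positions centred on the body
# midline ~20 cm in front of the chest, and two tactile target markers 3 cm
# apart slightly left of midline, ~30 cm out.
START_POSITIONS: tuple[tuple[float, float], ...] = (
    (-60.0, 200.0),
    (-30.0, 200.0),
    (0.0, 200.0),
    (30.0, 200.0),
    (60.0, 200.0),
)
TARGET_MARKERS: tuple[tuple[float, float], ...] = ((-45.0, 300.0), (-15.0, 300.0))

#: Total forward displacement of the visual cue by the end of a conflict or
#: visual-shift block (mm).
TOTAL_CONFLICT_MM = 70.0
#: Number of VP trials in a conflict block; the per-VP-trial increment is the
#: exact rational 70/42 mm (printed rounded as 1.67).
N_CONFLICT_VP = 42
N_CONFLICT_TRIALS = 84

BLOCK_LABELS = ("veridical1", "veridical2", "conflict", "vshift_control")
TARGET_TYPES = ("V", "P", "VP")

#: Fixed repeating unit realising "40 trials in repeating order (15 V, 15 P,
#: 10 VP)": 3 V + 3 P + 2 VP per unit, five units per block.
_EXPT2_UNIT = ("V", "P", "VP", "V", "P", "V", "P", "VP")

#: Repeating quartet realising "84 trials (42 VP, 21 V, and 21 P, alternating
#: order)".
_CONFLICT_QUARTET = ("VP", "V", "VP", "P")


class ScheduleError(ValueError):
    """Raised for invalid schedule configuration or malformed trial specs."""


@dataclass(frozen=True)
class TrialSpec:
    """One alignment-task trial before simulation.

    ``p_target`` is the tactile-marker position the target fingertip rests on
    (absent on V-only control trials, where the hand stays in the lap).
    ``v_cue`` is where the visual cue is drawn; on VP trials it equals
    ``p_target + (0, visual_offset)``.
    """

    block_label: str
    trial_index: int
    target_type: str
    start_pos: tuple[float, float]
    p_target: tuple[float, float] | None
    visual_offset: float
    v_cue: tuple[float, float] | None

    def __post_init__(self) -> None:
        if self.block_label not in BLOCK_LABELS:
            raise ScheduleError(f"unknown block label {self.block_label!r}")
        if self.target_type not in TARGET_TYPES:
            raise ScheduleError(f"unknown target type {self.target_type!r}")
        if self.visual_offset < 0 or self.visual_offset > TOTAL_CONFLICT_MM:
            raise ScheduleError("visual_offset outside [0, 70] mm")
        if self.target_type in ("P", "VP") and self.p_target is None:
            raise ScheduleError("P/VP trial requires a proprioceptive target")
        if self.target_type in ("V", "VP") and self.v_cue is None:
            raise ScheduleError("V/VP trial requires a visual cue")


@dataclass
class BlockSchedule:
    """An ordered block of trials, reproducible from ``seed``."""

    trials: list[TrialSpec]
    seed: int
    design_name: str

    def __len__(self) -> int:
        return len(self.trials)

    def counts(self) -> dict[str, int]:
        out = {t: 0 for t in TARGET_TYPES}
        for tr in self.trials:
            out[tr.target_type] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        """Serialise to a flat table (one row per trial)."""
        rows = []
        for tr in self.trials:
            rows.append(
                {
                    "block": tr.block_label,
                    "trial_index": tr.trial_index,
                    "target_type": tr.target_type,
                    "start_x": tr.start_pos[0],
                    "start_y": tr.start_pos[1],
                    "p_target_x": tr.p_target[0] if tr.p_target else np.nan,
                    "p_target_y": tr.p_target[1] if tr.p_target else np.nan,
                    "visual_offset": tr.visual_offset,
                    "v_cue_x": tr.v_cue[0] if tr.v_cue else np.nan,
                    "v_cue_y": tr.v_cue[1] if tr.v_cue else np.nan,
                }
            )
        return pd.DataFrame(rows)


def enumerate_start_target_pairs() -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """All start-position x target-marker combinations (5 x 2 = 10 pairs)."""
    return list(itertools.product(START_POSITIONS, TARGET_MARKERS))


def _draw_geometry(rng: np.random.Generator) -> tuple[tuple[float, float], tuple[float, float]]:
    start = START_POSITIONS[int(rng.integers(len(START_POSITIONS)))]
    marker = TARGET_MARKERS[int(rng.integers(len(TARGET_MARKERS)))]
    return start, marker


def _make_trial(
    label: str,
    index: int,
    ttype: str,
    offset: float,
    rng: np.random.Generator,
    *,
    record_p_on_v: bool = True,
) -> TrialSpec:
    start, marker = _draw_geometry(rng)
    cue = (marker[0], marker[1] + offset) if ttype in ("V", "VP") else None
    p_target: tuple[float, float] | None = marker
    if ttype == "V" and not record_p_on_v:
        p_target = None  # target hand in the lap, no marker in play
    return TrialSpec(
        block_label=label,
        trial_index=index,
        target_type=ttype,
        start_pos=start,
        p_target=p_target,
        visual_offset=offset,
        v_cue=cue,
    )


def _pseudorandom_types(
    counts: dict[str, int], rng: np.random.Generator, max_run: int = 2
) -> list[str]:
    """Seeded shuffle of the trial-type multiset, rejecting runs > ``max_run``."""
    pool = [t for t, n in counts.items() for _ in range(n)]
    for _ in range(10_000):
        seq = list(rng.permutation(pool))
        run, ok = 1, True
        for a, b in zip(seq, seq[1:]):
            run = run + 1 if a == b else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return seq
    raise ScheduleError("could not satisfy the run-length constraint")  # pragma: no cover


def build_baseline_block(
    design: str, seed: int, *, block_label: str = "veridical1"
) -> BlockSchedule:
    """A 40-trial veridical block (15 V, 15 P, 10 VP).

    ``expt1_baseline`` pseudorandomises the order under a max-run-of-2
    constraint; ``expt2_veridical`` uses a fixed repeating 8-trial unit.
    """
    if seed < 0:
        raise ScheduleError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    if design == "expt1_baseline":
        types = _pseudorandom_types({"V": 15, "P": 15, "VP": 10}, rng)
    elif design == "expt2_veridical":
        types = list(_EXPT2_UNIT) * 5
    else:
        raise ScheduleError(f"unknown baseline design {design!r}")
    trials = [
        _make_trial(block_label, i, t, 0.0, rng) for i, t in enumerate(types)
    ]
    return BlockSchedule(trials=trials, seed=seed, design_name=design)


def build_conflict_block(
    seed: int,
    *,
    total_offset: float = TOTAL_CONFLICT_MM,
    block_label: str = "conflict",
) -> BlockSchedule:
    """The 84-trial second block: quartet VP, V, VP, P repeated 21 times.

    The visual offset advances by ``total_offset / 42`` on each VP trial and
    is carried (not advanced) on the interleaved V trials, reaching
    ``total_offset`` exactly on the final VP trial.  ``total_offset=0`` gives
    the matched veridical second block.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    vp_seen = 0
    offset = 0.0
    for i, ttype in enumerate(_CONFLICT_QUARTET * (N_CONFLICT_TRIALS // 4)):
        if ttype == "VP":
            vp_seen += 1
            offset = min(total_offset, vp_seen * total_offset / N_CONFLICT_VP)
        trials.append(_make_trial(block_label, i, ttype, offset, rng))
    return BlockSchedule(trials=trials, seed=seed, design_name=f"{block_label}_84")


def build_vshift_block(seed: int) -> BlockSchedule:
    """The control experiment's visual-shift block: 84 V-only trials.

    The cue ramps linearly, reaching 70 mm forward displacement on the final
    trial; no proprioceptive target is ever present (hand in the lap).
    """
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(N_CONFLICT_TRIALS):
        offset = (i + 1) * TOTAL_CONFLICT_MM / N_CONFLICT_TRIALS
        trials.append(
            _make_trial("vshift_control", i, "V", offset, rng, record_p_on_v=False)
        )
    return BlockSchedule(trials=trials, seed=seed, design_name="vshift_control")


def session_blocks(experiment: str, seed: int) -> list[BlockSchedule]:
    """The ordered blocks of one session of a given experiment design.

    expt1 -> baseline + conflict; expt1_veridical -> baseline + matched
    zero-offset second block; expt2 -> veridical1, veridical2, conflict;
    control -> training block + visual-shift block.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    if experiment == "expt1":
        return [
            build_baseline_block("expt1_baseline", seeds[0]),
            build_conflict_block(seeds[1]),
        ]
    if experiment == "expt1_veridical":
        return [
            build_baseline_block("expt1_baseline", seeds[0]),
            build_conflict_block(seeds[1], total_offset=0.0, block_label="veridical2"),
        ]
    if experiment == "expt2":
        v1 = build_baseline_block("expt2_veridical", seeds[0])
        v2 = build_baseline_block("expt2_veridical", seeds[1], block_label="veridical2")
        return [v1, v2, build_conflict_block(seeds[2])]
    if experiment == "control":
        return [
            build_baseline_block("expt2_veridical", seeds[0]),
            build_vshift_block(seeds[1]),
        ]
    raise ScheduleError(f"unknown experiment {experiment!r}")
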
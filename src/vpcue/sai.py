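"""Short-latency afferent inhibition (SAI) quantification.

SAI is the suppression of a TMS-evoked motor potential (MEP) by a preceding
median-nerve stimulus.  It is quantified as the mean conditioned MEP
peak-to-peak amplitude expressed as a percentage of the mean unconditioned
amplitude (ratio of means); values below 100% denote inhibition.  The
pre-to-post change across a behavioural session is the post/pre ratio x 100.

Trace convention: ``samples`` start at the TMS pulse (t = 0), sampled at
``rate`` Hz, amplitudes in mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_RATE_HZ = 5_000.0
#: Search window for the MEP, ms after the TMS pulse.
DEFAULT_MEP_WINDOW_MS = (15.0, 60.0)


class SaiError(ValueError):
    """Raised for degenerate SAI inputs (empty windows, non-positive means)."""


@dataclass
class MepTrace:
    """A single EMG sweep time-locked to the TMS pulse."""

    samples: np.ndarray  # mV
    rate: float = DEFAULT_RATE_HZ  # samples/s
    condition: str = "unconditioned"  # conditioned | unconditioned
    timepoint: str = "pre"  # pre | post

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise SaiError("sampling rate must be positive")
        if self.condition not in ("conditioned", "unconditioned"):
            raise SaiError(f"unknown condition {self.condition!r}")
        if self.timepoint not in ("pre", "post"):
            raise SaiError(f"unknown timepoint {self.timepoint!r}")

    @property
    def duration_ms(self) -> float:
        return 1_000.0 * len(self.samples) / self.rate


@dataclass(frozen=True)
class SaiMeasure:
    """SAI at both timepoints and their post/pre change, in % units."""

    sai_pre: float
    sai_post: float
    delta_sai: float
    n_cond_pre: int
    n_uncond_pre: int
    n_cond_post: int
    n_uncond_post: int


def mep_peak_to_peak(
    trace: MepTrace, window_ms: tuple[float, float] = DEFAULT_MEP_WINDOW_MS
) -> float:
    """Peak-to-peak amplitude (max - min, mV) within a post-stimulus window."""
    lo, hi = window_ms
    i0 = int(np.floor(lo / 1_000.0 * trace.rate))
    i1 = int(np.ceil(hi / 1_000.0 * trace.rate)) + 1
    if i0 < 0 or i0 >= len(trace.samples) or hi <= lo:
        raise SaiError("MEP window is empty or outside the trace")
    seg = trace.samples[i0:i1]
    if seg.size == 0:
        raise SaiError("MEP window is empty or outside the trace")
    return float(seg.max() - seg.min())


def sai_percent(conditioned_mv: np.ndarray, unconditioned_mv: np.ndarray) -> float:
    """Ratio of mean conditioned to mean unconditioned amplitude, x 100."""
    cond = np.asarray(conditioned_mv, dtype=float)
    uncond = np.asarray(unconditioned_mv, dtype=float)
    if cond.size == 0 or uncond.size == 0:
        raise SaiError("need at least one amplitude per condition")
    denom = uncond.mean()
    if denom <= 0:
        raise SaiError("unconditioned mean amplitude must be positive")
    return float(cond.mean() / denom * 100.0)


def delta_sai(sai_pre: float, sai_post: float) -> float:
    """Post/pre change in SAI, x 100 (values > 100 = less inhibition post)."""
    if sai_pre <= 0:
        raise SaiError("pre-task SAI must be positive")
    return float(sai_post / sai_pre * 100.0)


def sai_from_traces(
    traces: list[MepTrace], window_ms: tuple[float, float] = DEFAULT_MEP_WINDOW_MS
) -> SaiMeasure:
    """Full SAI quantification from a mixed list of pre/post MEP traces."""
    amps: dict[tuple[str, str], list[float]] = {}
    for tr in traces:
        amps.setdefault((tr.timepoint, tr.condition), []).append(
            mep_peak_to_peak(tr, window_ms)
        )
    try:
        pre = sai_percent(amps[("pre", "conditioned")], amps[("pre", "unconditioned")])
        post = sai_percent(
            amps[("post", "conditioned")], amps[("post", "unconditioned")]
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise SaiError(f"missing traces for {exc.args[0]}") from exc
    return SaiMeasure(
        sai_pre=pre,
        sai_post=post,
        delta_sai=delta_sai(pre, post),
        n_cond_pre=len(amps[("pre", "conditioned")]),
        n_uncond_pre=len(amps[("pre", "unconditioned")]),
        n_cond_post=len(amps[("post", "conditioned")]),
        n_uncond_post=len(amps[("post", "unconditioned")]),
    )
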
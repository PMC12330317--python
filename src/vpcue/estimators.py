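"""Behavioural estimators for the alignment task.

Three families of statistics are computed from indicator-finger endpoints:

* **Recalibration** — the shift of each unimodal estimate across a block.
  Proprioceptive recalibration is the mean of the last four P-trial
  y-endpoints minus the mean of the first four; visual recalibration is the
  imposed cue displacement (70 mm in a conflict block) minus the analogous
  V-trial change, so that undershooting the shifted cue scores positive.
* **Weighting (W_v)** — per-VP-trial reliance on vision, from the position of
  a VP endpoint between the centroids of the four nearest V and four nearest
  P trials; 1 = pure vision, 0 = pure proprioception.
* **2D endpoint variance** — the sample variance of each endpoint's distance
  from the endpoint centroid, with an indicator-hand correction that
  attributes half of the P-trial endpoint variance to the reporting hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedule import TOTAL_CONFLICT_MM


class InsufficientDataError(ValueError):
    """Raised when a block has too few trials for an estimator."""


@dataclass(frozen=True)
class RecalibrationEstimate:
    """Recalibration of both modalities along one dimension (mm)."""

    delta_yp: float
    delta_yv: float
    dimension: str = "y"

    @property
    def total(self) -> float:
        return self.delta_yp + self.delta_yv


@dataclass
class WeightingEstimate:
    """Per-VP-trial visual weights and their block aggregate."""

    per_trial: list[tuple[int, float | None]]  # (vp trial_index, W_v or None)
    n_valid: int
    block_mean: float | None  # None when n_valid < min_valid


@dataclass(frozen=True)
class VarianceEstimate:
    """Raw and indicator-hand-corrected 2D endpoint variances (mm^2)."""

    raw_p: float
    raw_v: float

    @property
    def corrected_p(self) -> float:
        return 0.5 * self.raw_p

    @property
    def corrected_v(self) -> float:
        return self.raw_v - 0.5 * self.raw_p

    @property
    def negative_flag(self) -> bool:
        return self.corrected_v < 0


def _edge_means(values: np.ndarray, k: int = 4) -> tuple[float, float]:
    if len(values) < 2 * k:
        raise InsufficientDataError(
            f"need at least {2 * k} endpoints, got {len(values)}"
        )
    return float(np.mean(values[:k])), float(np.mean(values[-k:]))


def recalibration_p(p_endpoints: np.ndarray, true_shift: float = 0.0) -> float:
    """Proprioceptive recalibration: mean(last 4) - mean(first 4) - true shift.

    The true y-position of the P target does not move during a conflict block,
    so ``true_shift`` defaults to 0; positive values mean overshoot of the P
    target grew across the block (recalibration toward the visual cue).
    """
    first, last = _edge_means(np.asarray(p_endpoints, dtype=float))
    return last - first - true_shift


def recalibration_v(
    v_endpoints: np.ndarray,
    total_shift: float = TOTAL_CONFLICT_MM,
    offsets: np.ndarray | None = None,
) -> float:
    """Visual recalibration: imposed shift - (mean(last 4) - mean(first 4)).

    By convention the imposed shift is the block's nominal total (70 mm for a
    conflict block, 0 for veridical), even though the first four V trials
    already carry a small offset.  Passing the per-trial cue ``offsets``
    switches to the exact realised shift, mean(last-4 offsets) - mean(first-4
    offsets).
    """
    vals = np.asarray(v_endpoints, dtype=float)
    first, last = _edge_means(vals)
    if offsets is not None:
        off = np.asarray(offsets, dtype=float)
        if off.shape != vals.shape:
            raise InsufficientDataError("offsets must align with endpoints")
        o_first, o_last = _edge_means(off)
        total_shift = o_last - o_first
    return total_shift - (last - first)


def target_relative(trials: pd.DataFrame) -> pd.DataFrame:
    """Add target-relative endpoint columns ``rel_x``/``rel_y`` to a table.

    Start and target positions vary from trial to trial by design (so the
    indicator movement cannot be stereotyped), so endpoint clouds are only
    comparable after re-expressing each endpoint relative to its own trial's
    reference: the proprioceptive target on P/VP trials, the visual cue on V
    trials.  Raw endpoints are left untouched.
    """
    out = trials.copy()
    is_v = out["target_type"] == "V"
    ref_x = np.where(is_v, out["v_cue_x"], out["p_target_x"])
    ref_y = np.where(is_v, out["v_cue_y"], out["p_target_y"])
    out["rel_x"] = out["endpoint_x"] - ref_x
    out["rel_y"] = out["endpoint_y"] - ref_y
    return out


def _centroid_distances(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    return np.linalg.norm(pts - pts.mean(axis=0), axis=1)


def per_trial_wv(
    vp_endpoint: np.ndarray,
    v_nearest: np.ndarray,
    p_nearest: np.ndarray,
    sd_criterion: float = 0.5,
) -> float | None:
    """Visual weight for one VP trial, or ``None`` when it is not estimable.

    W_v = |yP - yVP| / (|yP - yVP| + |yV - yVP|) with yV, yP the centroids of
    the four nearest unimodal trials and distances 2D Euclidean.  The trial is
    invalid when the two centroids are closer than ``sd_criterion`` times the
    pooled spread (mean of the two modalities' centroid-distance SDs), or when
    both distances vanish.
    """
    v = np.asarray(v_nearest, dtype=float)
    p = np.asarray(p_nearest, dtype=float)
    if v.shape != (4, 2) or p.shape != (4, 2):
        raise InsufficientDataError("need exactly 4 endpoints per modality")
    y_v = v.mean(axis=0)
    y_p = p.mean(axis=0)
    pooled_sd = 0.5 * (
        _centroid_distances(v).std(ddof=1) + _centroid_distances(p).std(ddof=1)
    )
    if np.linalg.norm(y_v - y_p) < sd_criterion * pooled_sd:
        return None
    d_p = float(np.linalg.norm(y_p - np.asarray(vp_endpoint, dtype=float)))
    d_v = float(np.linalg.norm(y_v - np.asarray(vp_endpoint, dtype=float)))
    if d_p + d_v == 0:
        return None
    return d_p / (d_p + d_v)


def _nearest_by_index(indices: np.ndarray, idx: int, k: int = 4) -> np.ndarray:
    """Positions of the k trials nearest in trial index; ties to the earlier."""
    order = np.lexsort((indices, np.abs(indices - idx)))
    return order[:k]


def block_wv(
    trials: pd.DataFrame,
    sd_criterion: float = 0.5,
    min_valid: int = 3,
) -> WeightingEstimate:
    """W_v for every VP trial of a block, matched to neighbouring V/P trials.

    ``trials`` needs columns ``target_type``, ``trial_index``, ``endpoint_x``,
    ``endpoint_y``.  The block mean is reported only when at least
    ``min_valid`` per-trial weights survive the overlap-exclusion rule; blocks
    below that are flagged as having an undefined weighting (mirroring the
    exclusion of participants whose V and P endpoint clouds overlap).
    """
    ttype = trials["target_type"].to_numpy()
    indices = trials["trial_index"].to_numpy()
    points = trials[["endpoint_x", "endpoint_y"]].to_numpy(dtype=float)
    v_idx, v_pts = indices[ttype == "V"], points[ttype == "V"]
    p_idx, p_pts = indices[ttype == "P"], points[ttype == "P"]
    vp_idx, vp_pts = indices[ttype == "VP"], points[ttype == "VP"]
    if len(vp_idx) == 0:
        raise InsufficientDataError("block contains no VP trials")
    if len(v_idx) < 4 or len(p_idx) < 4:
        raise InsufficientDataError("need at least 4 V and 4 P trials")
    per_trial: list[tuple[int, float | None]] = []
    for idx, vp_endpoint in zip(vp_idx, vp_pts):
        v_sel = v_pts[_nearest_by_index(v_idx, idx)]
        p_sel = p_pts[_nearest_by_index(p_idx, idx)]
        wv = per_trial_wv(vp_endpoint, v_sel, p_sel, sd_criterion)
        per_trial.append((int(idx), wv))
    valid = [w for _, w in per_trial if w is not None]
    return WeightingEstimate(
        per_trial=per_trial,
        n_valid=len(valid),
        block_mean=float(np.mean(valid)) if len(valid) >= min_valid else None,
    )


def block_recalibration(block: pd.DataFrame, total_shift: float | None = None) -> dict:
    """Recalibration of both modalities, y and x, for one block of trials.

    y (the conflict dimension) follows the printed first-4/last-4 formulas on
    the endpoint y-coordinates; x uses target-relative endpoints with a zero
    true shift, since start and target positions alternate in x by design.
    ``total_shift`` defaults to the block's maximum visual offset (70 mm for
    a conflict or visual-shift block, 0 for veridical).  Modalities with
    fewer than 8 trials are reported as NaN.
    """
    if total_shift is None:
        total_shift = float(block["visual_offset"].max())
    rel = target_relative(block.sort_values("trial_index"))
    p = rel[rel.target_type == "P"]
    v = rel[rel.target_type == "V"]
    out = {
        "recal_p_y": np.nan, "recal_p_x": np.nan,
        "recal_v_y": np.nan, "recal_v_x": np.nan,
    }
    if len(p) >= 8:
        # the P target never moves, so raw and target-relative y agree
        out["recal_p_y"] = recalibration_p(p["rel_y"].to_numpy())
        out["recal_p_x"] = recalibration_p(p["rel_x"].to_numpy())
    if len(v) >= 8:
        # y relative to the unshifted cue anchor, so the printed constant
        # total shift applies; x relative to the cue, true shift 0
        anchor_y = (v["endpoint_y"] - (v["v_cue_y"] - v["visual_offset"])).to_numpy()
        out["recal_v_y"] = recalibration_v(anchor_y, total_shift)
        out["recal_v_x"] = recalibration_v(v["rel_x"].to_numpy(), 0.0)
    return out


def endpoint_variance_2d(endpoints: np.ndarray) -> float:
    """Sample variance (n-1) of 2D endpoint distances from their centroid."""
    pts = np.asarray(endpoints, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise InsufficientDataError("need at least 3 two-dimensional endpoints")
    return float(_centroid_distances(pts).var(ddof=1))


def corrected_variances(raw_p: float, raw_v: float) -> VarianceEstimate:
    """Apply the indicator-hand correction (subtract 0.5 x P variance).

    A negative corrected visual variance is returned as computed (and flagged
    via ``negative_flag``) rather than clamped, so downstream regressions see
    the raw arithmetic.
    """
    if raw_p < 0 or raw_v < 0:
        raise InsufficientDataError("raw variances must be non-negative")
    return VarianceEstimate(raw_p=raw_p, raw_v=raw_v)
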
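"""Rolling-window transport-mode segmentation of single-particle trajectories.

Intracellular trajectories alternate between transport modes on time scales
of seconds, so a whole-trajectory MSD averages over heterogeneous dynamics.
The segmentation slides an analysis window (one frame at a time) along each
trajectory, fits the four MSD models to every window's time-averaged MSD, and
assigns each position the majority mode over all windows covering it. Runs of
equal labels become segments; runs shorter than the minimum segment length
(default 60% of the window) are merged into the flanking segment whose model
describes them better. Per-segment parameters (D, v, α) are then refitted on
each segment's own MSD.

Window decision rule
--------------------
Each window's TA-MSD yields a log-log slope α (with standard error SE) and
relative fit errors ``err`` for the four models:

* α > ``alpha_super`` and the active model improves on the normal model by at
  least the margin (``err_active ≤ (1−margin)·err_normal``)  →  **active**
* α + SE < ``alpha_sub`` (a significance-gated subdiffusion call):
  **confined** if the confined model improves on the power law by at least
  the margin and its plateau is reached within the fitted lags, else
  **anomalous** (subdiffusive)
* otherwise (including a degenerate all-zero window → confined)  →  **normal**

The α thresholds (defaults 0.7 / 1.3), the improvement margin, the
plateau-saturation requirement and the significance gate are exposed in
:class:`SegmentationConfig`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory_io import Trajectory, TrajectoryEnsemble
from .msd import (
    fit_msd,
    time_averaged_msd,
    fit_normal_batch,
    fit_active_batch,
    fit_anomalous_batch,
    fit_confined_batch,
    loglog_slope_batch,
)

__all__ = [
    "SegmentationConfig",
    "TrajectorySegment",
    "SegmentStatistics",
    "classify_window",
    "rolling_classify",
    "segment_parameters",
    "classify_ensemble",
    "mode_proportions",
    "rapid_transport_fraction",
    "segments_to_table",
    "RAPID_TRANSPORT_CUTOFF_D",
]

MODES = ("normal", "active", "anomalous", "confined")

# diffusion-coefficient cutoff (μm²/s) above which an active segment is
# attributed to rapid microtubule-directed transport
RAPID_TRANSPORT_CUTOFF_D = 0.01


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the rolling-window segmentation.

    Parameters
    ----------
    window_s
        Analysis window length in seconds; only positions inside the window
        contribute to its MSD. Must not exceed the trajectory duration.
    min_segment_s
        Minimum accepted segment duration; defaults to 0.6·window_s.
    fit_lag_fraction
        Fraction of a window's lags used in the MSD fits (≥3 lags always).
        Windows default to 0.5 — the ballistic and plateau signatures that
        separate the modes only emerge at lags comparable to the window
        itself, unlike whole-trajectory parameter fits where short lags
        suffice.
    alpha_sub, alpha_super
        Anomalous-exponent thresholds below/above which a window is
        considered sub-/superdiffusive.
    margin
        Minimum relative fit-error improvement for preferring the more
        complex model (active over normal, confined over anomalous). The
        extra parameters of the richer models fit window-scale noise well,
        so a strong penalty (default: the richer model must halve the fit
        error) is needed to keep false transport-mode promotions rare.
    min_saturation
        Minimum rate·τ_max of the confined fit for a confinement call: the
        plateau must be essentially reached within the fitted lags (3 means
        the exponential has decayed to 5% of its initial amplitude).
    gate_z
        Significance requirement on the α gates: a sub-/superdiffusion call
        needs the log-log slope to clear its threshold by ``gate_z`` standard
        errors. Windows with few frames (low frame rates) have noisy slopes
        and therefore claim anomalous or active modes only on strong
        evidence — which is also why low-rate recordings recover less of the
        true subdiffusion.
    max_fit_lags
        Upper bound on the number of fitted lags per window; keeps the lag /
        window ratio small at high frame rates, where the finite-window bias
        of the TA-MSD mimics a confinement plateau.
    """

    window_s: float
    min_segment_s: float | None = None
    fit_lag_fraction: float = 0.5
    alpha_sub: float = 0.7
    alpha_super: float = 1.3
    margin: float = 0.50
    min_saturation: float = 3.0
    gate_z: float = 1.0
    max_fit_lags: int = 50

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ValueError(f"window_s must be positive, got {self.window_s}")
        if self.min_segment_s is None:
            object.__setattr__(self, "min_segment_s", 0.6 * self.window_s)
        if not 0 < self.min_segment_s <= self.window_s:
            raise ValueError(
                f"min_segment_s must lie in (0, window_s], got {self.min_segment_s}"
            )
        if not 0 < self.fit_lag_fraction <= 1:
            raise ValueError("fit_lag_fraction must lie in (0, 1]")
        if not self.alpha_sub < 1 < self.alpha_super:
            raise ValueError("need alpha_sub < 1 < alpha_super")
        if not 0 <= self.margin < 1:
            raise ValueError("margin must lie in [0, 1)")

    def window_positions(self, dt: float) -> int:
        """Window length in positions: spans window_s seconds."""
        return int(round(self.window_s / dt)) + 1

    def n_lags(self, dt: float) -> int:
        # the lag-count cap keeps the fitted lags short against the window at
        # high frame rates, where the finite-window downward bias of the
        # TA-MSD at long lags would otherwise mimic a confinement plateau
        L = self.window_positions(dt)
        k = max(3, int(math.floor(self.fit_lag_fraction * (L - 1))))
        return min(L - 1, k, self.max_fit_lags)

    def min_segment_frames(self, dt: float) -> int:
        """Minimum frame span so that span·dt ≥ min_segment_s."""
        return int(math.ceil(self.min_segment_s / dt - 1e-9))


@dataclass
class TrajectorySegment:
    """A maximal run of positions sharing one transport mode."""

    traj_id: str
    start_frame: int
    end_frame: int  # inclusive
    mode: str
    dt: float
    n_positions: int
    D: float | None = None
    v: float | None = None
    alpha: float | None = None
    r_c: float | None = None
    fit_ok: bool = True

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame) * self.dt


# ---------------------------------------------------------------------------
# Window classification
# ---------------------------------------------------------------------------


def _classify_msd_rows(
    tau: np.ndarray,
    M: np.ndarray,
    config: SegmentationConfig,
    window_positions: int | None = None,
) -> np.ndarray:
    """Vectorized mode decision for W window MSDs stacked as M (W, K).

    The sub-/superdiffusion gate uses the unweighted log-log slope so every
    lag of the window counts equally; model competition uses linear-space
    relative fit errors. A confined call additionally requires the fitted
    exponential to have substantially saturated inside the fitted lag range
    (rate·τ_max ≥ ``min_saturation``) — without that requirement the
    three-parameter confined model out-fits the power law on almost any noisy
    subdiffusive window without an observed plateau.
    """
    alpha, alpha_se = loglog_slope_batch(tau, M, with_se=True)
    if window_positions is not None:
        # residual-based SE underestimates the slope noise (TA-MSD residuals
        # are strongly correlated); floor it with the analytic TA-MSD
        # relative variance ~ 2k/(3(L−k)) propagated through the regression
        k = np.arange(1, len(tau) + 1, dtype=float)
        L = float(window_positions)
        var_log = 2.0 * k / (3.0 * np.maximum(L - k, 1.0))
        logt = np.log(tau)
        tc = logt - logt.mean()
        sxx = float((tc**2).sum())
        se_floor = math.sqrt(float(((tc / sxx) ** 2 * var_log).sum()))
        alpha_se = np.maximum(alpha_se, se_floor)
    norm = fit_normal_batch(tau, M)
    act = fit_active_batch(tau, M)
    anom = fit_anomalous_batch(tau, M)
    conf = fit_confined_batch(tau, M)
    W = M.shape[0]
    labels = np.full(W, "normal", dtype=object)
    degenerate = np.all(M == 0, axis=1)
    margin = 1.0 - config.margin
    z = config.gate_z

    # the active branch needs no significance gate: a false active call must
    # also halve the normal model's fit error, which noise alone rarely does
    superdiff = alpha > config.alpha_super
    active = superdiff & (norm["err"] > 0) & (act["err"] <= margin * norm["err"])
    labels[active] = "active"

    subdiff = alpha + z * alpha_se < config.alpha_sub
    saturated = conf["B"] * tau[-1] >= config.min_saturation
    confined = (
        subdiff & saturated & (anom["err"] > 0) & (conf["err"] <= margin * anom["err"])
    )
    labels[subdiff] = "anomalous"
    labels[confined] = "confined"
    labels[degenerate] = "confined"  # immobile particle: zero-radius confinement
    return labels


def classify_window(subtrajectory: Trajectory, config: SegmentationConfig) -> str:
    """Assign one transport mode to a window-sized piece of trajectory."""
    L = config.window_positions(subtrajectory.dt)
    if len(subtrajectory) < L:
        raise ValueError(
            f"window needs >= {L} positions, got {len(subtrajectory)}"
        )
    n_lags = config.n_lags(subtrajectory.dt)
    curve = time_averaged_msd(subtrajectory, max_lag_fraction=1.0)
    sel = curve.lags <= n_lags
    tau, m = curve.taus[sel], curve.values[sel]
    if len(tau) < 3:
        raise ValueError("window MSD has fewer than 3 usable lags")
    return str(_classify_msd_rows(tau, m[None, :], config, L)[0])


def _window_msds(
    traj: Trajectory, L: int, n_lags: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """TA-MSD of every length-L window (sliding by one frame).

    Returns (tau, M, valid, dense_index) where M is (W, n_lags), ``valid``
    flags windows whose every lag has at least one displacement pair, and
    ``dense_index`` maps each retained position to its dense frame offset.
    """
    dense_idx = traj.frames - traj.frames[0]
    S = int(dense_idx[-1]) + 1
    dense = np.full((S, 2), np.nan)
    dense[dense_idx, 0] = traj.x
    dense[dense_idx, 1] = traj.y
    W = S - L + 1
    tau = np.arange(1, n_lags + 1) * traj.dt
    M = np.empty((W, n_lags))
    valid = np.ones(W, dtype=bool)
    for k in range(1, n_lags + 1):
        diff = dense[k:] - dense[:-k]
        sq = diff[:, 0] ** 2 + diff[:, 1] ** 2
        ok = ~np.isnan(sq)
        sq = np.where(ok, sq, 0.0)
        # sliding sums over window starts: pairs j in [w, w + L - 1 - k]
        wlen = L - k
        csum = np.concatenate([[0.0], np.cumsum(sq)])
        ccnt = np.concatenate([[0], np.cumsum(ok)])
        tot = csum[wlen : wlen + W] - csum[:W]
        cnt = ccnt[wlen : wlen + W] - ccnt[:W]
        with np.errstate(invalid="ignore", divide="ignore"):
            M[:, k - 1] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
        valid &= cnt > 0
    return tau, M, valid, dense_idx


def _majority_vote(
    window_labels: np.ndarray,
    valid: np.ndarray,
    dense_idx: np.ndarray,
    L: int,
) -> list[str | None]:
    """Per-position majority over covering windows; ties keep the previous label."""
    W = len(window_labels)
    S = int(dense_idx[-1]) + 1
    # votes[mode][p] = number of valid windows of that mode covering dense p
    votes = {}
    for mode in MODES:
        ind = ((window_labels == mode) & valid).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(ind)])
        lo = np.clip(np.arange(S) - L + 1, 0, W)
        hi = np.clip(np.arange(S) + 1, 0, W)
        votes[mode] = csum[hi] - csum[lo]
    counts = np.column_stack([votes[m] for m in MODES])  # (S, 4)
    labels: list[str | None] = []
    prev: str | None = None
    for p in dense_idx:
        row = counts[p]
        top = row.max()
        if top == 0:
            labels.append(None)
            continue
        tied = [MODES[i] for i in np.flatnonzero(row == top)]
        lab = prev if (len(tied) > 1 and prev in tied) else tied[0]
        labels.append(lab)
        prev = lab
    return labels


def _runs(labels: Sequence[str | None]) -> list[tuple[int, int, str]]:
    """Maximal runs (start_idx, end_idx inclusive, label), skipping None."""
    runs = []
    start = None
    for i, lab in enumerate(labels):
        if lab is None:
            if start is not None:
                runs.append((start, i - 1, labels[start]))
                start = None
            continue
        if start is None:
            start = i
        elif lab != labels[start]:
            runs.append((start, i - 1, labels[start]))
            start = i
    if start is not None:
        runs.append((start, len(labels) - 1, labels[start]))
    return runs


def _run_fit_error(traj: Trajectory, i0: int, i1: int, mode: str) -> float:
    """Relative error of ``mode``'s model fitted to the run's own MSD."""
    if i1 - i0 + 1 < 4:
        return np.inf
    piece = Trajectory(
        id=traj.id,
        frames=traj.frames[i0 : i1 + 1],
        x=traj.x[i0 : i1 + 1],
        y=traj.y[i0 : i1 + 1],
        dt=traj.dt,
    )
    curve = time_averaged_msd(piece, max_lag_fraction=1.0)
    try:
        fit = fit_msd(curve, mode, (1, int(curve.lags[-1])))
    except ValueError:
        return np.inf
    return fit.fit_error


def _merge_short_runs(
    traj: Trajectory,
    runs: list[tuple[int, int, str]],
    min_frames: int,
) -> list[tuple[int, int, str]]:
    """Absorb runs spanning < min_frames into the better-fitting neighbor."""

    def span(run):
        i0, i1, _ = run
        return int(traj.frames[i1] - traj.frames[i0])

    runs = list(runs)
    while len(runs) > 1:
        # contiguity: merging only applies within one classified stretch
        short = [
            i
            for i, r in enumerate(runs)
            if span(r) < min_frames
            and (
                (i > 0 and runs[i - 1][1] == r[0] - 1)
                or (i < len(runs) - 1 and runs[i + 1][0] == r[1] + 1)
            )
        ]
        if not short:
            break
        i = min(short, key=lambda j: span(runs[j]))
        i0, i1, lab = runs[i]
        left = runs[i - 1] if i > 0 and runs[i - 1][1] == i0 - 1 else None
        right = runs[i + 1] if i < len(runs) - 1 and runs[i + 1][0] == i1 + 1 else None
        if left is not None and right is not None:
            err_l = _run_fit_error(traj, i0, i1, left[2])
            err_r = _run_fit_error(traj, i0, i1, right[2])
            into_left = err_l <= err_r  # ties -> earlier segment
        elif left is not None:
            into_left = True
        else:
            into_left = False
        if into_left:
            runs[i - 1] = (left[0], i1, left[2])
            del runs[i]
        else:
            runs[i + 1] = (i0, right[1], right[2])
            del runs[i]
        # coalesce equal-label neighbors created by the merge
        j = 0
        while j < len(runs) - 1:
            a, b = runs[j], runs[j + 1]
            if a[2] == b[2] and b[0] == a[1] + 1:
                runs[j] = (a[0], b[1], a[2])
                del runs[j + 1]
            else:
                j += 1
    return runs


def rolling_classify(
    traj: Trajectory, config: SegmentationConfig
) -> tuple[list[str | None], list[TrajectorySegment]]:
    """Label every position of a trajectory and build minimum-length segments.

    Returns per-position labels (None where no valid window covers a
    position) and the list of segments. A trajectory shorter than the
    analysis window yields an empty result with a warning.
    """
    L = config.window_positions(traj.dt)
    if len(traj) < L or traj.duration < config.window_s - 1e-9:
        warnings.warn(
            f"trajectory {traj.id!r} ({traj.duration:.3g} s) is shorter than "
            f"the {config.window_s} s analysis window; skipped",
            stacklevel=2,
        )
        return [None] * len(traj), []
    n_lags = config.n_lags(traj.dt)
    tau, M, valid, dense_idx = _window_msds(traj, L, n_lags)
    row_ok = valid & ~np.any(np.isnan(M), axis=1)
    labels_w = np.full(M.shape[0], "normal", dtype=object)
    if row_ok.any():
        labels_w[row_ok] = _classify_msd_rows(tau, M[row_ok], config, L)
    labels = _majority_vote(labels_w, row_ok, dense_idx, L)
    runs = _merge_short_runs(traj, _runs(labels), config.min_segment_frames(traj.dt))
    segments = []
    for i0, i1, mode in runs:
        segments.append(
            TrajectorySegment(
                traj_id=traj.id,
                start_frame=int(traj.frames[i0]),
                end_frame=int(traj.frames[i1]),
                mode=mode,
                dt=traj.dt,
                n_positions=i1 - i0 + 1,
            )
        )
        labels[i0 : i1 + 1] = [mode] * (i1 - i0 + 1)
    return labels, segments


def segment_parameters(
    segment: TrajectorySegment, traj: Trajectory
) -> TrajectorySegment:
    """Refit a segment's own TA-MSD with its mode's model and fill parameters.

    D is filled for every mode, v for active segments, α for anomalous ones.
    A failed fit flags the segment (``fit_ok=False``) instead of raising.
    """
    sel = (traj.frames >= segment.start_frame) & (traj.frames <= segment.end_frame)
    if sel.sum() < 3:
        return replace(segment, fit_ok=False)
    piece = Trajectory(
        id=traj.id,
        frames=traj.frames[sel],
        x=traj.x[sel],
        y=traj.y[sel],
        dt=traj.dt,
    )
    try:
        curve = time_averaged_msd(piece, max_lag_fraction=1.0)
        from .msd import default_lag_range

        k_min, k_max = default_lag_range(len(piece))
        if segment.mode != "active":
            # D is a short-lag property; long lags only add variance and
            # leak neighboring-mode behavior into the estimate. The active
            # model keeps the quarter-range: v carries signal at long lags.
            k_max = min(k_max, 10)
        k_max = min(k_max, int(curve.lags[-1]))
        fit = fit_msd(curve, segment.mode, (k_min, k_max))
    except ValueError:
        return replace(segment, fit_ok=False)
    return replace(
        segment,
        D=fit.D,
        v=fit.v,
        alpha=fit.alpha,
        r_c=fit.r_c,
        fit_ok=fit.converged,
    )


def classify_ensemble(
    ensemble: TrajectoryEnsemble, config: SegmentationConfig
) -> tuple[list[TrajectorySegment], dict[str, list[str | None]]]:
    """Segment every trajectory and fill per-segment parameters."""
    all_segments: list[TrajectorySegment] = []
    all_labels: dict[str, list[str | None]] = {}
    traj_by_id = {t.id: t for t in ensemble}
    for t in ensemble:
        labels, segments = rolling_classify(t, config)
        all_labels[t.id] = labels
        all_segments.extend(segment_parameters(s, traj_by_id[s.traj_id]) for s in segments)
    return all_segments, all_labels


# ---------------------------------------------------------------------------
# Ensemble statistics
# ---------------------------------------------------------------------------


@dataclass
class SegmentStatistics:
    """Position-weighted mode proportions and per-mode parameter distributions."""

    mode_proportions: dict[str, float]  # sums to 1 over classified positions
    velocity_distribution: np.ndarray  # v of active segments, μm/s
    D_distribution: dict[str, np.ndarray]  # per mode, μm²/s
    segment_length_distribution: dict[str, np.ndarray]  # per mode, s
    rapid_active_fraction: float  # NaN when no active segment has a D
    n_classified_positions: int


def mode_proportions(
    segments: Sequence[TrajectorySegment],
    cutoff_D: float = RAPID_TRANSPORT_CUTOFF_D,
) -> SegmentStatistics:
    """Aggregate segments into the ensemble summary.

    Proportions are weighted by position counts (a 100-position segment
    counts 100, not 1), so they answer "what fraction of observed time is
    spent in each mode".
    """
    if not segments:
        raise ValueError("no segments to aggregate")
    pos_counts = {m: 0 for m in MODES}
    vs, Ds, lens = [], {m: [] for m in MODES}, {m: [] for m in MODES}
    for s in segments:
        pos_counts[s.mode] += s.n_positions
        lens[s.mode].append(s.duration_s)
        if s.D is not None:
            Ds[s.mode].append(s.D)
        if s.mode == "active" and s.v is not None:
            vs.append(s.v)
    total = sum(pos_counts.values())
    props = {m: pos_counts[m] / total for m in MODES}
    active_D = [s.D for s in segments if s.mode == "active" and s.D is not None]
    if active_D:
        rapid = float(np.mean(np.asarray(active_D) >= cutoff_D))
    else:
        rapid = float("nan")
    return SegmentStatistics(
        mode_proportions=props,
        velocity_distribution=np.array(vs),
        D_distribution={m: np.array(Ds[m]) for m in MODES},
        segment_length_distribution={m: np.array(lens[m]) for m in MODES},
        rapid_active_fraction=rapid,
        n_classified_positions=total,
    )


def rapid_transport_fraction(
    segments: Sequence[TrajectorySegment],
    cutoff_D: float = RAPID_TRANSPORT_CUTOFF_D,
) -> float:
    """Fraction of active segments with D at or above the rapid-transport cutoff.

    The default cutoff 0.01 μm²/s separates rapid microtubule-directed
    transport from the slower microfilament-associated regime. Returns NaN
    (with a warning) when no active segment carries a diffusion coefficient.
    """
    active_D = [s.D for s in segments if s.mode == "active" and s.D is not None]
    if not active_D:
        warnings.warn("no active segments: rapid-transport fraction undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.mean(np.asarray(active_D) >= cutoff_D))


def segments_to_table(segments: Sequence[TrajectorySegment]) -> pd.DataFrame:
    """Segment list as a flat table (one row per segment)."""
    return pd.DataFrame(
        [
            {
                "traj_id": s.traj_id,
                "start_frame": s.start_frame,
                "end_frame": s.end_frame,
                "mode": s.mode,
                "n_positions": s.n_positions,
                "duration_s": s.duration_s,
                "D": s.D,
                "v": s.v,
                "alpha": s.alpha,
                "fit_ok": s.fit_ok,
            }
            for s in segments
        ]
    )
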
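"""Mean-squared-displacement analysis and transport-mode model fits.

For a trajectory of positions (x_j, y_j) at frame interval Δt, the squared
displacement over a time lag τ = k·Δt is d²_j(k) = (x_{j+k}−x_j)² +
(y_{j+k}−y_j)². Averaging d² over all start frames j of one trajectory gives
the time-averaged MSD (TA-MSD); averaging TA-MSDs across trajectories gives
the ensemble-averaged MSD (EA-MSD).

The shape of MSD(τ) identifies the transport mode. The four 2D model forms
fitted here are::

    normal     MSD(τ) = 4·D·τ
    active     MSD(τ) = 4·D·τ + (v·τ)²
    anomalous  MSD(τ) = 4·D·τ^α        (α<1 subdiffusion, α>1 superdiffusion)
    confined   MSD(τ) = r_c²·(1 − A1·exp(−4·A2·D·τ / r_c²))

The normal, active and confined models are fitted by unweighted least
squares on the linear MSD values; the anomalous (power-law) model is fitted
by lag-weighted least squares in log-log space, where α is well conditioned
(see :func:`fit_anomalous_batch`). For the confined model only r_c², A1 and
the rate B = 4·A2·D/r_c² are identifiable; D is reported under the
convention A2 = 1.

The module also provides the whole-trajectory ("nonsegmented") analysis:
per-trajectory anomalous-exponent and diffusion-coefficient distributions,
fast/slow grouping by relative displacement, displacement PDFs with a
Gaussianity score, and the Stokes–Einstein conversion of D to a viscosity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trajectory_io import Trajectory, TrajectoryEnsemble

__all__ = [
    "MSDCurve",
    "ModelFit",
    "MobilityClassification",
    "MobilitySplit",
    "DisplacementPDF",
    "ViscosityEstimate",
    "BOLTZMANN_SI",
    "time_averaged_msd",
    "ensemble_msd",
    "default_lag_range",
    "fit_msd",
    "per_trajectory_anomaly",
    "relative_displacement",
    "classify_mobility",
    "displacement_pdf",
    "stokes_einstein_viscosity",
]

ModelName = Literal["normal", "active", "anomalous", "confined"]

BOLTZMANN_SI = 1.380649e-23  # J/K

ALPHA_BOUNDS = (0.1, 2.0)  # physical range admitted for the anomalous exponent


# ---------------------------------------------------------------------------
# MSD curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MSDCurve:
    """MSD values at lags τ = k·Δt with per-lag averaging counts."""

    taus: np.ndarray  # s, strictly increasing
    values: np.ndarray  # μm²
    counts: np.ndarray  # displacement pairs averaged per lag
    dt: float  # s

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        values = np.asarray(self.values, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "counts", counts)
        if not (len(taus) == len(values) == len(counts)):
            raise ValueError("taus, values, counts must have equal length")
        if len(taus) and np.any(np.diff(taus) <= 0):
            raise ValueError("taus must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("MSD values must be nonnegative")

    def __len__(self) -> int:
        return len(self.taus)

    @property
    def lags(self) -> np.ndarray:
        """Integer lags k = τ/Δt."""
        return np.rint(self.taus / self.dt).astype(int)


def time_averaged_msd(traj: Trajectory, max_lag_fraction: float = 1.0) -> MSDCurve:
    """Time-averaged MSD of one trajectory.

    One value per integer lag k = 1 .. floor(max_lag_fraction·(N−1)) where N−1
    counts frame intervals including linking gaps; pairs spanning gaps use the
    true frame difference, and lags with no surviving pair are omitted.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError(f"max_lag_fraction must lie in (0, 1], got {max_lag_fraction}")
    span = int(traj.frames[-1] - traj.frames[0])
    max_lag = max(1, int(math.floor(max_lag_fraction * span)))
    # dense frame grid with NaN at missing frames -> vectorized lag differences
    dense = np.full((span + 1, 2), np.nan)
    dense[traj.frames - traj.frames[0], 0] = traj.x
    dense[traj.frames - traj.frames[0], 1] = traj.y
    taus, values, counts = [], [], []
    for k in range(1, max_lag + 1):
        diff = dense[k:] - dense[:-k]
        sq = diff[:, 0] ** 2 + diff[:, 1] ** 2
        n = int(np.sum(~np.isnan(sq)))
        if n == 0:
            continue
        taus.append(k * traj.dt)
        values.append(float(np.nanmean(sq)))
        counts.append(n)
    return MSDCurve(np.array(taus), np.array(values), np.array(counts), traj.dt)


def ensemble_msd(curves: Sequence[MSDCurve]) -> MSDCurve:
    """Ensemble-averaged MSD: unweighted mean of per-trajectory TA-MSDs.

    A lag is present in the result if at least one input curve contributes to
    it; the counts record how many curves contributed per lag.
    """
    if not curves:
        raise ValueError("ensemble_msd needs at least one curve")
    dts = {c.dt for c in curves}
    if len(dts) > 1:
        raise ValueError(f"curves mix frame intervals: {sorted(dts)}")
    dt = curves[0].dt
    acc: dict[int, list[float]] = {}
    for c in curves:
        for k, v in zip(c.lags, c.values):
            acc.setdefault(int(k), []).append(float(v))
    lags = np.array(sorted(acc))
    values = np.array([np.mean(acc[k]) for k in lags])
    counts = np.array([len(acc[k]) for k in lags])
    return MSDCurve(lags * dt, values, counts, dt)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelFit:
    """Result of fitting one transport-mode model to an MSD curve.

    ``fit_error`` is the residual 2-norm relative to the data 2-norm;
    ``converged`` is False when the optimizer reported failure (the best
    iterate is still returned, flagged, rather than raising).
    """

    model: ModelName
    D: float
    fit_error: float
    lag_range: tuple[int, int]
    v: float | None = None
    alpha: float | None = None
    r_c: float | None = None
    A1: float | None = None
    A2: float | None = None
    converged: bool = True

    def predict(self, taus: np.ndarray) -> np.ndarray:
        taus = np.asarray(taus, dtype=float)
        if self.model == "normal":
            return 4.0 * self.D * taus
        if self.model == "active":
            return 4.0 * self.D * taus + (self.v * taus) ** 2
        if self.model == "anomalous":
            return 4.0 * self.D * np.power(taus, self.alpha)
        rc2 = self.r_c**2
        return rc2 * (1.0 - self.A1 * np.exp(-4.0 * self.A2 * self.D * taus / rc2))


def default_lag_range(n_positions: int) -> tuple[int, int]:
    """Default fit window: lags 1..max(3, floor(0.25·(N−1))).

    TA-MSD estimates lose accuracy at large lags (few independent pairs), so
    fits use the first quarter of the available lags, never fewer than 3.
    """
    return (1, max(3, int(math.floor(0.25 * (n_positions - 1)))))


def _relative_error(resid: np.ndarray, values: np.ndarray) -> float:
    norm = float(np.linalg.norm(values))
    if norm == 0.0:
        return float(np.linalg.norm(resid))
    return float(np.linalg.norm(resid)) / norm


def _fit_normal(tau: np.ndarray, m: np.ndarray) -> dict:
    D = max(0.0, float(np.dot(m, tau) / (4.0 * np.dot(tau, tau))))
    return {"D": D, "resid": 4.0 * D * tau - m}


def _fit_active(tau: np.ndarray, m: np.ndarray) -> dict:
    # linear LS in the basis {4τ, τ²} with nonnegativity by clipped refit
    A = np.column_stack([4.0 * tau, tau**2])
    coef, *_ = np.linalg.lstsq(A, m, rcond=None)
    D, v2 = coef
    if v2 < 0:
        fit = _fit_normal(tau, m)
        D, v2 = fit["D"], 0.0
    elif D < 0:
        D, v2 = 0.0, max(0.0, float(np.dot(m, tau**2) / np.dot(tau**2, tau**2)))
    D, v = float(D), float(np.sqrt(v2))
    return {"D": D, "v": v, "resid": 4.0 * D * tau + (v * tau) ** 2 - m}


def _fit_anomalous(tau: np.ndarray, m: np.ndarray) -> dict:
    # weighted log-log regression; see fit_anomalous_batch for the rationale
    out = fit_anomalous_batch(tau, m[None, :])
    D, alpha = float(out["D"][0]), float(out["alpha"][0])
    return {"D": D, "alpha": alpha, "resid": 4.0 * D * tau**alpha - m}


def _fit_confined(tau: np.ndarray, m: np.ndarray) -> dict:
    # identifiable parameterization: plateau P = r_c², amplitude A1, rate B
    P0 = max(float(np.max(m)), 1e-12)
    A10 = 1.0
    B0 = max(float(m[0] / (P0 * tau[0])), 1e-6)

    def resid(p):
        P, A1, B = p
        return P * (1.0 - A1 * np.exp(-B * tau)) - m

    sol = optimize.least_squares(
        resid,
        x0=[P0, A10, min(B0, 1e6)],
        bounds=([1e-12, 1e-6, 1e-8], [np.inf, 2.0, np.inf]),
        method="trf",
        x_scale=[P0, 1.0, max(B0, 1e-6)],
    )
    P, A1, B = sol.x
    return {
        "r_c": float(np.sqrt(P)),
        "A1": float(A1),
        "A2": 1.0,
        "D": float(B * P / 4.0),  # short-time slope/4 under the A2=1 convention
        "resid": sol.fun,
        "converged": bool(sol.success),
    }


_FITTERS = {
    "normal": _fit_normal,
    "active": _fit_active,
    "anomalous": _fit_anomalous,
    "confined": _fit_confined,
}


def fit_msd(
    curve: MSDCurve,
    model: ModelName,
    lag_range: tuple[int, int] | None = None,
) -> ModelFit:
    """Fit one transport-mode model to an MSD curve over a lag range.

    ``lag_range`` is an inclusive (k_min, k_max) pair of integer lags; the
    default covers the first quarter of the curve's lags. The fit is
    unweighted least squares on the linear MSD values and is deterministic.
    Non-convergence is reported through ``ModelFit.converged``, not raised.
    """
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}")
    lags = curve.lags
    if lag_range is None:
        lag_range = default_lag_range(int(lags[-1]) + 1 if len(lags) else 2)
    k_min, k_max = lag_range
    sel = (lags >= k_min) & (lags <= k_max)
    tau, m = curve.taus[sel], curve.values[sel]
    min_pts = 4 if model == "confined" else 3
    if len(tau) < min_pts:
        raise ValueError(
            f"{model} fit needs >= {min_pts} lags in range {lag_range}, got {len(tau)}"
        )
    if np.all(m == 0):
        # stationary trajectory: every model degenerates to MSD = 0
        out = {"D": 0.0, "resid": np.zeros_like(m)}
        if model == "active":
            out["v"] = 0.0
        elif model == "anomalous":
            out["alpha"] = 1.0
        elif model == "confined":
            out.update({"r_c": 0.0, "A1": 1.0, "A2": 1.0})
    else:
        out = _FITTERS[model](tau, m)
    resid = out.pop("resid")
    converged = out.pop("converged", True)
    return ModelFit(
        model=model,
        fit_error=_relative_error(resid, m),
        lag_range=(int(k_min), int(k_max)),
        converged=converged,
        **out,
    )


# ---------------------------------------------------------------------------
# Vectorized fits over many curves sharing one lag grid (rolling windows)
# ---------------------------------------------------------------------------


def _batch_rel_err(resid: np.ndarray, m: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(m, axis=1)
    out = np.linalg.norm(resid, axis=1)
    nz = norm > 0
    out[nz] = out[nz] / norm[nz]
    return out


def fit_normal_batch(tau: np.ndarray, m: np.ndarray) -> dict[str, np.ndarray]:
    """Closed-form 4Dτ fit for W curves stacked as m (W, K)."""
    D = np.clip(m @ tau / (4.0 * tau @ tau), 0.0, None)
    resid = 4.0 * D[:, None] * tau[None, :] - m
    return {"D": D, "err": _batch_rel_err(resid, m)}


def fit_active_batch(tau: np.ndarray, m: np.ndarray) -> dict[str, np.ndarray]:
    A = np.column_stack([4.0 * tau, tau**2])
    G = A.T @ A
    coef = np.linalg.solve(G, A.T @ m.T).T  # (W, 2)
    D, v2 = coef[:, 0].copy(), coef[:, 1].copy()
    # clip to the physical quadrant, refitting the free parameter
    neg_v = v2 < 0
    if np.any(neg_v):
        v2[neg_v] = 0.0
        D[neg_v] = np.clip(m[neg_v] @ tau / (4.0 * tau @ tau), 0.0, None)
    neg_D = D < 0
    if np.any(neg_D):
        D[neg_D] = 0.0
        t2 = tau**2
        v2[neg_D] = np.clip(m[neg_D] @ t2 / (t2 @ t2), 0.0, None)
    v = np.sqrt(v2)
    resid = 4.0 * D[:, None] * tau[None, :] + (v[:, None] * tau[None, :]) ** 2 - m
    return {"D": D, "v": v, "err": _batch_rel_err(resid, m)}


def fit_anomalous_batch(tau: np.ndarray, m: np.ndarray) -> dict[str, np.ndarray]:
    """Power-law fit 4Dτ^α for W stacked curves (closed form).

    The fit is a weighted least-squares regression of log MSD on log τ with
    weights 1/k (k the integer lag). The relative variance of a TA-MSD value
    grows roughly linearly in the lag for lags short against the trajectory,
    so 1/k approximates inverse-variance weighting of the log values; an
    unweighted fit on the linear MSD lets the noisiest long lags dominate and
    biases α visibly downward on Brownian data. Exact on noiseless power
    laws. α is clamped to the physical window [0.1, 2]; the reported
    ``err`` is the relative residual norm in linear space, comparable across
    models.
    """
    W = m.shape[0]
    k = tau / tau[0]  # integer lags as floats
    pos = m > 0
    w = np.where(pos, 1.0 / k[None, :], 0.0)
    wsum = w.sum(axis=1)
    ok = pos.sum(axis=1) >= 2
    wsum_safe = np.where(wsum > 0, wsum, 1.0)
    logt = np.log(tau)
    logm = np.where(pos, np.log(np.where(pos, m, 1.0)), 0.0)
    tbar = (w * logt[None, :]).sum(axis=1) / wsum_safe
    mbar = (w * logm).sum(axis=1) / wsum_safe
    tc = logt[None, :] - tbar[:, None]
    var = (w * tc**2).sum(axis=1)
    var_safe = np.where(var > 0, var, 1.0)
    alpha = (w * tc * (logm - mbar[:, None])).sum(axis=1) / var_safe
    alpha = np.clip(alpha, *ALPHA_BOUNDS)
    # refit the amplitude at the (possibly clamped) exponent
    logD = (w * (logm - alpha[:, None] * logt[None, :])).sum(axis=1) / wsum_safe
    D = np.exp(logD - np.log(4.0))
    alpha = np.where(ok, alpha, 1.0)
    D = np.where(ok, D, 0.0)
    zero_rows = np.all(m == 0, axis=1)
    alpha[zero_rows] = 1.0
    D[zero_rows] = 0.0
    pred = 4.0 * D[:, None] * np.power(tau[None, :], alpha[:, None])
    return {"D": D, "alpha": alpha, "err": _batch_rel_err(pred - m, m)}


def loglog_slope_batch(
    tau: np.ndarray, m: np.ndarray, with_se: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Unweighted log-log slope (and optionally its standard error) per row.

    Unlike the 1/k weighting of :func:`fit_anomalous_batch` (tuned for
    parameter estimation on long trajectories), the unweighted slope gives
    every lag of a short analysis window equal say, which is what a
    sub-/superdiffusion gate needs: the anomalous signature grows with the
    lag. The standard error is the ordinary regression SE from the log-space
    residuals; with few or noisy lags it grows, so significance-based gates
    automatically turn conservative on sparse windows. Rows with fewer than
    2 positive values report slope 1 (and an infinite SE).
    """
    pos = m > 0
    ok = pos.sum(axis=1) >= 2
    w = pos.astype(float)
    wsum = np.where(ok, w.sum(axis=1), 1.0)
    logt = np.log(tau)
    logm = np.where(pos, np.log(np.where(pos, m, 1.0)), 0.0)
    tbar = (w * logt[None, :]).sum(axis=1) / wsum
    mbar = (w * logm).sum(axis=1) / wsum
    tc = logt[None, :] - tbar[:, None]
    sxx = (w * tc**2).sum(axis=1)
    sxx_safe = np.where(sxx > 0, sxx, 1.0)
    slope = (w * tc * (logm - mbar[:, None])).sum(axis=1) / sxx_safe
    slope = np.where(ok, slope, 1.0)
    if not with_se:
        return slope
    resid = logm - (mbar[:, None] + slope[:, None] * tc)
    dof = np.maximum(wsum - 2.0, 1.0)
    rss = (w * resid**2).sum(axis=1)
    se = np.sqrt(rss / dof / sxx_safe)
    se = np.where(ok & (sxx > 0), se, np.inf)
    return slope, se


def fit_confined_batch(
    tau: np.ndarray, m: np.ndarray, n_iter: int = 40
) -> dict[str, np.ndarray]:
    """Gauss–Newton fit of P(1−A1·exp(−Bτ)) for W stacked curves.

    P = r_c² is the plateau; D is reported as B·P/4 (A2 = 1 convention).
    """
    W = m.shape[0]
    P = np.clip(np.max(m, axis=1), 1e-12, None)
    A1 = np.full(W, 1.0)
    B = np.clip(m[:, 0] / (P * tau[0]), 1e-6, 1e6)
    theta = np.column_stack([np.log(P), A1, np.log(B)])
    lam = np.full(W, 1e-3)

    def predict(th):
        return np.exp(th[:, 0])[:, None] * (
            1.0 - th[:, 1][:, None] * np.exp(-np.exp(th[:, 2])[:, None] * tau[None, :])
        )

    pred = predict(theta)
    cost = np.sum((pred - m) ** 2, axis=1)
    for _ in range(n_iter):
        Pv = np.exp(theta[:, 0])[:, None]
        A1v = theta[:, 1][:, None]
        Bv = np.exp(theta[:, 2])[:, None]
        E = np.exp(-Bv * tau[None, :])
        r = pred - m
        # Jacobian columns wrt (logP, A1, logB)
        J1 = pred
        J2 = -Pv * E
        J3 = Pv * A1v * E * Bv * tau[None, :]
        # normal equations with Levenberg damping, solved per row (3x3)
        JTJ = np.empty((W, 3, 3))
        JTr = np.empty((W, 3))
        for a, Ja in enumerate((J1, J2, J3)):
            JTr[:, a] = np.sum(Ja * r, axis=1)
            for b, Jb in enumerate((J1, J2, J3)):
                if b < a:
                    JTJ[:, a, b] = JTJ[:, b, a]
                else:
                    JTJ[:, a, b] = np.sum(Ja * Jb, axis=1)
        diag = np.arange(3)
        JTJ[:, diag, diag] *= (1.0 + lam)[:, None]
        JTJ[:, diag, diag] += 1e-12
        try:
            step = -np.linalg.solve(JTJ, JTr[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = -np.stack(
                [np.linalg.lstsq(JTJ[w], JTr[w], rcond=None)[0] for w in range(W)]
            )
        cand = theta + step
        cand[:, 1] = np.clip(cand[:, 1], 1e-6, 2.0)
        cand[:, 0] = np.clip(cand[:, 0], -700.0, 700.0)
        cand[:, 2] = np.clip(cand[:, 2], np.log(1e-8), np.log(1e8))
        cand_pred = predict(cand)
        cand_cost = np.sum((cand_pred - m) ** 2, axis=1)
        better = cand_cost <= cost
        theta[better] = cand[better]
        pred[better] = cand_pred[better]
        cost[better] = cand_cost[better]
        lam = np.where(better, lam * 0.3, lam * 5.0)
    P = np.exp(theta[:, 0])
    B = np.exp(theta[:, 2])
    zero_rows = np.all(m == 0, axis=1)
    r_c = np.sqrt(P)
    r_c[zero_rows] = 0.0
    D = B * P / 4.0
    D[zero_rows] = 0.0
    pred[zero_rows] = 0.0
    return {
        "r_c": r_c,
        "A1": theta[:, 1],
        "A2": np.ones(W),
        "D": D,
        "B": B,  # exponential rate 4·A2·D/r_c², 1/s
        "err": _batch_rel_err(pred - m, m),
    }


# ---------------------------------------------------------------------------
# Nonsegmented (whole-trajectory) analysis
# ---------------------------------------------------------------------------


def per_trajectory_anomaly(
    ensemble: TrajectoryEnsemble, max_lag_fraction: float = 0.25
) -> pd.DataFrame:
    """Anomalous-model fit per trajectory: columns id, D, alpha, fit_error.

    In a homogeneous medium the α_i distribution is narrow around 1 and its
    spread reflects finite trajectory length; broad or multimodal α_i
    distributions indicate mixed transport modes. Fit failures are recorded
    as NaN rows, not raised.
    """
    rows = []
    for t in ensemble:
        row = {"id": t.id, "n_positions": len(t)}
        try:
            curve = time_averaged_msd(t, max_lag_fraction=1.0)
            fit = fit_msd(curve, "anomalous", default_lag_range(len(t)))
            row.update(
                D=fit.D, alpha=fit.alpha, fit_error=fit.fit_error,
                converged=fit.converged,
            )
        except ValueError as exc:
            row.update(D=np.nan, alpha=np.nan, fit_error=np.nan, converged=False)
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MobilityClassification:
    """Relative displacement of one trajectory, scaled by sqrt(duration)."""

    scaled_dx: float  # (max x − min x)/sqrt(duration), μm s^-1/2
    scaled_dy: float
    group: str | None = None  # "fast" | "slow" once classified


def relative_displacement(traj: Trajectory) -> MobilityClassification:
    """Span of the trajectory per square root of its duration.

    For Brownian motion the spatial span grows as sqrt(t), so this statistic
    is duration-independent and separates fast from slow particles.
    """
    dur = traj.duration
    if dur <= 0:
        raise ValueError("trajectory duration must be positive")
    return MobilityClassification(
        scaled_dx=float(np.ptp(traj.x)) / math.sqrt(dur),
        scaled_dy=float(np.ptp(traj.y)) / math.sqrt(dur),
    )


@dataclass
class MobilitySplit:
    """Fast/slow partition of an ensemble by scaled relative displacement."""

    fast: TrajectoryEnsemble
    slow: TrajectoryEnsemble
    threshold: float  # μm s^-1/2
    table: pd.DataFrame  # id, scaled_dx, scaled_dy, group


def _auto_threshold(scores: np.ndarray) -> float:
    """Minimum-density split between the two modes of the score distribution.

    Kernel density estimate on log10 scores; the threshold is the density
    minimum between the two highest local maxima. Raises when the
    distribution is unimodal.
    """
    logs = np.log10(np.clip(scores, 1e-12, None))
    kde = stats.gaussian_kde(logs)
    grid = np.linspace(logs.min() - 0.25, logs.max() + 0.25, 512)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    unimodal = ValueError(
        "scaled-displacement distribution is unimodal; pass an explicit threshold"
    )
    if len(interior) < 2:
        raise unimodal
    top2 = interior[np.argsort(dens[interior])][-2:]
    lo, hi = sorted(top2)
    split = lo + int(np.argmin(dens[lo : hi + 1]))
    # a real second mode needs a genuine dip, not a bandwidth ripple
    if dens[split] > 0.8 * min(dens[lo], dens[hi]):
        raise unimodal
    return float(10 ** grid[split])


def classify_mobility(
    ensemble: TrajectoryEnsemble, threshold: float | None = None
) -> MobilitySplit:
    """Split an ensemble into fast and slow trajectories.

    A trajectory is fast iff max(scaled_dx, scaled_dy) exceeds the threshold
    (μm s^-1/2). With ``threshold=None`` the cut is placed automatically at
    the density minimum between the two modes of the pooled score
    distribution; this fails with an explanatory error when the distribution
    is unimodal.
    """
    if threshold is not None and not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    recs = []
    for t in ensemble:
        rd = relative_displacement(t)
        recs.append((t, rd, max(rd.scaled_dx, rd.scaled_dy)))
    if threshold is None:
        threshold = _auto_threshold(np.array([s for _, _, s in recs]))
    fast, slow, rows = [], [], []
    for t, rd, score in recs:
        group = "fast" if score > threshold else "slow"
        (fast if group == "fast" else slow).append(t)
        rows.append(
            {
                "id": t.id,
                "scaled_dx": rd.scaled_dx,
                "scaled_dy": rd.scaled_dy,
                "group": group,
            }
        )
    return MobilitySplit(
        fast=TrajectoryEnsemble(fast, ensemble.metadata),
        slow=TrajectoryEnsemble(slow, ensemble.metadata),
        threshold=threshold,
        table=pd.DataFrame(rows),
    )


@dataclass(frozen=True)
class DisplacementPDF:
    """Probability density of pooled 1D displacements at one time lag.

    For normal diffusion the PDF is Gaussian with variance 2·D·τ per axis;
    heavy tails (positive excess kurtosis) reveal mixed mobilities.
    """

    tau: float  # s
    bin_centers: np.ndarray  # μm
    density: np.ndarray  # μm^-1
    gaussian_sigma: float  # μm
    non_gaussianity: float  # excess kurtosis of the samples
    n_samples: int


def displacement_pdf(
    ensemble: TrajectoryEnsemble, tau: float, bins: int = 50
) -> DisplacementPDF:
    """Pooled axis-displacement PDF at lag ``tau`` with a Gaussianity score."""
    dt = ensemble.dt
    k = max(1, int(round(tau / dt)))
    samples = []
    for t in ensemble:
        span = int(t.frames[-1] - t.frames[0])
        if span < k:
            continue
        dense = np.full((span + 1, 2), np.nan)
        dense[t.frames - t.frames[0], 0] = t.x
        dense[t.frames - t.frames[0], 1] = t.y
        diff = dense[k:] - dense[:-k]
        samples.append(diff[~np.isnan(diff)])
    pooled = np.concatenate(samples) if samples else np.array([])
    if len(pooled) < 100:
        raise ValueError(
            f"displacement PDF at tau={tau} needs >= 100 samples, got {len(pooled)}"
        )
    sigma = float(np.std(pooled))
    if sigma == 0.0:
        raise ValueError("degenerate displacement distribution (zero width)")
    hist, edges = np.histogram(pooled, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DisplacementPDF(
        tau=k * dt,
        bin_centers=centers,
        density=hist,
        gaussian_sigma=sigma,
        non_gaussianity=float(stats.kurtosis(pooled, fisher=True)),
        n_samples=len(pooled),
    )


# ---------------------------------------------------------------------------
# Passive microrheology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViscosityEstimate:
    """Stokes–Einstein viscosity from a diffusion coefficient."""

    eta: float  # mPa·s
    D: float  # μm²/s
    d: float  # hydrodynamic diameter, nm
    T: float  # K


def stokes_einstein_viscosity(
    D: float, d: float, T: float = 293.15
) -> ViscosityEstimate:
    """Viscosity η = k_B·T / (3π·D·d) of the medium around a diffusing sphere.

    Parameters
    ----------
    D
        Diffusion coefficient, μm²/s.
    d
        Hydrodynamic particle diameter, nm.
    T
        Absolute temperature, K (default room temperature).

    Returns the viscosity in mPa·s (water at room temperature is ~1 mPa·s).
    """
    if not (D > 0 and d > 0 and T > 0):
        raise ValueError("D, d and T must all be positive")
    eta_pa_s = BOLTZMANN_SI * T / (3.0 * math.pi * (D * 1e-12) * (d * 1e-9))
    return ViscosityEstimate(eta=eta_pa_s * 1e3, D=D, d=d, T=T)
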
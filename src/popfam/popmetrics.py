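"""Population statistics: sparseness, selectivity, orientation tuning,
representation-overlap persistence, and plasticity ratios.

Population sparseness is the Treves-Rolls-type statistic

    S = [1 - (sum R / n)^2 / (sum R^2 / n)] / (1 - 1/n)

over per-neuron responses R (AUC of the trial-averaged dF/F0 during the
stimulus window): 0 for equal activity across the population, 1 when a
single neuron carries all activity. The natural-image selectivity index is
the same statistic without the finite-size normalization, computed over the
13 per-frame trial-averaged deconvolved amplitudes of a 3-s natural-image
set: 0 when every frame has the same amplitude, close to 1 when a single
frame carries the response.

Orientation tuning is the von Mises curve

    f(phi) = A * exp(K * (cos(2*(phi - theta)) - 1)) + b

fit to the four grating AUCs; fits are accepted when they explain at least
70% of the variance, and the tuning width is reported as the full width at
half maximum FWHM = arccos(ln(0.5*e^K + 0.5*e^-K) / K).

Representation persistence: each frame's population dF/F0 vector is unit
normalized and the mean dot-product overlap is computed at lags of 1-50
frames, then fit with Overlap(t) = (1 - b) * exp(tau * t) + b (tau <= 0,
0 <= b <= 1); the fitted curve equals 1 at zero lag by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TuningFit",
    "OverlapCurve",
    "population_sparseness",
    "selectivity_index",
    "von_mises",
    "fit_von_mises",
    "fwhm",
    "neural_overlap",
    "fit_overlap_decay",
    "plasticity_ratios",
]


# ---------------------------------------------------------------------------
# sparseness & selectivity


def _ratio_term(R: np.ndarray) -> float:
    """(sum R / n)^2 / (sum R^2 / n), the shared core of both statistics."""
    n = R.size
    ss = float(np.sum(R**2))
    if ss == 0:
        raise ValueError("all responses are zero; statistic undefined")
    return (float(np.sum(R)) / n) ** 2 / (ss / n)


def population_sparseness(R: np.ndarray) -> float:
    """Treves-Rolls population sparseness in [0, 1].

    Negative responses are clipped to 0 (the statistic assumes nonnegative
    responses); raises on an all-zero population.
    """
    R = np.clip(np.asarray(R, dtype=float).ravel(), 0.0, None)
    n = R.size
    if n < 2:
        raise ValueError("need at least 2 neurons")
    return (1.0 - _ratio_term(R)) / (1.0 - 1.0 / n)


def selectivity_index(frame_amplitudes: np.ndarray) -> float:
    """Natural-image selectivity: 1 - (sum R/n)^2 / (sum R^2/n), without the
    finite-size normalization, over per-frame trial-averaged amplitudes."""
    R = np.clip(np.asarray(frame_amplitudes, dtype=float).ravel(), 0.0, None)
    if R.size < 2:
        raise ValueError("need at least 2 frames")
    return 1.0 - _ratio_term(R)


# ---------------------------------------------------------------------------
# orientation tuning


@dataclass
class TuningFit:
    """Fitted von Mises orientation tuning of one neuron."""

    theta: float  # preferred orientation, radians in [0, pi)
    K: float  # tuning width parameter (larger = sharper)
    A: float  # response amplitude (dF/F0 * s)
    b: float  # intercept (dF/F0 * s)
    r2: float  # fraction of variance explained
    valid: bool  # r2 >= 0.7 and K > 0

    @property
    def fwhm(self) -> float:
        return fwhm(self.K) if self.valid else np.nan

    def __call__(self, phi: np.ndarray) -> np.ndarray:
        return von_mises(phi, self.theta, self.K, self.A, self.b)


def von_mises(phi: np.ndarray, theta: float, K: float, A: float, b: float) -> np.ndarray:
    """Orientation tuning curve A*exp(K*(cos(2*(phi - theta)) - 1)) + b."""
    return A * np.exp(K * (np.cos(2.0 * (np.asarray(phi, dtype=float) - theta)) - 1.0)) + b


def _circular_init(phi: np.ndarray, R: np.ndarray) -> tuple[float, float]:
    """Initial (theta, K) by weighted circular statistics on doubled angles.

    Weights are the baseline-subtracted responses; K comes from the inverse
    of the first Bessel-function ratio (the standard ML kappa estimate).
    """
    w = R - R.min()
    if w.sum() == 0:
        return float(phi[np.argmax(R)]) % np.pi, 1.0
    z = np.sum(w * np.exp(2j * phi)) / w.sum()
    theta0 = float(np.angle(z) / 2.0) % np.pi
    rbar = min(abs(z), 0.999)
    # Fisher's approximation to A1inv(rbar)
    if rbar < 0.53:
        k0 = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k0 = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k0 = 1 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    return theta0, max(float(k0), 1e-3)


def fit_von_mises(
    responses: np.ndarray,
    angles_deg: np.ndarray = (0, 45, 90, 135),
    r2_threshold: float = 0.7,
) -> TuningFit:
    """Fit the von Mises tuning curve to grating responses.

    theta and K are initialized by weighted circular maximum likelihood on
    the doubled angles and A, b by linear least squares; all four parameters
    are then refined jointly by nonlinear least squares (with four stimulus
    angles the curve interpolates exact von Mises data). Flat responses are
    rejected as invalid.
    """
    R = np.asarray(responses, dtype=float).ravel()
    phi = np.deg2rad(np.asarray(angles_deg, dtype=float).ravel())
    if R.size != phi.size or R.size < 4:
        raise ValueError("need one response per stimulus angle (>= 4)")
    if not np.isfinite(R).all():
        raise ValueError("non-finite responses")
    if np.ptp(R) == 0:
        return TuningFit(theta=np.nan, K=np.nan, A=np.nan, b=float(R[0]),
                         r2=np.nan, valid=False)
    theta0, k0 = _circular_init(phi, R)
    basis = np.exp(k0 * (np.cos(2.0 * (phi - theta0)) - 1.0))
    X = np.column_stack([basis, np.ones_like(basis)])
    (a0, b0), *_ = np.linalg.lstsq(X, R, rcond=None)

    def resid(p: np.ndarray) -> np.ndarray:
        th, lk, A, b = p
        return von_mises(phi, th, np.exp(lk), A, b) - R

    sol = least_squares(
        resid,
        x0=[theta0, np.log(k0), max(a0, 1e-6), b0],
        method="lm",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    theta, K, A, b = float(sol.x[0]) % np.pi, float(np.exp(sol.x[1])), float(sol.x[2]), float(sol.x[3])
    if A < 0:  # flip a negative amplitude onto the orthogonal orientation
        theta = (theta + np.pi / 2.0) % np.pi
        fitted = von_mises(phi, theta, K, abs(A), b)
        A = abs(A)
    else:
        fitted = von_mises(phi, theta, K, A, b)
    ss_res = float(np.sum((R - fitted) ** 2))
    ss_tot = float(np.sum((R - R.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return TuningFit(theta=theta, K=K, A=A, b=b, r2=r2,
                     valid=bool(r2 >= r2_threshold and K > 0))


def fwhm(K: float) -> float:
    """Full width at half maximum of the von Mises tuning curve,
    ``arccos(ln(0.5*e^K + 0.5*e^-K) / K)`` (radians)."""
    if K <= 0:
        raise ValueError("K must be positive")
    return float(np.arccos(np.log(0.5 * np.exp(K) + 0.5 * np.exp(-K)) / K))


# ---------------------------------------------------------------------------
# neural overlap


@dataclass
class OverlapCurve:
    """Mean population-vector overlap at lags 1..max_lag (frames)."""

    lags: np.ndarray  # frames
    overlap: np.ndarray  # mean unit-vector dot product per lag
    dt: float = 1.0  # seconds per frame (lags * dt = seconds)


def neural_overlap(
    dff: np.ndarray,
    window_frames: np.ndarray,
    max_lag: int = 50,
    dt: float = 1.0,
) -> OverlapCurve:
    """Mean overlap of unit-normalized population vectors across time lags.

    For each analysis frame t in ``window_frames`` and each lag l in
    1..max_lag, the overlap is the dot product of the unit-normalized
    population dF/F0 vectors at t and t+l, averaged over t per lag.
    Zero-norm frames are excluded from the average.
    """
    X = np.asarray(dff, dtype=float)
    window_frames = np.asarray(window_frames, dtype=int)
    if window_frames.size == 0:
        raise ValueError("empty analysis window")
    if window_frames.max() + max_lag >= X.shape[1]:
        raise ValueError("window too short: lags extend past the recording")
    norms = np.linalg.norm(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        U = np.where(norms > 0, X / norms, np.nan)
    lags = np.arange(1, max_lag + 1)
    overlap = np.empty(max_lag)
    for i, l in enumerate(lags):
        dots = np.einsum("ij,ij->j", U[:, window_frames], U[:, window_frames + l])
        overlap[i] = np.nanmean(dots)
    return OverlapCurve(lags=lags, overlap=overlap, dt=dt)


def fit_overlap_decay(curve: OverlapCurve) -> tuple[float, float]:
    """Fit Overlap(t) = (1 - b) * exp(tau * t) + b to the overlap curve.

    t is the lag in frames; constraints tau <= 0 and 0 <= b <= 1. The model
    passes through 1 at t = 0 by construction. Returns (tau, b).
    """
    t = np.asarray(curve.lags, dtype=float)
    y = np.asarray(curve.overlap, dtype=float)
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 5:
        raise ValueError("need at least 5 lags to fit the decay")
    b0 = float(np.clip(y.min(), 0.0, 0.999))
    resid0 = np.clip(y - b0, 1e-6, None)
    tau0 = float(np.polyfit(t, np.log(resid0), 1)[0])
    tau0 = min(tau0, -1e-6)

    def resid(p: np.ndarray) -> np.ndarray:
        tau, b = p
        return (1.0 - b) * np.exp(tau * t) + b - y

    sol = least_squares(resid, x0=[tau0, b0], bounds=([-np.inf, 0.0], [0.0, 1.0]))
    if not sol.success:
        raise RuntimeError("overlap decay fit did not converge")
    return float(sol.x[0]), float(sol.x[1])


# ---------------------------------------------------------------------------
# plasticity ratios


def plasticity_ratios(pre: dict, post: dict) -> dict:
    """Post/pre-training ratios of session summary statistics.

    ``pre`` and ``post`` map statistic names (e.g. ``auc``,
    ``active_fraction``, ``mean_degree``, ``high_responder_fraction``,
    ``tau``) to scalars; only keys present in both are reported. A zero
    pre-training denominator yields NaN (flagged undefined).
    """
    out: dict[str, float] = {}
    for key in pre:
        if key not in post:
            continue
        denom = float(pre[key])
        out[key] = float(post[key]) / denom if denom != 0 else float("nan")
    return out
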
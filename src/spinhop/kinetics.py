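"""Mono- and biexponential fitting of population traces.

Saturating-rise forms are used for populations that grow from zero
(ground-state plus lowest-triplet recovery) and the mirrored decays for
populations that start at one (bright ππ* depopulation):

    mono-rise   P(t) = 1 − e^(−t/τ)
    bi-rise     P(t) = 1 − a·e^(−t/τ₁) − (1−a)·e^(−t/τ₂)
    mono-decay  P(t) = e^(−t/τ)
    bi-decay    P(t) = a·e^(−t/τ₁) + (1−a)·e^(−t/τ₂)

with time zero fixed at the (δ-pulse) excitation and no instrument
response.  Fits are unweighted nonlinear least squares, multi-started
from a log-spaced τ grid to avoid local minima; parameter uncertainties
are asymptotic standard errors from the scaled inverse Gauss–Newton
normal matrix at the optimum.  They quantify the fit alone, not the
sampling noise correlations of a finite trajectory ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FitResult",
    "FitError",
    "fit_exponential",
    "compare_fits",
    "counting_noise_trace",
    "MODEL_FORMS",
]

MODEL_FORMS = ("mono-rise", "bi-rise", "mono-decay", "bi-decay")


class FitError(RuntimeError):
    """Fit failed to converge; the message carries diagnostics."""


@dataclass(frozen=True)
class FitResult:
    """Decay-model fit: time constants with asymptotic standard errors,
    the fast-component amplitude fraction for biexponential forms, and the
    residual sum of squares.  τ₁ ≤ τ₂ by convention."""

    model_form: str
    tau_fs: tuple[float, ...]
    tau_stderr_fs: tuple[float, ...]
    amplitude: Optional[float]
    amplitude_stderr: Optional[float]
    rss: float
    n_points: int
    at_bounds: bool

    @property
    def n_parameters(self) -> int:
        return len(self.tau_fs) + (0 if self.amplitude is None else 1)

    def summary(self) -> str:
        parts = [
            f"tau{i + 1} = {t:.6g} +/- {s:.2g} fs"
            for i, (t, s) in enumerate(zip(self.tau_fs, self.tau_stderr_fs))
        ]
        if self.amplitude is not None:
            parts.append(
                f"a = {self.amplitude:.3f} +/- {self.amplitude_stderr:.2g}"
            )
        flag = " [at bounds]" if self.at_bounds else ""
        return f"{self.model_form}: " + ", ".join(parts) + flag


def _model(form: str, t: np.ndarray, params: np.ndarray) -> np.ndarray:
    if form == "mono-rise":
        return 1.0 - np.exp(-t / params[0])
    if form == "mono-decay":
        return np.exp(-t / params[0])
    a = params[2]
    decay = a * np.exp(-t / params[0]) + (1.0 - a) * np.exp(-t / params[1])
    if form == "bi-rise":
        return 1.0 - decay
    if form == "bi-decay":
        return decay
    raise ValueError(f"unknown model form: {form!r}")


def fit_exponential(
    times_fs: np.ndarray,
    values: np.ndarray,
    model_form: str,
    initial_guess: Sequence[float] | None = None,
) -> FitResult:
    """Fit one of the exponential forms to a population trace.

    ``initial_guess`` is (τ,) or (τ₁, τ₂, a); when omitted, a 3×3
    log-spaced (τ₁, τ₂) grid (3 points for monoexponentials) spanning the
    sampled time range seeds a multi-start search and the best optimum is
    kept.  Raises :class:`FitError` on non-convergence; τ estimates at the
    search bounds are flagged, never silently returned as converged.
    """
    if model_form not in MODEL_FORMS:
        raise ValueError(f"model_form must be one of {MODEL_FORMS}")
    t = np.asarray(times_fs, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    n_par = 1 if model_form.startswith("mono") else 3
    if len(t) < 3 * n_par:
        raise ValueError("trace must have at least 3 points per free parameter")
    if np.any((y < -1e-9) | (y > 1 + 1e-9)):
        raise ValueError("population values must lie in [0, 1]")

    t_span = max(t.max() - t.min(), 1e-12)
    lo_tau, hi_tau = t_span * 1e-4, t_span * 1e4
    if n_par == 1:
        bounds = ([lo_tau], [hi_tau])
        if initial_guess is not None:
            starts = [np.asarray(initial_guess, dtype=float)]
        else:
            starts = [np.array([g]) for g in np.geomspace(t_span / 30, 3 * t_span, 3)]
    else:
        bounds = ([lo_tau, lo_tau, 0.0], [hi_tau, hi_tau, 1.0])
        if initial_guess is not None:
            starts = [np.asarray(initial_guess, dtype=float)]
        else:
            g1 = np.geomspace(t_span / 100, t_span, 3)
            g2 = np.geomspace(t_span / 10, 10 * t_span, 3)
            starts = [np.array([a, b, 0.5]) for a in g1 for b in g2]

    def residuals(p: np.ndarray) -> np.ndarray:
        return _model(model_form, t, p) - y

    best = None
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            sol = least_squares(residuals, p0, bounds=bounds, method="trf")
        except Exception:  # ill-conditioned start; try the next one
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError(
            f"no start converged for {model_form} on {len(t)} points"
        )

    p = best.x
    rss = float(2.0 * best.cost)
    rss_const = float(np.sum((y - y.mean()) ** 2))
    if rss >= rss_const and rss_const >= 0:
        raise FitError(
            f"{model_form} does not describe the trace better than a "
            f"constant (RSS {rss:.3g} vs {rss_const:.3g}); "
            "the model form is misspecified for this data"
        )
    dof = len(t) - n_par
    jac = best.jac
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * (rss / dof)
        stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        raise FitError(
            f"singular normal matrix for {model_form}: parameters not "
            f"identifiable (estimate {p})"
        )

    at_bounds = bool(
        np.any(p <= np.asarray(bounds[0]) * (1 + 1e-6))
        or np.any(p >= np.asarray(bounds[1]) * (1 - 1e-6))
    )
    if n_par == 1:
        taus, errs = (float(p[0]),), (float(stderr[0]),)
        amp = amp_err = None
    else:
        order = np.argsort(p[:2])
        taus = tuple(float(p[i]) for i in order)
        errs = tuple(float(stderr[i]) for i in order)
        # amplitude convention: a is the fraction of the fast component
        amp = float(p[2]) if order[0] == 0 else float(1.0 - p[2])
        amp_err = float(stderr[2])
    return FitResult(
        model_form=model_form,
        tau_fs=taus,
        tau_stderr_fs=errs,
        amplitude=amp,
        amplitude_stderr=amp_err,
        rss=rss,
        n_points=len(t),
        at_bounds=at_bounds,
    )


def compare_fits(
    fit_a: FitResult, fit_b: FitResult, n_points: int | None = None
) -> tuple[FitResult, dict[str, float]]:
    """Small-sample information-criterion (AICc) comparison of two fits of
    the same trace.  Returns the preferred fit and both scores; with equal
    residuals the model with fewer parameters wins."""
    n = n_points if n_points is not None else fit_a.n_points
    if fit_b.n_points != fit_a.n_points:
        raise ValueError("fits must be on the same trace")

    def aicc(fit: FitResult) -> float:
        k = fit.n_parameters + 1  # + residual variance
        rss = max(fit.rss, 1e-300)
        score = n * np.log(rss / n) + 2 * k
        if n - k - 1 > 0:
            score += 2 * k * (k + 1) / (n - k - 1)
        return float(score)

    scores = {fit_a.model_form: aicc(fit_a), fit_b.model_form: aicc(fit_b)}
    if scores[fit_a.model_form] <= scores[fit_b.model_form]:
        return fit_a, scores
    return fit_b, scores


def counting_noise_trace(
    model_form: str,
    params: Sequence[float],
    times_fs: np.ndarray,
    n_trajectories: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthetic population trace with counting (shot) noise: at each grid
    time the observed fraction is an independent Binomial(n, P(t))/n draw
    around the exact curve.  Used for fitter-calibration studies."""
    t = np.asarray(times_fs, dtype=float)
    p = np.clip(_model(model_form, t, np.asarray(params, dtype=float)), 0.0, 1.0)
    return rng.binomial(n_trajectories, p) / n_trajectories
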
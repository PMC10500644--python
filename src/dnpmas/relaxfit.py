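"""Relaxation-model fitting for DNP MAS NMR build-up and echo decays.

Three models cover the measurements that fix acquisition parameters and
diagnose line broadening:

* saturation recovery, ``I(t) = A * (1 - exp(-t/T1))`` — longitudinal
  1H relaxation; T1 sets the optimal recycle delay;
* Hahn-echo decay, ``I(t) = A * exp(-t/T2)`` — homogeneous transverse
  relaxation (e.g. amide 15N);
* J-modulated Hahn-echo decay, ``I(t) = A * exp(-t/T2) * cos(pi*J*t)`` —
  carbonyl 13C echoes, where the one-bond CO-Calpha scalar coupling
  (1J = 50.7 Hz in proteins) modulates the refocused signal.  J is held
  fixed during fitting; t is the *total* echo evolution time (2*tau).

The modulated model is fit in signed form: sign inversions past the
cosine zero at t = 1/(2J) carry information and magnitude processing is
deliberately not assumed.  Confidence intervals come from the linearized
covariance at the optimum scaled by a Student-t quantile; a residual
bootstrap is available for small n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DataError, NumericalError

#: One-bond CO-Calpha scalar coupling in proteins, Hz.
J_CO_CA_HZ: float = 50.7

_UNIT_TO_S = {"s": 1.0, "ms": 1e-3}


@dataclass
class RelaxationCurve:
    """A delay/intensity series from an integrated relaxation experiment.

    ``delays`` are in ``time_unit`` ("s" or "ms"); for echo experiments
    they are total echo evolution times (convert tau -> 2*tau on read).
    ``ground_truth`` carries generative parameters when the curve is
    synthetic.
    """

    delays: np.ndarray
    intensities: np.ndarray
    kind: str  # "saturation_recovery" | "hahn_echo"
    site: str = ""
    time_unit: str = "s"
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.shape != self.intensities.shape:
            raise DataError("delays and intensities differ in length")
        if self.delays.ndim != 1 or self.delays.size < 3:
            raise DataError("need at least 3 (delay, intensity) points")
        if np.any(self.delays < 0):
            raise DataError("delays must be non-negative")
        if np.any(np.diff(self.delays) <= 0):
            raise DataError("delays must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise DataError("intensities must be finite")
        if self.time_unit not in _UNIT_TO_S:
            raise DataError(f"unknown time unit {self.time_unit!r}")
        if self.kind not in ("saturation_recovery", "hahn_echo"):
            raise DataError(f"unknown curve kind {self.kind!r}")

    @property
    def delays_s(self) -> np.ndarray:
        return self.delays * _UNIT_TO_S[self.time_unit]


@dataclass
class FitResult:
    """Best-fit parameters with 95% confidence half-widths.

    Times are in the unit of the fitted curve (``time_unit``).
    """

    model: str
    params: dict[str, float]
    ci95: dict[str, float]
    rss: float
    converged: bool
    n_points: int
    time_unit: str = "s"
    message: str = ""
    extras: dict = field(default_factory=dict)

    def covers(self, name: str, value: float) -> bool:
        """Does the 95% CI of parameter ``name`` contain ``value``?"""
        p, hw = self.params[name], self.ci95[name]
        return (p - hw) <= value <= (p + hw)


def saturation_recovery_model(t: np.ndarray, A: float, T1: float) -> np.ndarray:
    return A * (1.0 - np.exp(-np.asarray(t, float) / T1))


def echo_decay_model(
    t: np.ndarray, A: float, T2: float, J_hz: float | None = None, time_unit: str = "s"
) -> np.ndarray:
    """Signed Hahn-echo decay; ``t`` is total echo time in ``time_unit``."""
    t = np.asarray(t, dtype=float)
    decay = A * np.exp(-t / T2)
    if J_hz is not None:
        decay = decay * np.cos(np.pi * J_hz * t * _UNIT_TO_S[time_unit])
    return decay


def _ci_halfwidths(pcov: np.ndarray, n: int, n_par: int) -> np.ndarray:
    dof = max(n - n_par, 1)
    tval = stats.t.ppf(0.975, dof)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return tval * se


def _loglinear_T(t: np.ndarray, y: np.ndarray) -> float:
    """Decay time from a log-linear regression; robust fallback 1.0."""
    mask = y > 0
    if mask.sum() >= 2 and np.ptp(t[mask]) > 0:
        slope = np.polyfit(t[mask], np.log(y[mask]), 1)[0]
        if slope < 0:
            return -1.0 / slope
    span = np.ptp(t)
    return span / 3 if span > 0 else 1.0


def _failed(model: str, names: list[str], n: int, unit: str, msg: str) -> FitResult:
    nan = float("nan")
    return FitResult(
        model=model,
        params={k: nan for k in names},
        ci95={k: nan for k in names},
        rss=nan,
        converged=False,
        n_points=n,
        time_unit=unit,
        message=msg,
    )


def fit_saturation_recovery(curve: RelaxationCurve) -> FitResult:
    """Fit ``A * (1 - exp(-t/T1))`` to a saturation-recovery build-up."""
    if curve.kind != "saturation_recovery":
        raise DataError(f"expected a saturation_recovery curve, got {curve.kind!r}")
    t, y = curve.delays, curve.intensities
    names = ["A", "T1"]
    A0 = float(np.max(y))
    if A0 <= 0 or not np.any(y > 0):
        return _failed("saturation_recovery", names, t.size, curve.time_unit,
                       "degenerate intensities (no positive signal)")
    # log-linear init on the approach to the plateau
    T0 = _loglinear_T(t, np.clip(A0 * 1.05 - y, 1e-12 * A0, None))
    try:
        popt, pcov = optimize.curve_fit(
            saturation_recovery_model, t, y, p0=[A0, max(T0, 1e-9)], maxfev=10000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        return _failed("saturation_recovery", names, t.size, curve.time_unit, str(exc))
    resid = y - saturation_recovery_model(t, *popt)
    hw = _ci_halfwidths(pcov, t.size, 2)
    ok = popt[1] > 0 and np.all(np.isfinite(popt))
    return FitResult(
        model="saturation_recovery",
        params=dict(zip(names, map(float, popt))),
        ci95=dict(zip(names, map(float, hw))),
        rss=float(resid @ resid),
        converged=bool(ok),
        n_points=t.size,
        time_unit=curve.time_unit,
    )


def fit_echo_decay(curve: RelaxationCurve, J_fixed_hz: float | None = None) -> FitResult:
    """Fit a (possibly J-modulated) Hahn-echo decay.

    With ``J_fixed_hz`` the model is ``A*exp(-t/T2)*cos(pi*J*t)`` with J
    held at the given value; otherwise a plain exponential.  Curves with
    J modulation need >= 4 points so the envelope is determined on both
    sides of the cosine zero.
    """
    if curve.kind != "hahn_echo":
        raise DataError(f"expected a hahn_echo curve, got {curve.kind!r}")
    if J_fixed_hz is not None:
        if J_fixed_hz <= 0:
            raise DataError("J_fixed_hz must be positive")
        if curve.delays.size < 4:
            raise DataError("J-modulated fit needs at least 4 points")
    t, y = curve.delays, curve.intensities
    names = ["A", "T2"]
    if not np.any(np.abs(y) > 0):
        return _failed("j_modulated_echo" if J_fixed_hz else "exponential_echo",
                       names, t.size, curve.time_unit, "all-zero intensities")

    unit = curve.time_unit
    if J_fixed_hz is None:
        model_name = "exponential_echo"
        def f(tt, A, T2):
            return echo_decay_model(tt, A, T2, None, unit)
        env_mask = np.ones_like(t, dtype=bool)
        env = np.abs(y)
    else:
        model_name = "j_modulated_echo"
        def f(tt, A, T2):
            return echo_decay_model(tt, A, T2, J_fixed_hz, unit)
        cosine = np.cos(np.pi * J_fixed_hz * t * _UNIT_TO_S[unit])
        env_mask = np.abs(cosine) > 0.3  # away from the modulation zeros
        env = np.abs(np.divide(y, cosine, out=np.zeros_like(y), where=cosine != 0))

    A0 = float(np.max(env[env_mask])) if env_mask.any() else float(np.max(np.abs(y)))
    T0 = _loglinear_T(t[env_mask], env[env_mask]) if env_mask.any() else 1.0
    try:
        popt, pcov = optimize.curve_fit(f, t, y, p0=[A0, max(T0, 1e-9)], maxfev=10000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        return _failed(model_name, names, t.size, unit, str(exc))
    resid = y - f(t, *popt)
    hw = _ci_halfwidths(pcov, t.size, 2)
    ok = popt[1] > 0 and np.all(np.isfinite(popt)) and np.all(np.isfinite(hw))
    result = FitResult(
        model=model_name,
        params=dict(zip(names, map(float, popt))),
        ci95=dict(zip(names, map(float, hw))),
        rss=float(resid @ resid),
        converged=bool(ok),
        n_points=t.size,
        time_unit=unit,
    )
    if J_fixed_hz is not None:
        result.extras["J_hz"] = J_fixed_hz
    return result


def bootstrap_ci(
    curve: RelaxationCurve,
    fit: FitResult,
    n_boot: int = 500,
    seed: int = 0,
) -> dict[str, float]:
    """Residual-bootstrap 95% half-widths as a small-n alternative.

    Resamples residuals around the fitted curve, refits, and reports half
    the central-95% percentile spread per parameter.
    """
    if not fit.converged:
        raise NumericalError("cannot bootstrap a non-converged fit")
    rng = np.random.default_rng(seed)
    t, y = curve.delays, curve.intensities
    J = fit.extras.get("J_hz")
    if fit.model == "saturation_recovery":
        def predict(tt, A, T):
            return saturation_recovery_model(tt, A, T)
        refit = fit_saturation_recovery
        kwargs = {}
    else:
        def predict(tt, A, T):
            return echo_decay_model(tt, A, T, J, curve.time_unit)
        refit = fit_echo_decay
        kwargs = {"J_fixed_hz": J}
    yhat = predict(t, fit.params["A"], fit.params["T1" if "T1" in fit.params else "T2"])
    resid = y - yhat
    draws: dict[str, list[float]] = {k: [] for k in fit.params}
    for _ in range(n_boot):
        yb = yhat + rng.choice(resid, size=resid.size, replace=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cb = RelaxationCurve(t, yb, kind=curve.kind, time_unit=curve.time_unit)
                rb = refit(cb, **kwargs)
            except DataError:
                continue
        if rb.converged:
            for k, v in rb.params.items():
                draws[k].append(v)
    out = {}
    for k, vals in draws.items():
        if len(vals) < max(20, n_boot // 10):
            raise NumericalError("bootstrap refits failed too often")
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[k] = float((hi - lo) / 2)
    return out


def homogeneous_linewidth(T2_s: float) -> float:
    """FWHM (Hz) of the homogeneous Lorentzian implied by T2 (seconds).

    ``1 / (pi * T2)``; the yardstick against which an observed linewidth
    is judged homogeneous or inhomogeneous.
    """
    if T2_s <= 0:
        raise DataError("T2 must be positive")
    return 1.0 / (np.pi * T2_s)
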
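"""Nonlinear least-squares fitting of activation profiles and AIC selection.

Each trace is fitted to the single-activation profile (3 parameters: A, k_f,
k_d), optionally with the time origin shifted to a later context exposure
("delayed" fit), and to the double-activation profile (4 parameters, adding
t_d).  Fits are unweighted least squares.  The amplitude enters the model
linearly, so it is profiled out analytically (variable projection) and the
optimiser works on the rate constants (in log space, enforcing positivity)
and t_d only; a deterministic set of rate starting points -- the published
initialisation k_f = 0.01, k_d = 0.001 min^-1 first -- guards against the
local minima that single-start Levenberg-Marquardt falls into when the
imaging window begins after the expression peak.  A final full-parameter
refinement provides the Jacobian-based standard errors.

Goodness of fit uses the adjusted R^2 (threshold 0.5 to call a cell
activated) and the least-squares Akaike Information Criterion
AIC = n ln(RSS/n) + 2 (p + 1), counting the noise variance as a parameter;
the candidate model with the lowest AIC wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import DEGENERACY_RTOL, DualActivationParams, KineticParams, dac_shape, sac_shape
from .traces import FluorescenceTrace

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_sac",
    "fit_dac",
    "adjusted_r_squared",
    "aic",
    "select_model",
    "fit_results_frame",
]

#: Auxiliary deterministic rate starts (k_f, k_d) in min^-1, spanning the
#: slow-to-fast range observed across fitted cells; the configured
#: initialisation is always tried first.
DEFAULT_EXTRA_STARTS = (
    (0.0369, 0.016),
    (0.04, 0.006),
    (0.1, 0.02),
    (0.3, 0.05),
    (0.005, 0.003),
)


@dataclass(frozen=True)
class FitConfig:
    """Fitting and model-selection settings.

    ``kf_init``/``kd_init``/``td_init`` are the published starting values;
    ``amplitude_init_rule`` is kept for provenance (the variable-projection
    solver computes the optimal amplitude in closed form at every step, which
    subsumes starting A at the maximum observed fluorescence).
    """

    kf_init: float = 0.01
    kd_init: float = 0.001
    td_init: float = 60.0
    amplitude_init_rule: str = "max_observed"
    adj_r2_threshold: float = 0.5
    delay_offset: float = 60.0
    rate_lower_bound: float = 1e-6
    extra_rate_starts: tuple = DEFAULT_EXTRA_STARTS
    degenerate_refit_rtol: float = 1e-4
    max_nfev: int = 1000
    ftol: float = 1e-12
    xtol: float = 1e-12

    def __post_init__(self) -> None:
        if not (0 <= self.adj_r2_threshold <= 1):
            raise ValueError("adj_r2_threshold must lie in [0, 1]")
        if min(self.kf_init, self.kd_init, self.td_init) <= 0:
            raise ValueError("initial values must be > 0")


DEFAULT_CONFIG = FitConfig()


@dataclass
class FitResult:
    """One model fit to one trace."""

    model_kind: str  # SAC | SAC_DELAYED | DAC
    time_origin_offset: float
    params: KineticParams | DualActivationParams | None
    stderr: dict
    rss: float
    n_points: int
    n_params: int
    adj_r2: float
    aic: float
    converged: bool
    degenerate_rates: bool = False


def adjusted_r_squared(rss: float, tss: float, n: int, p: int) -> float:
    """Adjusted coefficient of determination.

    1 - (RSS / (n - p - 1)) / (TSS / (n - 1)).  Returns NaN when TSS is 0
    (a constant trace has no variance to explain).
    """
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 points, got n={n}, p={p}")
    if tss <= 0:
        return float("nan")
    return 1.0 - (rss / (n - p - 1)) / (tss / (n - 1))


def aic(rss: float, n: int, p: int) -> float:
    """Least-squares AIC, n ln(RSS/n) + 2 (p + 1).

    The +1 counts the estimated noise variance.  A perfect fit (RSS = 0)
    returns -inf.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss == 0:
        return -math.inf
    return n * math.log(rss / n) + 2.0 * (p + 1)


def _vp_solve(t, y, shape_fn, starts, bounds, config):
    """Variable-projection multistart: minimise ||A(theta) s(theta) - y||."""

    def residual(theta):
        s = shape_fn(t, theta)
        ss = float(s @ s)
        amp = max(0.0, float(s @ y) / ss) if ss > 0 else 0.0
        return amp * s - y

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residual,
                x0,
                bounds=bounds,
                max_nfev=config.max_nfev,
                ftol=config.ftol,
                xtol=config.xtol,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _polish(t, y, model_fn, p0, bounds, config):
    """Full-parameter refinement; returns (popt, stderr, rss, success)."""
    sol = least_squares(
        lambda p: model_fn(t, p) - y,
        p0,
        bounds=bounds,
        max_nfev=config.max_nfev,
        ftol=config.ftol,
        xtol=config.xtol,
    )
    rss = 2.0 * sol.cost
    n, p = t.size, len(p0)
    stderr = np.full(p, np.nan)
    if n > p:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(jtj) * (rss / (n - p))
            stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            pass
    return sol.x, stderr, rss, bool(sol.success)


def _make_result(model_kind, offset, params, stderr_names, stderr, rss, y, n_params, success, degenerate):
    n = y.size
    tss = float(np.sum((y - y.mean()) ** 2))
    if success and n > n_params + 1:
        r2 = adjusted_r_squared(rss, tss, n, n_params)
        a = aic(rss, n, n_params)
    else:
        r2, a = float("nan"), float("nan")
    return FitResult(
        model_kind=model_kind,
        time_origin_offset=offset,
        params=params,
        stderr=dict(zip(stderr_names, stderr)),
        rss=float(rss),
        n_points=n,
        n_params=n_params,
        adj_r2=r2,
        aic=a,
        converged=success,
        degenerate_rates=degenerate,
    )


def _rate_starts(config):
    starts = [(config.kf_init, config.kd_init), *config.extra_rate_starts]
    return [np.log([kf, kd]) for kf, kd in starts]


def _canonical_rates(amp, kf, kd):
    """Resolve the rate-swap aliasing of the profile.

    F1 is invariant under (k_f, k_d) -> (k_d, k_f) with A -> A k_f / k_d, so
    the labelling is a convention; report k_f >= k_d (formation faster than
    degradation, as observed for these fluorophore constructs).
    """
    if kf < kd:
        return amp * kf / kd, kd, kf
    return amp, kf, kd


def _limit_sac_model(t, p):
    amp, k = p
    return amp * k * t * np.exp(-k * np.clip(t, 0.0, None))


def fit_sac(
    trace: FluorescenceTrace,
    config: FitConfig = DEFAULT_CONFIG,
    time_origin_offset: float = 0.0,
) -> FitResult:
    """Fit the single-activation profile, optionally with a shifted origin.

    Only points with t >= ``time_origin_offset`` are fitted (at least 5
    required).  When the optimum collapses onto equal rates the
    two-parameter equal-rate limit model is refitted and reported with
    ``degenerate_rates`` set.
    """
    mask = trace.time_points >= time_origin_offset
    if mask.sum() < 5:
        raise ValueError(
            f"need >= 5 points with t >= {time_origin_offset}, got {int(mask.sum())}"
        )
    t = trace.time_points[mask] - time_origin_offset
    y = trace.values[mask]
    kind = "SAC_DELAYED" if time_origin_offset > 0 else "SAC"

    lb = math.log(config.rate_lower_bound)
    best = _vp_solve(
        t,
        y,
        lambda tt, th: sac_shape(tt, *np.exp(th)),
        _rate_starts(config),
        ([lb, lb], [8.0, 8.0]),
        config,
    )
    if best is None:
        return _make_result(kind, time_origin_offset, None, (), (), np.nan, y, 3, False, False)

    kf0, kd0 = np.exp(best.x)
    s = sac_shape(t, kf0, kd0)
    amp0 = max(0.0, float(s @ y) / max(float(s @ s), 1e-300))
    amp0, kf0, kd0 = _canonical_rates(amp0, kf0, kd0)
    popt, stderr, rss, ok = _polish(
        t,
        y,
        lambda tt, p: p[0] * sac_shape(tt, p[1], p[2]),
        [amp0, kf0, kd0],
        ([0.0, config.rate_lower_bound, config.rate_lower_bound], [np.inf, np.inf, np.inf]),
        config,
    )
    amp, kf, kd = popt

    if abs(kf - kd) < config.degenerate_refit_rtol * max(kf, kd):
        k0 = 0.5 * (kf + kd)
        popt2, stderr2, rss2, ok2 = _polish(
            t,
            y,
            _limit_sac_model,
            [amp, k0],
            ([0.0, config.rate_lower_bound], [np.inf, np.inf]),
            config,
        )
        if ok2 and rss2 <= rss * (1.0 + 1e-9):
            amp2, k2 = popt2
            params = KineticParams(amp2, k2, k2) if amp2 >= 0 else None
            return _make_result(
                kind,
                time_origin_offset,
                params,
                ("amplitude", "k"),
                stderr2,
                rss2,
                y,
                2,
                ok2,
                True,
            )

    params = KineticParams(max(amp, 0.0), kf, kd)
    return _make_result(
        kind,
        time_origin_offset,
        params,
        ("amplitude", "k_f", "k_d"),
        stderr,
        rss,
        y,
        3,
        ok,
        abs(kf - kd) < DEGENERACY_RTOL * max(kf, kd),
    )


def _limit_dac_model(t, p):
    amp, k, td = p
    first = k * t * np.exp(-k * t)
    t2 = t - td
    second = np.where(t2 >= 0, k * np.clip(t2, 0, None) * np.exp(-k * np.clip(t2, 0, None)), 0.0)
    return amp * (first + second)


def fit_dac(trace: FluorescenceTrace, config: FitConfig = DEFAULT_CONFIG) -> FitResult:
    """Fit the double-activation profile (A, k_f, k_d, t_d).

    t_d starts at the configured second-exposure delay and is bounded to
    [0, last time point].
    """
    if len(trace) < 6:
        raise ValueError(f"need >= 6 points for the 4-parameter fit, got {len(trace)}")
    t, y = trace.time_points, trace.values
    td_max = float(t.max())
    lb = math.log(config.rate_lower_bound)

    best = _vp_solve(
        t,
        y,
        lambda tt, th: dac_shape(tt, math.exp(th[0]), math.exp(th[1]), th[2]),
        [np.array([x0[0], x0[1], config.td_init]) for x0 in _rate_starts(config)],
        ([lb, lb, 0.0], [8.0, 8.0, td_max]),
        config,
    )
    if best is None:
        return _make_result("DAC", 0.0, None, (), (), np.nan, y, 4, False, False)

    kf0, kd0 = np.exp(best.x[:2])
    td0 = best.x[2]
    s = dac_shape(t, kf0, kd0, td0)
    amp0 = max(0.0, float(s @ y) / max(float(s @ s), 1e-300))
    amp0, kf0, kd0 = _canonical_rates(amp0, kf0, kd0)
    popt, stderr, rss, ok = _polish(
        t,
        y,
        lambda tt, p: p[0] * dac_shape(tt, p[1], p[2], p[3]),
        [amp0, kf0, kd0, td0],
        (
            [0.0, config.rate_lower_bound, config.rate_lower_bound, 0.0],
            [np.inf, np.inf, np.inf, td_max],
        ),
        config,
    )
    amp, kf, kd, td = popt

    if abs(kf - kd) < config.degenerate_refit_rtol * max(kf, kd):
        popt2, stderr2, rss2, ok2 = _polish(
            t,
            y,
            _limit_dac_model,
            [amp, 0.5 * (kf + kd), td],
            ([0.0, config.rate_lower_bound, 0.0], [np.inf, np.inf, td_max]),
            config,
        )
        if ok2 and rss2 <= rss * (1.0 + 1e-9):
            amp2, k2, td2 = popt2
            params = DualActivationParams(amp2, k2, k2, t_d=td2)
            return _make_result(
                "DAC", 0.0, params, ("amplitude", "k", "t_d"), stderr2, rss2, y, 3, ok2, True
            )

    params = DualActivationParams(max(amp, 0.0), kf, kd, t_d=td)
    return _make_result(
        "DAC",
        0.0,
        params,
        ("amplitude", "k_f", "k_d", "t_d"),
        stderr,
        rss,
        y,
        4,
        ok,
        abs(kf - kd) < DEGENERACY_RTOL * max(kf, kd),
    )


def select_model(candidates, config: FitConfig = DEFAULT_CONFIG):
    """Pick the activated model: survivors by adjusted R^2, then minimum AIC.

    Non-converged fits and fits with adjusted R^2 below the threshold (or
    undefined) are discarded; among the rest the lowest AIC wins, with ties
    (|dAIC| < 1e-6) going to the model with fewer parameters.  Returns None
    when no candidate survives (the cell is not activated).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    survivors = [
        c
        for c in candidates
        if c.converged and np.isfinite(c.adj_r2) and c.adj_r2 >= config.adj_r2_threshold
    ]
    if not survivors:
        return None
    best = min(survivors, key=lambda c: (c.aic,))
    tied = [c for c in survivors if abs(c.aic - best.aic) < 1e-6]
    return min(tied, key=lambda c: c.n_params)


_TABLE_COLUMNS = [
    "Cell No",
    "Amplitude(D.U.)",
    "Error in Amplitude",
    "k_f(min^-1)",
    "Error in k_f",
    "k_d(min^-1)",
    "Error in k_d",
    "t_d",
    "Error in t_d",
    "Adj-R-sq",
    "AIC",
    "model_kind",
    "offset_min",
    "flags",
]


def fit_results_frame(results: dict) -> pd.DataFrame:
    """Tabulate {roi_id: FitResult} with the conventional report columns."""
    rows = []
    for roi_id, r in results.items():
        if r is None or r.params is None:
            rows.append({"Cell No": roi_id, "model_kind": "none", "flags": "not_activated"})
            continue
        p = r.params
        flags = []
        if r.degenerate_rates:
            flags.append("shared_rates")
        if not r.converged:
            flags.append("not_converged")
        err = r.stderr
        rows.append(
            {
                "Cell No": roi_id,
                "Amplitude(D.U.)": p.amplitude,
                "Error in Amplitude": err.get("amplitude", np.nan),
                "k_f(min^-1)": p.k_f,
                "Error in k_f": err.get("k_f", err.get("k", np.nan)),
                "k_d(min^-1)": p.k_d,
                "Error in k_d": err.get("k_d", err.get("k", np.nan)),
                "t_d": getattr(p, "t_d", np.nan),
                "Error in t_d": err.get("t_d", np.nan),
                "Adj-R-sq": r.adj_r2,
                "AIC": r.aic,
                "model_kind": r.model_kind,
                "offset_min": r.time_origin_offset,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
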
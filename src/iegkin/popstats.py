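"""Population histograms of fitted rate constants and modality selection.

Across the fitted cells, the formation rate k_f, degradation rate k_d and
the derived time-to-peak T_max are histogrammed; sparsely populated bins
(counts <= 10 by default) are dropped and one- and two-component Gaussian
curves are least-squares fitted to the retained (bin centre, count) pairs.
The number of components is chosen by AIC, which is how a bimodal
degradation-rate distribution (fast- and slow-decay subpopulations) is
detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fitting import aic
from .kinetics import KineticParams, time_to_peak

__all__ = [
    "ParamHistogram",
    "GaussianComponentFit",
    "build_histogram",
    "fit_modality",
    "derive_tmax_distribution",
]


@dataclass(frozen=True)
class ParamHistogram:
    """Uniform histogram from 0 to the data maximum, with a retention mask."""

    name: str
    bin_edges: np.ndarray
    counts: np.ndarray
    retained_mask: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class GaussianComponentFit:
    """One- or two-Gaussian fit to retained histogram bins.

    ``weights`` are the component peak heights (counts); ``aic_candidates``
    holds the AIC of both candidate modalities when the comparison ran.
    """

    n_components: int
    means: tuple
    sds: tuple
    weights: tuple
    rss: float
    aic: float
    adj_r2: float
    compared: bool
    aic_candidates: dict
    mean_stderrs: tuple = ()


def build_histogram(values, bin_width: float, min_count: int = 10, name: str = "") -> ParamHistogram:
    """Histogram with uniform bins on [0, max]; retain bins with count > min_count."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to histogram")
    vmax = float(values.max())
    n_bins = max(1, int(np.ceil(vmax / bin_width))) if vmax > 0 else 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    if edges[-1] < vmax:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return ParamHistogram(name, edges, counts, counts > min_count)


def _gaussians(x, params):
    """Sum of peak-height Gaussians; params = [h1, m1, s1, h2, m2, s2, ...]."""
    out = np.zeros_like(x)
    for i in range(0, len(params), 3):
        h, m, s = params[i : i + 3]
        out = out + h * np.exp(-((x - m) ** 2) / (2.0 * s**2))
    return out


def _fit_counts(x, y, p0, bounds):
    sol = least_squares(lambda p: _gaussians(x, p) - y, p0, bounds=bounds, max_nfev=2000)
    rss = 2.0 * sol.cost
    n, p = x.size, len(p0)
    stderr = np.full(p, np.nan)
    if n > p:
        try:
            stderr = np.sqrt(
                np.clip(np.diag(np.linalg.pinv(sol.jac.T @ sol.jac) * (rss / (n - p))), 0.0, None)
            )
        except np.linalg.LinAlgError:
            pass
    return sol.x, rss, bool(sol.success), stderr


def _count_aic(rss: float, n: int, p: int) -> float:
    """Small-sample AIC for the histogram-count fits.

    With only ~10 retained bins the plain least-squares AIC overfits badly
    (the second component chases Poisson count noise), so the corrected
    AICc penalty is used whenever its denominator n - k - 1 (k = p + 1) is
    positive for the richer candidate; below that the plain penalty is the
    only defined choice.
    """
    k = p + 1
    if n - k - 1 > 0:
        return n * np.log(rss / n) + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)
    return aic(rss, n, p)


def fit_modality(hist: ParamHistogram, max_components: int = 2) -> GaussianComponentFit:
    """Fit one- and two-Gaussian models to the retained bins; pick by AIC.

    Needs >= 5 retained bins for one component and >= 7 for two; when two
    components cannot be fitted (or ``max_components`` is 1) the
    single-Gaussian result is returned without a comparison (``compared``
    False).  The comparison uses the corrected criterion of ``_count_aic``,
    applied consistently to both candidates.
    """
    x = hist.centers[hist.retained_mask]
    y = hist.counts[hist.retained_mask].astype(float)
    n = x.size
    if n < 5:
        raise ValueError(f"need >= 5 retained bins, got {n}")

    mass = y.sum()
    m0 = float((x * y).sum() / mass)
    s0 = float(np.sqrt(((x - m0) ** 2 * y).sum() / mass)) or hist.bin_edges[1]
    lo, hi = float(x.min()), float(x.max())
    span = max(hi - lo, hist.bin_edges[1])
    b1 = ([0, lo - span, 1e-12], [np.inf, hi + span, np.inf])
    p1, rss1, ok1, err1 = _fit_counts(x, y, [float(y.max()), m0, s0], b1)
    # use the small-sample penalty only when it is defined for BOTH
    # candidates, so the comparison stays consistent
    use_corrected = n - (6 + 1) - 1 > 0
    crit = _count_aic if use_corrected else aic
    aic1 = crit(rss1, n, 3)

    result1 = GaussianComponentFit(
        1,
        (float(p1[1]),),
        (float(abs(p1[2])),),
        (float(p1[0]),),
        rss1,
        aic1,
        _adj_r2(rss1, y, 3),
        False,
        {1: aic1},
        (float(err1[1]),),
    )
    if n < 7 or max_components < 2:
        return result1

    b2 = (
        [0, lo - span, 1e-12, 0, lo - span, 1e-12],
        [np.inf, hi + span, np.inf, np.inf, hi + span, np.inf],
    )
    starts = [
        # split the retained range in two
        [y.max(), lo + 0.25 * span, s0 / 2, y.max() / 2, lo + 0.75 * span, s0 / 2],
        # nested seed: the one-component optimum plus a vanishing second
        [p1[0], p1[1], abs(p1[2]), 1e-6, lo + 0.75 * span, s0 / 2],
    ]
    best = None
    for p0 in starts:
        p2, rss2, ok2, err2 = _fit_counts(x, y, p0, b2)
        if best is None or rss2 < best[1]:
            best = (p2, rss2, ok2, err2)
    p2, rss2, ok2, err2 = best
    aic2 = crit(rss2, n, 6)

    cand = {1: aic1, 2: aic2}
    if aic2 < aic1:
        order = np.argsort([p2[1], p2[4]])
        means = tuple(float([p2[1], p2[4]][i]) for i in order)
        sds = tuple(float(abs([p2[2], p2[5]][i])) for i in order)
        weights = tuple(float([p2[0], p2[3]][i]) for i in order)
        errs = tuple(float([err2[1], err2[4]][i]) for i in order)
        return GaussianComponentFit(
            2, means, sds, weights, rss2, aic2, _adj_r2(rss2, y, 6), True, cand, errs
        )
    return GaussianComponentFit(
        1,
        result1.means,
        result1.sds,
        result1.weights,
        rss1,
        aic1,
        result1.adj_r2,
        True,
        cand,
        result1.mean_stderrs,
    )


def _adj_r2(rss, y, p):
    n = y.size
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0 or n <= p + 1:
        return float("nan")
    return 1.0 - (rss / (n - p - 1)) / (tss / (n - 1))


def derive_tmax_distribution(
    fit_table: pd.DataFrame,
    bin_width: float = 5.0,
    min_count: int = 10,
) -> dict:
    """Per-cell time-to-peak distribution and its modality.

    ``fit_table`` needs columns ``k_f`` and ``k_d`` (one row per fitted
    cell); equal-rate cells use the 1/k limit and are counted in
    ``n_degenerate``.  Besides the histogram summary, the closed-form
    time-to-peak evaluated at the mean rates is reported separately
    (``tmax_at_mean_rates``): a population's histogram mean and the peak
    time of the mean-parameter curve are distinct quantities.
    """
    kf = fit_table["k_f"].to_numpy(float)
    kd = fit_table["k_d"].to_numpy(float)
    good = np.isfinite(kf) & np.isfinite(kd) & (kf > 0) & (kd > 0)
    values = np.array([time_to_peak(KineticParams(1.0, f, d)) for f, d in zip(kf[good], kd[good])])
    degenerate = np.isclose(kf[good], kd[good], rtol=1e-9)

    hist = build_histogram(values, bin_width, min_count, name="T_max")
    out = {
        "values": values,
        "histogram": hist,
        "n_degenerate": int(degenerate.sum()),
        "mean": float(values.mean()),
        "tmax_at_mean_rates": time_to_peak(
            KineticParams(1.0, float(kf[good].mean()), float(kd[good].mean()))
        ),
    }
    try:
        out["modality"] = fit_modality(hist)
    except ValueError:
        out["modality"] = None
    return out
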
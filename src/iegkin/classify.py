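"""Context-representation classification and ensemble statistics.

Per session each ROI gets a selected activation model (or none).  The first
imaging session IS1 follows a single exposure to context A; the second, IS2,
follows exposures to context A and, 60 min later, context B, so IS2 traces
are arbitrated jointly between a zero-delay single activation (context A), a
60-min-delayed single activation (context B) and a double activation (both).
The resulting activation triple (a1: CtxtA in IS1, a2: CtxtA in IS2,
b: CtxtB) maps bijectively onto eight context-representation categories.
On top of the categories the module computes ensemble fractions and their
chance overlap, the double-activation fraction comparison between dual- and
single-exposure conditions, and the amplitude-binned reactivation
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import DEFAULT_CONFIG, FitConfig, FitResult, fit_dac, fit_sac, select_model
from .traces import FluorescenceTrace

__all__ = [
    "SessionOutcome",
    "ActivationTriple",
    "CategoryLabel",
    "ReactivationBin",
    "CATEGORY_MEANINGS",
    "fit_session",
    "session_flags",
    "categorize",
    "classify_rois",
    "ensemble_fractions",
    "chance_overlap",
    "dac_fraction_comparison",
    "reactivation_probability",
]

#: Candidate models arbitrated per session.  IS2 is fitted twice to the
#: single-activation profile -- once from the context-A origin, once delayed
#: to the context-B exposure -- plus the double-activation profile.
SESSION_CANDIDATES = {
    "IS1": ("SAC", "DAC"),
    "IS2": ("SAC", "SAC_DELAYED", "DAC"),
}


@dataclass
class SessionOutcome:
    """Selected model (or None) for one ROI in one session."""

    roi_id: str
    session: str
    model_kind: str | None
    result: FitResult | None


@dataclass(frozen=True)
class ActivationTriple:
    """Context activation flags: (CtxtA in IS1, CtxtA in IS2, CtxtB)."""

    a1: bool
    a2: bool
    b: bool

    def as_tuple(self) -> tuple:
        return (int(self.a1), int(self.a2), int(self.b))


CATEGORY_MEANINGS = {
    1: "Cell that is present in all contexts",
    2: "Cell that is present in CtxtA only",
    3: "Cells present in IS1 CtxtA only",
    4: "Cells present in IS2 CtxtA only",
    5: "Cells present in B only",
    6: "Cells present in IS1 CtxtA and IS2 CtxtB",
    7: "Cells present in IS2 CtxtA and IS2 CtxtB",
    8: "Cells not activated in all contexts",
}

_TRIPLE_TO_CATEGORY = {
    (1, 1, 1): 1,
    (1, 1, 0): 2,
    (1, 0, 0): 3,
    (0, 1, 0): 4,
    (0, 0, 1): 5,
    (1, 0, 1): 6,
    (0, 1, 1): 7,
    (0, 0, 0): 8,
}


@dataclass(frozen=True)
class CategoryLabel:
    category: int
    meaning: str

    def __post_init__(self) -> None:
        if self.category not in range(1, 9):
            raise ValueError(f"category must be 1..8, got {self.category}")


@dataclass(frozen=True)
class ReactivationBin:
    """One amplitude bin of the reactivation-probability curve."""

    amplitude_lo: float
    amplitude_hi: float
    n_bin: int
    n_fit: int

    @property
    def probability(self) -> float:
        return self.n_fit / self.n_bin

    def __post_init__(self) -> None:
        if not (0 <= self.n_fit <= self.n_bin):
            raise ValueError("need 0 <= n_fit <= n_bin")


def fit_session(
    trace: FluorescenceTrace,
    session: str,
    config: FitConfig = DEFAULT_CONFIG,
    candidates: tuple | None = None,
) -> SessionOutcome:
    """Fit the session's candidate models to a trace and arbitrate by AIC."""
    cand_kinds = candidates if candidates is not None else SESSION_CANDIDATES[session]
    fits = []
    for kind in cand_kinds:
        try:
            if kind == "SAC":
                fits.append(fit_sac(trace, config))
            elif kind == "SAC_DELAYED":
                fits.append(fit_sac(trace, config, time_origin_offset=config.delay_offset))
            elif kind == "DAC":
                fits.append(fit_dac(trace, config))
            else:
                raise ValueError(f"unknown candidate kind {kind!r}")
        except ValueError:
            continue
    chosen = select_model(fits, config) if fits else None
    return SessionOutcome(trace.roi_id, session, chosen.model_kind if chosen else None, chosen)


def session_flags(is1: SessionOutcome, is2: SessionOutcome) -> ActivationTriple:
    """Combine the two sessions' selections into context flags.

    a1: any activation in IS1 (single or double; a double activation in the
    single-exposure session is attributed to the context exposure plus a
    spontaneous event and still flags only CtxtA).  a2: IS2 selection is the
    zero-delay single activation or the double activation.  b: IS2 selection
    is the double activation or the delayed single activation.
    """
    if is1.roi_id != is2.roi_id:
        raise ValueError(f"ROI mismatch: {is1.roi_id} vs {is2.roi_id}")
    a1 = is1.model_kind in ("SAC", "DAC")
    a2 = is2.model_kind in ("SAC", "DAC")
    b = is2.model_kind in ("DAC", "SAC_DELAYED")
    return ActivationTriple(a1, a2, b)


def categorize(triple: ActivationTriple) -> CategoryLabel:
    """Exact lookup of the eight-category truth table."""
    cat = _TRIPLE_TO_CATEGORY[triple.as_tuple()]
    return CategoryLabel(cat, CATEGORY_MEANINGS[cat])


def classify_rois(
    traces_is1,
    traces_is2,
    config: FitConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """End-to-end per-ROI classification from matched IS1/IS2 traces.

    Returns one row per ROI: flags a1/a2/b, category, the per-session
    selected model kinds and, when available, amplitude and adjusted R^2 of
    the selected IS1/IS2 fits (used by the reactivation analysis), plus a
    diagnostics column marking double activations seen in the
    single-exposure session.
    """
    by_id2 = {tr.roi_id: tr for tr in traces_is2}
    rows = []
    for tr1 in traces_is1:
        if tr1.roi_id not in by_id2:
            raise ValueError(f"roi {tr1.roi_id} missing from IS2 traces")
        o1 = fit_session(tr1, "IS1", config)
        o2 = fit_session(by_id2[tr1.roi_id], "IS2", config)
        triple = session_flags(o1, o2)
        label = categorize(triple)
        rows.append(
            {
                "roi_id": tr1.roi_id,
                "a1": int(triple.a1),
                "a2": int(triple.a2),
                "b": int(triple.b),
                "category": label.category,
                "is1_model": o1.model_kind or "none",
                "is2_model": o2.model_kind or "none",
                "is1_amplitude": o1.result.params.amplitude if o1.result else np.nan,
                "is1_adj_r2": o1.result.adj_r2 if o1.result else np.nan,
                "is2_adj_r2": o2.result.adj_r2 if o2.result else np.nan,
                "diagnostics": "is1_dac_spontaneous" if o1.model_kind == "DAC" else "",
            }
        )
    return pd.DataFrame(rows)


def ensemble_fractions(classified: pd.DataFrame) -> dict:
    """Session/context activation fractions over all ROIs.

    Overlap and conditional fractions are reported both normalised to all
    ROIs (``*_of_total``) and to the relevant activated subset.
    """
    n = len(classified)
    if n == 0:
        raise ValueError("no ROIs to summarise")
    a1 = classified["a1"].to_numpy(bool)
    a2 = classified["a2"].to_numpy(bool)
    b = classified["b"].to_numpy(bool)
    act1 = a1
    act2 = a2 | b
    both = act1 & act2

    def frac(mask, denom_mask=None):
        if denom_mask is None:
            return float(mask.sum()) / n
        d = int(denom_mask.sum())
        return float((mask & denom_mask).sum()) / d if d else float("nan")

    cats = classified["category"].value_counts()
    out = {
        "frac_active_is1": frac(act1),
        "frac_active_is2": frac(act2),
        "frac_overlap_of_total": frac(both),
        "frac_overlap_of_is1_active": frac(both, act1),
        "frac_ctxtA_is1": frac(a1),
        "frac_ctxtA_is2": frac(a2),
        "frac_ctxtB": frac(b),
        "frac_ctxtA_is1_and_ctxtB_of_total": frac(a1 & b),
        "frac_a2_also_a1": frac(a1, a2),
        "frac_a2_also_b": frac(b, a2),
        "frac_a1_also_b": frac(b, a1),
        "category_fractions": {c: float(cats.get(c, 0)) / n for c in range(1, 9)},
    }
    return out


def chance_overlap(frac_a: float, frac_b: float) -> float:
    """Chance overlap of two independently drawn ensembles: the product."""
    if not (0 <= frac_a <= 1 and 0 <= frac_b <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    return frac_a * frac_b


def dac_fraction_comparison(classified: pd.DataFrame, replicate_col: str = "replicate"):
    """Double-activation fractions: dual-exposure vs single-exposure.

    Dual exposure: fraction of double activations among IS2 cells activated
    in context A (zero-delay single or double activation).  Single exposure:
    fraction of double activations among IS1-activated cells.  With a
    ``replicate`` column (e.g. per animal), per-replicate fractions feed a
    one-tailed Welch t test (dual > single); p is NaN below 2 replicates per
    group.

    Returns (frac_dual, frac_single, p_one_tailed, per_replicate_frame).
    """
    df = classified.copy()
    if replicate_col not in df.columns:
        df[replicate_col] = "all"

    def fracs(grp):
        is2_a = grp["is2_model"].isin(["SAC", "DAC"])
        dual = grp.loc[is2_a, "is2_model"].eq("DAC").mean() if is2_a.any() else np.nan
        is1_a = grp["is1_model"].isin(["SAC", "DAC"])
        single = grp.loc[is1_a, "is1_model"].eq("DAC").mean() if is1_a.any() else np.nan
        return pd.Series({"frac_dac_dual": dual, "frac_dac_single": single})

    per_rep = df.groupby(replicate_col).apply(fracs, include_groups=False)
    dual = per_rep["frac_dac_dual"].dropna()
    single = per_rep["frac_dac_single"].dropna()
    p = float("nan")
    if len(dual) >= 2 and len(single) >= 2:
        p = float(
            stats.ttest_ind(dual, single, equal_var=False, alternative="greater").pvalue
        )
    return float(dual.mean()), float(single.mean()), p, per_rep


def reactivation_probability(classified: pd.DataFrame, bin_size: float = 500.0):
    """Reactivation probability vs IS1 amplitude, in fixed-width bins.

    IS1-activated ROIs are binned by the fitted amplitude of their selected
    IS1 model into half-open intervals [k*bin, (k+1)*bin); per bin the
    probability is the fraction whose IS2 trace also produced an activated
    fit.  Returns (bins, stats_dict) where stats_dict has the Pearson
    correlation of bin centre vs probability (NaN + flag when the
    probabilities have zero variance) and the slope of the IS1 adjusted R^2
    vs amplitude regression (amplitude-bias control).
    """
    act1 = classified[classified["is1_model"].isin(["SAC", "DAC"])]
    if len(act1) == 0:
        raise ValueError("no IS1-activated ROIs")
    amp = act1["is1_amplitude"].to_numpy(float)
    refit = act1["is2_model"].ne("none").to_numpy()

    idx = np.floor(amp / bin_size).astype(int)
    bins = []
    for k in sorted(set(idx)):
        sel = idx == k
        bins.append(
            ReactivationBin(k * bin_size, (k + 1) * bin_size, int(sel.sum()), int(refit[sel].sum()))
        )

    centers = np.array([0.5 * (b.amplitude_lo + b.amplitude_hi) for b in bins])
    probs = np.array([b.probability for b in bins])
    out = {"pearson_r": float("nan"), "pearson_p": float("nan"), "zero_variance": False}
    if len(bins) >= 2 and np.ptp(probs) > 0:
        r, p = stats.pearsonr(centers, probs)
        out.update(pearson_r=float(r), pearson_p=float(p))
    else:
        out["zero_variance"] = True

    r2 = act1["is1_adj_r2"].to_numpy(float)
    good = np.isfinite(r2)
    if good.sum() >= 2 and np.ptp(amp[good]) > 0:
        reg = stats.linregress(amp[good], r2[good])
        out["adj_r2_slope"] = float(reg.slope)
        out["adj_r2_slope_stderr"] = float(reg.stderr)
    else:
        out["adj_r2_slope"] = float("nan")
        out["adj_r2_slope_stderr"] = float("nan")
    return bins, out
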
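"""Closed-form immediate-early-gene (IEG) expression profiles.

The fluorescence of an IEG-coupled fluorophore following a single triggering
event is modelled as consecutive first-order kinetics,

    mRNA --k_f--> protein --k_d--> degraded protein,

with fluorescence proportional to the protein concentration.  Solving the
coupled ODEs for a unit bolus of mRNA gives the single-activation profile

    F1(t) = A * k_f / (k_f - k_d) * (exp(-k_d t) - exp(-k_f t)),

which rises with characteristic time 1/k_f, peaks at
T_max = ln(k_f/k_d) / (k_f - k_d) and decays with 1/k_d.  A neuron activated
twice (e.g. by two context exposures separated by t_d minutes) superposes two
such profiles with shared amplitude and rate constants:

    F2(t) = F1(t) + [t >= t_d] * F1(t - t_d).

All times are laboratory time in minutes with t = 0 at the session's first
triggering event; fluorescence is in detector units (D.U.) and is
background-referenced, so F1(0) = 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticParams",
    "DualActivationParams",
    "ProfileSample",
    "sac_value",
    "dac_value",
    "time_to_peak",
    "characteristic_times",
    "DEGENERACY_RTOL",
]

#: Relative tolerance below which k_f and k_d are treated as equal and the
#: analytic equal-rate limit A * k * t * exp(-k t) is used instead of the
#: two-exponential difference (which suffers catastrophic cancellation).
DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class KineticParams:
    """Single-activation model parameters.

    Attributes
    ----------
    amplitude : float
        Fluorescence scale A in detector units (D.U.); >= 0.
    k_f : float
        Formation (protein synthesis) rate constant, min^-1; > 0.
    k_d : float
        Degradation rate constant, min^-1; > 0.  No ordering is imposed
        between ``k_f`` and ``k_d``; the profile is symmetric under swapping
        them.
    """

    amplitude: float
    k_f: float
    k_d: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise ValueError(f"amplitude must be finite and >= 0, got {self.amplitude}")
        if not np.isfinite(self.k_f) or self.k_f <= 0:
            raise ValueError(f"k_f must be finite and > 0, got {self.k_f}")
        if not np.isfinite(self.k_d) or self.k_d <= 0:
            raise ValueError(f"k_d must be finite and > 0, got {self.k_d}")

    @property
    def degenerate(self) -> bool:
        """True when |k_f - k_d| is below the degeneracy tolerance."""
        return abs(self.k_f - self.k_d) < DEGENERACY_RTOL * max(self.k_f, self.k_d)


@dataclass(frozen=True)
class DualActivationParams(KineticParams):
    """Double-activation model parameters: a second event at ``t_d`` minutes."""

    t_d: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.isfinite(self.t_d) or self.t_d < 0:
            raise ValueError(f"t_d must be finite and >= 0, got {self.t_d}")


@dataclass(frozen=True)
class ProfileSample:
    """A single (time, fluorescence) evaluation of a model profile."""

    time: float
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"time must be finite and >= 0, got {self.time}")
        if not np.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value}")


def _check_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    if np.any(t < 0):
        raise ValueError("time values must be >= 0")
    return t


def sac_shape(t, k_f: float, k_d: float):
    """Unit-amplitude single-activation profile (no input validation).

    Used as the inner evaluation kernel by the fitting routines; scales
    linearly with amplitude.  Negative ``t`` evaluates to 0.
    """
    t = np.asarray(t, dtype=float)
    tp = np.clip(t, 0.0, None)
    if abs(k_f - k_d) < DEGENERACY_RTOL * max(k_f, k_d):
        out = k_f * tp * np.exp(-k_f * tp)
    else:
        out = k_f / (k_f - k_d) * (np.exp(-k_d * tp) - np.exp(-k_f * tp))
    return np.where(t < 0, 0.0, out)


def dac_shape(t, k_f: float, k_d: float, t_d: float):
    """Unit-amplitude double-activation profile (no input validation)."""
    return sac_shape(t, k_f, k_d) + sac_shape(np.asarray(t, dtype=float) - t_d, k_f, k_d)


def sac_value(t, p: KineticParams):
    """Evaluate the single-activation profile F1(t).

    Parameters
    ----------
    t : float or array-like
        Laboratory time in minutes, >= 0.
    p : KineticParams

    Returns
    -------
    float or ndarray
        Fluorescence in D.U.; always >= 0 and finite, 0 at t = 0.
    """
    t = _check_time(t)
    out = p.amplitude * sac_shape(t, p.k_f, p.k_d)
    return float(out) if out.ndim == 0 else out


def dac_value(t, p: DualActivationParams):
    """Evaluate the double-activation profile F2(t).

    Before ``p.t_d`` this equals ``sac_value``; afterwards the identically
    parameterised second event is added.
    """
    t = _check_time(t)
    out = p.amplitude * dac_shape(t, p.k_f, p.k_d, p.t_d)
    return float(out) if out.ndim == 0 else out


def time_to_peak(p: KineticParams) -> float:
    """Time of maximal response, T_max = ln(k_f/k_d) / (k_f - k_d) minutes.

    Obtained by setting the first derivative of F1 to zero.  Symmetric under
    swapping the two rate constants; reduces to 1/k in the equal-rate limit.
    """
    if p.degenerate:
        return 1.0 / p.k_f
    return float(np.log(p.k_f / p.k_d) / (p.k_f - p.k_d))


def characteristic_times(p: KineticParams) -> tuple[float, float]:
    """Characteristic (rise, decay) times, (1/k_f, 1/k_d) in minutes."""
    return 1.0 / p.k_f, 1.0 / p.k_d
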
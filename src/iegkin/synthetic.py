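"""Synthetic IEG-imaging data with known ground truth.

Emulates the in vivo protocols the package is built for: an imaging session
samples each nucleus's fluorescence every ~10 min, either from 20-180 min
after the triggering context exposure (first imaging session, IS1) or from
90-300 min after the first of two exposures 60 min apart (second imaging
session, IS2).  Cells are single-activation (SAC), double-activation (DAC)
or inactive; their kinetic parameters are drawn from the population
distributions observed for cfos-shGFP expression (formation rate centred at
0.0369 min^-1).  Scenes can be rendered as 4D image stacks with Gaussian
nuclei, rigid per-time-point jitter and configurable noise so that the whole
extraction -> fitting -> classification chain is testable without real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import DualActivationParams, KineticParams, dac_value, sac_value
from .traces import FluorescenceTrace

__all__ = [
    "SamplingProtocol",
    "NoiseModel",
    "RateDistributions",
    "SyntheticTruth",
    "DualSessionConfig",
    "DualSessionDataset",
    "CATEGORY_MODELS",
    "gen_trace",
    "gen_population",
    "gen_image_stack",
    "gen_dual_session_dataset",
    "disc_mean_factor",
]

logger = logging.getLogger(__name__)

#: Ratio of nominal nucleus diameter to rendered Gaussian sigma.  Pixels
#: brighter than ~6% of the blob peak then span about one nominal diameter,
#: matching the "quasi-circular bright region" appearance, while the tail at
#: the background annulus (1-2 radii out) is negligible.
DIAMETER_TO_SIGMA = 4.71


@dataclass(frozen=True)
class SamplingProtocol:
    """Imaging time grid and context-exposure schedule of one session."""

    name: str
    time_points: np.ndarray
    context_events: tuple = ()

    def __post_init__(self) -> None:
        tp = np.asarray(self.time_points, dtype=float)
        if tp.size and (np.any(np.diff(tp) <= 0) or np.any(tp < 0)):
            raise ValueError("time_points must be strictly increasing and >= 0")
        object.__setattr__(self, "time_points", tp)

    @classmethod
    def is1(cls) -> "SamplingProtocol":
        """First imaging session: 20-180 min every 10 min, one exposure at 0."""
        return cls("IS1", np.arange(20.0, 181.0, 10.0), (("CtxtA", 0.0),))

    @classmethod
    def is2(cls) -> "SamplingProtocol":
        """Second imaging session: 90-300 min every 10 min, exposures at 0 and 60."""
        return cls("IS2", np.arange(90.0, 301.0, 10.0), (("CtxtA", 0.0), ("CtxtB", 60.0)))


@dataclass(frozen=True)
class NoiseModel:
    """Detection-noise model applied to model fluorescence values.

    kind
        ``gaussian_multiplicative`` (default): v -> v * (1 + scale * N(0,1))
        plus an additive floor of ``floor_du`` * N(0,1) D.U.;
        ``gaussian_additive``: v -> v + scale * N(0,1) with scale in D.U.;
        ``poisson``: v -> Poisson(v / gain) * gain with gain = ``scale``
        (detector counts of ``scale`` D.U. each), plus the additive floor.
    scale
        Dimensionless fraction (multiplicative), D.U. (additive) or D.U. per
        count (poisson); >= 0.
    floor_du
        Additive Gaussian floor in D.U., present even at zero signal.
    seed
        Default RNG seed used when no generator is passed explicitly.
    """

    kind: str = "gaussian_multiplicative"
    scale: float = 0.05
    floor_du: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scale < 0 or self.floor_du < 0:
            raise ValueError("noise scale and floor must be >= 0")
        if self.kind not in ("gaussian_multiplicative", "gaussian_additive", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind == "gaussian_multiplicative":
            out = v * (1.0 + self.scale * rng.standard_normal(v.shape))
        elif self.kind == "gaussian_additive":
            out = v + self.scale * rng.standard_normal(v.shape)
        else:  # poisson
            if self.scale > 0:
                out = rng.poisson(np.clip(v, 0.0, None) / self.scale) * self.scale
            else:
                out = v.copy()
        if self.floor_du > 0:
            out = out + self.floor_du * rng.standard_normal(v.shape)
        return out

    def rng(self, rng: np.random.Generator | None = None) -> np.random.Generator:
        return rng if rng is not None else np.random.default_rng(self.seed)


NOISELESS = NoiseModel(scale=0.0, floor_du=0.0)


@dataclass(frozen=True)
class RateDistributions:
    """Population distributions of the per-cell kinetic parameters.

    Defaults centre on the cfos-shGFP population values (k_f mean
    0.0369 min^-1; faster decay component k_d = 0.016 +- 0.002 min^-1); the
    k_f population SD of 0.01 min^-1 gives the cell-to-cell spread seen in
    the rate histograms.  Draws are truncated to stay positive.
    """

    kf_mean: float = 0.0369
    kf_sd: float = 0.01
    kd_mean: float = 0.016
    kd_sd: float = 0.002
    td_mean: float = 60.0
    td_sd: float = 0.0

    def draw(self, rng: np.random.Generator, min_rate: float = 1e-4):
        kf = max(min_rate, rng.normal(self.kf_mean, self.kf_sd)) if self.kf_sd else self.kf_mean
        kd = max(min_rate, rng.normal(self.kd_mean, self.kd_sd)) if self.kd_sd else self.kd_mean
        td = max(0.0, rng.normal(self.td_mean, self.td_sd)) if self.td_sd else self.td_mean
        return kf, kd, td


TRUTH_COLUMNS = [
    "roi_id",
    "model_kind",
    "amplitude",
    "k_f",
    "k_d",
    "t_d",
    "time_origin",
    "x",
    "y",
    "z",
    "diameter_px",
    "baseline_du",
    "category",
]


@dataclass
class SyntheticTruth:
    """Generator ground truth: one row per cell.

    ``cells`` columns: roi_id, model_kind (SAC | SAC_DELAYED | DAC |
    INACTIVE), amplitude, k_f, k_d, t_d, time_origin (min; onset of the
    modelled event), nucleus centre (x, y, z; px / slice), diameter_px,
    baseline_du, category (intended Table-of-eight category, when generated
    by the dual-session generator; otherwise NaN).
    """

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        for col in TRUTH_COLUMNS:
            if col not in self.cells.columns:
                self.cells[col] = np.nan
        bad = self.cells["diameter_px"].notna() & (self.cells["diameter_px"] <= 0)
        if bad.any():
            raise ValueError("nucleus diameters must be > 0")

    def __len__(self) -> int:
        return len(self.cells)


def _model_values(model_kind, params, time_origin, t):
    """Noiseless model evaluation at laboratory times ``t``."""
    if model_kind == "INACTIVE":
        return np.zeros_like(np.asarray(t, dtype=float))
    tt = np.asarray(t, dtype=float) - time_origin
    tt = np.clip(tt, 0.0, None)
    if model_kind == "DAC":
        return dac_value(tt, params)
    return sac_value(tt, params)  # SAC or SAC_DELAYED (origin already shifted)


def gen_trace(
    model_kind: str,
    params,
    protocol: SamplingProtocol,
    noise: NoiseModel = NOISELESS,
    rng: np.random.Generator | None = None,
    roi_id: str = "roi0",
    time_origin: float = 0.0,
) -> FluorescenceTrace:
    """Sample one model trace on the protocol grid, plus noise.

    ``model_kind`` is SAC, SAC_DELAYED, DAC or INACTIVE.  SAC_DELAYED shifts
    the time origin to ``time_origin`` (the second context exposure); for
    INACTIVE cells the trace is pure noise around zero (traces are
    background-referenced).  With noise scale and floor both zero the trace
    equals the model exactly.
    """
    if protocol.time_points.size == 0:
        raise ValueError("protocol has no time points")
    vals = _model_values(model_kind, params, time_origin, protocol.time_points)
    vals = noise.apply(vals, noise.rng(rng))
    return FluorescenceTrace(roi_id=roi_id, time_points=protocol.time_points, values=vals)


def _place_nuclei(n, rng, field_of_view, z_slices, diameter):
    """Nucleus centres on a jittered lattice, >= 1 diameter from the border.

    The lattice keeps neighbours separated (no overlapping somata in a
    single optical field) while the +-15% spacing jitter gives sub-pixel
    centre positions.
    """
    nx, ny = field_of_view
    m = diameter
    if nx - 2 * m <= 0 or ny - 2 * m <= 0:
        raise ValueError("field of view too small for the nucleus diameter margin")
    if n == 0:
        return np.array([]), np.array([]), np.array([])
    nc = int(np.ceil(np.sqrt(n)))
    sx, sy = (nx - 2 * m) / nc, (ny - 2 * m) / nc
    ii = np.arange(n) % nc
    jj = np.arange(n) // nc
    x = m + (ii + 0.5) * sx + rng.uniform(-0.15 * sx, 0.15 * sx, n)
    y = m + (jj + 0.5) * sy + rng.uniform(-0.15 * sy, 0.15 * sy, n)
    z = rng.uniform(z_slices * 0.3, z_slices * 0.7, n)
    return x, y, z


def gen_population(
    n_cells: int,
    fraction_sac: float,
    fraction_dac: float = 0.0,
    rate_distributions: RateDistributions = RateDistributions(),
    amplitude_range: tuple = (500.0, 5000.0),
    protocol: SamplingProtocol | None = None,
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | None = None,
    field_of_view: tuple = (256, 256),
    z_slices: int = 21,
    diameter_px: float = 20.0,
    baseline_du: float = 50.0,
) -> tuple[list, SyntheticTruth]:
    """Draw an i.i.d. population of cells and their traces.

    The non-SAC, non-DAC remainder is INACTIVE.  Amplitudes are uniform on
    ``amplitude_range`` (the 500-5000 D.U. scale of observed cells); rates
    come from ``rate_distributions`` truncated positive.
    """
    if not (0 <= fraction_sac <= 1 and 0 <= fraction_dac <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if fraction_sac + fraction_dac > 1 + 1e-12:
        raise ValueError("fraction_sac + fraction_dac must be <= 1")
    protocol = protocol or SamplingProtocol.is1()
    rng = noise.rng(rng)

    n_sac = int(round(n_cells * fraction_sac))
    n_dac = int(round(n_cells * fraction_dac))
    n_sac = min(n_sac, n_cells)
    n_dac = min(n_dac, n_cells - n_sac)
    kinds = ["SAC"] * n_sac + ["DAC"] * n_dac + ["INACTIVE"] * (n_cells - n_sac - n_dac)

    x, y, z = _place_nuclei(n_cells, rng, field_of_view, z_slices, diameter_px) if n_cells else ([], [], [])
    rows, traces = [], []
    for i, kind in enumerate(kinds):
        roi_id = f"cell{i:04d}"
        kf, kd, td = rate_distributions.draw(rng)
        amp = rng.uniform(*amplitude_range)
        if kind == "DAC":
            params = DualActivationParams(amp, kf, kd, t_d=td)
        else:
            params = KineticParams(amp, kf, kd)
        traces.append(gen_trace(kind, params, protocol, noise, rng, roi_id=roi_id))
        rows.append(
            dict(
                roi_id=roi_id,
                model_kind=kind,
                amplitude=amp if kind != "INACTIVE" else 0.0,
                k_f=kf,
                k_d=kd,
                t_d=td if kind == "DAC" else np.nan,
                time_origin=0.0,
                x=x[i],
                y=y[i],
                z=z[i],
                diameter_px=diameter_px,
                baseline_du=baseline_du,
                category=np.nan,
            )
        )
    truth = SyntheticTruth(pd.DataFrame(rows, columns=TRUTH_COLUMNS))
    return traces, truth


def disc_mean_factor(radius: float, sigma: float) -> float:
    """Mean of a unit-peak lateral Gaussian over a disc of ``radius``.

    (2 sigma^2 / r^2) * (1 - exp(-r^2 / 2 sigma^2)); the analytic calibration
    factor between a blob's peak voxel and the ROI-disc-averaged readout.
    """
    r2 = radius**2 / (2.0 * sigma**2)
    return float((1.0 - np.exp(-r2)) / r2)


def _discrete_disc_mean(cx: float, cy: float, radius: float, sigma: float) -> float:
    """Mean of a unit-peak Gaussian over the pixel centres within ``radius``.

    Matches the discrete circular footprint the extraction workflow averages
    over, including the sub-pixel position of the blob centre.
    """
    half = int(np.ceil(radius)) + 1
    xs = np.arange(int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1)
    ys = np.arange(int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1)
    d2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    mask = d2 < radius**2
    return float(np.exp(-d2[mask] / (2.0 * sigma**2)).mean())


def gen_image_stack(
    truth: SyntheticTruth,
    protocol: SamplingProtocol,
    field_of_view: tuple = (256, 256),
    z_slices: int = 21,
    axial_sigma: float = 3.0,
    jitter_px: float = 0.0,
    noise: NoiseModel = NOISELESS,
    rng: np.random.Generator | None = None,
    ambient_du: float = 0.0,
):
    """Render the truth table as a 4D (t, z, y, x) stack plus an ROI table.

    Each nucleus is an isotropic-in-plane 3D Gaussian blob with lateral sigma
    = diameter / 4.71 and axial sigma ``axial_sigma`` slices.  The blob is
    calibrated so the disc-average over the nominal ROI (radius diameter/2)
    at the central slice equals baseline + model value at each time point,
    matching the mean-over-ROI readout convention of the extraction workflow.
    A rigid lateral jitter, uniform in [-jitter_px, jitter_px] per time point
    and shared by all nuclei, emulates inter-time-point misalignment.  The
    ROI table holds the nominal (t = 0, unjittered) centres.
    """
    rng = noise.rng(rng)
    nx, ny = field_of_view
    cells = truth.cells
    nt = protocol.time_points.size

    for col, lim in (("x", nx), ("y", ny)):
        c = cells[col].to_numpy(float)
        d = cells["diameter_px"].to_numpy(float)
        if len(cells) and (np.any(c - d < 0) or np.any(c + d > lim)):
            raise ValueError("nuclei must fit inside the field of view with >= 1 diameter margin")
    if len(cells) >= 2:
        xy = cells[["x", "y"]].to_numpy(float)
        dmin = cells["diameter_px"].to_numpy(float).max()
        d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if np.any(d2 < dmin**2):
            logger.warning("some nuclei are closer than one diameter; overlapping blobs")

    jit = rng.uniform(-jitter_px, jitter_px, size=(nt, 2)) if jitter_px > 0 else np.zeros((nt, 2))
    stack = np.full((nt, z_slices, ny, nx), float(ambient_du))
    zz = np.arange(z_slices, dtype=float)

    for _, cell in cells.iterrows():
        sigma_l = cell["diameter_px"] / DIAMETER_TO_SIGMA
        radius = cell["diameter_px"] / 2.0
        params = None
        if cell["model_kind"] != "INACTIVE":
            if cell["model_kind"] == "DAC":
                params = DualActivationParams(cell["amplitude"], cell["k_f"], cell["k_d"], t_d=cell["t_d"])
            else:
                params = KineticParams(cell["amplitude"], cell["k_f"], cell["k_d"])
        zprof = np.exp(-((zz - cell["z"]) ** 2) / (2.0 * axial_sigma**2))
        half = int(np.ceil(4 * sigma_l))
        for it, t in enumerate(protocol.time_points):
            cx, cy = cell["x"] + jit[it, 0], cell["y"] + jit[it, 1]
            value = _model_values(cell["model_kind"], params, cell.get("time_origin", 0.0) or 0.0, np.array([t]))[0]
            peak = (cell["baseline_du"] + value) / _discrete_disc_mean(cx, cy, radius, sigma_l)
            x0, x1 = max(0, int(cx) - half), min(nx, int(cx) + half + 1)
            y0, y1 = max(0, int(cy) - half), min(ny, int(cy) + half + 1)
            gx = np.exp(-((np.arange(x0, x1) - cx) ** 2) / (2.0 * sigma_l**2))
            gy = np.exp(-((np.arange(y0, y1) - cy) ** 2) / (2.0 * sigma_l**2))
            stack[it, :, y0:y1, x0:x1] += peak * zprof[:, None, None] * gy[None, :, None] * gx[None, None, :]

    if noise.scale > 0 or noise.floor_du > 0:
        stack = noise.apply(stack, rng)

    roi_table = pd.DataFrame(
        {
            "roi_id": cells["roi_id"],
            "x": cells["x"],
            "y": cells["y"],
            "z": cells["z"],
            "radius": cells["diameter_px"] / 2.0,
        }
    )
    return stack, roi_table


#: Intended per-session generating models for each of the eight categories:
#: (IS1 model, IS2 model, IS2 time origin in lab minutes).
CATEGORY_MODELS = {
    1: ("SAC", "DAC", 0.0),
    2: ("SAC", "SAC", 0.0),
    3: ("SAC", "INACTIVE", 0.0),
    4: ("INACTIVE", "SAC", 0.0),
    5: ("INACTIVE", "SAC_DELAYED", 60.0),
    6: ("SAC", "SAC_DELAYED", 60.0),
    7: ("INACTIVE", "DAC", 0.0),
    8: ("INACTIVE", "INACTIVE", 0.0),
}


@dataclass
class DualSessionConfig:
    """Configuration of the two-session synthetic experiment."""

    n_cells: int = 160
    category_fractions: dict = field(default_factory=lambda: {c: 0.125 for c in range(1, 9)})
    rates: RateDistributions = field(default_factory=RateDistributions)
    amplitude_range: tuple = (500.0, 5000.0)
    noise: NoiseModel = field(default_factory=NoiseModel)
    second_event_delay: float = 60.0
    seed: int | None = None


@dataclass
class DualSessionDataset:
    traces_is1: list
    traces_is2: list
    truth: SyntheticTruth
    protocol_is1: SamplingProtocol
    protocol_is2: SamplingProtocol


def _exact_counts(fractions: dict, n: int) -> dict:
    """Largest-remainder apportionment so counts match the mix exactly."""
    cats = sorted(fractions)
    total = sum(fractions[c] for c in cats)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category fractions must sum to 1, got {total}")
    raw = {c: fractions[c] * n for c in cats}
    counts = {c: int(np.floor(raw[c])) for c in cats}
    rem = n - sum(counts.values())
    order = sorted(cats, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:rem]:
        counts[c] += 1
    return counts


def gen_dual_session_dataset(config: DualSessionConfig, rng: np.random.Generator | None = None) -> DualSessionDataset:
    """Generate matched IS1/IS2 traces for a configured category mix.

    Each cell draws one (amplitude, k_f, k_d) set used in both sessions; the
    IS2 model follows the intended category (single activation at the first
    or second exposure, double activation with t_d equal to the exposure
    spacing, or inactive).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p1, p2 = SamplingProtocol.is1(), SamplingProtocol.is2()
    counts = _exact_counts(config.category_fractions, config.n_cells)
    td = config.second_event_delay

    x, y, z = _place_nuclei(config.n_cells, rng, (340, 340), 21, 20.0) if config.n_cells else ([], [], [])
    rows, tr1, tr2 = [], [], []
    i = 0
    for cat in sorted(counts):
        for _ in range(counts[cat]):
            roi_id = f"cell{i:04d}"
            kf, kd, _td_draw = config.rates.draw(rng)
            amp = rng.uniform(*config.amplitude_range)
            m1, m2, origin2 = CATEGORY_MODELS[cat]
            sac_p = KineticParams(amp, kf, kd)
            dac_p = DualActivationParams(amp, kf, kd, t_d=td)
            tr1.append(gen_trace(m1, sac_p, p1, config.noise, rng, roi_id=roi_id))
            p = dac_p if m2 == "DAC" else sac_p
            tr2.append(gen_trace(m2, p, p2, config.noise, rng, roi_id=roi_id, time_origin=origin2))
            rows.append(
                dict(
                    roi_id=roi_id,
                    model_kind=m2,
                    amplitude=amp,
                    k_f=kf,
                    k_d=kd,
                    t_d=td if m2 == "DAC" else np.nan,
                    time_origin=origin2,
                    x=x[i],
                    y=y[i],
                    z=z[i],
                    diameter_px=20.0,
                    baseline_du=50.0,
                    category=cat,
                )
            )
            i += 1
    truth = SyntheticTruth(pd.DataFrame(rows, columns=TRUTH_COLUMNS))
    return DualSessionDataset(tr1, tr2, truth, p1, p2)
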
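"""Per-ROI fluorescence time-series container and CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FluorescenceTrace", "traces_to_frame", "frame_to_traces"]


@dataclass
class FluorescenceTrace:
    """Background-referenced fluorescence of one ROI over an imaging session.

    Attributes
    ----------
    roi_id : str
        ROI label.
    time_points : ndarray
        Minutes, strictly increasing, laboratory time.
    values : ndarray
        Fluorescence in D.U. after background subtraction; same length.
    background : ndarray or None
        Per-time-point background estimate in D.U. (None for model-generated
        traces, which are background-free by construction).
    recenter_dx, recenter_dy : ndarray or None
        Lateral ROI re-centering displacement applied at each time point, px.
    flags : list of str
        Per-trace quality flags accumulated during extraction.
    """

    roi_id: str
    time_points: np.ndarray
    values: np.ndarray
    background: np.ndarray | None = None
    recenter_dx: np.ndarray | None = None
    recenter_dy: np.ndarray | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_points = np.asarray(self.time_points, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_points.shape != self.values.shape:
            raise ValueError("time_points and values must have equal length")
        if self.time_points.size and np.any(np.diff(self.time_points) <= 0):
            raise ValueError("time_points must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    def __len__(self) -> int:
        return self.time_points.size


def traces_to_frame(traces) -> pd.DataFrame:
    """Long-format table: one row per (roi_id, time point)."""
    rows = []
    for tr in traces:
        n = len(tr)
        z = np.zeros(n)
        rows.append(
            pd.DataFrame(
                {
                    "roi_id": tr.roi_id,
                    "time_min": tr.time_points,
                    "value_du": tr.values,
                    "background_du": tr.background if tr.background is not None else z,
                    "recenter_dx": tr.recenter_dx if tr.recenter_dx is not None else z,
                    "recenter_dy": tr.recenter_dy if tr.recenter_dy is not None else z,
                    "flags": ";".join(tr.flags),
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "roi_id",
                "time_min",
                "value_du",
                "background_du",
                "recenter_dx",
                "recenter_dy",
                "flags",
            ]
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list:
    """Rebuild :class:`FluorescenceTrace` objects from a long-format table."""
    out = []
    for roi_id, grp in df.groupby("roi_id", sort=False):
        grp = grp.sort_values("time_min")
        flags = []
        if "flags" in grp and len(grp):
            raw = grp["flags"].iloc[0]
            if isinstance(raw, str) and raw:
                flags = raw.split(";")
        out.append(
            FluorescenceTrace(
                roi_id=str(roi_id),
                time_points=grp["time_min"].to_numpy(),
                values=grp["value_du"].to_numpy(),
                background=grp["background_du"].to_numpy() if "background_du" in grp else None,
                recenter_dx=grp["recenter_dx"].to_numpy() if "recenter_dx" in grp else None,
                recenter_dy=grp["recenter_dy"].to_numpy() if "recenter_dy" in grp else None,
                flags=flags,
            )
        )
    return out
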
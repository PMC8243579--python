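"""File I/O: commented CSV tables, TIFF stack series with manifests, YAML config."""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .synthetic import SamplingProtocol

__all__ = [
    "write_table",
    "read_table",
    "write_stack_series",
    "read_stack_series",
    "config_hash",
    "load_config",
    "protocol_from_manifest",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: dict) -> str:
    items = {"version": __version__, **meta}
    return "".join(f"# {k}={v}\n" for k, v in items.items())


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """CSV with '#'-prefixed provenance header (version, config hash, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    path.write_text(_header_lines(meta or {}) + buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_stack_series(stack4d: np.ndarray, protocol: SamplingProtocol, out_dir, meta=None):
    """One multi-page TIFF per time point plus a manifest CSV.

    Returns the manifest path.  The manifest has columns (time_min, filename)
    with filenames relative to the manifest's directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(protocol.time_points):
        fn = f"stack_t{int(round(t)):04d}.tif"
        tifffile.imwrite(out_dir / fn, stack4d[i].astype(np.float32))
        rows.append({"time_min": float(t), "filename": fn})
    manifest = out_dir / "manifest.csv"
    write_table(pd.DataFrame(rows), manifest, meta or {})
    return manifest


def read_stack_series(manifest_path) -> dict:
    """{time_min: 3D stack} from a manifest CSV."""
    manifest_path = Path(manifest_path)
    df = read_table(manifest_path)
    out = {}
    for row in df.itertuples():
        out[float(row.time_min)] = tifffile.imread(manifest_path.parent / row.filename)
    return out


def protocol_from_manifest(manifest_path, name: str = "custom") -> SamplingProtocol:
    df = read_table(manifest_path)
    return SamplingProtocol(name, np.sort(df["time_min"].to_numpy(float)))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
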
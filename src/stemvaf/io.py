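"""Readers, writers and configuration for the pipeline file formats.

TSV with a header is the canonical tabular dialect (CSV accepted on read):

* burden list -- single column ``burden`` of non-negative integers;
* cell x variant matrix -- one row per cell, binary entries, variant ids as
  header;
* VAF spectrum -- two columns ``abundance``, ``count``;
* bulk frequency list -- single column ``frequency`` (one row per variant);
* run configuration -- flat ``key = value`` lines, keys named exactly as
  the model-parameter fields;
* manifest -- JSON sidecar with resolved parameters, seed and version.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .burden import BurdenSample
from .params import ModelParams, build_params

__all__ = [
    "read_burdens", "write_burdens",
    "read_cell_variant_matrix", "write_cell_variant_matrix",
    "read_vaf_table", "write_vaf_table",
    "read_frequencies", "write_frequencies",
    "read_config", "params_from_config", "params_to_dict",
    "write_manifest",
]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_burdens(path) -> BurdenSample:
    """Single-column burden TSV/CSV -> :class:`BurdenSample`."""
    df = pd.read_csv(path, sep=_sep(path))
    if "burden" not in df.columns:
        raise ValueError(f"{path}: expected a 'burden' column")
    col = df["burden"]
    bad = col[~col.apply(lambda x: float(x).is_integer() and x >= 0)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad.index[:5])
        raise ValueError(f"{path}: non-integer burden entries at line(s) {lines}")
    return BurdenSample(col.to_numpy(dtype=np.int64))


def write_burdens(sample: BurdenSample, path) -> Path:
    path = Path(path)
    pd.DataFrame({"burden": sample.burdens}).to_csv(
        path, sep=_sep(path), index=False)
    return path


def read_cell_variant_matrix(path) -> np.ndarray:
    """Binary cell x variant TSV (cells = rows) -> int8 array."""
    df = pd.read_csv(path, sep=_sep(path))
    mat = df.to_numpy()
    if mat.size and not np.isin(mat, (0, 1)).all():
        rows = np.nonzero(~np.isin(mat, (0, 1)).all(axis=1))[0]
        raise ValueError(
            f"{path}: non-binary entries at line(s) "
            + ", ".join(str(r + 2) for r in rows[:5]))
    return mat.astype(np.int8)


def write_cell_variant_matrix(matrix: np.ndarray, path) -> Path:
    path = Path(path)
    matrix = np.asarray(matrix)
    cols = [f"v{i}" for i in range(matrix.shape[1])]
    pd.DataFrame(matrix, columns=cols).to_csv(path, sep=_sep(path), index=False)
    return path


def read_vaf_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column (abundance, count) table -> (abundances, counts)."""
    df = pd.read_csv(path, sep=_sep(path))
    missing = {"abundance", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return (df["abundance"].to_numpy(dtype=np.int64),
            df["count"].to_numpy(dtype=float))


def write_vaf_table(abundance, counts, path) -> Path:
    path = Path(path)
    pd.DataFrame({"abundance": np.asarray(abundance),
                  "count": np.asarray(counts)}).to_csv(
        path, sep=_sep(path), index=False)
    return path


def read_frequencies(path) -> np.ndarray:
    df = pd.read_csv(path, sep=_sep(path))
    if "frequency" not in df.columns:
        raise ValueError(f"{path}: expected a 'frequency' column")
    return df["frequency"].to_numpy(dtype=float)


def write_frequencies(freqs, path) -> Path:
    path = Path(path)
    pd.DataFrame({"frequency": np.asarray(freqs)}).to_csv(
        path, sep=_sep(path), index=False)
    return path


# --- configuration ---------------------------------------------------------

_PARAM_KEYS = {"NM", "tM", "NH", "lam", "p", "mu", "growth_kind",
               "linear_slope"}
_RUN_KEYS = {"t_obs", "S", "seed", "n_grid", "depth", "age", "ages",
             "dispersion", "outdir"}


def read_config(path) -> dict:
    """Flat ``key = value`` config; unknown keys are rejected."""
    out = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in _PARAM_KEYS | _RUN_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        out[key] = val
    return out


def params_from_config(cfg: dict) -> ModelParams:
    kw = {}
    for key in _PARAM_KEYS & set(cfg):
        val = cfg[key]
        kw[key] = val if key == "growth_kind" else float(val)
    return build_params(**kw)


def params_to_dict(params: ModelParams) -> dict:
    return asdict(params)


def write_manifest(payload: dict, path) -> Path:
    from . import __version__
    path = Path(path)
    doc = dict(payload)
    doc["stemvaf_version"] = __version__
    path.write_text(json.dumps(doc, indent=2, default=float) + "\n")
    return path
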
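"""Study-like synthetic datasets for end-to-end pipeline testing.

Two dataset kinds mirror the data modalities the estimators consume:

* ``single-cell`` -- one population simulated through all three phases, a
  uniform sample of ``S`` cells (default 89, the size of the reference
  hematopoietic dataset, observed at age 59), written as a per-cell burden
  list, a binary cell x variant matrix and the sample VAF spectrum;
* ``bulk-cohort`` -- per-donor bulk VAF tables: the expected spectrum from
  the VAF equation at each donor age, a Poisson-realized variant set
  (independent-sites approximation) and binomial read-depth noise.

The generating parameters and seed ("truth") are recorded in a manifest next
to every dataset, so the inference chain can be validated against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as svio
from .burden import BurdenSample
from .params import ModelParams
from .sampling import SampledSpectrum, read_depth_noise
from .simulator import Genealogy, simulate
from .vafpde import evolve_expected_vaf

__all__ = ["SyntheticDataset", "make_single_cell_dataset", "make_bulk_cohort"]


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus optional on-disk file map."""

    kind: str
    truth: dict
    burdens: BurdenSample | None = None
    matrix: np.ndarray | None = None  # cells x variants, binary
    vaf: np.ndarray | None = None     # sample spectrum (single-cell kind)
    donors: dict = field(default_factory=dict)  # age -> frequency array
    files: dict = field(default_factory=dict)


def _cell_variant_matrix(g: Genealogy, cells: np.ndarray) -> np.ndarray:
    """Binary occupancy matrix of all variants carried by ``cells``.

    Branches shared along root paths give identical columns for the variants
    they carry; columns are ordered by global variant id.
    """
    parent = g.parent
    nmut = g.nmut
    paths = []
    branches = set()
    for c in cells.tolist():
        path = []
        i = int(c)
        while i >= 0:
            if nmut[i] > 0:
                path.append(i)
                branches.add(i)
            i = int(parent[i])
        paths.append(set(path))
    branches = sorted(branches)
    col_of = {}
    col = 0
    for b in branches:
        col_of[b] = (col, col + int(nmut[b]))
        col += int(nmut[b])
    mat = np.zeros((len(cells), col), dtype=np.int8)
    for r, path in enumerate(paths):
        for b in path:
            lo, hi = col_of[b]
            mat[r, lo:hi] = 1
    return mat


def make_single_cell_dataset(
    params: ModelParams,
    S: int = 89,
    age: float = 59.0,
    seed=None,
    outdir=None,
) -> SyntheticDataset:
    """Simulate, sample S cells, and package burdens/matrix/VAF.

    With ``outdir`` set, writes ``burdens.tsv``, ``matrix.tsv``, ``vaf.tsv``
    and ``manifest.json`` and records the paths in ``files``.
    """
    if S > params.NM:
        raise ValueError("sample size exceeds the mature population")
    rng = np.random.default_rng(seed)
    g = simulate(params, age, seed=rng)
    cells = g.sample_cells(S, seed=rng)
    sample_b = g.burdens_of(cells)
    spectrum = g.spectrum_of(cells)
    truth = {"params": svio.params_to_dict(params), "seed": seed,
             "S": S, "age": age}
    matrix = _cell_variant_matrix(g, cells)
    ds = SyntheticDataset(kind="single-cell", truth=truth, burdens=sample_b,
                          matrix=matrix, vaf=spectrum.astype(float))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ds.files["burdens"] = svio.write_burdens(
            sample_b, outdir / "burdens.tsv")
        ds.files["matrix"] = svio.write_cell_variant_matrix(
            matrix, outdir / "matrix.tsv")
        ds.files["vaf"] = svio.write_vaf_table(
            np.arange(1, S + 1), spectrum, outdir / "vaf.tsv")
        ds.files["manifest"] = svio.write_manifest(
            truth, outdir / "manifest.json")
    return ds


def make_bulk_cohort(
    ages,
    params: ModelParams,
    depth: int = 100,
    seed=None,
    n_grid: int = 400,
    outdir=None,
) -> SyntheticDataset:
    """Per-donor bulk VAF tables from the expected spectrum + noise.

    For each age: solve the VAF equation, convert the density to expected
    counts per integer abundance, draw realized counts ``Poisson`` around
    them (independent sites), and jitter each variant's frequency with
    binomial read sampling at ``depth``.  Same age and seed give identical
    donors.
    """
    ages = list(ages)
    if any(a <= 0 for a in ages):
        raise ValueError("ages must be positive")
    truth = {"params": svio.params_to_dict(params), "seed": seed,
             "ages": ages, "depth": depth}
    ds = SyntheticDataset(kind="bulk-cohort", truth=truth)
    N = int(round(params.NM))
    n_grid = min(n_grid, N - 1)
    for idx, age in enumerate(ages):
        rng = np.random.default_rng(
            None if seed is None else (int(seed) + 1000 * idx) % (2**31))
        sol = evolve_expected_vaf(params, age, n=n_grid)
        j = np.arange(1, N)
        expected = np.clip(sol.interp(j), 0.0, None)  # unit-width classes
        realized = rng.poisson(expected)
        samp = SampledSpectrum(S=N, counts=realized.astype(float),
                               parent_N=N)
        freqs = read_depth_noise(samp, depth=depth, seed=rng)
        freqs = freqs[freqs > 0]
        ds.donors[age] = freqs
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            path = outdir / f"donor_{idx:02d}_age{age:g}.tsv"
            ds.files[f"donor_{idx:02d}"] = svio.write_frequencies(freqs, path)
    if outdir is not None:
        ds.files["manifest"] = svio.write_manifest(
            truth, Path(outdir) / "manifest.json")
    return ds
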
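"""CSV serialization of spectra sets.

Layout: one header row with ``sample_id,label,site`` followed by the
wavenumbers in descending order; one row per sample.  UTF-8, '.' decimal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grid import WavenumberGrid
from .synthetic import SpectraSet

__all__ = ["write_spectra_csv", "read_spectra_csv"]

_META_COLS = ["sample_id", "label", "site"]


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    df = pd.DataFrame(spectra.absorbance, columns=[f"{v:g}" for v in spectra.grid.values])
    df.insert(0, "site", spectra.site)
    df.insert(0, "label", spectra.labels)
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> SpectraSet:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"spectra CSV is missing columns {missing}")
    wavenumbers = np.array([float(c) for c in df.columns if c not in _META_COLS])
    if wavenumbers.size < 2:
        raise ValueError("spectra CSV must contain at least two wavenumber columns")
    steps = -np.diff(wavenumbers)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
        raise ValueError("wavenumber header must be uniformly descending")
    grid = WavenumberGrid(float(wavenumbers[0]), float(wavenumbers[-1]), float(steps[0]))
    sites = df["site"].unique()
    if len(sites) != 1:
        raise ValueError(f"spectra CSV mixes body sites {sorted(sites)}")
    return SpectraSet(
        grid=grid,
        absorbance=df.drop(columns=_META_COLS).to_numpy(dtype=float),
        labels=df["label"].to_numpy(),
        site=str(sites[0]),
        sample_ids=[str(s) for s in df["sample_id"]],
    )
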
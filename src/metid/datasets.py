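"""Packaged reference tables and the 21-metabolite fixture set.

The reference tables carry the published exact masses, kinetic parameters
and thermodynamic-cycle terms used throughout the tests and analyses; the
metabolite manifest lists the 21 identified metabolites with their
modification truths, from which noise-free fixture spectra are rendered at
run time (nothing binary ships with the package).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import List, Tuple

import pandas as pd

from .fragment_model import FragmentLibrary, ModificationSet, default_library
from .spectra_io import Spectrum
from .synthetic_data import SpectrumSimConfig, simulate_spectrum

__all__ = [
    "published_exact_masses",
    "published_kinetics",
    "published_thermo",
    "metabolite_manifest",
    "fixture_spectra",
]


def _read(name: str) -> pd.DataFrame:
    path = Path(str(resources.files("metid.data").joinpath(name)))
    return pd.read_csv(path, sep="\t", comment="#")


def published_exact_masses() -> pd.DataFrame:
    """Theoretical vs measured fragment masses with the printed ppm column."""
    return _read("table2_exact_masses.tsv")


def published_kinetics() -> pd.DataFrame:
    """Apparent Vmax/Km (n=4) and printed CL_int per metabolite."""
    df = _read("table3_kinetics.tsv")
    return df.astype({"vmax": float, "km": float})


def published_thermo() -> pd.DataFrame:
    """Demethylation thermodynamic-cycle terms per candidate site."""
    return _read("table4_thermo.tsv")


def metabolite_manifest() -> pd.DataFrame:
    """The 21 identified metabolites with modification truths and classes."""
    return _read("srl_metabolites.tsv")


def fixture_spectra(
    lib: FragmentLibrary | None = None,
    ppm_sigma: float = 0.0,
    n_decoys: int = 0,
    seed: int = 0,
) -> List[Tuple[pd.Series, Spectrum]]:
    """Render the manifest into (manifest row, spectrum) pairs.

    Noise-free by default — the exact inverse-image test bed; pass a
    mass-error sigma and decoy count for stress tests.
    """
    lib = lib or default_library()
    out = []
    for i, row in metabolite_manifest().iterrows():
        truth = ModificationSet.parse(row["truth"])
        cfg = SpectrumSimConfig(
            truth=truth, ppm_sigma=ppm_sigma, n_decoys=n_decoys, seed=seed + i
        )
        spec = simulate_spectrum(lib, cfg)
        spec = Spectrum(spec.mz, spec.intensity, spec.precursor_mz, spec.adduct, id=row["id"])
        out.append((row, spec))
    return out
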
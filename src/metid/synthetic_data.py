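"""Seeded generators for every input the pipeline consumes.

No raw data are deposited with this kind of microsomal-metabolism study, so
the test bed is synthetic: QTOF-style sodiated MS/MS peak lists with
Gaussian ppm-scale mass error and uniform decoy peaks, Michaelis-Menten
velocity data with multiplicative (log-normal) noise on the experimental
substrate grid, and positive-truncated Gaussian atom-to-heme-iron distance
trajectories.  Everything is bit-reproducible given (config, seed).

What the spectrum simulator emulates: the fragment positions, the
water-loss-dominance signature of C23/C24 hydroxylation, the methanol-loss
signature of C45/C46 hydroxylation, and a mass-error scale matching the
0.0-3.5 ppm spread of the published exact-mass table (default sigma =
2 ppm).  What it does not emulate: chromatography, isotope envelopes,
detector saturation, and realistic intensity physics (intensities are flat
apart from the rule signatures; the solver must not rely on them except
for the water-loss dominance rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chem_mass import SHIFTS
from .fragment_model import (
    ExpectedIon,
    FragmentLibrary,
    ModificationSet,
    expected_peaks,
    fragment_shift,
)
from .spectra_io import Spectrum

__all__ = [
    "SpectrumSimConfig",
    "KineticsSimConfig",
    "KineticsDataset",
    "DistanceTrajectory",
    "simulate_spectrum",
    "simulate_kinetics",
    "simulate_distance_traj",
    "PAPER_SUBSTRATE_GRID_UM",
]

#: Substrate concentrations (µM) of the microsomal formation-kinetics design.
PAPER_SUBSTRATE_GRID_UM: Tuple[float, ...] = (3.25, 7.5, 15.0, 30.0, 60.0, 90.0, 120.0)

#: Decoys must stay this far (ppm) from every expected ion.
DECOY_EXCLUSION_PPM = 10.0


@dataclass(frozen=True)
class SpectrumSimConfig:
    truth: ModificationSet
    ppm_sigma: float = 2.0
    n_decoys: int = 20
    decoy_range: Tuple[float, float] = (300.0, 1000.0)
    base_intensity: float = 100.0
    waterloss_dominance: float = 1.5  # water-loss satellite / parent intensity for C23/C24
    methanol_satellite_factor: float = 0.6
    diagnostic_factor: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be >= 0")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")


def simulate_spectrum(lib: FragmentLibrary, cfg: SpectrumSimConfig) -> Spectrum:
    """Render a modification truth into a noisy peak list.

    Expected ions are perturbed by Normal(0, sigma*mz/1e6); decoys are drawn
    uniformly in ``decoy_range`` excluding +-10 ppm of any expected ion; the
    precursor is the shifted molecular ion.  For C23/C24 truths the
    water-loss satellite intensity exceeds its parent fragment (the
    dominance signature the inverse solver's rule R2 keys on).
    """
    rng = np.random.default_rng(cfg.seed)
    ions = expected_peaks(lib, cfg.truth)
    mzs: List[float] = []
    intens: List[float] = []
    parent_int = {}
    for ion in ions:
        if ion.kind == "fragment":
            inten = cfg.base_intensity
            parent_int[ion.source_label] = inten
        elif ion.kind == "water_loss_satellite":
            inten = cfg.waterloss_dominance * parent_int.get(ion.source_label, cfg.base_intensity)
        elif ion.kind == "methanol_loss_satellite":
            inten = cfg.methanol_satellite_factor * parent_int.get(ion.source_label, cfg.base_intensity)
        else:  # diagnostic
            inten = cfg.diagnostic_factor * cfg.base_intensity
        mz = ion.mz * (1 + rng.normal(0.0, cfg.ppm_sigma) * 1e-6)
        mzs.append(mz)
        intens.append(inten)
    # decoys: uniform, rejected within 10 ppm of any expected ion
    expected_mz = np.array([ion.mz for ion in ions])
    lo, hi = cfg.decoy_range
    if hi <= lo:
        raise ValueError("empty decoy range")
    n_placed = 0
    attempts = 0
    while n_placed < cfg.n_decoys:
        attempts += 1
        if attempts > 1000 * max(cfg.n_decoys, 1):
            raise ValueError("decoy range exhausted after exclusions")
        x = rng.uniform(lo, hi)
        if np.min(np.abs(x - expected_mz) / expected_mz) * 1e6 < DECOY_EXCLUSION_PPM:
            continue
        mzs.append(x)
        intens.append(rng.uniform(1.0, 30.0))
        n_placed += 1
    mol_delta, _ = fragment_shift(lib.molecular_ion, cfg.truth)
    precursor = lib.molecular_ion.theoretical_mz + mol_delta
    return Spectrum(
        np.array(mzs),
        np.array(intens),
        precursor_mz=precursor,
        adduct=lib.adduct.name,
        id=f"sim:{cfg.truth}:seed={cfg.seed}",
    )


@dataclass(frozen=True)
class KineticsDataset:
    """Formation-velocity measurements per substrate concentration."""

    substrate_uM: np.ndarray  # one entry per observation
    velocity: np.ndarray  # pmol/mg protein/min
    metabolite_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_uM, dtype=float)
        v = np.asarray(self.velocity, dtype=float)
        if s.shape != v.shape:
            raise ValueError("substrate and velocity arrays differ in length")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be > 0")
        object.__setattr__(self, "substrate_uM", s)
        object.__setattr__(self, "velocity", v)

    @property
    def n_distinct_concentrations(self) -> int:
        return int(np.unique(self.substrate_uM).size)

    @property
    def replicates_per_concentration(self) -> dict:
        conc, counts = np.unique(self.substrate_uM, return_counts=True)
        return dict(zip(conc.tolist(), counts.tolist()))


@dataclass(frozen=True)
class KineticsSimConfig:
    vmax: float
    km: float
    substrate_uM: Tuple[float, ...] = PAPER_SUBSTRATE_GRID_UM
    n_rep: int = 4
    cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be > 0")


def simulate_kinetics(cfg: KineticsSimConfig, metabolite_id: str = "sim") -> KineticsDataset:
    """v = Vmax*S/(Km+S) x LogNormal(0, cv), per replicate; seed-deterministic."""
    rng = np.random.default_rng(cfg.seed)
    s = np.repeat(np.asarray(cfg.substrate_uM, dtype=float), cfg.n_rep)
    v_true = cfg.vmax * s / (cfg.km + s)
    if cfg.cv > 0:
        noise = rng.lognormal(mean=0.0, sigma=cfg.cv, size=s.size)
    else:
        noise = np.ones_like(s)
    return KineticsDataset(s, v_true * noise, metabolite_id=metabolite_id)


@dataclass(frozen=True)
class DistanceTrajectory:
    """Per-frame distance (Å) of one candidate atom to the heme iron."""

    atom_id: str
    distances: np.ndarray
    frame_dt_ps: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if np.any(d <= 0):
            raise ValueError("distances must be > 0")
        object.__setattr__(self, "distances", d)

    @property
    def n_frames(self) -> int:
        return int(self.distances.size)


def simulate_distance_traj(
    atom_id: str,
    mu: float,
    sigma: float,
    n_frames: int,
    seed: int,
    frame_dt_ps: float = 1.0,
) -> DistanceTrajectory:
    """Positive-truncated Normal(mu, sigma) distance draws; seed-deterministic."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if sigma == 0:
        d = np.full(n_frames, mu)
    else:
        d = rng.normal(mu, sigma, size=n_frames)
        while True:  # redraw the non-physical tail
            bad = d <= 0
            if not bad.any():
                break
            d[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
    return DistanceTrajectory(atom_id, d, frame_dt_ps)
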
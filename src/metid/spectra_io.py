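"""Peak-list I/O (CSV and MGF) and ppm-tolerance peak matching.

A ``Spectrum`` is a sorted (m/z, intensity) peak list with precursor and
adduct metadata.  Matching assigns each expected ion to the nearest
observed peak within a ppm tolerance (default 5 ppm, the confirmation rule
used throughout this kind of high-resolution metabolite work); ties break
on smallest |ppm|, then highest intensity.  One observed peak may satisfy
several expected ions — such degeneracy is recorded, never hidden.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from pyteomics import mgf as _mgf

from .chem_mass import ppm_error
from .fragment_model import ExpectedIon

__all__ = [
    "Spectrum",
    "PeakMatch",
    "MatchResult",
    "read_peaklist",
    "write_peaklist",
    "match_peaks",
    "read_mzml",
]

DEFAULT_TOL_PPM = 5.0


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list with precursor metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    adduct: str = "M+Na"
    id: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.size == 0:
            raise ValueError("no peaks")
        if mz.shape != inten.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(inten < 0):
            raise ValueError("negative intensity")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    def __len__(self) -> int:
        return int(self.mz.size)

    def normalized(self) -> "Spectrum":
        """Intensities rescaled so the base peak is 100."""
        base = float(self.intensity.max())
        scale = 100.0 / base if base > 0 else 1.0
        return Spectrum(self.mz, self.intensity * scale, self.precursor_mz, self.adduct, self.id)


def read_peaklist(path: Union[str, Path], format: Optional[str] = None) -> Spectrum:
    """Read a spectrum from ``mz,intensity`` CSV or standard MGF.

    The format is inferred from the suffix when not given.  Peaks are
    sorted on read; malformed lines raise with their line number.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        mzs: List[float] = []
        intens: List[float] = []
        precursor = 0.0
        spec_id = path.stem
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            for lineno, row in enumerate(reader, 1):
                if not row or row[0].startswith("#"):
                    if row and row[0].startswith("#precursor"):
                        precursor = float(row[0].split("=", 1)[1])
                    continue
                if row[0].strip().lower() == "mz":  # header row
                    continue
                try:
                    mzs.append(float(row[0]))
                    intens.append(float(row[1]))
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path} line {lineno}: malformed peak row {row!r}") from exc
        if not mzs:
            raise ValueError(f"{path}: no peaks")
        return Spectrum(np.array(mzs), np.array(intens), precursor, id=spec_id)
    if fmt == "mgf":
        with _mgf.MGF(str(path)) as reader:
            try:
                entry = next(iter(reader))
            except StopIteration:
                raise ValueError(f"{path}: no spectra in MGF") from None
        mz = np.asarray(entry["m/z array"], dtype=float)
        if mz.size == 0:
            raise ValueError(f"{path}: no peaks")
        pepmass = entry["params"].get("pepmass", (0.0,))
        return Spectrum(
            mz,
            np.asarray(entry["intensity array"], dtype=float),
            float(pepmass[0]) if pepmass else 0.0,
            id=str(entry["params"].get("title", path.stem)),
        )
    raise ValueError(f"unknown peak-list format: {fmt!r}")


def write_peaklist(spec: Spectrum, path: Union[str, Path], format: Optional[str] = None) -> Path:
    """Write a spectrum as CSV or MGF (round-trips peaks to 6 dp)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            fh.write(f"#precursor_mz={spec.precursor_mz:.6f}\n")
            fh.write("mz,intensity\n")
            for m, i in zip(spec.mz, spec.intensity):
                fh.write(f"{m:.6f},{i:.6f}\n")
        return path
    if fmt == "mgf":
        entry = {
            "m/z array": spec.mz,
            "intensity array": spec.intensity,
            "params": {"title": spec.id or "spectrum", "pepmass": spec.precursor_mz, "charge": "1+"},
        }
        _mgf.write([entry], str(path))
        return path
    raise ValueError(f"unknown peak-list format: {fmt!r}")


def read_mzml(path: Union[str, Path], index: int = 0) -> Spectrum:
    """Optional adapter: read one spectrum from an mzML file (pyteomics)."""
    from pyteomics import mzml as _mzml  # local import; optional pathway

    with _mzml.MzML(str(path)) as reader:
        for i, entry in enumerate(reader):
            if i == index:
                precursor = 0.0
                try:
                    precursor = float(
                        entry["precursorList"]["precursor"][0]["selectedIonList"][
                            "selectedIon"
                        ][0]["selected ion m/z"]
                    )
                except (KeyError, IndexError):
                    pass
                return Spectrum(
                    np.asarray(entry["m/z array"], dtype=float),
                    np.asarray(entry["intensity array"], dtype=float),
                    precursor,
                    id=str(entry.get("id", index)),
                )
    raise ValueError(f"{path}: spectrum index {index} not found")


@dataclass(frozen=True)
class PeakMatch:
    """An expected ion matched to an observed peak within tolerance."""

    fragment_label: str
    observed_mz: float
    expected_mz: float
    ppm: float
    shift_trail: Tuple[str, ...]
    intensity: float
    kind: str = "fragment"
    source_label: str = ""
    degenerate: bool = False  # observed peak also satisfies another expected ion


@dataclass(frozen=True)
class MatchResult:
    matches: Tuple[PeakMatch, ...]
    unmatched: Tuple[ExpectedIon, ...]

    def by_label(self) -> dict:
        return {m.fragment_label: m for m in self.matches}


def match_peaks(
    spec: Spectrum,
    expected: Sequence[ExpectedIon],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> MatchResult:
    """Match each expected ion to the nearest observed peak within tol_ppm."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    mz = spec.mz
    matches: List[PeakMatch] = []
    unmatched: List[ExpectedIon] = []
    used: dict = {}
    for ion in expected:
        lo = ion.mz * (1 - tol_ppm * 1e-6)
        hi = ion.mz * (1 + tol_ppm * 1e-6)
        i0, i1 = np.searchsorted(mz, [lo, hi])
        if i1 <= i0:
            unmatched.append(ion)
            continue
        cand = np.arange(i0, i1)
        ppms = np.array([ppm_error(mz[i], ion.mz) for i in cand])
        # smallest |ppm|, then highest intensity
        order = sorted(
            range(len(cand)), key=lambda j: (ppms[j], -spec.intensity[cand[j]])
        )
        best = cand[order[0]]
        matches.append(
            PeakMatch(
                fragment_label=ion.label,
                observed_mz=float(mz[best]),
                expected_mz=ion.mz,
                ppm=float(ppms[order[0]]),
                shift_trail=ion.shift_trail,
                intensity=float(spec.intensity[best]),
                kind=ion.kind,
                source_label=ion.source_label,
            )
        )
        used.setdefault(int(best), []).append(len(matches) - 1)
    # flag degeneracy: one observed peak satisfying several expected ions
    final: List[PeakMatch] = list(matches)
    for idxs in used.values():
        if len(idxs) > 1:
            for i in idxs:
                m = final[i]
                final[i] = PeakMatch(
                    m.fragment_label,
                    m.observed_mz,
                    m.expected_mz,
                    m.ppm,
                    m.shift_trail,
                    m.intensity,
                    m.kind,
                    m.source_label,
                    degenerate=True,
                )
    return MatchResult(tuple(final), tuple(unmatched))
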
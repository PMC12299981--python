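"""Sirolimus fragment library and the forward spectrum model.

The library holds the alpha-cleavage fragments (A-R) of sodiated sirolimus
together with the carbon positions each fragment retains ("coverage"), the
MSn fragmentation-tree parentage, and site-specific hydroxylation
diagnostic ions.  The forward model maps a modification hypothesis (up to
two O-demethylations / hydroxylations) to the full set of expected ions:

* every fragment whose coverage intersects a modified site shifts by the
  summed mass deltas of the modifications that hit it;
* hydroxylation at a methyl carbon (C45/C46) additionally emits a methanol
  -loss satellite on each shifted fragment (rule R1);
* hydroxylation at C23/C24 emits a water-loss satellite expected to
  dominate its parent's intensity (rule R2);
* site-specific diagnostic ions are appended for hydroxylated sites, with
  any co-modification shift applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .chem_mass import (
    ADDUCTS,
    SHIFTS,
    AdductSpec,
    ElementalFormula,
    MassShift,
    adduct_mz,
    round_half_up,
)

__all__ = [
    "Site",
    "SRL_FORMULA",
    "DEMETHYLATION_SITES",
    "HYDROXYLATION_SITES",
    "IUPAC_TO_CAS",
    "ModificationEntry",
    "ModificationSet",
    "FragmentDef",
    "FragmentLibrary",
    "ExpectedIon",
    "load_library",
    "default_library",
    "expected_peaks",
    "parse_site",
    "site_label",
]

#: A metabolic site: a frozenset of carbon positions (ints) and/or the token
#: "pip" for the unresolved piperidine ring C3-C6.  Singletons are resolved
#: sites; pairs like {23,24} are candidate pairs MS evidence cannot split.
Site = FrozenSet[Union[int, str]]

SRL_FORMULA = ElementalFormula.parse("C51H79NO13")

#: Methoxy carbons open to O-demethylation.
DEMETHYLATION_SITES: Tuple[Site, ...] = (
    frozenset({16}),
    frozenset({27}),
    frozenset({39}),
)

#: Hydroxylation site units: resolved carbons, the two candidate pairs, and
#: the piperidine ring token.
HYDROXYLATION_SITES: Tuple[Site, ...] = (
    frozenset({11}),
    frozenset({12}),
    frozenset({14}),
    frozenset({23, 24}),
    frozenset({25}),
    frozenset({45, 46}),
    frozenset({49}),
    frozenset({"pip"}),
)

#: Minimal IUPAC -> Chemical Abstracts position map (39-O-desmethyl is
#: 41-O-desmethyl in CAS numbering; 16 is 7).
IUPAC_TO_CAS: Dict[int, int] = {39: 41, 16: 7}

_ALL_TOKENS: Set[Union[int, str]] = set(range(1, 53)) | {"pip"}


def parse_site(text: str) -> Site:
    """Parse a site string: ``16``, ``23/24``, or ``pip``."""
    parts = []
    for tok in text.split("/"):
        tok = tok.strip()
        if tok == "pip":
            parts.append("pip")
        else:
            n = int(tok)
            if not 1 <= n <= 52:
                raise ValueError(f"carbon position out of range 1-52: {n}")
            parts.append(n)
    return frozenset(parts)


def site_label(site: Site) -> str:
    """Canonical display form of a site: ``16``, ``23/24``, ``pip``."""
    return "/".join(
        str(t) for t in sorted(site, key=lambda x: (isinstance(x, str), x))
    )


@dataclass(frozen=True)
class ModificationEntry:
    """One modification: type plus site (possibly an unresolved candidate set)."""

    type: str  # "demethylation" | "hydroxylation"
    site: Site

    def __post_init__(self) -> None:
        if self.type not in ("demethylation", "hydroxylation"):
            raise ValueError(f"unknown modification type: {self.type!r}")
        if not self.site:
            raise ValueError("modification site must be non-empty")
        bad = set(self.site) - _ALL_TOKENS
        if bad:
            raise ValueError(f"site tokens outside 1-52/'pip': {bad}")
        if self.type == "demethylation" and not self.site <= {16, 27, 39}:
            raise ValueError(
                f"demethylation restricted to C16/C27/C39, got {site_label(self.site)}"
            )

    @property
    def delta(self) -> float:
        return SHIFTS[self.type].delta

    def __str__(self) -> str:
        tag = "DM" if self.type == "demethylation" else "OH"
        return f"{tag}@{site_label(self.site)}"


@dataclass(frozen=True)
class ModificationSet:
    """0-2 modification entries (first/second-generation metabolites)."""

    entries: Tuple[ModificationEntry, ...] = ()

    def __post_init__(self) -> None:
        if len(self.entries) > 2:
            raise ValueError("at most two modifications are considered")

    @classmethod
    def parse(cls, text: str) -> "ModificationSet":
        """Parse e.g. ``DM@16``, ``OH@45/46``, ``OH@12+DM@39`` ("" = none)."""
        text = text.strip()
        if not text or text == "-":
            return cls(())
        entries = []
        for part in text.split("+"):
            tag, _, site = part.strip().partition("@")
            mtype = {"DM": "demethylation", "OH": "hydroxylation"}.get(tag.upper())
            if mtype is None:
                raise ValueError(f"unknown modification tag in {part!r}")
            entries.append(ModificationEntry(mtype, parse_site(site)))
        return cls(tuple(entries))

    @property
    def net_delta(self) -> float:
        return sum(e.delta for e in self.entries)

    @property
    def type_multiset(self) -> Tuple[str, ...]:
        return tuple(sorted(e.type for e in self.entries))

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __str__(self) -> str:
        return "+".join(str(e) for e in self.entries) or "(unmodified)"


@dataclass(frozen=True)
class FragmentDef:
    """One library ion: a fragment, the precursor, or a diagnostic ion."""

    label: str
    kind: str  # "precursor" | "alpha_cleavage" | "hydroxylation_diagnostic"
    theoretical_mz: float
    coverage: Site
    parent_label: Optional[str] = None
    diagnostic_site: Optional[Site] = None

    def __post_init__(self) -> None:
        if self.theoretical_mz <= 0:
            raise ValueError(f"{self.label}: theoretical m/z must be > 0")
        if self.kind not in ("precursor", "alpha_cleavage", "hydroxylation_diagnostic"):
            raise ValueError(f"{self.label}: unknown kind {self.kind!r}")
        if self.kind != "hydroxylation_diagnostic" and not self.coverage:
            raise ValueError(f"{self.label}: coverage must be non-empty")
        if self.kind == "hydroxylation_diagnostic" and self.diagnostic_site is None:
            raise ValueError(f"{self.label}: diagnostic ions need a diagnostic_site")


class LibraryValidationError(ValueError):
    """Raised when a fragment-library configuration violates an invariant."""


@dataclass(frozen=True)
class FragmentLibrary:
    """Validated fragment library rooted at the sodiated molecular ion."""

    fragments: Tuple[FragmentDef, ...]
    molecular_formula: ElementalFormula = SRL_FORMULA
    adduct: AdductSpec = ADDUCTS["M+Na"]
    by_label: Dict[str, FragmentDef] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        by_label: Dict[str, FragmentDef] = {}
        for f in self.fragments:
            if f.label in by_label:
                raise LibraryValidationError(f"duplicate fragment label {f.label!r}")
            by_label[f.label] = f
        object.__setattr__(self, "by_label", by_label)
        roots = [f for f in self.fragments if f.kind == "precursor"]
        if len(roots) != 1:
            raise LibraryValidationError("library needs exactly one molecular (precursor) ion")
        root = roots[0]
        # precursor mass must agree with the formula + adduct arithmetic
        want = adduct_mz(self.molecular_formula, self.adduct)
        if abs(root.theoretical_mz - want) > 1e-4:
            raise LibraryValidationError(
                f"molecular ion {root.theoretical_mz} disagrees with "
                f"computed {want:.6f} by > 0.0001 Da"
            )
        # tree: every alpha-cleavage fragment reaches the root, coverage nested
        for f in self.fragments:
            if f.kind != "alpha_cleavage":
                continue
            seen = {f.label}
            node = f
            while node.label != root.label:
                if not node.parent_label or node.parent_label not in by_label:
                    raise LibraryValidationError(f"{f.label}: broken parent chain")
                parent = by_label[node.parent_label]
                if parent.label in seen:
                    raise LibraryValidationError(f"{f.label}: parent cycle")
                if not node.coverage <= parent.coverage:
                    raise LibraryValidationError(
                        f"{node.label}: coverage not a subset of parent {parent.label}"
                    )
                seen.add(parent.label)
                node = parent

    @property
    def molecular_ion(self) -> FragmentDef:
        return next(f for f in self.fragments if f.kind == "precursor")

    @property
    def alpha_fragments(self) -> Tuple[FragmentDef, ...]:
        return tuple(f for f in self.fragments if f.kind == "alpha_cleavage")

    @property
    def diagnostics(self) -> Tuple[FragmentDef, ...]:
        return tuple(f for f in self.fragments if f.kind == "hydroxylation_diagnostic")

    def diagnostics_for(self, site: Site) -> Tuple[FragmentDef, ...]:
        return tuple(d for d in self.diagnostics if d.diagnostic_site == site)


def _parse_coverage(text: str) -> Site:
    tokens: Set[Union[int, str]] = set()
    text = text.strip()
    if text in ("", "-"):
        return frozenset()
    for tok in text.split(","):
        tok = tok.strip()
        if tok == "pip":
            tokens.add("pip")
        elif "-" in tok:
            a, b = tok.split("-")
            tokens.update(range(int(a), int(b) + 1))
        else:
            tokens.add(int(tok))
    bad = tokens - _ALL_TOKENS
    if bad:
        raise LibraryValidationError(f"coverage tokens outside 1-52/'pip': {bad}")
    return frozenset(tokens)


def load_library(
    path: Union[str, Path],
    reference_masses: Optional[Dict[str, float]] = None,
) -> FragmentLibrary:
    """Load and validate a fragment library from tab-separated text.

    Columns: label, kind, mz, parent, coverage, diagnostic_site.  If
    ``reference_masses`` maps labels to 4-dp reference m/z values, any
    stored mass differing from its reference by more than 0.0001 Da after
    4-dp rounding raises ``LibraryValidationError``.
    """
    frags: List[FragmentDef] = []
    with open(path) as fh:
        header: Optional[List[str]] = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            fields = dict(zip(header, line.split("\t")))
            try:
                diag = fields.get("diagnostic_site", "-").strip()
                frags.append(
                    FragmentDef(
                        label=fields["label"].strip(),
                        kind=fields["kind"].strip(),
                        theoretical_mz=float(fields["mz"]),
                        coverage=_parse_coverage(fields.get("coverage", "")),
                        parent_label=(
                            None
                            if fields.get("parent", "-").strip() in ("", "-")
                            else fields["parent"].strip()
                        ),
                        diagnostic_site=None if diag in ("", "-") else parse_site(diag),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise LibraryValidationError(f"{path} line {lineno}: {exc}") from exc
    lib = FragmentLibrary(tuple(frags))
    if reference_masses:
        for label, ref in reference_masses.items():
            frag = lib.by_label.get(label)
            if frag is None:
                raise LibraryValidationError(f"reference fragment {label!r} missing")
            if abs(round_half_up(frag.theoretical_mz, 4) - ref) > 1e-4:
                raise LibraryValidationError(
                    f"{label}: stored m/z {frag.theoretical_mz} does not round to "
                    f"reference {ref}"
                )
    return lib


def _packaged(name: str) -> Path:
    return Path(str(resources.files("metid.data").joinpath(name)))


def table2_reference() -> Dict[str, Tuple[float, float, float]]:
    """Published (theoretical, measured, printed ppm) per fragment label."""
    out: Dict[str, Tuple[float, float, float]] = {}
    with open(_packaged("table2_exact_masses.tsv")) as fh:
        header = None
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            if header is None:
                header = line.split()
                continue
            label, theo, meas, ppm = line.split()
            out[label] = (float(theo), float(meas), float(ppm))
    return out


def default_library() -> FragmentLibrary:
    """The packaged sirolimus library, validated against the published masses."""
    ref = {label: theo for label, (theo, _, _) in table2_reference().items()}
    return load_library(_packaged("srl_fragments.tsv"), reference_masses=ref)


@dataclass(frozen=True)
class ExpectedIon:
    """One predicted ion of a modified metabolite's MS/MS spectrum."""

    label: str
    mz: float
    shift_trail: Tuple[str, ...]
    kind: str  # "fragment" | "methanol_loss_satellite" | "water_loss_satellite" | "diagnostic"
    source_label: str  # underlying library fragment / diagnostic
    dominant_intensity_expected: bool = False


def fragment_shift(fragment: FragmentDef, mods: ModificationSet) -> Tuple[float, Tuple[ModificationEntry, ...]]:
    """Summed delta and the entries whose site intersects the fragment."""
    hits = tuple(e for e in mods if e.site & fragment.coverage)
    return sum(e.delta for e in hits), hits


def expected_peaks(
    lib: FragmentLibrary,
    mods: ModificationSet,
    rules_on: Iterable[str] = ("R1", "R2"),
) -> List[ExpectedIon]:
    """Forward model: expected ions for a modification hypothesis.

    With no modifications this reproduces the library masses identically.
    """
    rules = set(rules_on)
    out: List[ExpectedIon] = []
    methanol = SHIFTS["methanol_loss"].delta
    water = SHIFTS["water_loss"].delta
    for frag in (lib.molecular_ion,) + lib.alpha_fragments:
        delta, hits = fragment_shift(frag, mods)
        trail = tuple(str(e) for e in hits)
        mz = frag.theoretical_mz + delta
        out.append(ExpectedIon(frag.label, mz, trail, "fragment", frag.label))
        hydrox_units = {e.site for e in hits if e.type == "hydroxylation"}
        if "R1" in rules and frozenset({45, 46}) in hydrox_units:
            out.append(
                ExpectedIon(
                    f"{frag.label}[-CH3OH]",
                    mz + methanol,
                    trail + ("methanol_loss",),
                    "methanol_loss_satellite",
                    frag.label,
                )
            )
        if "R2" in rules and frozenset({23, 24}) in hydrox_units:
            out.append(
                ExpectedIon(
                    f"{frag.label}[-H2O]",
                    mz + water,
                    trail + ("water_loss",),
                    "water_loss_satellite",
                    frag.label,
                    dominant_intensity_expected=True,
                )
            )
    # diagnostic ions for hydroxylated sites, shifted by co-modifications
    for entry in mods:
        if entry.type != "hydroxylation":
            continue
        for diag in lib.diagnostics_for(entry.site):
            co = tuple(
                e for e in mods if e is not entry and e.site & diag.coverage
            )
            mz = diag.theoretical_mz + sum(e.delta for e in co)
            out.append(
                ExpectedIon(
                    diag.label,
                    mz,
                    tuple(str(e) for e in co),
                    "diagnostic",
                    diag.label,
                )
            )
    return out
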
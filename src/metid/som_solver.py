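"""Site-of-metabolism localization: inverting the fragment-shift model.

Given a metabolite's precursor m/z and its MS/MS peak list, the solver

1. infers the net modification multiset (up to two of net -CH2 / +O) from
   the precursor mass offset against the parent drug's molecular ion;
2. enumerates the legal modification hypotheses for that multiset
   (O-demethylation at C16/C27/C39; hydroxylation at C11, C12, C14,
   C23/24, C25, C45/46, C49 or the piperidine ring);
3. rejects every hypothesis contradicted by positive evidence — a
   fragment observed UNSHIFTED whose coverage contains a hypothesized
   site, or observed at a shift the hypothesis cannot produce — unless
   the peak has an alternative explanation among the hypothesis' own
   expected ions (isobaric coincidences are resolved in favor of the
   interpretation consistent with the net precursor delta);
4. applies the neutral-loss rules: methanol-loss satellites restrict a
   hydroxylation to the C45/C46 methyls (R1); water-loss satellites that
   dominate their parent's intensity restrict it to C23/C24 (R2);
   matched site-specific diagnostic ions pin their site;
5. ranks surviving hypotheses by how many of their predicted satellite and
   diagnostic ions are actually observed, and reports the survivors with a
   full evidence trail.  Candidate pairs that cannot be split ({23,24},
   {45,46}) are reported jointly with the ambiguity flag set.

Enumeration + contradiction filtering is equivalent to constraint
propagation over per-modification candidate sets for single modifications,
and stays well-defined when two modifications of the same type are present
(where per-entry set intersection is ambiguous).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .chem_mass import SHIFTS, ppm_error
from .fragment_model import (
    DEMETHYLATION_SITES,
    HYDROXYLATION_SITES,
    FragmentDef,
    FragmentLibrary,
    ModificationEntry,
    ModificationSet,
    Site,
    expected_peaks,
    fragment_shift,
    site_label,
)
from .spectra_io import DEFAULT_TOL_PPM, MatchResult, Spectrum, match_peaks

__all__ = [
    "EvidenceItem",
    "SOMAssignment",
    "InconsistentEvidenceError",
    "infer_net_modification",
    "legal_modification_sets",
    "localize",
    "classify",
    "batch_report",
]

_DM = SHIFTS["demethylation"].delta
_OH = SHIFTS["hydroxylation"].delta
_WATER = SHIFTS["water_loss"].delta
_METHANOL = SHIFTS["methanol_loss"].delta

#: Net modification multisets considered (first- and second-generation).
_NET_COMBOS: Tuple[Tuple[str, ...], ...] = (
    (),
    ("demethylation",),
    ("hydroxylation",),
    ("demethylation", "demethylation"),
    ("demethylation", "hydroxylation"),
    ("hydroxylation", "hydroxylation"),
)

_PAIR_2324 = frozenset({23, 24})
_PAIR_4546 = frozenset({45, 46})


@dataclass(frozen=True)
class EvidenceItem:
    """One piece of localization evidence with the sites it bears on."""

    kind: str  # unshifted_exclusion | shifted_support | diagnostic_support
    #        | methanol_loss_rule | waterloss_intensity_rule
    fragment_label: str
    affected_sites: Site
    detail: str = ""

    def __post_init__(self) -> None:
        if not self.affected_sites:
            raise ValueError("affected_sites must be non-empty")


@dataclass(frozen=True)
class SOMAssignment:
    """The solver's verdict for one spectrum."""

    mods: ModificationSet
    class_label: str
    ambiguous: bool
    evidence: Tuple[EvidenceItem, ...]
    candidate_sites_remaining: Dict[str, FrozenSet[Site]]
    surviving_hypotheses: Tuple[ModificationSet, ...] = ()
    spectrum_id: str = ""

    @property
    def sites_string(self) -> str:
        return "+".join(site_label(e.site) for e in self.mods.entries) or "-"


class InconsistentEvidenceError(ValueError):
    """All hypotheses contradicted: structured failure, never a silent guess."""

    def __init__(self, message: str, evidence: Sequence[EvidenceItem] = ()):
        super().__init__(message)
        self.evidence = tuple(evidence)


def infer_net_modification(
    precursor_mz: float,
    parent_mz: float,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> Tuple[str, ...]:
    """Net modification multiset from the precursor mass offset.

    Finds the unique combination of up to two entries from {net -CH2, +O}
    whose summed delta matches ``precursor_mz - parent_mz`` within
    ``tol_ppm`` of the precursor.  The six combination deltas are separated
    by >= 12 Da, so two solutions within a 5 ppm window cannot occur.
    """
    if precursor_mz <= 0 or parent_mz <= 0:
        raise ValueError("masses must be > 0")
    delta = precursor_mz - parent_mz
    tol_da = tol_ppm * 1e-6 * precursor_mz
    hits = [
        combo
        for combo in _NET_COMBOS
        if abs(delta - sum(SHIFTS[t].delta for t in combo)) <= tol_da
    ]
    if not hits:
        raise ValueError(
            f"no combination of <=2 modifications explains a precursor offset "
            f"of {delta:+.4f} Da within {tol_ppm} ppm"
        )
    if len(hits) > 1:  # unreachable for these deltas at sane tolerances
        raise ValueError(f"ambiguous net modification: {hits}")
    return hits[0]


def legal_modification_sets(max_mods: int = 2) -> List[ModificationSet]:
    """The full legal hypothesis space (67 sets for the default cap of 2)."""
    singles = [ModificationEntry("demethylation", s) for s in DEMETHYLATION_SITES] + [
        ModificationEntry("hydroxylation", s) for s in HYDROXYLATION_SITES
    ]
    out = [ModificationSet(())]
    if max_mods >= 1:
        out += [ModificationSet((e,)) for e in singles]
    if max_mods >= 2:
        for a, b in itertools.combinations(singles, 2):
            # hydroxylation listed first, matching metabolite naming convention
            ea, eb = sorted(
                (a, b), key=lambda e: (e.type != "hydroxylation", site_label(e.site))
            )
            out.append(ModificationSet((ea, eb)))
    return out


def classify(mods: ModificationSet) -> str:
    """Structural class from the net modification multiset."""
    if isinstance(mods, SOMAssignment):  # convenience
        mods = mods.mods
    key = mods.type_multiset
    return {
        (): "unmodified",
        ("demethylation",): "O-demethylated",
        ("hydroxylation",): "hydroxylated",
        ("demethylation", "demethylation"): "didemethylated",
        ("hydroxylation", "hydroxylation"): "di-hydroxylated",
        ("demethylation", "hydroxylation"): "hydroxylated/demethylated",
    }[key]


def _nearest_peak(spec: Spectrum, target: float, tol_ppm: float) -> Optional[int]:
    """Index of the nearest observed peak within tol_ppm, else None."""
    i = int(np.searchsorted(spec.mz, target))
    best, best_ppm = None, tol_ppm
    for j in (i - 1, i):
        if 0 <= j < len(spec):
            p = ppm_error(float(spec.mz[j]), target)
            if p <= best_ppm:
                best, best_ppm = j, p
    return best


def _variant_deltas(net: Tuple[str, ...]) -> Dict[float, Tuple[str, ...]]:
    """All sub-multiset shift sums achievable under the net modification."""
    out: Dict[float, Tuple[str, ...]] = {}
    for r in range(len(net) + 1):
        for combo in set(itertools.combinations(net, r)):
            out[round(sum(SHIFTS[t].delta for t in combo), 6)] = combo
    return out


def localize(
    spec: Spectrum,
    lib: FragmentLibrary,
    tol_ppm: float = DEFAULT_TOL_PPM,
    waterloss_intensity_ratio: float = 1.0,
    rules_on: Sequence[str] = ("R1", "R2"),
) -> SOMAssignment:
    """Infer the modification set behind a metabolite MS/MS spectrum."""
    net = infer_net_modification(spec.precursor_mz, lib.molecular_ion.theoretical_mz, tol_ppm)
    legal_sites = {
        "demethylation": frozenset().union(*DEMETHYLATION_SITES),
        "hydroxylation": frozenset().union(*HYDROXYLATION_SITES),
    }
    all_legal = legal_sites["demethylation"] | legal_sites["hydroxylation"]
    frags: Tuple[FragmentDef, ...] = (lib.molecular_ion,) + lib.alpha_fragments
    variants = _variant_deltas(net)

    # --- observed variant matches: fragment x achievable delta -> peak index
    obs: Dict[Tuple[str, float], int] = {}
    for f in frags:
        for delta in variants:
            idx = _nearest_peak(spec, f.theoretical_mz + delta, tol_ppm)
            if idx is not None:
                obs[(f.label, delta)] = idx

    # --- global signature detection (R1/R2/diagnostic pins)
    # Satellite candidates that coincide with a legitimate shift variant of
    # some fragment are ignored: several fragments differ by exactly CH3OH
    # or H2O (they are each other's MSn neutral-loss products), so e.g. a
    # hydroxylated A sits where shifted B's methanol satellite would be.
    variant_positions = np.array(
        [f.theoretical_mz + d for f in frags for d in variants]
    )

    def _explained_as_variant(peak_mz: float) -> bool:
        return bool(
            np.min(np.abs(peak_mz - variant_positions) / variant_positions) * 1e6
            <= tol_ppm
        )

    rules = set(rules_on)
    r1_fired: List[EvidenceItem] = []
    r2_fired: List[EvidenceItem] = []
    oh_deltas = [d for d, combo in variants.items() if "hydroxylation" in combo]
    for f in frags:
        for delta in oh_deltas:
            if (f.label, delta) not in obs:
                continue
            main_idx = obs[(f.label, delta)]
            base = f.theoretical_mz + delta
            if "R1" in rules:
                sat = _nearest_peak(spec, base + _METHANOL, tol_ppm)
                if sat is not None and not _explained_as_variant(float(spec.mz[sat])):
                    r1_fired.append(
                        EvidenceItem(
                            "methanol_loss_rule",
                            f.label,
                            _PAIR_4546,
                            f"-CH3OH satellite at {spec.mz[sat]:.4f} on shifted {f.label}",
                        )
                    )
            if "R2" in rules:
                sat = _nearest_peak(spec, base + _WATER, tol_ppm)
                if (
                    sat is not None
                    and not _explained_as_variant(float(spec.mz[sat]))
                    and spec.intensity[sat]
                    > waterloss_intensity_ratio * spec.intensity[main_idx]
                ):
                    r2_fired.append(
                        EvidenceItem(
                            "waterloss_intensity_rule",
                            f.label,
                            _PAIR_2324,
                            f"dominant -H2O satellite at {spec.mz[sat]:.4f} on shifted {f.label}",
                        )
                    )
    pinned: Dict[Site, EvidenceItem] = {}
    for diag in lib.diagnostics:
        for delta in variants:
            idx = _nearest_peak(spec, diag.theoretical_mz + delta, tol_ppm)
            if idx is not None:
                pinned.setdefault(
                    diag.diagnostic_site,
                    EvidenceItem(
                        "diagnostic_support",
                        diag.label,
                        diag.diagnostic_site,
                        f"diagnostic ion at {spec.mz[idx]:.4f}",
                    ),
                )
                break

    # --- hypothesis filtering
    hypotheses = [h for h in legal_modification_sets() if h.type_multiset == net]
    survivors: List[ModificationSet] = []
    for hyp in hypotheses:
        e_mz = np.array([ion.mz for ion in expected_peaks(lib, hyp, rules)])
        contradicted = False
        for f in frags:
            s_h, _ = fragment_shift(f, hyp)
            for delta, combo in variants.items():
                if (f.label, delta) not in obs or abs(delta - s_h) < 1e-6:
                    continue
                peak = float(spec.mz[obs[(f.label, delta)]])
                # alternative explanation among the hypothesis' own ions?
                if np.min(np.abs(peak - e_mz) / e_mz) * 1e6 <= tol_ppm:
                    continue
                contradicted = True
                break
            if contradicted:
                break
        if not contradicted:
            survivors.append(hyp)

    def _hyp_units(h: ModificationSet, mtype: str) -> Set[Site]:
        return {e.site for e in h if e.type == mtype}

    conflicts: List[EvidenceItem] = []

    def _apply(filtered: List[ModificationSet], why: EvidenceItem) -> List[ModificationSet]:
        nonlocal survivors
        if filtered:
            return filtered
        conflicts.append(why)
        return survivors

    if r1_fired:
        survivors = _apply(
            [h for h in survivors if _PAIR_4546 in _hyp_units(h, "hydroxylation")],
            r1_fired[0],
        )
    if r2_fired:
        survivors = _apply(
            [h for h in survivors if _PAIR_2324 in _hyp_units(h, "hydroxylation")],
            r2_fired[0],
        )
    for site, item in pinned.items():
        survivors = _apply(
            [h for h in survivors if site in _hyp_units(h, "hydroxylation")], item
        )

    if not survivors:
        conflict_items = [
            EvidenceItem(
                "unshifted_exclusion" if abs(delta) < 1e-6 else "shifted_support",
                label,
                lib.by_label[label].coverage & all_legal,
                f"{label} matched at {spec.mz[idx]:.4f} ({delta:+.4f} Da)",
            )
            for (label, delta), idx in sorted(obs.items())
            if lib.by_label[label].coverage & all_legal
        ]
        raise InconsistentEvidenceError(
            f"{spec.id or 'spectrum'}: every {'+'.join(net) or 'unmodified'} hypothesis "
            "is contradicted by the matched fragments",
            evidence=conflict_items + r1_fired + r2_fired + list(pinned.values()),
        )

    # --- best-explanation ranking: matched satellites + diagnostics
    def _score(h: ModificationSet) -> int:
        ions = [
            ion
            for ion in expected_peaks(lib, h, rules)
            if ion.kind in ("methanol_loss_satellite", "water_loss_satellite", "diagnostic")
        ]
        return sum(1 for ion in ions if _nearest_peak(spec, ion.mz, tol_ppm) is not None)

    scores = {str(h): _score(h) for h in survivors}
    top = max(scores.values())
    survivors = [h for h in survivors if scores[str(h)] == top]
    survivors.sort(key=str)

    chosen = survivors[0]
    candidates: Dict[str, FrozenSet[Site]] = {}
    for mtype in set(net):
        candidates[mtype] = frozenset().union(
            *[frozenset({u}) for h in survivors for u in _hyp_units(h, mtype)]
        ) if survivors else frozenset()
    evidence = _collect_evidence(
        spec, lib, chosen, variants, obs, all_legal, r1_fired, r2_fired, pinned, tol_ppm
    ) + tuple(conflicts)
    ambiguous = len(survivors) > 1 or any(len(e.site) > 1 for e in chosen)
    return SOMAssignment(
        mods=chosen,
        class_label=classify(chosen),
        ambiguous=ambiguous,
        evidence=evidence,
        candidate_sites_remaining=candidates,
        surviving_hypotheses=tuple(survivors),
        spectrum_id=spec.id,
    )


def _collect_evidence(
    spec: Spectrum,
    lib: FragmentLibrary,
    chosen: ModificationSet,
    variants: Dict[float, Tuple[str, ...]],
    obs: Dict[Tuple[str, float], int],
    all_legal: Site,
    r1: List[EvidenceItem],
    r2: List[EvidenceItem],
    pinned: Dict[Site, EvidenceItem],
    tol_ppm: float,
) -> Tuple[EvidenceItem, ...]:
    items: List[EvidenceItem] = []
    frags = (lib.molecular_ion,) + lib.alpha_fragments
    for f in frags:
        s_c, hits = fragment_shift(f, chosen)
        affected = f.coverage & all_legal
        if not affected:
            continue
        if (f.label, 0.0) in obs and abs(s_c) < 1e-6 and len(chosen) > 0:
            items.append(
                EvidenceItem(
                    "unshifted_exclusion",
                    f.label,
                    affected,
                    f"unshifted {f.label} at {f.theoretical_mz:.4f} excludes its coverage",
                )
            )
        elif abs(s_c) >= 1e-6:
            delta = round(s_c, 6)
            key = (f.label, min(variants, key=lambda d: abs(d - s_c)))
            if key in obs:
                items.append(
                    EvidenceItem(
                        "shifted_support",
                        f.label,
                        affected,
                        f"{f.label} shifted {s_c:+.4f} Da "
                        f"({'+'.join(str(e) for e in hits)})",
                    )
                )
    items += [pinned[s] for s in pinned]
    items += r1[:1] + r2[:1]
    return tuple(items)


def batch_report(
    assignments: Sequence[SOMAssignment],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate assignments: one row each, plus per-class summary counts.

    Unmodified spectra are excluded from the metabolite count; entries that
    share one MS-level structure (e.g. chromatographic isomers) still count
    as distinct rows, as the published metabolite inventory does.
    """
    rows = [
        {
            "id": a.spectrum_id,
            "class": a.class_label,
            "sites": a.sites_string,
            "ambiguous": a.ambiguous,
            "n_evidence": len(a.evidence),
        }
        for a in assignments
    ]
    report = pd.DataFrame(
        rows, columns=["id", "class", "sites", "ambiguous", "n_evidence"]
    )
    metab = report[report["class"] != "unmodified"]
    summary = (
        metab.groupby("class").size().rename("n").reset_index()
        if len(metab)
        else pd.DataFrame(columns=["class", "n"])
    )
    return report, summary
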
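"""Thermodynamic-cycle site ranking and heme-proximity analysis.

Combines per-site free-energy terms of the CYP demethylation cycle —
methyl abstraction (MO-CH3 -> MO + CH3) plus hydrogenation of the radical
(MO + H -> MOH) — into the overall reaction dG, ranks candidate sites by
it (most favorable = lowest first), and ranks candidate atoms by the
fraction of molecular-dynamics frames they spend within a distance
threshold of the CYP3A4 heme iron (soft, ordinal site-of-metabolism
evidence; the quantum-chemistry and MD engines themselves are out of
scope — this module consumes their outputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .synthetic_data import DistanceTrajectory

__all__ = [
    "ThermoCycle",
    "overall_dg",
    "rank_sites_by_dg",
    "proximity_rank",
    "DEFAULT_PROXIMITY_THRESHOLD_A",
]

#: Reactive groups sit within 3-5 Å of the heme iron in the bound poses.
DEFAULT_PROXIMITY_THRESHOLD_A = 5.0


@dataclass(frozen=True)
class ThermoCycle:
    """Per-site demethylation thermodynamic cycle (kcal/mol)."""

    site: str
    dg_demethylation: float
    dg_hydrogenation: float

    @property
    def dg_overall(self) -> float:
        return overall_dg(self.dg_demethylation, self.dg_hydrogenation)


def overall_dg(demeth: float, hydrog: float) -> float:
    """Overall cycle free energy: sum of the two legs (kcal/mol)."""
    if not (np.isfinite(demeth) and np.isfinite(hydrog)):
        raise ValueError("dG terms must be finite")
    return demeth + hydrog


def rank_sites_by_dg(
    cycles: Sequence[ThermoCycle],
) -> Tuple[List[str], bool]:
    """Sites ordered most-favorable-first (ascending overall dG).

    Ties break on site name; returns (ordered sites, tie flag).
    """
    if not cycles:
        raise ValueError("need at least one thermodynamic cycle")
    ordered = sorted(cycles, key=lambda c: (c.dg_overall, c.site))
    dgs = [round(c.dg_overall, 10) for c in ordered]
    tie = len(dgs) != len(set(dgs))
    return [c.site for c in ordered], tie


def proximity_rank(
    trajs: Sequence[DistanceTrajectory],
    threshold_A: float = DEFAULT_PROXIMITY_THRESHOLD_A,
) -> pd.DataFrame:
    """Occupancy-within-threshold ranking of candidate atoms.

    Occupancy is the fraction of frames with distance <= threshold; the
    table is sorted descending by occupancy (then by median distance and
    atom id, for determinism) and carries a tie flag on equal occupancies.
    """
    if len(trajs) < 2:
        raise ValueError("need >= 2 trajectories to rank")
    if threshold_A <= 0:
        raise ValueError("threshold must be > 0")
    n = {t.n_frames for t in trajs}
    if len(n) != 1:
        raise ValueError(f"mismatched frame counts: {sorted(n)}")
    rows = [
        {
            "atom_id": t.atom_id,
            "occupancy": float(np.mean(t.distances <= threshold_A)),
            "median_distance_A": float(np.median(t.distances)),
        }
        for t in trajs
    ]
    df = pd.DataFrame(rows).sort_values(
        ["occupancy", "median_distance_A", "atom_id"],
        ascending=[False, True, True],
        ignore_index=True,
    )
    occ = df["occupancy"].round(12)
    df["tie"] = occ.duplicated(keep=False)
    df["rank"] = range(1, len(df) + 1)
    return df
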
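#!/usr/bin/env python
"""Demethylation-site energetics and heme-proximity ranking.

Combines the published DFT cycle terms into overall reaction free energies
and ranks the three methoxy sites; then ranks the C45/C46 methyl pair by
heme-iron proximity occupancy from synthetic distance trajectories that
mirror the reported MD ordering (C46 closer than C45).  Writes
results/06_thermo.tsv and results/06_proximity.tsv.
"""

from pathlib import Path

from metid.datasets import published_thermo
from metid.site_energetics import ThermoCycle, proximity_rank, rank_sites_by_dg
from metid.synthetic_data import simulate_distance_traj

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 5

tab = published_thermo()
cycles = [
    ThermoCycle(r["site"], r["dg_demethylation"], r["dg_hydrogenation"])
    for _, r in tab.iterrows()
]
tab["dg_overall_computed"] = [c.dg_overall for c in cycles]
tab.to_csv(OUT / "06_thermo.tsv", sep="\t", index=False)
order, tie = rank_sites_by_dg(cycles)
print(tab.to_string(index=False))
print(f"\nSite preference (lowest overall dG first): {' > '.join(order)}"
      + ("  [ties]" if tie else ""))
print("C27 computes to -12.70 from its printed legs (printed overall: -12.71).")

c46 = simulate_distance_traj("C46", 4.0, 0.5, 5000, SEED)
c45 = simulate_distance_traj("C45", 6.0, 0.5, 5000, SEED + 1)
prox = proximity_rank([c46, c45], threshold_A=5.0)
prox.to_csv(OUT / "06_proximity.tsv", sep="\t", index=False)
print("\nHeme-proximity occupancy (threshold 5 Å, 5000 frames):")
print(prox.to_string(index=False))
print("C46 spends far more frames within reach of the heme iron than C45,")
print("the ordinal signal used to prefer C46 within the unsplit 45/46 pair.")
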
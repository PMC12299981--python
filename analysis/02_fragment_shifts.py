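#!/usr/bin/env python
"""Forward fragment-shift predictions for the key metabolite hypotheses.

For each first-generation modification hypothesis, tabulates which library
fragments shift, by how much, and which satellites/diagnostics appear.
Writes results/02_fragment_shifts.tsv.
"""

from pathlib import Path

import pandas as pd

from metid.chem_mass import format_mz
from metid.fragment_model import ModificationSet, default_library, expected_peaks

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

lib = default_library()
hypotheses = [
    "DM@16", "DM@27", "DM@39",
    "OH@11", "OH@12", "OH@14", "OH@23/24", "OH@25", "OH@45/46", "OH@49", "OH@pip",
]

rows = []
for h in hypotheses:
    mods = ModificationSet.parse(h)
    for ion in expected_peaks(lib, mods):
        base = lib.by_label.get(ion.source_label)
        delta = ion.mz - base.theoretical_mz if base else float("nan")
        if ion.kind == "fragment" and abs(delta) < 1e-9:
            continue  # only report ions that move or appear
        rows.append(
            {
                "hypothesis": h,
                "ion": ion.label,
                "kind": ion.kind,
                "mz_4dp": format_mz(ion.mz),
                "shift_trail": "+".join(ion.shift_trail) or "-",
            }
        )
df = pd.DataFrame(rows)
df.to_csv(OUT / "02_fragment_shifts.tsv", sep="\t", index=False)
print(f"{len(df)} shifted/diagnostic ions across {len(hypotheses)} hypotheses.")
key = df[
    (df.hypothesis.isin(["DM@27", "DM@39", "OH@45/46", "OH@23/24"]))
    & (df.ion.isin(["K", "C", "D", "G", "G[-H2O]"]))
]
print("Key printed anchors:")
print(key.to_string(index=False))
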
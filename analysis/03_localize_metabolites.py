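#!/usr/bin/env python
"""Identify the 21 metabolites from their (simulated) MS/MS spectra.

Renders the packaged metabolite manifest into noise-free spectra, runs the
site-of-metabolism solver on each, and tabulates the batch report with
per-class counts.  Writes results/03_metabolite_report.tsv and
results/03_class_summary.tsv.
"""

from pathlib import Path

from metid.datasets import fixture_spectra, metabolite_manifest
from metid.fragment_model import default_library
from metid.som_solver import batch_report, localize

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

lib = default_library()
manifest = metabolite_manifest().set_index("id")
assigns = [localize(spec, lib) for _, spec in fixture_spectra(lib)]
report, summary = batch_report(assigns)
report["name"] = [manifest.loc[i, "name"] for i in report["id"]]
report["matches_manifest"] = [
    (manifest.loc[r["id"], "class_expected"] == r["class"])
    and (manifest.loc[r["id"], "reported_sites"] == r["sites"])
    for _, r in report.iterrows()
]
report.to_csv(OUT / "03_metabolite_report.tsv", sep="\t", index=False)
summary.to_csv(OUT / "03_class_summary.tsv", sep="\t", index=False)

print(report[["id", "name", "class", "sites", "ambiguous"]].to_string(index=False))
print(f"\n{len(report)} metabolites in {len(summary)} structural classes:")
print(summary.to_string(index=False))
n_ok = int(report["matches_manifest"].sum())
print(f"\nSolver agrees with the documented assignment for {n_ok}/{len(report)} spectra.")
print("Candidate pairs 23/24 and 45/46 and the piperidine ring stay unsplit,")
print("matching what MS/MSn evidence alone can establish.")
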
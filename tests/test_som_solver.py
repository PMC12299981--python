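"""Inverse site-of-metabolism solver: net inference, localization, classes."""

import numpy as np
import pytest

from metid.fragment_model import ModificationSet, default_library, expected_peaks
from metid.som_solver import (
    InconsistentEvidenceError,
    batch_report,
    classify,
    infer_net_modification,
    legal_modification_sets,
    localize,
)
from metid.spectra_io import Spectrum
from metid.synthetic_data import SpectrumSimConfig, simulate_spectrum


def _noise_free(lib, truth):
    return simulate_spectrum(
        lib, SpectrumSimConfig(truth=truth, ppm_sigma=0.0, n_decoys=0, seed=0)
    )


class TestNetInference:
    @pytest.mark.parametrize(
        "precursor,expect",
        [
            (922.5287, ("demethylation",)),
            (952.5393, ("hydroxylation",)),
            (908.5131, ("demethylation", "demethylation")),
            (968.5342, ("hydroxylation", "hydroxylation")),
            (938.5236, ("demethylation", "hydroxylation")),
            (936.5444, ()),
        ],
    )
    def test_published_molecular_ions(self, precursor, expect):
        assert infer_net_modification(precursor, 936.5444) == expect

    def test_unexplained_offset_raises(self):
        with pytest.raises(ValueError, match="no combination"):
            infer_net_modification(900.0, 936.5444)

    def test_combination_deltas_cannot_be_ambiguous_at_5ppm(self):
        # minimal spacing between any two net deltas is ~12 Da >> 5 ppm of 936
        from metid.som_solver import _NET_COMBOS
        from metid.chem_mass import SHIFTS

        deltas = sorted(sum(SHIFTS[t].delta for t in c) for c in _NET_COMBOS)
        gaps = np.diff(deltas)
        assert gaps.min() > 1.9  # Da; tolerance window at 936 m/z is ~0.005 Da


class TestHypothesisSpace:
    def test_size_and_legality(self):
        space = legal_modification_sets()
        assert len(space) == 67
        assert all(len(h) <= 2 for h in space)
        assert len({str(h) for h in space}) == 67


class TestLocalizeRoundTrips:
    def test_16_demethylation_recovered_with_unshifted_K_evidence(self, lib):
        a = localize(_noise_free(lib, ModificationSet.parse("DM@16")), lib)
        assert str(a.mods) == "DM@16" and not a.ambiguous
        unshifted = [e for e in a.evidence if e.kind == "unshifted_exclusion"]
        assert any(e.fragment_label == "K" for e in unshifted)

    def test_methyl_hydroxylation_reported_as_unsplit_pair(self, lib):
        a = localize(_noise_free(lib, ModificationSet.parse("OH@45/46")), lib)
        assert a.ambiguous
        assert a.sites_string == "45/46"
        assert any(e.kind == "methanol_loss_rule" for e in a.evidence)

    def test_23_24_hydroxylation_pinned_by_waterloss_dominance(self, lib):
        a = localize(_noise_free(lib, ModificationSet.parse("OH@23/24")), lib)
        assert a.sites_string == "23/24" and a.ambiguous
        assert any(e.kind == "waterloss_intensity_rule" for e in a.evidence)

    def test_unmodified_spectrum_yields_empty_mods(self, lib):
        ions = expected_peaks(lib, ModificationSet(()))
        mz = np.array([i.mz for i in ions])
        spec = Spectrum(mz, np.full_like(mz, 50.0), 936.5444, id="parent")
        a = localize(spec, lib)
        assert len(a.mods) == 0 and a.class_label == "unmodified"

    def test_second_generation_sites_recovered_via_shifted_diagnostic(self, lib):
        a = localize(_noise_free(lib, ModificationSet.parse("OH@12+DM@39")), lib)
        assert str(a.mods) == "OH@12+DM@39"
        assert any(e.kind == "diagnostic_support" for e in a.evidence)

    def test_inconsistent_evidence_is_a_structured_failure(self, lib):
        # demethylated precursor but every fragment at its unmodified mass
        ions = expected_peaks(lib, ModificationSet(()))
        mz = np.array([i.mz for i in ions if i.label != "SRL"])
        spec = Spectrum(mz, np.ones_like(mz), 922.5287, id="conflict")
        with pytest.raises(InconsistentEvidenceError) as err:
            localize(spec, lib)
        assert err.value.evidence  # conflicting items are reported


class TestSoundness:
    def test_exhaustive_noise_free_sweep_never_excludes_truth(self, lib):
        for truth in legal_modification_sets():
            a = localize(_noise_free(lib, truth), lib)
            for entry in truth:
                assert entry.site in a.candidate_sites_remaining[entry.type], str(truth)

    def test_unmatched_expected_fragment_never_enlarges_candidates(self, lib):
        # drop one observed peak at a time: candidate sets must not shrink
        truth = ModificationSet.parse("OH@25")
        spec = _noise_free(lib, truth)
        base = localize(spec, lib)
        base_c = base.candidate_sites_remaining["hydroxylation"]
        for i in range(len(spec)):
            if len(spec) <= 1:
                break
            mz = np.delete(spec.mz, i)
            inten = np.delete(spec.intensity, i)
            a = localize(Spectrum(mz, inten, spec.precursor_mz, id="drop"), lib)
            assert base_c <= a.candidate_sites_remaining["hydroxylation"]

    def test_site_recovery_under_noise_and_decoys(self, lib):
        # 2 ppm mass error, 20 uniform decoys, 200 seeded runs
        space = [h for h in legal_modification_sets() if len(h) > 0]
        rng = np.random.default_rng(2024)
        contained = 0
        n_runs = 200
        for _ in range(n_runs):
            truth = space[rng.integers(len(space))]
            cfg = SpectrumSimConfig(
                truth=truth, ppm_sigma=2.0, n_decoys=20, seed=int(rng.integers(2**31))
            )
            try:
                a = localize(simulate_spectrum(lib, cfg), lib)
                ok = all(
                    e.site in a.candidate_sites_remaining[e.type] for e in truth
                )
            except InconsistentEvidenceError:
                ok = False
            contained += ok
        assert contained / n_runs >= 0.95

    def test_unique_recovery_when_diagnostic_exists_noise_free(self, lib):
        for site in ("11", "12", "14", "25", "49", "pip"):
            truth = ModificationSet.parse(f"OH@{site}")
            a = localize(_noise_free(lib, truth), lib)
            assert len(a.surviving_hypotheses) == 1 and a.mods == truth


class TestClassification:
    @pytest.mark.parametrize(
        "mods,label",
        [
            ("DM@16", "O-demethylated"),
            ("OH@12", "hydroxylated"),
            ("DM@16+DM@39", "didemethylated"),
            ("OH@12+OH@23/24", "di-hydroxylated"),
            ("OH@pip+DM@39", "hydroxylated/demethylated"),
            ("", "unmodified"),
        ],
    )
    def test_class_from_net_modification(self, mods, label):
        assert classify(ModificationSet.parse(mods)) == label


class TestBatchReport:
    def test_21_fixtures_give_21_rows_in_5_classes(self, lib, fixtures21):
        assigns = [localize(spec, lib) for _, spec in fixtures21]
        report, summary = batch_report(assigns)
        assert len(report) == 21
        assert summary["n"].sum() == 21
        assert set(summary["class"]) == {
            "O-demethylated",
            "hydroxylated",
            "didemethylated",
            "di-hydroxylated",
            "hydroxylated/demethylated",
        }

    def test_fixture_classes_sites_and_ambiguity_match_manifest(self, lib, fixtures21):
        for row, spec in fixtures21:
            a = localize(spec, lib)
            assert a.class_label == row["class_expected"], row["id"]
            assert a.sites_string == row["reported_sites"], row["id"]

    def test_ambiguity_flag_only_for_unsplit_pairs(self, lib, fixtures21):
        for row, spec in fixtures21:
            a = localize(spec, lib)
            expect_amb = "23/24" in row["reported_sites"] or "45/46" in row["reported_sites"]
            assert a.ambiguous == expect_amb, row["id"]

    def test_empty_and_unmodified_inputs(self, lib):
        report, summary = batch_report([])
        assert report.empty and summary.empty
        ions = expected_peaks(lib, ModificationSet(()))
        mz = np.array([i.mz for i in ions])
        a = localize(Spectrum(mz, np.ones_like(mz), 936.5444, id="u"), lib)
        report, summary = batch_report([a])
        assert len(report) == 1 and summary["n"].sum() if len(summary) else 0 == 0
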
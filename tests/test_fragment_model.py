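"""Fragment library validation and the forward spectrum model."""

from pathlib import Path

import pytest

from metid.chem_mass import SHIFTS, format_mz
from metid.fragment_model import (
    LibraryValidationError,
    ModificationEntry,
    ModificationSet,
    default_library,
    expected_peaks,
    load_library,
    parse_site,
    site_label,
    IUPAC_TO_CAS,
)
from metid.datasets import published_exact_masses


def _library_path() -> Path:
    from importlib import resources

    return Path(str(resources.files("metid.data").joinpath("srl_fragments.tsv")))


class TestLibraryLoading:
    def test_packaged_library_loads_with_18_fragments(self, lib):
        assert len(lib.alpha_fragments) == 18
        assert format_mz(lib.molecular_ion.theoretical_mz) == "936.5444"
        assert sorted(f.label for f in lib.alpha_fragments) == sorted(
            "ABCDEFGHIJKLMNOPQR"
        )

    def test_every_table_mass_matches_at_4dp(self, lib):
        table = published_exact_masses().set_index("label")["theoretical"]
        for f in (lib.molecular_ion,) + lib.alpha_fragments:
            key = f.label if f.label != "SRL" else "SRL"
            assert float(format_mz(f.theoretical_mz)) == pytest.approx(
                table[key], abs=1e-9
            )

    def test_corrupted_mass_rejected(self, tmp_path, lib):
        text = _library_path().read_text()
        bad = text.replace("607.396920", "607.400000")
        p = tmp_path / "bad.tsv"
        p.write_text(bad)
        ref = {"K": 607.3969}
        with pytest.raises(LibraryValidationError):
            load_library(p, reference_masses=ref)

    def test_child_coverage_must_nest_in_parent(self, tmp_path):
        text = _library_path().read_text()
        # fragment D is a child of C ({28-44,49,52}); give D a carbon C lacks
        bad = text.replace(
            "D\talpha_cleavage\t345.203620\tC\t33-44,49,52",
            "D\talpha_cleavage\t345.203620\tC\t33-44,49,52,16",
        )
        p = tmp_path / "bad_tree.tsv"
        p.write_text(bad)
        with pytest.raises(LibraryValidationError, match="subset"):
            load_library(p)

    def test_duplicate_label_rejected(self, tmp_path):
        text = _library_path().read_text()
        bad = text.replace(
            "L\talpha_cleavage\t397.234900\tO",
            "K\talpha_cleavage\t397.234900\tO",
        )
        p = tmp_path / "dup.tsv"
        p.write_text(bad)
        with pytest.raises(LibraryValidationError, match="duplicate"):
            load_library(p)

    def test_coverage_anchors(self, lib):
        K = lib.by_label["K"].coverage
        assert K == parse_site_set("17-49,51,52")
        for excluded in (16, 11, 12, 14, "pip"):
            assert excluded not in K
        for frag in ("C", "D"):
            cov = lib.by_label[frag].coverage
            assert 39 in cov and 27 not in cov
        for frag in ("G", "O"):
            assert {23, 24} <= lib.by_label[frag].coverage
        assert "pip" in lib.by_label["Q"].coverage

    def test_iupac_to_cas_positions(self):
        assert IUPAC_TO_CAS[39] == 41
        assert IUPAC_TO_CAS[16] == 7


def parse_site_set(text):
    from metid.fragment_model import _parse_coverage

    return _parse_coverage(text)


class TestModificationSet:
    def test_parse_round_trip(self):
        m = ModificationSet.parse("OH@12+DM@39")
        assert str(m) == "OH@12+DM@39"
        assert m.net_delta == pytest.approx(15.994915 - 14.015650, abs=1e-6)

    def test_demethylation_restricted_to_methoxy_carbons(self):
        with pytest.raises(ValueError):
            ModificationEntry("demethylation", frozenset({11}))

    def test_at_most_two_entries(self):
        e = ModificationEntry("hydroxylation", frozenset({11}))
        with pytest.raises(ValueError):
            ModificationSet((e,) * 3)

    def test_site_tokens_validated(self):
        with pytest.raises(ValueError):
            parse_site("60")


class TestExpectedPeaks:
    def test_identity_reproduces_library(self, lib):
        ions = expected_peaks(lib, ModificationSet(()))
        assert len(ions) == 19  # molecular ion + 18 fragments, nothing else
        for ion in ions:
            assert ion.mz == lib.by_label[ion.label].theoretical_mz
            assert ion.shift_trail == ()

    def test_demethylation_at_39_shifts_C_D_and_K(self, lib):
        ions = {i.label: i for i in expected_peaks(lib, ModificationSet.parse("DM@39"))}
        assert format_mz(ions["C"].mz) == "628.3092"
        assert format_mz(ions["D"].mz) == "331.1880"
        assert format_mz(ions["K"].mz) == "593.3813"  # C39 is in K's coverage

    def test_demethylation_at_16_leaves_K_D_P_J_unchanged(self, lib):
        ions = {i.label: i for i in expected_peaks(lib, ModificationSet.parse("DM@16"))}
        for label, printed in [("K", "607.3969"), ("D", "345.2036"), ("P", "381.2400"), ("J", "409.2349")]:
            assert format_mz(ions[label].mz) == printed
            assert ions[label].shift_trail == ()

    def test_methyl_hydroxylation_shifts_K_and_emits_methanol_satellites(self, lib):
        ions = {i.label: i for i in expected_peaks(lib, ModificationSet.parse("OH@45/46"))}
        assert format_mz(ions["K"].mz) == "623.3918"
        sats = [i for i in ions.values() if i.kind == "methanol_loss_satellite"]
        assert sats and all(
            i.mz == pytest.approx(ions[i.source_label].mz - 32.026215, abs=1e-6)
            for i in sats
        )

    def test_waterloss_satellites_for_23_24_flagged_dominant(self, lib):
        ions = {i.label: i for i in expected_peaks(lib, ModificationSet.parse("OH@23/24"))}
        assert format_mz(ions["G"].mz) == "630.3249"
        assert format_mz(ions["G[-H2O]"].mz) == "612.3144"
        assert ions["G[-H2O]"].dominant_intensity_expected

    def test_rules_can_be_switched_off(self, lib):
        ions = expected_peaks(lib, ModificationSet.parse("OH@23/24"), rules_on=())
        assert all(i.kind == "fragment" for i in ions)

    @pytest.mark.parametrize("truth", ["OH@11", "OH@12", "OH@25", "OH@49", "OH@pip", "OH@23/24"])
    def test_single_hydroxylation_deltas_are_zero_or_plus_O(self, lib, truth):
        mods = ModificationSet.parse(truth)
        oh = SHIFTS["hydroxylation"].delta
        for ion in expected_peaks(lib, mods):
            if ion.kind != "fragment":
                continue
            delta = ion.mz - lib.by_label[ion.label].theoretical_mz
            assert delta == pytest.approx(0.0, abs=1e-9) or delta == pytest.approx(
                oh, abs=1e-9
            )

    @pytest.mark.parametrize(
        "truth",
        ["DM@16", "DM@27", "DM@39", "OH@45/46", "OH@12+DM@39", "DM@16+DM@39"],
    )
    def test_ancestors_of_shifted_fragments_also_shift(self, lib, truth):
        mods = ModificationSet.parse(truth)
        shifted = {
            i.label
            for i in expected_peaks(lib, mods)
            if i.kind == "fragment"
            and abs(i.mz - lib.by_label[i.label].theoretical_mz) > 1e-9
        }
        for label in shifted:
            frag = lib.by_label[label]
            while frag.parent_label:
                parent = lib.by_label[frag.parent_label]
                hit_sites = frozenset().union(
                    *[e.site & lib.by_label[label].coverage for e in mods]
                )
                if hit_sites & parent.coverage:
                    assert parent.label in shifted or parent.kind == "precursor"
                frag = parent

    @pytest.mark.parametrize(
        "truth", ["DM@16", "OH@12", "OH@23/24", "OH@12+DM@39", "DM@16+DM@39"]
    )
    def test_molecular_ion_carries_net_shift(self, lib, truth):
        mods = ModificationSet.parse(truth)
        ions = {i.label: i for i in expected_peaks(lib, mods)}
        assert ions["SRL"].mz - lib.molecular_ion.theoretical_mz == pytest.approx(
            mods.net_delta, abs=1e-9
        )

    def test_doubly_shifted_diagnostic_of_second_generation_metabolite(self, lib):
        # the 12-hydroxy diagnostic ion appears -CH2 when C39 is also demethylated
        ions = {i.label: i for i in expected_peaks(lib, ModificationSet.parse("OH@12+DM@39"))}
        diag = ions["OH12-diag-a"]
        assert diag.mz == pytest.approx(711.4442 - 14.015650, abs=5e-4)
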
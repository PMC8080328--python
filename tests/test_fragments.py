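"""Neutral-loss fragment explanation and identification confidence."""

from __future__ import annotations

import pytest

from conftest import make_feature, make_ion
from phytoscreen.chem import adduct_mz, parse_formula
from phytoscreen.fragments import (
    DEFAULT_LOSSES,
    MSMSSpectrum,
    assign_confidence,
    explain_fragments,
)
from phytoscreen.screening import score_candidate


def _spectrum(ion, mzs, polarity=None):
    return MSMSSpectrum(
        precursor_mz=ion.mz,
        polarity=polarity or ion.adduct.polarity,
        peaks=tuple(sorted((m, 100.0) for m in mzs)),
    )


@pytest.fixture(scope="module")
def ophiopogonin_d():
    return make_ion(
        "C44H70O16", "[M-H]-", name="Ophiopogonin D",
        compound_class="triterpenoid_saponin",
    )


class TestLossLibrary:
    def test_masses_match_formulas(self):
        from phytoscreen.chem import monoisotopic_mass

        for loss in DEFAULT_LOSSES:
            assert loss.exact_mass == pytest.approx(
                monoisotopic_mass(dict(loss.formula)), abs=1e-5
            )

    def test_sugar_residue_nominal_masses(self):
        by_name = {l.name: l for l in DEFAULT_LOSSES}
        assert round(by_name["Glc"].exact_mass) == 162
        assert round(by_name["Rha"].exact_mass) == 146
        assert round(by_name["Xyl"].exact_mass) == 132


class TestExplainFragments:
    def test_pentose_loss(self, ophiopogonin_d):
        anns = explain_fragments(ophiopogonin_d, _spectrum(ophiopogonin_d, [721.4158]))
        (ann,) = anns
        assert [l.name for l in ann.loss_path] == ["Xyl"]
        assert ann.error_ppm == pytest.approx(-1.5, abs=0.3)

    def test_mass_beats_printed_label(self, ophiopogonin_d):
        # 575.3584 is a Xyl+Rha loss by mass (theor. 575.3590), not Xyl+Glc
        # (theor. 559.36) as annotation tables sometimes print
        anns = explain_fragments(ophiopogonin_d, _spectrum(ophiopogonin_d, [575.3584]))
        (ann,) = anns
        assert sorted(l.name for l in ann.loss_path) == ["Rha", "Xyl"]

    def test_survivor_ion_has_empty_path(self, ophiopogonin_d):
        anns = explain_fragments(ophiopogonin_d, _spectrum(ophiopogonin_d, [ophiopogonin_d.mz]))
        (ann,) = anns
        assert ann.loss_path == ()
        assert ann.theoretical_mz == ophiopogonin_d.mz

    def test_random_peak_unannotated(self, ophiopogonin_d):
        anns = explain_fragments(ophiopogonin_d, _spectrum(ophiopogonin_d, [400.0]))
        assert anns == []

    def test_annotation_mass_balance(self, ophiopogonin_d):
        spectrum = _spectrum(ophiopogonin_d, [721.4158, 575.3584, 853.4574])
        for ann in explain_fragments(ophiopogonin_d, spectrum):
            total = sum(l.exact_mass for l in ann.loss_path)
            assert ann.theoretical_mz == pytest.approx(
                ophiopogonin_d.mz - total, abs=1e-6
            )

    def test_deterministic(self, ophiopogonin_d):
        spectrum = _spectrum(ophiopogonin_d, [721.4158, 575.3584])
        a = explain_fragments(ophiopogonin_d, spectrum)
        b = explain_fragments(ophiopogonin_d, spectrum)
        assert a == b

    def test_depth_monotone_coverage(self):
        ion = make_ion("C27H32O14", "[M-H]-", compound_class="flavonoid")
        # peaks needing 1, 2 and 3 losses
        glc = 162.05282
        mzs = [ion.mz - glc, ion.mz - 2 * glc, ion.mz - 2 * glc - 18.01056]
        spectrum = _spectrum(ion, mzs)
        counts = [
            len(explain_fragments(ion, spectrum, max_depth=d)) for d in (1, 2, 3)
        ]
        assert counts == sorted(counts)
        assert counts[2] == 3

    def test_rda_diagnostic_ion(self):
        ion = make_ion("C15H10O7", "[M+H]+", name="Quercetin", compound_class="flavonoid")
        anns = explain_fragments(ion, _spectrum(ion, [153.0188]))
        (ann,) = anns
        assert ann.diagnostic is not None and ann.diagnostic.name == "RDA_1,3A"

    def test_polarity_mismatch_rejected(self, ophiopogonin_d):
        bad = _spectrum(ophiopogonin_d, [721.4], polarity="positive")
        with pytest.raises(ValueError, match="polarity"):
            explain_fragments(ophiopogonin_d, bad)

    def test_bracket_labels(self, ophiopogonin_d):
        spectrum = _spectrum(ophiopogonin_d, [721.4158, 575.3584])
        labels = {
            a.label(ophiopogonin_d.adduct.name)
            for a in explain_fragments(ophiopogonin_d, spectrum)
        }
        assert "[M-H-Xyl]-" in labels
        assert "[M-H-Xyl-Rha]-" in labels or "[M-H-Rha-Xyl]-" in labels


class TestAssignConfidence:
    def _candidate(self, ion, rt):
        feat = make_feature(ion.mz, polarity=ion.adduct.polarity, rt=rt)
        return score_candidate(feat, ion)

    def test_standard_confirmed(self):
        ion = make_ion(
            "C12H16O4", "[M-H]-", name="Senkyunolide H",
            compound_class="phthalide", is_standard=True, reference_rt=8.90,
        )
        cand = self._candidate(ion, rt=8.95)
        anns = explain_fragments(ion, _spectrum(ion, [ion.mz - 43.98983]))
        rec = assign_confidence(cand, anns)
        assert rec.confidence == "standard_confirmed"

    def test_fragments_without_standard_is_tentative(self, ophiopogonin_d):
        cand = self._candidate(ophiopogonin_d, rt=54.0)
        anns = explain_fragments(
            ophiopogonin_d, _spectrum(ophiopogonin_d, [721.4158, 575.3584])
        )
        assert len(anns) == 2
        rec = assign_confidence(cand, anns)
        assert rec.confidence == "tentative"

    def test_no_msms_stays_candidate_only(self, ophiopogonin_d):
        cand = self._candidate(ophiopogonin_d, rt=54.0)
        rec = assign_confidence(cand, [])
        assert rec.confidence == "candidate_only"

    def test_standard_outside_rt_window_is_tentative(self):
        ion = make_ion(
            "C12H16O4", "[M-H]-", name="Senkyunolide H",
            compound_class="phthalide", is_standard=True, reference_rt=8.90,
        )
        cand = self._candidate(ion, rt=10.5)
        anns = explain_fragments(ion, _spectrum(ion, [ion.mz - 43.98983]))
        rec = assign_confidence(cand, anns, standards_rt_tol=0.2)
        assert rec.confidence == "tentative"
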
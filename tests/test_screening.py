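"""MS1 screening: XIC windows, combined score, sorted-table search."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import brute_force_screen
from conftest import make_feature, make_ion
from phytoscreen.screening import (
    Feature,
    MS1Scan,
    ScreeningConfig,
    extract_xic,
    score_candidate,
    screen_features,
)


@pytest.fixture(scope="module")
def succinate_ion():
    return make_ion("C4H6O4", "[M-H]-", name="Succinic acid")


class TestXic:
    def test_window_membership(self):
        scans = [MS1Scan(rt=1.0, mz=np.array([500.009, 500.011]), intensity=np.array([10.0, 20.0]))]
        (rt, total), = extract_xic(scans, 500.0, width_da=0.02)
        assert total == 10.0  # +0.009 inside the +-0.01 half-window, +0.011 outside

    def test_empty_scan_list(self):
        assert extract_xic([], 500.0) == []

    def test_gaussian_peak_apex_recovered(self):
        rts = np.arange(0, 5, 0.05)
        apex = 2.35
        scans = [
            MS1Scan(
                rt=float(t),
                mz=np.array([500.0]),
                intensity=np.array([1e5 * np.exp(-0.5 * ((t - apex) / 0.1) ** 2)]),
            )
            for t in rts
        ]
        chrom = extract_xic(scans, 500.0, 0.02)
        best_rt = max(chrom, key=lambda p: p[1])[0]
        assert abs(best_rt - apex) <= 0.05


class TestScore:
    def test_perfect_match_scores_one(self, succinate_ion):
        env = tuple((k, v) for k, v in succinate_ion.pattern.binned if k >= 1)
        feat = make_feature(succinate_ion.mz, isotope_envelope=env)
        match = score_candidate(feat, succinate_ion)
        assert match.combined_score == pytest.approx(1.0)
        assert match.ppm_dev == 0.0

    def test_mass_at_tolerance_with_exact_envelope(self, succinate_ion):
        env = tuple((k, v) for k, v in succinate_ion.pattern.binned if k >= 1)
        mz = np.nextafter(succinate_ion.mz * (1 + 10e-6), 0)  # just inside +10 ppm
        match = score_candidate(make_feature(mz, isotope_envelope=env), succinate_ion)
        assert match.combined_score == pytest.approx(0.40, abs=1e-6)

    def test_half_and_half(self):
        # 5 ppm mass deviation, isotope ratios off by half the tolerance;
        # a large molecule keeps every binned ratio above the denominator floor
        ion = make_ion("C44H70O16", "[M-H]-")
        env = tuple((k, v * 1.05) for k, v in ion.pattern.binned if k >= 1)
        feat = make_feature(ion.mz * (1 + 5e-6), isotope_envelope=env)
        match = score_candidate(feat, ion)
        assert match.combined_score == pytest.approx(0.50, abs=1e-6)

    def test_beyond_tolerance_is_none(self, succinate_ion):
        feat = make_feature(succinate_ion.mz * (1 + 11e-6))
        assert score_candidate(feat, succinate_ion) is None

    def test_missing_envelope_flagged(self, succinate_ion):
        match = score_candidate(make_feature(succinate_ion.mz), succinate_ion)
        assert match.no_envelope
        assert match.isotope_score == 1.0

    def test_polarity_mismatch_rejected(self, succinate_ion):
        feat = make_feature(succinate_ion.mz, polarity="positive")
        with pytest.raises(ValueError, match="polarity"):
            score_candidate(feat, succinate_ion)

    @given(
        ppm=st.floats(min_value=0, max_value=7.9),
        ratio_factor=st.floats(min_value=0.5, max_value=1.5),
    )
    def test_score_bounded_and_monotone(self, ppm, ratio_factor):
        ion = make_ion("C10H10O4", "[M-H]-")
        env = tuple((k, v * ratio_factor) for k, v in ion.pattern.binned if k >= 1)
        feat = make_feature(ion.mz * (1 + ppm * 1e-6), isotope_envelope=env)
        match = score_candidate(feat, ion)
        assert 0.0 <= match.combined_score <= 1.0
        # worsening the mass deviation alone never raises the score
        worse = make_feature(ion.mz * (1 + (ppm + 2) * 1e-6), isotope_envelope=env)
        worse_match = score_candidate(worse, ion)
        if worse_match is not None:
            assert worse_match.combined_score <= match.combined_score + 1e-12


class TestScreenFeatures:
    def test_planted_compound_found(self, bundled_records):
        from phytoscreen.database import build_ion_table

        table = build_ion_table(bundled_records, "negative")
        feat = make_feature(117.0193)
        accepted, summary = screen_features([feat], table)
        assert any(m.ion.compound.name == "Succinic acid" for m in accepted)
        assert "Succinic acid" in summary.candidate_compounds

    def test_far_feature_matches_nothing(self, bundled_records):
        from phytoscreen.database import build_ion_table

        table = build_ion_table(bundled_records, "negative")
        accepted, summary = screen_features([make_feature(117.08)], table)
        assert accepted == [] and summary.n_scored == 0

    def test_equivalent_to_brute_force(self):
        rng = np.random.default_rng(42)
        formulas = [
            f"C{c}H{h}O{o}"
            for c, h, o in zip(
                rng.integers(5, 40, 60), rng.integers(6, 60, 60), rng.integers(1, 15, 60)
            )
        ]
        ions = sorted(
            (
                make_ion(f, adduct, name=f"cpd-{i}-{adduct}")
                for i, f in enumerate(formulas)
                for adduct in ("[M-H]-", "[M+Cl]-", "[M+HCOO]-")
            ),
            key=lambda ion: ion.mz,
        )
        assert len(ions) <= 200
        features = []
        for i in range(80):
            base = ions[int(rng.integers(0, len(ions)))].mz
            mz = base * (1 + rng.normal(0, 8) * 1e-6)  # some inside, some outside
            if 100 <= mz <= 2000:
                features.append(make_feature(mz, feature_id=f"f{i}"))
        cfg = ScreeningConfig(accept_threshold=0.0)
        accepted, _ = screen_features(features, ions, cfg)
        expected = brute_force_screen(features, ions, cfg)

        def key(matches):
            return sorted(
                (m.feature.feature_id, m.ion.compound.name, m.ion.adduct.name,
                 round(m.combined_score, 12))
                for m in matches
            )

        assert key(accepted) == key(expected)

    def test_unsorted_table_rejected(self, succinate_ion):
        other = make_ion("C4H6O4", "[M+HCOO]-")
        with pytest.raises(ValueError, match="sorted"):
            screen_features([make_feature(117.0)], [other, succinate_ion])
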
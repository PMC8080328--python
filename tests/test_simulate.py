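"""Synthetic study generator: determinism, noise laws, closure, recovery."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import phytoscreen as ps
from phytoscreen.simulate import (
    DEFAULT_ABSORPTION,
    SimulationConfig,
    generate_dataset,
    pad_database,
    recovery_report,
)


@pytest.fixture(scope="module")
def records():
    recs, _ = ps.load_bundled_database()
    return recs


class TestDeterminism:
    def test_same_seed_identical_datasets(self, records):
        cfg = SimulationConfig(seed=11, n_decoys=30)
        a = generate_dataset(records, cfg)
        b = generate_dataset(records, cfg)
        assert a.formulation_features == b.formulation_features
        assert a.formulation_spectra == b.formulation_spectra
        assert a.plasma_features == b.plasma_features
        assert a.blank_features == b.blank_features
        assert a.truth == b.truth

    def test_different_seeds_differ(self, records):
        a = generate_dataset(records, SimulationConfig(seed=1, n_decoys=0))
        b = generate_dataset(records, SimulationConfig(seed=2, n_decoys=0))
        assert a.formulation_features != b.formulation_features


class TestGenerativeLaws:
    def test_mass_error_distribution_is_gaussian(self, records):
        padded = pad_database(records, 1000, seed=7)
        cfg = SimulationConfig(seed=13, n_compounds=650, n_decoys=0)
        study = generate_dataset(padded, cfg)
        errors = [
            (e.observed_mz - e.theoretical_mz) / e.theoretical_mz * 1e6
            for e in study.truth.compounds
        ]
        assert len(errors) >= 600
        _, p = stats.kstest(errors, "norm", args=(0.0, cfg.mass_error_sigma_ppm))
        assert p > 0.01

    def test_rt_spacing_and_range(self, records):
        study = generate_dataset(records, SimulationConfig(seed=3, n_decoys=0))
        rts = sorted(
            e.rt
            for e in study.truth.compounds
            # pinned reference-standard rts are exempt from the spacing rule
            if e.name
            not in {
                r.name for r in records if r.is_reference_standard
            }
        )
        assert all(0.0 <= t <= 65.0 for t in rts)
        gaps = np.diff(rts)
        assert gaps.min() >= 0.1 - 1e-9

    def test_decoys_avoid_true_ion_windows(self, records):
        cfg = SimulationConfig(seed=5, n_decoys=150)
        study = generate_dataset(records, cfg)
        by_pol = {
            "negative": [e.theoretical_mz for e in study.truth.compounds if e.polarity == "negative"],
            "positive": [e.theoretical_mz for e in study.truth.compounds if e.polarity == "positive"],
        }
        decoys = [f for f in study.formulation_features if f.feature_id in study.truth.decoy_ids]
        assert len(decoys) == 150
        for d in decoys:
            for t in by_pol[d.polarity]:
                assert abs(d.mz - t) / t * 1e6 >= cfg.decoy_exclusion_ppm

    def test_blank_contains_only_decoys(self, records):
        study = generate_dataset(records, SimulationConfig(seed=5, n_decoys=20))
        assert all(f.feature_id.startswith("B") for f in study.blank_features)

    def test_absorption_defaults_are_probabilities(self):
        assert set(DEFAULT_ABSORPTION) == ps.database.COMPOUND_CLASSES
        assert all(0.0 <= p <= 1.0 for p in DEFAULT_ABSORPTION.values())


class TestFragmentClosure:
    def test_every_planted_fragment_explained_at_generating_depth(self, records):
        cfg = SimulationConfig(
            seed=17, n_decoys=0, mass_error_sigma_ppm=0.0, isotope_noise_cv=0.0,
            dropout_prob=0.0,
        )
        study = generate_dataset(records, cfg)
        by_name = {r.name: r for r in records}
        checked = 0
        for entry in study.truth.compounds:
            if entry.ms2_id is None:
                continue
            spectrum = study.formulation_spectra[entry.ms2_id]
            rec = by_name[entry.name]
            adduct = ps.ADDUCTS[entry.adduct_name]
            ion = ps.TheoreticalIon(
                compound=rec,
                adduct=adduct,
                mz=entry.theoretical_mz,
                pattern=ps.isotope_pattern(adduct.ion_counts(rec.counts)),
            )
            anns = ps.explain_fragments(ion, spectrum, max_depth=cfg.fragment_depth)
            assert len(anns) == len(spectrum.peaks), entry.name
            checked += 1
        assert checked > 100


class TestRecoveryReport:
    def test_noiseless_recovery_is_perfect(self, records):
        cfg = SimulationConfig(
            seed=19, n_decoys=0, mass_error_sigma_ppm=0.0, isotope_noise_cv=0.0,
            dropout_prob=0.0,
        )
        result = ps.run_study(records, cfg)
        rec = result.recovery
        assert rec.candidate_recall == 1.0
        assert rec.identification_recall == 1.0
        assert rec.prototype_recall == 1.0
        assert rec.decoy_hit_rate == 0.0

    def test_run_id_mismatch_rejected(self, records):
        study = generate_dataset(records, SimulationConfig(seed=1, n_decoys=0))
        with pytest.raises(ValueError, match="run id"):
            recovery_report(study.truth, set(), set(), set(), set(), run_id="sim-999")

    def test_absorbed_count_tracks_binomial_law(self, records):
        cfg = SimulationConfig(
            seed=23,
            absorption_prob_by_class={c: 0.5 for c in ps.database.COMPOUND_CLASSES},
        )
        study = generate_dataset(records, cfg)
        n_absorbed = len(study.truth.absorbed)
        # Binomial(117, 0.5): mean 58.5, sd ~5.4; a 4-sigma band is ample
        assert 37 <= n_absorbed <= 80


class TestPadDatabase:
    def test_pads_to_target_and_is_deterministic(self, records):
        a = pad_database(records, 667, seed=1)
        b = pad_database(records, 667, seed=1)
        assert len(a) == 667
        assert [r.name for r in a] == [r.name for r in b]
        assert a[: len(records)] == list(records)

    def test_synthetic_entries_marked(self, records):
        padded = pad_database(records, 200, seed=1)
        extra = padded[len(records):]
        assert all(r.name.startswith("Synthetic constituent") for r in extra)

    def test_no_padding_needed(self, records):
        assert pad_database(records, 50, seed=1) == list(records)
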
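"""Synthetic-data generator: determinism, ground truth, noiseless limits."""

import numpy as np
import pytest

from targetmet.chem import monoisotopic_mass, theoretical_mz
from targetmet.simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_experiment,
    simulate_isotopologue_series,
    simulate_library,
    simulate_run,
    simulate_truth,
    write_experiment,
)
from targetmet.tracing import NaturalAbundanceModel, natural_envelope

from conftest import noiseless_config


def test_library_is_deterministic_and_parseable():
    cfg = SimulationConfig(n_metabolites=10, seed=1)
    lib1 = simulate_library(cfg)
    lib2 = simulate_library(cfg)
    assert lib1 == lib2
    assert len({e.name for e in lib1}) == 10
    for e in lib1:
        assert monoisotopic_mass(e.formula) > 0
        assert cfg.rt_range[0] <= e.rt_min <= cfg.rt_range[1]


def test_library_cycles_formulas_with_unique_names():
    lib = simulate_library(SimulationConfig(n_metabolites=50, seed=1))
    assert len({e.name for e in lib}) == 50


def test_single_entry_library():
    assert len(simulate_library(SimulationConfig(n_metabolites=1))) == 1


def test_noiseless_apex_centroid_matches_theory(noiseless_experiment):
    """With zero mass error and jitter, the apex centroid sits exactly at
    the theoretical m/z and the library retention time."""
    exp = noiseless_experiment
    entry = exp.library[0]
    run = exp.runs[0]
    mz0 = theoretical_mz(entry.formula, entry.ion, 0)
    best = (0.0, None, None)
    for spec in run.spectra:
        if spec.polarity != entry.ion.polarity:
            continue
        mask = np.abs(spec.mz - mz0) / mz0 < 20e-6
        if mask.any() and spec.intensity[mask].max() > best[0]:
            best = (float(spec.intensity[mask].max()), spec.rt, spec.mz[mask][np.argmax(spec.intensity[mask])])
    height, apex_rt, apex_mz = best
    assert height == exp.truth.heights.loc[entry.name, run.sample_id]
    assert apex_rt == entry.rt_min
    assert apex_mz == mz0


def test_zero_height_leaves_no_signal(noiseless_experiment):
    exp = noiseless_experiment
    entry = exp.library[0]
    truth = GroundTruth(exp.truth.heights.copy(), exp.truth.apex_rt, exp.truth.log2fc)
    truth.heights.loc[entry.name, :] = 0.0
    run = simulate_run(exp.library, truth, exp.config, exp.runs[0].sample_id, "study", "control", np.random.default_rng(0))
    mz0 = theoretical_mz(entry.formula, entry.ion, 0)
    for spec in run.spectra:
        assert not ((np.abs(spec.mz - mz0) / mz0) < 20e-6).any()


def test_emitted_signal_mass_matches_discretized_gaussian(noiseless_experiment):
    """Total emitted intensity per metabolite equals the Gaussian profile
    summed over that polarity's scan grid (to the 6-sigma truncation)."""
    exp = noiseless_experiment
    cfg = exp.config
    run = exp.runs[0]
    for entry in exp.library[:3]:
        mz0 = theoretical_mz(entry.formula, entry.ion, 0)
        emitted = sum(
            float(spec.intensity[(np.abs(spec.mz - mz0) / mz0) < 20e-6].sum())
            for spec in run.spectra
            if spec.polarity == entry.ion.polarity
        )
        h = float(exp.truth.heights.loc[entry.name, run.sample_id])
        apex_s = entry.rt_min * 60.0
        sigma = cfg.peak_sigma_s
        expected = 0.0
        for spec in run.spectra:
            if spec.polarity != entry.ion.polarity:
                continue
            t = spec.rt * 60.0
            if abs(t - apex_s) <= 6 * sigma:
                expected += h * np.exp(-((t - apex_s) ** 2) / (2 * sigma**2))
        assert emitted == pytest.approx(expected, rel=1e-6)


def test_group_mean_ratio_converges_to_effect():
    """log2fc = 1 on one metabolite: the group-mean ratio approaches 2 at
    large n (law of large numbers, matrix level)."""
    cfg = SimulationConfig(seed=3, n_metabolites=5, n_samples_per_group=200, true_log2fc={"glucose": 1.0})
    library, samples, truth = simulate_truth(cfg)
    a_cols = [s for s in samples.index if samples.loc[s, "group"] == "control"]
    b_cols = [s for s in samples.index if samples.loc[s, "group"] == "treated"]
    ratio = truth.heights.loc["glucose", b_cols].mean() / truth.heights.loc["glucose", a_cols].mean()
    assert ratio == pytest.approx(2.0, rel=0.05)
    other = truth.heights.loc["lactate", b_cols].mean() / truth.heights.loc["lactate", a_cols].mean()
    assert other == pytest.approx(1.0, rel=0.05)


def test_same_seed_gives_byte_identical_mzml(tmp_path):
    cfg = noiseless_config(n_metabolites=3, n_samples_per_group=1, n_blanks=1, baseline_level=500.0)
    p1 = write_experiment(simulate_experiment(cfg), tmp_path / "a")
    p2 = write_experiment(simulate_experiment(cfg), tmp_path / "b")
    for f1 in sorted(p1["mzml_dir"].glob("*.mzML")):
        f2 = p2["mzml_dir"] / f1.name
        assert f1.read_bytes() == f2.read_bytes()


def test_ground_truth_round_trips_through_json(tmp_path, noiseless_experiment):
    truth = noiseless_experiment.truth
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = GroundTruth.from_json(path)
    assert np.allclose(back.heights.to_numpy(), truth.heights.to_numpy())
    assert list(back.heights.index) == list(truth.heights.index)
    assert np.allclose(back.apex_rt.to_numpy(), truth.apex_rt.to_numpy())
    assert back.log2fc.to_dict() == truth.log2fc.to_dict()


def test_blank_truth_is_carryover_fraction():
    cfg = SimulationConfig(seed=2, n_metabolites=4, n_samples_per_group=3, n_blanks=2, sample_cv=0.0)
    _, samples, truth = simulate_truth(cfg)
    study = [s for s in samples.index if samples.loc[s, "role"] == "study"]
    blanks = [s for s in samples.index if samples.loc[s, "role"] == "blank"]
    expected = cfg.blank_carryover * truth.heights[study].mean(axis=1)
    for b in blanks:
        assert np.allclose(truth.heights[b], expected)


def test_isotopologue_series_natural_envelope_limit():
    env = natural_envelope(NaturalAbundanceModel(6, 0.0107))
    series = simulate_isotopologue_series("C6H12O6", {}, 1e6)
    np.testing.assert_allclose(series.raw, 1e6 * env, rtol=1e-12)


def test_isotopologue_series_spike_arithmetic():
    """20% m+3 spike: raw m+3 = 0.2 x total + natural m+3 of the 0.8 share."""
    env3 = natural_envelope(NaturalAbundanceModel(3, 0.0107))
    series = simulate_isotopologue_series("C3H6O3", {3: 0.2}, 1e6)
    assert series.raw[3] == pytest.approx(0.2 * 1e6 + 0.8 * 1e6 * env3[3], rel=1e-12)
    assert series.raw.sum() == pytest.approx(1e6, rel=1e-12)


def test_isotopologue_series_edge_cases():
    assert simulate_isotopologue_series("C3H6O3", {3: 0.2}, 0.0).raw.sum() == 0.0
    with pytest.raises(ValueError):
        simulate_isotopologue_series("C3H6O3", {1: 0.7, 2: 0.6}, 1e6)
    with pytest.raises(ValueError):
        simulate_isotopologue_series("C3H6O3", {5: 0.1}, 1e6)


def test_isotopologue_series_noise_is_seeded():
    s1 = simulate_isotopologue_series("C3H6O3", {3: 0.2}, 1e6, seed=9, noise_cv=0.05)
    s2 = simulate_isotopologue_series("C3H6O3", {3: 0.2}, 1e6, seed=9, noise_cv=0.05)
    np.testing.assert_array_equal(s1.raw, s2.raw)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_metabolites=0)
    with pytest.raises(ValueError):
        SimulationConfig(sample_cv=-0.1)
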
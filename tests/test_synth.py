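import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from keraspec import synth
from keraspec.descriptors import default_config


# -- latent sampling --------------------------------------------------------

def test_default_mix_reproduces_species_pool_counts():
    latents = synth.sample_latents(63, seed=1)
    counts = pd.Series([lat.species for lat in latents]).value_counts()
    assert counts["cat"] == 9 and counts["cow"] == 12
    assert counts["human"] == 21 and counts["pig"] == 21


def test_latents_deterministic_under_seed():
    a = synth.sample_latents(4, species_mix=(0.25,) * 4, seed=0)
    b = synth.sample_latents(4, species_mix=(0.25,) * 4, seed=0)
    assert a == b


def test_latent_invariants_hold():
    for lat in synth.sample_latents(63, seed=2):
        assert 0.0 <= lat.alpha_helix_fraction <= 1.0
        assert 0.0 <= lat.lipid_content <= 1.0
        assert lat.cross_section_area > 0


def test_species_cluster_structure_present():
    latents = synth.sample_latents(200, seed=3)
    frame = pd.DataFrame([{"sp": l.species, "a": l.alpha_helix_fraction}
                          for l in latents])
    means = frame.groupby("sp")["a"].mean()
    assert means["pig"] - means["cat"] > 0.15


def test_too_few_samples_rejected():
    with pytest.raises(ValueError):
        synth.sample_latents(3, species_mix=(0.25,) * 4, seed=0)


def test_monte_carlo_latent_mean_matches_configuration():
    latents = synth.sample_latents(1000, seed=2)
    alphas = np.array([l.alpha_helix_fraction for l in latents])
    target = sum(m * synth.SPECIES_MEANS[s]["alpha_helix_fraction"]
                 for m, s in zip(synth.DEFAULT_SPECIES_MIX, synth.SPECIES))
    # donor effects are shared by ~2 pools each, so the effective sample
    # size for the standard error is about n/2
    se = alphas.std(ddof=1) / np.sqrt(len(alphas) / 2)
    assert abs(alphas.mean() - target) < 3 * se


# -- spectra ----------------------------------------------------------------

def _latent(**kw):
    base = dict(sample_id="S1", species="human", donor="human_d1",
                alpha_helix_fraction=0.65, lipid_content=0.4,
                bound_water=0.5, thermal_resistance=0.5,
                cross_section_area=0.004)
    base.update(kw)
    return synth.LatentComposition(**base)


def test_zero_lipid_leaves_baseline_at_lipid_peak():
    with_lipid = synth.mas_template(_latent(lipid_content=0.5))
    without = synth.mas_template(_latent(lipid_content=0.0))
    idx = int(np.argmin(np.abs(synth.MAS_AXIS - 1.30)))
    assert with_lipid[idx] > without[idx]
    # at zero lipid the 1.3 ppm point equals the lipid-free baseline
    baseline = synth.mas_template(_latent(lipid_content=0.0))
    assert without[idx] == pytest.approx(baseline[idx])


def test_carbonyl_band_integral_increases_with_alpha_helix():
    integrals = []
    mask = (synth.CPMAS_AXIS >= 165) & (synth.CPMAS_AXIS <= 178)
    for alpha in (0.3, 0.6, 0.9):
        y = synth.cpmas_template(_latent(alpha_helix_fraction=alpha))
        integrals.append(np.trapezoid(y[mask], synth.CPMAS_AXIS[mask]))
    assert integrals[0] < integrals[1] < integrals[2]


def test_replicate_structure_matches_design():
    latents = synth.sample_latents(4, species_mix=(0.25,) * 4, seed=0)
    spectra = synth.render_spectra(latents, seed=0)
    frame = pd.DataFrame([{"sid": s.sample_id, "mod": s.modality,
                           "rep": s.replicate} for s in spectra])
    counts = frame.groupby(["sid", "mod"])["rep"].nunique()
    for sid in {l.sample_id for l in latents}:
        assert counts[(sid, "tdnmr")] == 5
        assert counts[(sid, "ftir")] >= 3
        for mod in synth.REPLICATES:
            assert counts[(sid, mod)] >= 1


def test_unknown_modality_rejected():
    latents = synth.sample_latents(4, species_mix=(0.25,) * 4, seed=0)
    with pytest.raises(ValueError, match="modality"):
        synth.render_spectra(latents, modalities=("raman",))


def test_rendered_spectra_deterministic():
    latents = synth.sample_latents(4, species_mix=(0.25,) * 4, seed=0)
    a = synth.render_spectra(latents, seed=5)
    b = synth.render_spectra(latents, seed=5)
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.intensity, sb.intensity)


# -- properties -------------------------------------------------------------

def test_zero_noise_gives_identical_replicates():
    latents = synth.sample_latents(4, species_mix=(0.25,) * 4, seed=0)
    truth = synth.GroundTruth(
        informative_descriptor_ids=frozenset(["x"]),
        property_weights=synth.DEFAULT_PROPERTY_WEIGHTS,
        noise_sd={p: 0.0 for p in synth.PROPERTY_COLUMNS})
    table = synth.render_properties(latents, truth, seed=0)
    sds = table.groupby("sample_id")[list(synth.PROPERTY_COLUMNS)].std()
    assert np.allclose(sds.to_numpy(), 0.0)


def test_breaking_force_tracks_cross_section_area():
    latents = synth.sample_latents(63, seed=4)
    truth = synth.default_truth()
    table = synth.render_properties(latents, truth, seed=4)
    means = table.groupby("sample_id")["breaking_force_N"].mean()
    areas = pd.Series({l.sample_id: l.cross_section_area for l in latents})
    rho, _ = spearmanr(means, areas.loc[means.index])
    assert rho > 0.9


def test_pig_stronger_than_cat():
    latents = synth.sample_latents(63, seed=5)
    truth = synth.default_truth()
    table = synth.render_properties(latents, truth, seed=5)
    means = table.groupby("sample_id")["breaking_force_N"].mean()
    species = {l.sample_id: l.species for l in latents}
    by_sp = means.groupby(species).median()
    assert by_sp["pig"] > by_sp["cat"]


def test_replicate_noise_sd_calibrated():
    latents = [_latent()]
    truth = synth.default_truth()
    table = synth.render_properties(latents, truth, seed=0,
                                    n_replicates=1000)
    sd = table["yield_strength_MPa"].std(ddof=1)
    target = truth.noise_sd["yield_strength_MPa"]
    assert abs(sd - target) / target < 0.2


# -- ground truth and persistence ------------------------------------------

def test_default_truth_plants_twenty_informative_descriptors():
    truth = synth.default_truth()
    ids = truth.informative_descriptor_ids
    assert len(ids) == 20
    # every planted band owns a nonderivative MAS bin in the lipid or
    # H-alpha window
    assert all(i.startswith("mas.") and "2der" not in i for i in ids)
    assert "mas.30" in ids    # first lipid band at 0.85 ppm


def test_informative_ids_only_cover_breaking_force_latents():
    truth = synth.default_truth()
    assert truth.latents_for_property("breaking_force_N") == {
        "alpha_helix_fraction", "lipid_content"}
    assert "bound_water" in truth.latents_for_property("extension_pct")


def test_dataset_round_trip(tmp_path, small_dataset):
    manifest = synth.write_dataset(small_dataset, tmp_path / "ds")
    assert manifest["seed"] == small_dataset.seed
    back = synth.read_dataset(tmp_path / "ds")
    assert back.latents == small_dataset.latents
    assert back.truth.informative_descriptor_ids == \
        small_dataset.truth.informative_descriptor_ids
    pd.testing.assert_frame_equal(back.properties, small_dataset.properties)
    key = lambda s: (s.sample_id, s.modality, s.replicate)
    for orig, rec in zip(sorted(small_dataset.spectra, key=key),
                         sorted(back.spectra, key=key)):
        np.testing.assert_allclose(rec.intensity, orig.intensity)


def test_write_refuses_overwrite(tmp_path, small_dataset):
    synth.write_dataset(small_dataset, tmp_path / "ds")
    with pytest.raises(FileExistsError):
        synth.write_dataset(small_dataset, tmp_path / "ds")
    synth.write_dataset(small_dataset, tmp_path / "ds", overwrite=True)


def test_spectra_csv_row_count_oracle(tmp_path, small_dataset):
    synth.write_dataset(small_dataset, tmp_path / "ds")
    frame = pd.read_csv(tmp_path / "ds" / "spectra.csv")
    expected = sum(sp.n_points for sp in small_dataset.spectra)
    assert len(frame) == expected
    # per modality: axis length x replicates x samples
    n = len(small_dataset.latents)
    axis_len = {"tdnmr": synth.TD_AXIS.size, "ftir": synth.FTIR_AXIS.size}
    for mod, length in axis_len.items():
        got = (frame["modality"] == mod).sum()
        assert got == length * synth.REPLICATES[mod] * n


def test_generate_dataset_deterministic():
    a = synth.generate_dataset(n_samples=6, seed=9)
    b = synth.generate_dataset(n_samples=6, seed=9)
    pd.testing.assert_frame_equal(a.properties, b.properties)
    np.testing.assert_array_equal(a.spectra[10].intensity,
                                  b.spectra[10].intensity)
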
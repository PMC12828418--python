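"""The synthetic identification generator and its analytic ground truth."""

import numpy as np
import pandas as pd
import pytest

from ppepkit.library import NON_PRIME_DESIGN, PRIME_DESIGN, VARIABLE_ALPHABET, LibraryDesign
from ppepkit.logo import combine_profiles, relative_occurrence
from ppepkit.quantify import filter_products, merge_isobaric
from ppepkit.simulate import (
    MODEL_POSITIONS,
    IonizationModel,
    RunConfig,
    SpecificityModel,
    default_specificity_model,
    expected_product_abundances,
    generate_identifications,
    ground_truth_logo,
)


def pipeline_logo(table):
    """filter -> merge -> per-side occurrence -> combined profile."""
    merged = merge_isobaric(filter_products(table))
    profiles = {}
    for design in (NON_PRIME_DESIGN, PRIME_DESIGN):
        side = [p for p in merged if p.side == design.name]
        profiles[design.readout_side] = relative_occurrence(
            side, design.product_template()
        )
    return combine_profiles(**profiles)


def test_model_validation():
    eff = pd.DataFrame(0.5, index=list(VARIABLE_ALPHABET), columns=list(MODEL_POSITIONS))
    SpecificityModel(efficiency=eff)  # valid
    bad = eff.copy()
    bad["P2"] = 0.0
    with pytest.raises(ValueError, match="P2"):
        SpecificityModel(efficiency=bad)
    bad = eff.copy()
    bad.loc["L", "P3"] = 1.5
    with pytest.raises(ValueError):
        SpecificityModel(efficiency=bad)


def test_ionization_model_validation():
    with pytest.raises(ValueError):
        IonizationModel(response_factor={"H": 0.0})
    assert IonizationModel().factor("PHP") == 2.0
    assert IonizationModel().factor("HKH") == 8.0


def test_run_config_validation():
    with pytest.raises(ValueError):
        RunConfig(seed=0, noise_sigma=-0.1)
    with pytest.raises(ValueError):
        RunConfig(seed=0, lod=-1.0)


def test_zero_efficiency_residue_never_survives(default_model, unit_ionization):
    eff = default_model.efficiency.copy()
    eff.loc["W", "P2"] = 0.0
    model = SpecificityModel(efficiency=eff)
    table, _ = generate_identifications(
        model, unit_ionization, cfg=RunConfig(seed=5, noise_sigma=0.0, contaminant_rows=0)
    )
    non_prime = table[table["side"] == "non_prime"]
    surviving = non_prime[non_prime["abundance"] > 0]
    assert not (surviving["sequence"].str[7] == "W").any()  # slot 8 is P2


def test_uniform_model_ground_truth_is_flat(uniform_model, unit_ionization):
    _, truth = generate_identifications(
        uniform_model, unit_ionization,
        cfg=RunConfig(seed=1, noise_sigma=0.0, contaminant_rows=0),
    )
    for side in ("non_prime", "prime"):
        vals = truth.products.loc[truth.products["side"] == side, "true_abundance"]
        assert len(vals) == 361
        assert np.allclose(vals, vals.iloc[0])


def test_listed_abundance_is_shared_within_mass_group(default_model):
    table, truth = generate_identifications(
        default_model, cfg=RunConfig(seed=3, noise_sigma=0.3, contaminant_rows=0)
    )
    products = table.merge(truth.products, on=["sequence", "side"])
    for (_, _), grp in products.groupby(["side", "mass_key"]):
        assert grp["abundance"].nunique() == 1
        # noise acts on the group's combined true abundance
        assert grp["abundance"].iloc[0] > 0


def test_determinism_given_seed(default_model):
    cfg = RunConfig(seed=11, noise_sigma=0.3)
    a, _ = generate_identifications(default_model, cfg=cfg)
    b, _ = generate_identifications(default_model, cfg=cfg)
    pd.testing.assert_frame_equal(a, b)
    c, _ = generate_identifications(default_model, cfg=RunConfig(seed=12, noise_sigma=0.3))
    assert not a["abundance"].equals(c["abundance"])


def test_missing_model_position_rejected(unit_ionization):
    eff = pd.DataFrame(
        0.5, index=list(VARIABLE_ALPHABET), columns=["P3", "P2", "P2'"]
    )
    model = SpecificityModel(efficiency=eff)
    with pytest.raises(KeyError, match="absent from model"):
        generate_identifications(model, unit_ionization, cfg=RunConfig(seed=0))


def test_raising_lod_never_increases_rows(default_model):
    sizes = []
    for lod in (0.0, 0.5, 2.0, 10.0, 100.0):
        table, _ = generate_identifications(
            default_model,
            cfg=RunConfig(seed=2, noise_sigma=0.3, lod=lod, contaminant_rows=0),
        )
        sizes.append(len(table))
    assert sizes == sorted(sizes, reverse=True)


def test_contaminants_are_rejected_by_filters(default_model):
    table, _ = generate_identifications(
        default_model, cfg=RunConfig(seed=4, noise_sigma=0.0, contaminant_rows=10)
    )
    assert (table["side"] == "unknown").sum() == 10
    filtered = filter_products(table)
    assert (filtered["sequence"].str.len() == 9).all()
    assert set(filtered["side"]) <= {"non_prime", "prime"}
    assert len(filtered) == len(table) - 10


class TestGroundTruthLogo:
    def test_uniform_model_gives_one_nineteenth(self, uniform_model, unit_ionization):
        profile = ground_truth_logo(uniform_model, unit_ionization)
        for pos in ("P3", "P2", "P2'", "P3'"):
            assert np.allclose(profile.matrix[pos], 1 / 19, atol=1e-12)
        assert profile.matrix.loc["P", "P1"] == 1.0

    def test_single_allowed_residue_gives_indicator(self, unit_ionization):
        eff = pd.DataFrame(
            0.0, index=list(VARIABLE_ALPHABET), columns=list(MODEL_POSITIONS)
        )
        for pos, res in zip(MODEL_POSITIONS, "LSPP"):
            eff.loc[res, pos] = 1.0
        profile = ground_truth_logo(SpecificityModel(efficiency=eff), unit_ionization)
        assert profile.matrix.loc["L", "P3"] == 1.0
        assert profile.matrix.loc["S", "P2"] == 1.0
        assert profile.matrix.loc["P", "P2'"] == 1.0

    def test_ionization_bias_closed_form(self, uniform_model):
        # Uniform cleavage, H responds 2x: expected H share 2/(18+2) = 0.10.
        profile = ground_truth_logo(
            uniform_model, IonizationModel({"H": 2.0}), merge_aware=False
        )
        assert profile.matrix.loc["H", "P2"] == pytest.approx(0.10, abs=1e-12)

    def test_all_zero_position_rejected(self, unit_ionization):
        eff = pd.DataFrame(
            0.0, index=list(VARIABLE_ALPHABET), columns=list(MODEL_POSITIONS)
        )
        eff.loc["L"] = 1.0
        eff.loc["L", "P3"] = 0.0
        with pytest.raises(ValueError):
            ground_truth_logo(SpecificityModel(efficiency=eff), unit_ionization)


def test_noise_free_pipeline_equals_ground_truth(default_model):
    table, truth = generate_identifications(
        default_model, cfg=RunConfig(seed=7, noise_sigma=0.0, lod=0.0)
    )
    profile = pipeline_logo(table)
    expected = ground_truth_logo(truth.model, truth.ionization)
    assert np.abs(profile.matrix - expected.matrix).to_numpy().max() <= 1e-9


def test_hard_floor_vetoes_weak_positions(unit_ionization):
    eff = pd.DataFrame(
        0.5, index=list(VARIABLE_ALPHABET), columns=list(MODEL_POSITIONS)
    )
    eff.loc["V", "P2'"] = 0.05
    model = SpecificityModel(efficiency=eff, floor=0.1)
    frame = expected_product_abundances(model, unit_ionization, PRIME_DESIGN)
    with_v = frame[frame["sequence"].str[1] == "V"]  # slot 2 is P2'
    assert np.allclose(with_v["true_abundance"], 0.0)
    no_floor = SpecificityModel(efficiency=eff, floor=0.0)
    frame2 = expected_product_abundances(no_floor, unit_ionization, PRIME_DESIGN)
    assert (frame2[frame2["sequence"].str[1] == "V"]["true_abundance"] > 0).all()
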
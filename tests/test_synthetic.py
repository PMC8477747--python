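"""Synthetic clearance datasets: generation, noise model, exponent recovery."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mabscale import (
    HUMAN_WEIGHT_KG,
    SyntheticConfig,
    afe,
    generate,
    predict_cl_allometric,
    recover_exponent,
)

SPECIES_WEIGHTS = {"mouse": 0.02, "rat": 0.25, "monkey": 3.5}


class TestGenerate:
    def test_every_mab_has_a_human_record(self):
        ds = generate(SyntheticConfig(n_mabs=8, seed=3))
        by_species = {}
        for r in ds.records:
            by_species.setdefault(r.species, set()).add(r.mab_id)
        assert len(by_species["human"]) == 8
        for sp in ("mouse", "rat", "monkey"):
            assert by_species[sp] == by_species["human"]

    def test_same_seed_identical_datasets(self):
        cfg = SyntheticConfig(n_mabs=10, seed=42)
        assert generate(cfg) == generate(cfg)

    def test_different_seeds_differ(self):
        a = generate(SyntheticConfig(n_mabs=10, seed=1))
        b = generate(SyntheticConfig(n_mabs=10, seed=2))
        assert a != b

    def test_noise_free_data_lies_exactly_on_power_law(self):
        ds = generate(SyntheticConfig(n_mabs=5, noise_sigma=0.0, seed=0))
        for r in ds.records:
            w = SPECIES_WEIGHTS.get(r.species, HUMAN_WEIGHT_KG)
            expected = ds.intercepts[r.mab_id] * w**ds.true_exponent
            assert r.clearance == pytest.approx(expected, rel=1e-12)

    def test_noise_free_ratios_are_unity_at_true_exponent(self):
        ds = generate(SyntheticConfig(n_mabs=6, noise_sigma=0.0, seed=9))
        human = ds.by_species("human")
        for sp, w in SPECIES_WEIGHTS.items():
            for mab_id, rec in ds.by_species(sp).items():
                pred = predict_cl_allometric(rec.clearance, w, HUMAN_WEIGHT_KG, 0.85)
                assert pred / human[mab_id].clearance == pytest.approx(1.0, rel=1e-12)

    def test_log_ratio_noise_is_centred(self):
        # ln(pred/obs) = ln(eps_animal) - ln(eps_human): mean 0, sd sigma*sqrt(2)
        sigma = 0.3
        ds = generate(SyntheticConfig(n_mabs=200, noise_sigma=sigma, seed=11))
        human = ds.by_species("human")
        log_ratios = [
            math.log(
                predict_cl_allometric(r.clearance, 0.25, HUMAN_WEIGHT_KG, 0.85)
                / human[mab_id].clearance
            )
            for mab_id, r in ds.by_species("rat").items()
        ]
        se = sigma * math.sqrt(2) / math.sqrt(len(log_ratios))
        assert abs(np.mean(log_ratios)) < 3 * se

    @given(
        n=st.integers(min_value=1, max_value=20),
        sigma=st.floats(min_value=0.0, max_value=1.0),
        b=st.floats(min_value=0.5, max_value=1.2),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_clearances_positive_finite(self, n, sigma, b, seed):
        ds = generate(
            SyntheticConfig(n_mabs=n, noise_sigma=sigma, true_exponent=b, seed=seed)
        )
        for r in ds.records:
            assert r.clearance > 0 and math.isfinite(r.clearance)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_mabs": 0},
            {"noise_sigma": -0.1},
            {"true_exponent": 1.6},
            {"species_panel": ()},
            {"species_panel": ("dog",)},
            {"intercept_range": (5.0, 1.0)},
            {"dose_menu": (10.0, -1.0)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestNoiseFreeAfeClosedForm:
    @pytest.mark.parametrize("b_true", [0.75, 0.85, 0.90])
    @pytest.mark.parametrize("b_used", [0.75, 0.80, 0.85, 0.90])
    @pytest.mark.parametrize("species", ["mouse", "rat", "monkey"])
    def test_afe_equals_weight_ratio_power(self, b_true, b_used, species):
        # predicting with b' on data generated with b gives every ratio
        # (70/W)^(b'-b), so AFE = (W/70)^(b-b') = (W/70)^-(b'-b)
        ds = generate(
            SyntheticConfig(n_mabs=4, noise_sigma=0.0, true_exponent=b_true, seed=5)
        )
        human = ds.by_species("human")
        w = SPECIES_WEIGHTS[species]
        ratios = [
            predict_cl_allometric(r.clearance, w, HUMAN_WEIGHT_KG, b_used)
            / human[mab_id].clearance
            for mab_id, r in ds.by_species(species).items()
        ]
        expected = (w / HUMAN_WEIGHT_KG) ** (b_true - b_used)
        assert afe(ratios) == pytest.approx(expected, rel=1e-10)


class TestRecoverExponent:
    @pytest.mark.parametrize("b", [0.75, 0.80, 0.85, 0.90])
    def test_noise_free_exact_recovery(self, b):
        ds = generate(SyntheticConfig(n_mabs=5, noise_sigma=0.0, true_exponent=b, seed=2))
        for sp in ("mouse", "rat", "monkey"):
            assert recover_exponent(ds, sp) == b

    def test_recovery_under_noise_is_modal_at_truth(self):
        # study conditions: b = 0.85, n = 50, sigma = 0.2, 100 seeds.
        # Frozen baseline: mouse recovers 0.85 in 100/100 of these seeds.
        counts = Counter()
        for seed in range(100):
            ds = generate(
                SyntheticConfig(
                    n_mabs=50, noise_sigma=0.2, seed=seed, species_panel=("mouse",)
                )
            )
            counts[recover_exponent(ds, "mouse")] += 1
        assert counts.most_common(1)[0][0] == 0.85
        assert counts[0.85] / 100 >= 0.6
        assert counts[0.85] == 100  # regression baseline at these seeds

    def test_recovery_within_one_grid_step(self):
        # Frozen baseline: monkey (hardest: smallest weight ratio) recovers
        # 0.85 in 97/100 seeds, always within one 0.05 grid step.
        counts = Counter()
        for seed in range(100):
            ds = generate(SyntheticConfig(n_mabs=50, noise_sigma=0.2, seed=seed))
            counts[recover_exponent(ds, "monkey")] += 1
        within_one_step = sum(v for b, v in counts.items() if abs(b - 0.85) <= 0.051)
        assert within_one_step / 100 >= 0.9
        assert counts[0.85] == 97  # regression baseline at these seeds

    def test_tie_breaks_to_smaller_exponent(self):
        ds = generate(SyntheticConfig(n_mabs=5, noise_sigma=0.0, true_exponent=0.85, seed=0))
        # grid without the true value: 0.80 and 0.90 are equidistant in
        # |log10 AFE|, the smaller wins
        assert recover_exponent(ds, "rat", (0.80, 0.90)) == 0.80

    def test_missing_species_rejected(self):
        ds = generate(SyntheticConfig(n_mabs=3, species_panel=("rat",), seed=0))
        with pytest.raises(ValueError):
            recover_exponent(ds, "mouse")

    def test_unsorted_grid_rejected(self):
        ds = generate(SyntheticConfig(n_mabs=3, seed=0))
        with pytest.raises(ValueError):
            recover_exponent(ds, "rat", (0.9, 0.75))
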
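"""Synthetic-study generator: calibration envelopes and ground truth."""

import numpy as np
import pytest

from biofilmkit.classify import Category, classify_triplet
from biofilmkit.conjugation import conjugation_efficiency, double_plasmid_proportion
from biofilmkit.growth import fit_growth_rate
from biofilmkit.plates import (
    BLANK_CONDITION,
    REFERENCE_CONDITION,
    aggregate_replicates,
    normalize_plate,
)
from biofilmkit.simulate import (
    GrowthParams,
    SimulationConfig,
    biofilm_inoculum_cfu,
    growth_assay_inoculum_density,
    pair_mode_mean,
    simulate_double_proportion,
    simulate_growth_curves,
    simulate_mating,
    simulate_plate_set,
    simulate_triplet_study,
    true_outcome,
)


class TestDilutionArithmetic:
    def test_biofilm_inoculum(self):
        # 2e9 CFU/mL overnight -> 5 uL into 200 uL mix -> 5 uL transferred
        assert biofilm_inoculum_cfu(2e9) == pytest.approx(2.5e5)

    def test_growth_inoculum(self):
        assert growth_assay_inoculum_density(2e9) == pytest.approx(2e7)


class TestPlateSet:
    def test_noiseless_effect_is_exact(self):
        cfg = SimulationConfig(
            seed=1,
            noise_sd=0.0,
            baseline_range=(0.15, 0.2),
            plasmid_effects={"X": 2.0},
            pair_modes={},
        )
        readings, _ = simulate_plate_set(cfg)
        by_plate: dict = {}
        for w in readings:
            by_plate.setdefault(w.plate_id, []).append(w)
        for plate in by_plate.values():
            rel = {w.condition: v for w, v in normalize_plate(plate)}
            assert rel["X"] == pytest.approx(2.0)

    def test_default_config_respects_envelopes(self):
        readings, _ = simulate_plate_set(SimulationConfig(seed=3))
        for w in readings:
            if w.condition == BLANK_CONDITION:
                assert 0.05 <= w.od595 <= 0.07
            else:
                assert 0.10 <= w.od595 <= 0.51

    def test_same_seed_bit_identical(self):
        a, _ = simulate_plate_set(SimulationConfig(seed=9))
        b, _ = simulate_plate_set(SimulationConfig(seed=9))
        assert a == b

    def test_different_seed_differs(self):
        a, _ = simulate_plate_set(SimulationConfig(seed=9))
        b, _ = simulate_plate_set(SimulationConfig(seed=10))
        assert a != b

    def test_ground_truth_directions(self):
        _, truth = simulate_plate_set(SimulationConfig(seed=1))
        assert truth.effect_direction["R124"] == "increased"
        assert truth.effect_direction["R16a"] == "decreased"
        assert truth.effect_direction["R388"] == "no_change"


class TestTripletStudy:
    def test_dominant_a_noiseless_construction(self):
        cfg = SimulationConfig(seed=2, noise_sd=0.0, plasmid_effects={"A": 3.0, "B": 1.5})
        t = simulate_triplet_study(cfg, ("A", "B"), "dominant_A", n=5)
        assert np.mean(t.values_ab) == pytest.approx(np.mean(t.values_a))

    def test_null_mode_centers_on_one(self):
        cfg = SimulationConfig(seed=2, noise_sd=0.0, plasmid_effects={"A": 3.0, "B": 1.5})
        t = simulate_triplet_study(cfg, ("A", "B"), "null", n=5)
        assert np.mean(t.values_ab) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "effects, mode, expected",
        [
            ((3.0, 1.5), "dominant_A", Category.DOMINANCE_HIGHEST),
            ((3.0, 1.5), "dominant_B", Category.DOMINANCE_LOWEST),
            ((3.0, 1.5), "increased", Category.INCREASED),
            ((3.0, 1.5), "decreased", Category.DECREASED),
            ((3.0, 1.5), "intermediate", Category.INTERMEDIATE),
            # null mode pins the pair at the plasmid-free level: with
            # enhancer singles that is a joint decrease, with neutral
            # singles nothing is distinguishable
            ((3.0, 1.5), "null", Category.DECREASED),
            ((1.0, 1.0), "null", Category.UNDETERMINED),
        ],
    )
    def test_true_outcome_per_mode(self, effects, mode, expected):
        assert true_outcome(*effects, mode).category is expected

    def test_additive_mode_mean(self):
        assert pair_mode_mean(2.0, 1.5, "additive") == pytest.approx(2.5)
        # both enhancers additive exceed either single: a joint increase
        assert true_outcome(2.0, 1.5, "additive").category is Category.INCREASED


class TestMating:
    def test_zero_efficiency_zero_transconjugants(self):
        cfg = SimulationConfig(seed=5, conjugation_efficiencies={"P": 0.0})
        m, counts = simulate_mating(cfg, "P")
        assert m.T == 0.0 and counts["T"].colonies == 0

    def test_efficiency_recovery_within_ten_percent(self):
        gamma = 1e-12
        cfg = SimulationConfig(seed=6, conjugation_efficiencies={"P": gamma})
        rng = np.random.default_rng(6)
        estimates = []
        for _ in range(100):
            m, _ = simulate_mating(cfg, "P", rng=rng)
            estimates.append(conjugation_efficiency(m).value)
        assert np.mean(estimates) == pytest.approx(gamma, rel=0.10)

    def test_double_proportion_bands(self):
        cfg = SimulationConfig(seed=7)
        rng = np.random.default_rng(7)
        f_props, other_props = [], []
        for _ in range(50):
            d, t = simulate_double_proportion(cfg, ("F", "R388"), rng=rng)
            f_props.append(double_plasmid_proportion(d, t))
            d, t = simulate_double_proportion(cfg, ("R16a", "R388"), rng=rng)
            other_props.append(double_plasmid_proportion(d, t))
        assert 0.30 <= np.mean(f_props) <= 0.59
        assert 0.09 <= np.mean(other_props) <= 0.17


class TestGrowthCurves:
    def test_initial_density_is_hundredth_of_overnight(self):
        cfg = SimulationConfig(seed=8, growth_noise_sd=0.0)
        curve = simulate_growth_curves(cfg, REFERENCE_CONDITION, n_replicates=1)[0]
        # OD 0.01 corresponds to 2e7 CFU/mL at the OD calibration used
        assert curve.od600[0] == pytest.approx(0.01)

    def test_zero_noise_exponential_model_exact(self):
        cfg = SimulationConfig(seed=8, growth_noise_sd=0.0, growth_model="exponential")
        curve = simulate_growth_curves(cfg, REFERENCE_CONDITION, n_replicates=1)[0]
        est = fit_growth_rate(curve)
        assert est.accepted and est.rate == pytest.approx(0.02, abs=1e-9)

    def test_zero_noise_logistic_close(self):
        cfg = SimulationConfig(seed=8, growth_noise_sd=0.0)
        est = fit_growth_rate(simulate_growth_curves(cfg, REFERENCE_CONDITION, 1)[0])
        assert est.rate == pytest.approx(0.02, rel=0.05)

    def test_growth_cost_recovery(self):
        # configured 20% slower strain recovers relative rate 0.80 +/- 0.02
        cfg = SimulationConfig(
            seed=9,
            growth={
                REFERENCE_CONDITION: GrowthParams(rate=0.02),
                "S": GrowthParams(rate=0.016),
            },
        )
        rng = np.random.default_rng(9)
        from biofilmkit.growth import relative_growth_rate

        wt = [fit_growth_rate(c).rate for c in simulate_growth_curves(cfg, "WT", 6, rng=rng)]
        s = [fit_growth_rate(c).rate for c in simulate_growth_curves(cfg, "S", 6, rng=rng)]
        rel = relative_growth_rate(s, wt)
        assert np.mean(rel) == pytest.approx(0.80, abs=0.02)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(blank_range=(0.07, 0.05))
    with pytest.raises(ValueError):
        SimulationConfig(plasmid_effects={"X": -1.0})
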
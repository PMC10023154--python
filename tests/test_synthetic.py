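import numpy as np
import pandas as pd
import pytest

from vesselmech.calibration import ECHO_GROUPS, SURVIVAL
from vesselmech.cardiac import summarize_echo
from vesselmech.io import validate_protocol_design
from vesselmech.synthetic import (GeneratorConfig, generate_active_traces,
                                  generate_echo_records,
                                  generate_histology_image,
                                  generate_passive_dataset)
from vesselmech.vasoactive import constriction_metrics

from .conftest import NOISE_FREE


class TestPassiveGeneration:
    def test_seven_protocols_and_point_budget(self):
        ds, _ = generate_passive_dataset("WT", 168, "DTA", seed=42)
        kinds = [t.protocol_kind for t in ds.passive]
        assert kinds.count("Pd") == 3 and kinds.count("fl") == 4
        total = sum(len(t.samples) for t in ds.passive)
        assert total >= 2800

    def test_same_seed_bit_identical(self):
        a, _ = generate_passive_dataset("GG", 42, "DTA", seed=7)
        b, _ = generate_passive_dataset("GG", 42, "DTA", seed=7)
        assert a.record == b.record
        for ta, tb in zip(a.passive, b.passive):
            pd.testing.assert_frame_equal(ta.samples, tb.samples,
                                          check_exact=True)

    def test_different_seeds_differ(self):
        a, ta = generate_passive_dataset("GG", 42, "DTA", seed=7)
        b, tb = generate_passive_dataset("GG", 42, "DTA", seed=8)
        assert ta.params.c != tb.params.c

    def test_generated_datasets_conform_to_protocol_design(self):
        for vessel in ("DTA", "MA"):
            ds, _ = generate_passive_dataset("GG", 168, vessel, seed=3)
            report = validate_protocol_design(ds.passive, vessel)
            assert report.passed, report.entries

    def test_noise_free_traces_solve_the_forward_model(self):
        from vesselmech.fitting import objective
        ds, truth = generate_passive_dataset("GG+L(P21)", 168, "DTA",
                                             seed=1, config=NOISE_FREE)
        assert objective(truth.params, ds) < 1e-10


class TestActiveGeneration:
    def test_wild_type_constriction_over_20pct(self):
        # design property of the wild-type aorta at any seed
        for seed in range(5):
            traces = generate_active_traces("WT", 168, "DTA", seed=seed,
                                            specimen_id=f"wt{seed}")
            kcl = next(t for t in traces if t.stimulus == "KCl100mM")
            summ = constriction_metrics(kcl)
            assert summ.percent_constriction > 20.0

    def test_perimorbid_progeria_has_lost_contractility(self):
        traces = generate_active_traces("GG", 168, "DTA", seed=0)
        kcl = next(t for t in traces if t.stimulus == "KCl100mM")
        summ = constriction_metrics(kcl)
        assert summ.percent_constriction < 2.0
        assert "no_response" in summ.flags

    def test_isobaric_pressures_match_vessel(self):
        dta = generate_active_traces("WT", 168, "DTA", seed=0)
        ma = generate_active_traces("WT", 168, "MA", seed=0)
        assert all(t.fixed_pressure == 90.0 for t in dta)
        assert all(t.fixed_pressure == 60.0 for t in ma)


class TestEchoGeneration:
    @pytest.mark.parametrize("group", ["WT", "GG", "GG+L(P21)"])
    def test_cohort_means_near_targets(self, group):
        animals = generate_echo_records(group, seed=0, n_animals=6)
        summaries = [summarize_echo(reps) for reps in animals]
        e_ep = np.mean([s.E_over_eprime for s in summaries])
        target = ECHO_GROUPS[group].E_over_eprime
        assert e_ep == pytest.approx(target, rel=0.08)
        ef = np.mean([s.EF_pct for s in summaries])
        assert ef == pytest.approx(ECHO_GROUPS[group].EF, rel=0.05)

    def test_determinism(self):
        a = generate_echo_records("WT", seed=3, n_animals=2)
        b = generate_echo_records("WT", seed=3, n_animals=2)
        assert a == b


class TestHistologyGeneration:
    def test_painted_fraction_matches_request_closely(self):
        img, truth = generate_histology_image({"proteoglycan": 0.480,
                                               "elastin": 0.2,
                                               "cytoplasm": 0.1,
                                               "collagen": 0.05}, seed=1)
        assert truth["media_fractions"]["proteoglycan"] == \
            pytest.approx(0.480, abs=0.005)

    def test_zero_fraction_paints_no_pixels(self):
        img, truth = generate_histology_image({"elastin": 0.5,
                                               "cytoplasm": 0.0,
                                               "proteoglycan": 0.3,
                                               "collagen": 0.1}, seed=1)
        assert truth["media_fractions"]["cytoplasm"] == 0.0

    def test_same_seed_identical_image(self):
        img1, _ = generate_histology_image({"elastin": 0.4}, seed=9)
        img2, _ = generate_histology_image({"elastin": 0.4}, seed=9)
        np.testing.assert_array_equal(img1, img2)

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ValueError, match="<= 1"):
            generate_histology_image({"elastin": 0.7, "cytoplasm": 0.5},
                                     seed=0)


class TestSurvivalConditions:
    def test_untreated_progeria_counts(self):
        gg = SURVIVAL["GG"]
        deaths = np.asarray(gg["death_days"])
        assert gg["n_total"] == 19
        assert gg["n_total"] - (deaths <= 168).sum() == 10
        assert gg["n_total"] - (deaths <= 169).sum() == 7

    def test_lonafarnib_arms_combined(self):
        l21, l100 = SURVIVAL["GG+L(P21)"], SURVIVAL["GG+L(P100)"]
        n = l21["n_total"] + l100["n_total"]
        d = np.asarray(l21["death_days"] + l100["death_days"], dtype=float)
        assert n == 10
        assert n - (d <= 168).sum() == 10
        assert n - (d <= 169).sum() == 9
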
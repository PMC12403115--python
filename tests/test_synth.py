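"""Synthetic woodland generator: determinism, invariants, validation."""

import numpy as np
import pandas as pd
import pytest

from phenometrics import (SpeciesConfig, WoodlandConfig, default_config,
                          generate_woodland)


def noiseless_config(**kw):
    base = dict(
        rng_seed=1,
        species=[SpeciesConfig("oak", 6, 112.0, 7, 30.0)],
        within_species_sd=3.0, rate_sd=0.0, cross_trophic_sd=0.0,
        bud_section_sd=1e-9, observer_sd=0.0, lai_noise_sd=0.0,
        ndvi_noise_sd=0.0, frass_noise_sd=0.0, outlier_prob=0.0,
        missed_visit_prob=0.0, visit_interval=1.0, abundance_cv=0.0,
    )
    base.update(kw)
    return default_config(**base)


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = default_config(rng_seed=42,
                             species=[SpeciesConfig("oak", 5, 112.0, 7, 30.0)])
        t1, o1, tr1 = generate_woodland(cfg)
        t2, o2, tr2 = generate_woodland(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(o1, o2)
        pd.testing.assert_frame_equal(tr1.per_tree, tr2.per_tree)

    def test_different_seeds_differ(self):
        base = dict(species=[SpeciesConfig("oak", 5, 112.0, 7, 30.0)])
        _, o1, _ = generate_woodland(default_config(rng_seed=1, **base))
        _, o2, _ = generate_woodland(default_config(rng_seed=2, **base))
        assert not o1["value"].equals(o2["value"])


class TestStreamInvariants:
    def test_bud_scores_bounded_and_trending_up(self, small_woodland):
        trees, obs, _ = small_woodland
        bud = obs[obs.method == "bud_score"]
        assert bud.value.between(1, 7).all()
        # expectation increases over time: early-season mean < late-season mean
        for tid, sub in bud.groupby("tree_id"):
            sub = sub.sort_values("day")
            third = len(sub) // 3
            assert sub.value.iloc[:third].mean() <= sub.value.iloc[-third:].mean()

    def test_counts_nonnegative_integers(self, small_woodland):
        _, obs, _ = small_woodland
        counts = obs[obs.method.isin(["count_total", "count_fwm"])].value
        assert (counts >= 0).all()
        assert np.allclose(counts, np.round(counts))

    def test_fwm_subset_of_total(self, small_woodland):
        _, obs, _ = small_woodland
        tot = obs[obs.method == "count_total"].set_index(["tree_id", "day"]).value
        fwm = obs[obs.method == "count_fwm"].set_index(["tree_id", "day"]).value
        assert (fwm <= tot.loc[fwm.index]).all()

    def test_frass_nonnegative(self, small_woodland):
        _, obs, _ = small_woodland
        assert (obs[obs.method == "frass_mass_g"].value >= 0).all()

    def test_herbivory_fractions_open_interval(self, small_woodland):
        trees, _, truth = small_woodland
        assert trees.herbivory.between(0, 1).all()
        assert truth.per_tree.herbivory_mean.between(0, 1, inclusive="neither").all()

    def test_timing_spread_monotone_in_within_species_sd(self):
        spreads = []
        for sd in (1.0, 4.0, 8.0):
            cfg = default_config(
                rng_seed=5, within_species_sd=sd,
                species=[SpeciesConfig("oak", 40, 112.0, 7, 30.0)],
            )
            _, _, truth = generate_woodland(cfg)
            spreads.append(truth.per_tree.half_date.var())
        assert spreads[0] < spreads[1] < spreads[2]

    def test_frass_precedes_counts_in_truth(self, small_woodland):
        _, _, truth = small_woodland
        tt = truth.per_tree
        assert (tt.frass_peak_day < tt.cat_peak_day).all()
        assert (tt.fwm_peak_day >= tt.cat_peak_day).all()  # thinned peak later


class TestNoiselessLimit:
    def test_half_dates_recoverable_from_noiseless_streams(self):
        from phenometrics.pipeline import compute_half_dates

        trees, obs, truth = generate_woodland(noiseless_config())
        hd = compute_half_dates(obs, trees, methods=("bud_score", "ndvi"),
                                ensemble_size=0, seed=0)
        m = hd[hd.flag == "ok"].merge(truth.per_tree, on="tree_id")
        bud = m[m.metric == "budburst"]
        ndvi = m[m.metric == "half_ndvi"]
        assert len(bud) and len(ndvi)
        assert np.max(np.abs(bud.half_day - bud.half_date)) < 0.6
        assert np.max(np.abs(ndvi.half_day - ndvi.ndvi_half_date)) < 0.2


class TestNullLinkage:
    def test_b_zero_pipeline_slope_interval_covers_zero(self):
        # with no tree->caterpillar linkage the full pipeline should find none
        from phenometrics import fit_cross_trophic_model
        from phenometrics.pipeline import compute_half_dates, metrics_wide

        hits = 0
        for rep in range(20):
            cfg = default_config(
                rng_seed=7000 + rep, cross_trophic_slope=0.0,
                cross_trophic_intercept=150.0,
                species=[SpeciesConfig("oak", 25, 112.0, 7, 30.0)],
            )
            trees, obs, _ = generate_woodland(cfg)
            hd = compute_half_dates(obs, trees, methods=("ndvi", "count_total"),
                                    ensemble_size=0, seed=rep)
            wide = metrics_wide(hd, None, trees)
            res = fit_cross_trophic_model(
                wide, "tc_half_fall", "half_ndvi", area_reference="Great Wood",
                n_boot=300, random_state=rep)
            row = res.coef.set_index("term").loc["half_ndvi"]
            hits += row["ci_low"] <= 0.0 <= row["ci_high"]
        assert hits >= 18  # 95% nominal intervals over 20 replicates


class TestValidation:
    def test_zero_trees_rejected(self):
        cfg = default_config(species=[SpeciesConfig("oak", 0, 112.0, 7, 30.0)])
        with pytest.raises(ValueError, match="at least one tree"):
            generate_woodland(cfg)

    def test_non_finite_parameter_rejected(self):
        cfg = default_config(cross_trophic_slope=np.nan)
        with pytest.raises(ValueError, match="cross_trophic_slope"):
            generate_woodland(cfg)

    def test_negative_sd_rejected(self):
        cfg = default_config(within_species_sd=-1.0)
        with pytest.raises(ValueError, match="within_species_sd"):
            generate_woodland(cfg)

    def test_bad_probability_rejected(self):
        cfg = default_config(missed_visit_prob=1.5)
        with pytest.raises(ValueError, match="missed_visit_prob"):
            generate_woodland(cfg)

    def test_bad_max_stage_rejected(self):
        with pytest.raises(ValueError, match="max_stage"):
            default_config(species=[SpeciesConfig("oak", 5, 112.0, 6, 30.0)]).validate()

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = default_config(rng_seed=9, within_species_sd=4.5)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = WoodlandConfig.from_yaml(path)
        assert back == cfg
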
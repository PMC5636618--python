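"""Synthetic-data generator: determinism, calibration and degenerate configs."""

import copy

import numpy as np
import pandas as pd
import pytest

from mibgdose.synth import (
    SynthConfig,
    gen_biodistribution,
    gen_dce,
    gen_growth_cohort,
    write_dataset,
)
from tests.conftest import dce_session_summaries


class TestDeterminism:
    def test_biodistribution_reproducible(self, config):
        assert gen_biodistribution(config, 5).equals(gen_biodistribution(config, 5))

    def test_growth_reproducible(self, config):
        v1, s1 = gen_growth_cohort(config, 5)
        v2, s2 = gen_growth_cohort(config, 5)
        assert v1.equals(v2) and s1.equals(s2)

    def test_csv_bytes_identical(self, config, tmp_path):
        p1 = write_dataset(config, 9, tmp_path / "a")
        p2 = write_dataset(config, 9, tmp_path / "b")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()

    def test_different_seeds_differ(self, config):
        assert not gen_biodistribution(config, 1).equals(gen_biodistribution(config, 2))


class TestBiodistribution:
    def test_zero_sd_gives_group_means(self, config):
        cfg = copy.deepcopy(config)
        for g in cfg.biodistribution["groups"].values():
            g["sds"] = [0.0] * 5
        df = gen_biodistribution(cfg, 1)
        m = df[(df.group == "mrt") & (df.time_h == 24.0)].pct_id_per_g
        assert np.allclose(m, 3.57)

    def test_sample_sizes_match_design(self, config):
        df = gen_biodistribution(config, 1)
        counts = df.groupby(["group", "time_h"]).size()
        assert counts[("ebrt_mrt", 24.0)] == 3
        assert counts[("mrt", 72.0)] == 2

    def test_values_nonnegative(self, config):
        df = gen_biodistribution(config, 3)
        assert (df.pct_id_per_g >= 0).all()

    def test_mean_calibrated_to_target_over_seeds(self, config):
        # 24 h EBRT+MRT target 10.47 +/- 1.86; mean over 300 seeds within 3 SE
        vals = []
        for seed in range(300):
            df = gen_biodistribution(config, seed)
            vals.extend(df[(df.group == "ebrt_mrt") & (df.time_h == 24.0)].pct_id_per_g)
        se = 1.86 / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 10.47) < 3 * se

    def test_law_of_large_numbers(self, config):
        cfg = copy.deepcopy(config)
        cfg.biodistribution["n_per_time"] = [4000] * 5
        df = gen_biodistribution(cfg, 2)
        sub = df[(df.group == "ebrt_mrt") & (df.time_h == 24.0)].pct_id_per_g
        assert sub.mean() == pytest.approx(10.47, abs=0.15)
        assert sub.std(ddof=1) == pytest.approx(1.86, rel=0.06)


class TestGrowthCohort:
    def test_group_sizes(self, config):
        _, surv = gen_growth_cohort(config, 1)
        sizes = surv.groupby("group").size().to_dict()
        assert sizes == {"control": 3, "ebrt": 5, "mrt": 6, "ebrt_mrt": 5, "mrt_ebrt": 6}

    def test_full_kill_no_regrowth_all_censored(self, config):
        cfg = copy.deepcopy(config)
        for g in cfg.growth["groups"].values():
            g["cure_prob"] = 1.0
            g["surviving_fraction"] = 0.01
            g["sf_dispersion"] = 0.0
        _, surv = gen_growth_cohort(cfg, 4)
        assert (surv.event == 0).all()
        assert (surv.time_days == cfg.censor_day).all()

    def test_controls_reach_endpoint_by_day7(self, config):
        hits = 0
        for seed in range(200):
            _, surv = gen_growth_cohort(config, seed)
            ctrl = surv[surv.group == "control"]
            hits += int((ctrl.event == 1).all() and (ctrl.time_days <= 7.0).all())
        assert hits / 200 >= 0.95

    def test_ebrt_day6_regression_calibrated(self, config):
        # mean day-6 percent change target -65.00 over many seeds
        changes = []
        for seed in range(300):
            vol, _ = gen_growth_cohort(config, seed)
            sub = vol[vol.group == "ebrt"].pivot(index="animal_id", columns="day", values="volume_mm3")
            changes.extend(100.0 * (sub[6.0] / sub[0.0] - 1.0))
        se = 16.67 / np.sqrt(len(changes))
        assert abs(np.mean(changes) - (-65.0)) < 3 * se

    def test_volumes_stop_at_endpoint(self, config):
        vol, surv = gen_growth_cohort(config, 7)
        for _, row in surv[surv.event == 1].iterrows():
            days = vol[vol.animal_id == row.animal_id].day
            assert days.max() == row.time_days


class TestDCE:
    def test_noise_free_sessions_identical_without_effect(self, config):
        cfg = copy.deepcopy(config)
        cfg.dce["noise_sigma"] = 0.0
        cfg.dce["animal_amplitude_sigma"] = 0.0
        for r in cfg.dce["regions"].values():
            r["session_jitter_sigma"] = 0.0
            r["multipliers"] = [1.0, 1.0, 1.0]
        df = gen_dce(cfg, 1)
        summ = dce_session_summaries(df, cfg.dce["injection_index"])
        vals = {k[2]: v for k, v in summ.items() if k[0] == "mouse_0" and k[1] == "tumour"}
        assert len(set(np.round(list(vals.values()), 12))) == 1

    def test_muscle_stable_across_sessions(self, config):
        df = gen_dce(config, 2)
        summ = dce_session_summaries(df, config.dce["injection_index"])
        per_session = {}
        for (aid, region, session), v in summ.items():
            if region == "muscle":
                per_session.setdefault(session, []).append(v)
        means = {s: np.mean(v) for s, v in per_session.items()}
        assert max(means.values()) - min(means.values()) < 0.02

    def test_tumour_enhancement_elevated_at_24h(self, config):
        df = gen_dce(config, 3)
        summ = dce_session_summaries(df, config.dce["injection_index"])
        base = [v for k, v in summ.items() if k[1] == "tumour" and k[2] == "baseline"]
        h24 = [v for k, v in summ.items() if k[1] == "tumour" and k[2] == "24h"]
        assert np.mean(h24) > 1.5 * np.mean(base)


class TestConfig:
    def test_yaml_round_trip(self, config, tmp_path):
        p = tmp_path / "synth.yaml"
        config.to_yaml(p)
        cfg2 = SynthConfig.from_yaml(p)
        assert cfg2.growth == config.growth
        assert gen_biodistribution(cfg2, 3).equals(gen_biodistribution(config, 3))

    def test_invalid_endpoint_rejected(self, config):
        with pytest.raises(ValueError):
            SynthConfig(endpoint_volume_mm3=400.0)
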
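import dataclasses

import numpy as np
import pytest

from saplingcrown.io import read_branch_table, write_dataset
from saplingcrown.models import ProfileParams, eval_profile
from saplingcrown.synthetic import (GrowthConfig, StandConfig, StripStandConfig,
                                    generate_growth_series, generate_stand,
                                    stand_config_from_yaml, stand_config_to_yaml)

CUT = "shelterwood_cut"
UNCUT = "uncut"


def _small_config(seed=0, n_cut=8, n_uncut=6, **kw):
    base = StandConfig()
    strips = {
        CUT: dataclasses.replace(base.strips[CUT], n_saplings=n_cut),
        UNCUT: dataclasses.replace(base.strips[UNCUT], n_saplings=n_uncut),
    }
    return dataclasses.replace(base, strips=strips, seed=seed, **kw)


class TestGenerateStand:
    def test_empty_config(self):
        ds = generate_stand(_small_config(n_cut=0, n_uncut=0))
        assert ds.n_saplings() == 0 and ds.n_branches() == 0

    def test_counts_per_strip(self):
        ds = generate_stand(_small_config())
        assert ds.n_saplings(CUT) == 8 and ds.n_saplings(UNCUT) == 6
        assert ds.n_branches() > ds.n_saplings()

    def test_determinism_byte_identical_csv(self, tmp_path):
        for sub in ("a", "b"):
            write_dataset(generate_stand(_small_config(seed=42)), tmp_path / sub)
        for name in ("saplings.csv", "branches.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_envelope_never_exceeded(self, stand):
        cfg = StandConfig()
        for strip in (CUT, UNCUT):
            sub = stand.subset(strip)
            sap = sub.saplings.set_index("sapling_id")
            env = cfg.strips[strip].envelope
            for sid, grp in sub.branches.groupby("sapling_id"):
                cr = sap.loc[sid, "cl_m"] / sap.loc[sid, "ht_m"]
                r_env = np.asarray(eval_profile(env, dbh=sap.loc[sid, "dbh_cm"],
                                                cr=cr,
                                                rdinc=grp["rdinc"].to_numpy()))
                assert np.all(grp["ocr_m"].to_numpy() <= r_env + 1e-9)

    def test_geometry_round_trips_through_csv(self, tmp_path):
        ds = generate_stand(_small_config(seed=3))
        write_dataset(ds, tmp_path)
        back = read_branch_table(tmp_path)
        np.testing.assert_allclose(back.branches["rdinc"], ds.branches["rdinc"],
                                   atol=1e-9)
        np.testing.assert_allclose(back.branches["ocr_m"], ds.branches["ocr_m"],
                                   atol=1e-9)

    def test_sampling_criteria_respected(self):
        ds = generate_stand(_small_config(n_cut=200, n_uncut=0, seed=1))
        assert (ds.saplings["ht_m"] > 1.3).all()
        assert ds.saplings["dbh_cm"].between(0.5, 5.0).all()
        assert (ds.saplings["cl_m"] <= ds.saplings["ht_m"] + 1e-12).all()
        assert ds.branches["rdinc"].between(0, 1).all()

    def test_moment_recovery_at_large_n(self):
        cfg = _small_config(n_cut=500, n_uncut=0, seed=9)
        sc = cfg.strips[CUT]
        ds = generate_stand(cfg)
        se = sc.dbh_sd / np.sqrt(500)
        # truncation to (0.5, 5) trims both tails roughly symmetrically here
        assert abs(ds.saplings["dbh_cm"].mean() - sc.dbh_mean) < 3 * se + 0.05
        assert abs(ds.saplings["ht_m"].mean() - sc.ht_mean) < 3 * sc.ht_sd / np.sqrt(500) + 0.05
        assert abs(ds.branches["va_deg"].mean() - sc.va_mean) < 3.0

    def test_degenerate_noise_hits_envelope(self):
        # alpha -> infinity limit approximated by a huge alpha: u ~= 1
        cfg = _small_config(seed=2, noise_alpha=5e6, noise_beta=1e-6)
        ds = generate_stand(cfg)
        sap = ds.saplings.set_index("sapling_id")
        for strip in (CUT, UNCUT):
            env = cfg.strips[strip].envelope
            sub = ds.subset(strip)
            for sid, grp in sub.branches.groupby("sapling_id"):
                cr = sap.loc[sid, "cl_m"] / sap.loc[sid, "ht_m"]
                r_env = np.asarray(eval_profile(env, dbh=sap.loc[sid, "dbh_cm"],
                                                cr=cr,
                                                rdinc=grp["rdinc"].to_numpy()))
                np.testing.assert_allclose(grp["ocr_m"].to_numpy(), r_env,
                                           rtol=1e-4)

    def test_negative_envelope_rejected(self):
        bad = ProfileParams("power_exp_full", (-0.4, 0.5, 1.2, -0.5, -0.9))
        cfg = _small_config()
        strips = dict(cfg.strips)
        strips[CUT] = dataclasses.replace(strips[CUT], envelope=bad)
        with pytest.raises(ValueError):
            generate_stand(dataclasses.replace(cfg, strips=strips))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            _small_config(noise_alpha=0.0)
        with pytest.raises(ValueError):
            StripStandConfig(5, 2.0, -1.0, 2.4, 0.5, 0.8, 0.1, 60, 10,
                             StandConfig().strips[CUT].envelope)


class TestGrowthSeries:
    def test_zero_sd_gives_exact_strip_year_means(self):
        ds = generate_stand(_small_config(seed=4))
        cfg = GrowthConfig(rate_sd=0.0, seed=0)
        out = generate_growth_series(ds, cfg)
        sap = out.saplings.set_index("sapling_id")["strip_type"]
        for y, (mc, mu) in cfg.post_treatment_rates.items():
            col = out.branches[f"year_{y}"].dropna()
            strips = out.branches.loc[col.index, "sapling_id"].map(sap)
            assert (col[strips == CUT] == mc).all()
            assert (col[strips == UNCUT] == mu).all()
        pre = out.branches["year_2013"].dropna()
        assert (pre == cfg.pre_treatment_rate_mean).all()

    def test_pre_treatment_means_equal_within_sampling_error(self):
        ds = generate_stand(_small_config(n_cut=200, n_uncut=200, seed=6))
        cfg = GrowthConfig(seed=1)
        out = generate_growth_series(ds, cfg)
        sap = out.saplings.set_index("sapling_id")["strip_type"]
        col = out.branches["year_2013"].dropna()
        strips = out.branches.loc[col.index, "sapling_id"].map(sap)
        a, b = col[strips == CUT], col[strips == UNCUT]
        se = cfg.rate_sd * np.sqrt(1 / len(a) + 1 / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_one_sampled_branch_per_sapling(self):
        ds = generate_stand(_small_config(seed=7))
        out = generate_growth_series(ds, GrowthConfig(seed=2))
        per_sapling = out.branches.groupby("sapling_id")["year_2014"].count()
        assert (per_sapling == 1).all()

    def test_seeded_reruns_identical(self):
        ds = generate_stand(_small_config(seed=8))
        a = generate_growth_series(ds, GrowthConfig(seed=5)).branches
        b = generate_growth_series(ds, GrowthConfig(seed=5)).branches
        import pandas as pd
        pd.testing.assert_frame_equal(a, b)

    def test_nonconsecutive_years_rejected(self):
        with pytest.raises(ValueError):
            GrowthConfig(years=(2013, 2015))

    def test_requires_both_strips(self):
        ds = generate_stand(_small_config(n_uncut=0))
        with pytest.raises(ValueError):
            generate_growth_series(ds, GrowthConfig())


def test_yaml_config_round_trip(tmp_path):
    cfg = _small_config(seed=21)
    stand_config_to_yaml(cfg, tmp_path / "stand.yaml")
    back = stand_config_from_yaml(tmp_path / "stand.yaml")
    assert back == cfg
    reseeded = stand_config_from_yaml(tmp_path / "stand.yaml", seed=99)
    assert reseeded.seed == 99
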
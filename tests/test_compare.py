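import dataclasses
import json

import numpy as np
import pytest

from saplingcrown.compare import (annual_growth_compare, crown_metrics_table,
                                  render_report, welch_p_value)
from saplingcrown.synthetic import GrowthConfig, StandConfig, generate_growth_series, generate_stand

from conftest import CUT_SELECTED, UNCUT_SELECTED

CUT = "shelterwood_cut"
UNCUT = "uncut"
SELECTED = {CUT: CUT_SELECTED, UNCUT: UNCUT_SELECTED}


class TestCrownMetricsTable:
    def test_equal_params_zero_differences(self):
        tab = crown_metrics_table({CUT: CUT_SELECTED, UNCUT: CUT_SELECTED},
                                  dbh_grid=[1.0, 2.0, 3.0])
        assert np.allclose(tab[["d_largest_radius", "d_inflection", "d_volume"]], 0)

    def test_published_directional_contrasts(self):
        tab = crown_metrics_table(SELECTED, cr=0.80)
        # shade-grown (uncut) saplings hold the larger maximal radius ...
        assert (tab["d_largest_radius"] > 0).all()
        # ... while the released (cut) saplings peak deeper into the crown
        assert (tab["d_inflection"] < 0).all()

    def test_volume_contrast_shrinks_with_size(self):
        tab = crown_metrics_table(SELECTED, dbh_grid=[1.0, 3.0], cr=0.80)
        rel = tab.set_index("dbh_cm")["d_volume_rel"]
        assert abs(rel[3.0]) < abs(rel[1.0])

    def test_antisymmetric_under_label_swap(self):
        tab = crown_metrics_table(SELECTED, dbh_grid=[2.0])
        swapped = crown_metrics_table({CUT: UNCUT_SELECTED, UNCUT: CUT_SELECTED},
                                      dbh_grid=[2.0])
        assert tab["d_volume"].iloc[0] == pytest.approx(
            -swapped["d_volume"].iloc[0], rel=1e-12)

    def test_missing_strip_rejected(self):
        with pytest.raises(ValueError):
            crown_metrics_table({CUT: CUT_SELECTED})


def _growth_dataset(seed=0, n=10, rate_sd=2.5, growth_cfg=None):
    base = StandConfig()
    strips = {s: dataclasses.replace(c, n_saplings=n)
              for s, c in base.strips.items()}
    ds = generate_stand(dataclasses.replace(base, strips=strips, seed=seed))
    cfg = growth_cfg or GrowthConfig(rate_sd=rate_sd, seed=seed + 1)
    return generate_growth_series(ds, cfg)


class TestAnnualGrowthCompare:
    def test_identical_samples_not_significant(self):
        ds = _growth_dataset(rate_sd=0.0)
        out = annual_growth_compare(ds, years=[2013])
        assert np.allclose(out["p_value"], 1.0)
        means = out.set_index("strip_type")["mean_increment_cm"]
        assert means[CUT] == pytest.approx(means[UNCUT])

    def test_separated_means_strongly_significant(self):
        a = np.random.default_rng(0).normal(10, 0.1, 30)
        b = np.random.default_rng(1).normal(20, 0.1, 30)
        assert welch_p_value(a, b) < 1e-10

    def test_welch_matches_permutation_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 2, 20)
        b = rng.normal(11, 2, 20)
        p_welch = welch_p_value(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            count += abs(pooled[:20].mean() - pooled[20:].mean()) >= obs
        p_perm = count / n_perm
        assert p_welch == pytest.approx(p_perm, abs=0.03)

    def test_power_under_default_trajectory(self):
        # pre-treatment year should be non-significant and the final years
        # significant in at least 90% of seeded replicates
        hits_pre, hits_post, reps = 0, 0, 20
        for rep in range(reps):
            ds = _growth_dataset(seed=100 + rep, n=30)
            out = annual_growth_compare(ds)
            p = out.drop_duplicates("year").set_index("year")["p_value"]
            hits_pre += p[2013] > 0.05
            hits_post += (p[2016] < 0.05) and (p[2017] < 0.05)
        assert hits_pre >= 0.9 * reps
        assert hits_post >= 0.9 * reps

    def test_small_strip_flagged_untested(self):
        ds = _growth_dataset(n=10)
        # drop all but one uncut sapling's growth record for 2014
        sap = ds.saplings.set_index("sapling_id")["strip_type"]
        uncut_rows = ds.branches["sapling_id"].map(sap) == UNCUT
        has_growth = ds.branches["year_2014"].notna()
        idx = ds.branches.index[uncut_rows & has_growth][1:]
        ds.branches.loc[idx, [c for c in ds.branches if c.startswith("year_")]] = np.nan
        out = annual_growth_compare(ds, years=[2014])
        assert not out["tested"].any()

    def test_holm_column_present_and_valid(self):
        out = annual_growth_compare(_growth_dataset(n=15))
        assert ((out["p_holm"] >= out["p_value"] - 1e-12) |
                out["p_holm"].isna()).all()


class TestRenderReport:
    def test_full_report_sections(self, tmp_path):
        metrics = crown_metrics_table(SELECTED, dbh_grid=[1.0, 2.0])
        growth = annual_growth_compare(_growth_dataset())
        written = render_report(tmp_path, metrics=metrics, growth=growth,
                                selection={"note": "toy"}, params={"p": 1},
                                metadata={"seed": 0})
        for f in ("metrics.csv", "growth.csv", "selection.json", "params.json",
                  "run.log"):
            assert (tmp_path / f).exists()
        log = json.loads((tmp_path / "run.log").read_text())
        assert log["sections_absent"] == []

    def test_missing_growth_marked_absent(self, tmp_path):
        metrics = crown_metrics_table(SELECTED, dbh_grid=[1.0])
        render_report(tmp_path, metrics=metrics, growth=None,
                      selection=None, params=None, figures=False)
        log = json.loads((tmp_path / "run.log").read_text())
        assert "growth" in log["sections_absent"]

    def test_deterministic_csv_payloads(self, tmp_path):
        metrics = crown_metrics_table(SELECTED, dbh_grid=[1.0, 2.0])
        render_report(tmp_path / "a", metrics=metrics, figures=False)
        render_report(tmp_path / "b", metrics=metrics, figures=False)
        assert (tmp_path / "a" / "metrics.csv").read_bytes() == \
            (tmp_path / "b" / "metrics.csv").read_bytes()
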
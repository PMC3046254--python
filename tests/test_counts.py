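"""Proliferation-count generator: determinism, calibration, planted effects."""

import numpy as np
import pandas as pd
import pytest

from jointmorph.counts import (
    CountSimParams,
    generate_proliferation_counts,
    pooled_proportions,
    read_counts_csv,
    write_counts_csv,
)


def test_same_seed_gives_identical_tables():
    p = CountSimParams(seed=99)
    a = generate_proliferation_counts(p)
    b = generate_proliferation_counts(p)
    pd.testing.assert_frame_equal(a, b)
    c = generate_proliferation_counts(CountSimParams(seed=100))
    assert not a.equals(c)


def test_null_generator_hits_its_baseline():
    p = CountSimParams(n_individuals=30, baseline=0.05, treatment_effect=0.0,
                       effect_scale="logodds", sd_individual=0.0, sd_section=0.0,
                       mean_n_total=1000, seed=2)
    df = generate_proliferation_counts(p)
    pooled = pooled_proportions(df)
    n_tot = df["n_total"].sum() / 2
    se = np.sqrt(0.05 * 0.95 / n_tot)
    for arm in ("control", "immobilised"):
        assert abs(pooled[arm] - 0.05) < 3 * se


def test_planted_per_1000_effect_reproduced_at_large_n():
    p = CountSimParams(n_individuals=200, baseline=0.05, treatment_effect=-15.0,
                       effect_scale="per1000", sd_individual=0.0, sd_section=0.0,
                       mean_n_total=1000, seed=3)
    pooled = pooled_proportions(generate_proliferation_counts(p))
    diff = 1000 * (pooled["immobilised"] - pooled["control"])
    assert diff == pytest.approx(-15.0, abs=2.0)


def test_design_matches_study_layout():
    df = generate_proliferation_counts(CountSimParams(seed=0))
    assert df["individual_id"].nunique() == 6          # three per arm
    one = df[df["individual_id"] == df["individual_id"].iloc[0]]
    assert one["section_id"].nunique() == 4            # 2 sections x 2 planes
    assert set(one["region"]) == {1, 2, 3, 4, 5}
    assert (df["n_pos"] <= df["n_total"]).all()


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        CountSimParams(baseline=1.2)
    with pytest.raises(ValueError):
        CountSimParams(sd_individual=-0.1)
    with pytest.raises(ValueError):
        CountSimParams(baseline=0.005, treatment_effect=-11.8,
                       effect_scale="per1000").effect_logodds()


def test_csv_roundtrip(tmp_path):
    df = generate_proliferation_counts(CountSimParams(seed=4))
    path = tmp_path / "counts.csv"
    write_counts_csv(df, path)
    back = read_counts_csv(path)
    pd.testing.assert_frame_equal(back, df)
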
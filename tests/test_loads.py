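"""Muscle load cases: group filtering, paralysis scaling, regime algebra."""

import numpy as np
import pytest

from jointmorph.loads import (
    LoadCase,
    MuscleSpec,
    build_load_case,
    default_muscle_table,
    load_vector,
    read_muscle_csv,
    write_muscle_csv,
)


def table():
    return [
        MuscleSpec("f1", "a1", (0.0, 1.0), 10.0, "flexor_set"),
        MuscleSpec("f2", "a2", (0.6, 0.8), 10.0, "flexor_set"),
        MuscleSpec("e1", "a3", (0.0, -1.0), 8.0, "extensor_set"),
    ]


def test_paralysis_totals_three_quarters_of_all_peaks():
    case = build_load_case(table(), "paralysis", paralysis_scale=0.75)
    assert case.total_magnitude() == pytest.approx(0.75 * 28.0)
    assert case.total_magnitude() == pytest.approx(21.0)
    assert case.temporal_tag == "constant"
    assert len(case.entries) == 3


def test_flexion_carries_only_flexors_at_full_magnitude():
    case = build_load_case(table(), "flexion")
    assert case.total_magnitude() == pytest.approx(20.0)
    assert case.temporal_tag == "ramped_cycle"
    assert {e.node_set for e in case.entries} == {"a1", "a2"}


def test_identity_scale_reproduces_all_normal_peaks():
    case = build_load_case(table(), "paralysis", paralysis_scale=1.0)
    assert case.total_magnitude() == pytest.approx(28.0)


def test_paralysis_vector_is_scaled_sum_of_contraction_vectors(rng):
    muscles = [MuscleSpec(f"m{i}", f"s{i}",
                          tuple(v / np.linalg.norm(v)), float(rng.uniform(1, 20)),
                          "flexor_set" if i % 2 else "extensor_set")
               for i, v in enumerate(rng.normal(size=(6, 2)))]
    flex = load_vector(build_load_case(muscles, "flexion"))
    ext = load_vector(build_load_case(muscles, "extension"))
    par = load_vector(build_load_case(muscles, "paralysis", 0.75))
    assert np.allclose(par, 0.75 * (flex + ext))


def test_unknown_regime_and_empty_group_rejected():
    with pytest.raises(ValueError):
        build_load_case(table(), "hopping")
    with pytest.raises(ValueError):
        build_load_case([m for m in table() if m.group == "flexor_set"], "extension")
    with pytest.raises(ValueError):
        MuscleSpec("bad", "a", (0.5, 0.5), 1.0, "flexor_set")  # not unit length


def test_muscle_table_csv_roundtrip(tmp_path):
    path = tmp_path / "muscles.csv"
    write_muscle_csv(default_muscle_table(), path)
    back = read_muscle_csv(path)
    assert back == default_muscle_table()
    assert isinstance(build_load_case(back, "extension"), LoadCase)
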
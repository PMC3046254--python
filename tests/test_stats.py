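"""Percent reductions and the two-group one-way ANOVA stage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from jointmorph.stats import oneway_anova, percent_reduction


def test_percent_reduction_closed_forms():
    assert percent_reduction(1.0, 0.5) == pytest.approx(50.0)
    assert percent_reduction(0.37, 0.37) == pytest.approx(0.0)
    # arithmetic on tabulated rounded means; raw-data tabulations may differ
    # in the last digits
    assert percent_reduction(0.29, 0.17) == pytest.approx(41.38, abs=0.01)
    with pytest.raises(ValueError):
        percent_reduction(0.0, 0.1)


def test_percent_reduction_scale_invariant():
    for c in (0.2, 3.0, 117.0):
        assert percent_reduction(c * 0.8, c * 0.5) == pytest.approx(percent_reduction(0.8, 0.5))


def test_anova_matches_brute_force_sums_of_squares(rng):
    a = rng.normal(1.0, 0.2, size=16)
    b = rng.normal(0.8, 0.2, size=17)
    F, d1, d2, p = oneway_anova(a, b)
    # independent oracle: explicit between/within SS decomposition
    grand = np.concatenate([a, b]).mean()
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    F_oracle = ss_between / 1 / (ss_within / (len(a) + len(b) - 2))
    assert F == pytest.approx(F_oracle, abs=1e-12 * max(F_oracle, 1))
    assert (d1, d2) == (1, 31)
    assert p == pytest.approx(sstats.f.sf(F_oracle, 1, 31), abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_anova_F_equals_squared_pooled_t(seed):
    r = np.random.default_rng(seed)
    a = r.normal(0, 1, size=int(r.integers(2, 20)))
    b = r.normal(0.3, 1, size=int(r.integers(2, 20)))
    F, _, _, _ = oneway_anova(a, b)
    t, _ = sstats.ttest_ind(a, b)
    assert F == pytest.approx(t ** 2, abs=1e-10 * max(abs(F), 1))


def test_identical_degenerate_groups_give_F_zero_p_one():
    F, _, _, p = oneway_anova([2.0, 2.0, 2.0], [2.0, 2.0])
    assert (F, p) == (0.0, 1.0)


def test_df_follows_sample_sizes():
    a, b = np.arange(16.0), np.arange(17.0) + 0.5
    _, d1, d2, _ = oneway_anova(a, b)
    assert (d1, d2) == (1, 31)
    with pytest.raises(ValueError):
        oneway_anova([1.0], [2.0, 3.0])
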
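"""Nested binomial mixed model: limits, recovery, independent oracle."""

import shutil
import subprocess

import numpy as np
import pytest

from jointmorph.counts import CountSimParams, generate_proliferation_counts
from jointmorph.glmm import GLMMError, fit_binomial_glmm


def test_zero_variance_limit_matches_plain_logistic_regression():
    p = CountSimParams(n_individuals=15, baseline=0.05, treatment_effect=-0.4,
                       effect_scale="logodds", sd_individual=0.0, sd_section=0.0,
                       mean_n_total=800, seed=21)
    df = generate_proliferation_counts(p)
    fit = fit_binomial_glmm(df)

    import statsmodels.api as sm
    y = df["n_pos"].to_numpy(float)
    n = df["n_total"].to_numpy(float)
    X = np.column_stack([np.ones(len(df)), (df["treatment"] == "immobilised").to_numpy(float)])
    glm = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
    assert fit.beta["treatment"] == pytest.approx(glm.params[1], abs=5e-3)
    assert fit.sd_individual < 0.05 and fit.sd_section < 0.05


def test_recovers_planted_log_odds_effect():
    p = CountSimParams(n_individuals=20, baseline=0.05, treatment_effect=-0.3,
                       effect_scale="logodds", sd_individual=0.15, sd_section=0.1,
                       mean_n_total=800, seed=42)
    fit = fit_binomial_glmm(generate_proliferation_counts(p))
    assert fit.effect_logodds == pytest.approx(-0.3, abs=3 * fit.se_logodds)
    assert fit.converged and not fit.separation
    # per-1000 conversion is consistent with the logistic link at baseline
    from scipy.special import expit, logit
    p0 = fit.baseline_proportion
    expect = 1000 * (expit(logit(p0) + fit.effect_logodds) - p0)
    assert fit.effect_per_1000 == pytest.approx(expect, abs=1e-9)


def test_single_individual_per_arm_is_inestimable():
    p = CountSimParams(n_individuals=1, seed=1)
    with pytest.raises(GLMMError):
        fit_binomial_glmm(generate_proliferation_counts(p))


def test_df_convention_matches_nested_design():
    fit = fit_binomial_glmm(generate_proliferation_counts(CountSimParams(seed=8)))
    assert fit.df == 4  # 3 + 3 individuals -> df = n_individuals - 2


def test_matches_lme4_glmer_laplace_fit(tmp_path):
    """Independent oracle: R lme4 glmer (Laplace) on the same nested table."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable: cannot run the lme4 oracle")
    p = CountSimParams(n_individuals=8, baseline=0.05, treatment_effect=-0.3,
                       effect_scale="logodds", sd_individual=0.2, sd_section=0.15,
                       mean_n_total=600, seed=3)
    df = generate_proliferation_counts(p)
    fit = fit_binomial_glmm(df)

    csv = tmp_path / "counts.csv"
    df.to_csv(csv, index=False)
    script = f"""
    suppressMessages(library(lme4))
    d <- read.csv("{csv}")
    d$treat <- as.integer(d$treatment == "immobilised")
    m <- glmer(cbind(n_pos, n_total - n_pos) ~ treat + (1 | individual_id / section_id),
               family = binomial, data = d)
    cat(fixef(m), as.data.frame(VarCorr(m))$sdcor, sqrt(diag(vcov(m))), sep = "\\n")
    """
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                         timeout=300)
    assert out.returncode == 0, out.stderr[-800:]
    vals = [float(v) for v in out.stdout.split()]
    intercept, treat, sd_sec, sd_ind, se_int, se_treat = vals
    assert fit.beta["intercept"] == pytest.approx(intercept, abs=1e-3)
    assert fit.beta["treatment"] == pytest.approx(treat, abs=1e-3)
    assert fit.sd_individual == pytest.approx(sd_ind, abs=5e-3)
    assert fit.sd_section == pytest.approx(sd_sec, abs=5e-3)
    assert fit.se_logodds == pytest.approx(se_treat, rel=0.1)
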
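"""Group-comparison statistics for the morphometric measurements.

Each measurement is compared between control and immobilised arms with a
percent reduction of the means and a two-group one-way ANOVA (df 1 and
n1+n2-2; F equals the squared pooled two-sample t).  Percent reductions are
recomputed from the supplied means; tabulated values elsewhere may differ in
the last digits when computed from unrounded raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass(frozen=True)
class GroupComparison:
    measurement: str
    day: int
    control_mean: float
    treated_mean: float
    percent_reduction: float
    F: float
    df_num: int
    df_den: int
    p_value: float


def percent_reduction(control_mean: float, treated_mean: float) -> float:
    """100 * (control - treated) / control; requires a positive control mean."""
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * (control_mean - treated_mean) / control_mean


def oneway_anova(control, treated) -> tuple[float, int, int, float]:
    """Two-group one-way ANOVA: (F, df_num, df_den, p).

    Degenerate groups (zero within-group variance, equal means) yield F = 0,
    p = 1 rather than NaN.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.size < 2 or treated.size < 2:
        raise ValueError("need at least two values per group")
    df_num = 1
    df_den = control.size + treated.size - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = sstats.f_oneway(control, treated)
    if not np.isfinite(F):
        scale = max(np.abs(control).max(), np.abs(treated).max(), 1.0)
        ss_within = ((control - control.mean()) ** 2).sum() + \
                    ((treated - treated.mean()) ** 2).sum()
        mean_gap = abs(control.mean() - treated.mean())
        if ss_within <= 1e-20 * scale ** 2 and mean_gap <= 1e-10 * scale:
            F, p = 0.0, 1.0
        else:
            raise ValueError("ANOVA undefined for the supplied groups")
    return float(F), df_num, df_den, float(p)


def compare_measurements(df: pd.DataFrame, day: int = 4) -> pd.DataFrame:
    """Per-measurement ANOVA table from a specimen-level measurement frame.

    ``df`` needs columns ``treatment`` plus one column per measurement id.
    """
    from .phantom import MEASUREMENT_IDS

    rows = []
    ctrl = df[df["treatment"] == "control"]
    immo = df[df["treatment"] == "immobilised"]
    for m in MEASUREMENT_IDS:
        c = ctrl[m].dropna().to_numpy()
        t = immo[m].dropna().to_numpy()
        F, d1, d2, p = oneway_anova(c, t)
        rows.append(GroupComparison(
            measurement=m, day=day,
            control_mean=float(c.mean()), treated_mean=float(t.mean()),
            percent_reduction=percent_reduction(float(c.mean()), float(t.mean())),
            F=F, df_num=d1, df_den=d2, p_value=p))
    return pd.DataFrame([r.__dict__ for r in rows])
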
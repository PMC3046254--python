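"""Synthetic chondrocyte proliferation counts with nested structure.

Counting boxes sit in five femoral regions (1: adjacent to the intercondylar
fossa; 2/3: dorsal/ventral medial condyle; 4/5: dorsal/ventral lateral
condyle).  Counts are generated per box from a binomial whose log-odds is

    baseline(region) + treatment_effect + b_individual + b_section

with Gaussian random intercepts for individual and for section nested within
individual, mirroring the design the fitted mixed model assumes: by default
three specimens per arm, each contributing two sections with two independent
focal planes (the planes share the section intercept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

REGIONS = (1, 2, 3, 4, 5)
REGION_NAMES = {
    1: "fossa_adjacent",
    2: "dorsal_medial",
    3: "ventral_medial",
    4: "dorsal_lateral",
    5: "ventral_lateral",
}
TABLE_COLUMNS = ("individual_id", "treatment", "section_id", "region",
                 "n_total", "n_pos")


@dataclass(frozen=True)
class CountSimParams:
    """Study-condition parameters of the count generator.

    The treatment effect may be given on the log-odds scale
    (``effect_scale="logodds"``) or as a difference in proliferating cells
    per 1000 (``effect_scale="per1000"``), converted to log-odds at the
    baseline proportion.  The defaults emulate the reported study: n = 3 per
    arm, two sections x two focal planes, ~1000 cells per 1.44 mm^2 box, a
    baseline of ~5% proliferating and an average reduction of 11.8/1000.
    """

    n_individuals: int = 3                   # per arm
    n_sections: int = 2
    n_planes: int = 2
    baseline: dict[int, float] | float = field(
        default_factory=lambda: {1: 0.045, 2: 0.05, 3: 0.05, 4: 0.05, 5: 0.05})
    treatment_effect: float = -11.8
    effect_scale: str = "per1000"
    sd_individual: float = 0.15              # log-odds scale
    sd_section: float = 0.10
    mean_n_total: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_sections < 1 or self.n_planes < 1:
            raise ValueError("design sizes must be >= 1")
        for p in self.baseline_map().values():
            if not 0.0 < p < 1.0:
                raise ValueError("baseline probabilities must be in (0, 1)")
        if self.sd_individual < 0 or self.sd_section < 0:
            raise ValueError("random-intercept SDs must be >= 0")
        if self.effect_scale not in ("logodds", "per1000"):
            raise ValueError("effect_scale must be 'logodds' or 'per1000'")
        if self.mean_n_total <= 0:
            raise ValueError("mean_n_total must be > 0")

    def baseline_map(self) -> dict[int, float]:
        if isinstance(self.baseline, dict):
            return dict(self.baseline)
        return {r: float(self.baseline) for r in REGIONS}

    def effect_logodds(self) -> float:
        """Planted treatment effect on the log-odds scale."""
        if self.effect_scale == "logodds":
            return float(self.treatment_effect)
        p0 = float(np.mean(list(self.baseline_map().values())))
        p1 = p0 + self.treatment_effect / 1000.0
        if not 0.0 < p1 < 1.0:
            raise ValueError("per-1000 effect pushes proportion outside (0, 1)")
        return float(logit(p1) - logit(p0))


def generate_proliferation_counts(params: CountSimParams) -> pd.DataFrame:
    """Simulate the nested count table; reproducible for a given seed."""
    rng = np.random.default_rng(params.seed)
    beta = params.effect_logodds()
    base = {r: math.log(p / (1 - p)) for r, p in params.baseline_map().items()}
    rows = []
    for arm, treat in (("control", 0), ("immobilised", 1)):
        for i in range(params.n_individuals):
            ind = f"{arm[:3]}{i + 1:03d}"
            b_ind = rng.normal(0.0, params.sd_individual)
            for s in range(params.n_sections):
                b_sec = rng.normal(0.0, params.sd_section)
                for plane in range(params.n_planes):
                    sec_id = f"s{s + 1}p{plane + 1}"
                    for r in REGIONS:
                        eta = base[r] + beta * treat + b_ind + b_sec
                        n_tot = int(rng.poisson(params.mean_n_total))
                        n_tot = max(n_tot, 1)
                        n_pos = int(rng.binomial(n_tot, expit(eta)))
                        rows.append((ind, arm, sec_id, r, n_tot, n_pos))
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    validate_counts(df)
    return df


def validate_counts(df: pd.DataFrame) -> None:
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if (df["n_pos"] < 0).any() or (df["n_pos"] > df["n_total"]).any():
        raise ValueError("require 0 <= n_pos <= n_total")
    if not set(df["region"]).issubset(set(REGIONS)):
        raise ValueError(f"region codes must be in {REGIONS}")
    # section ids must not be shared between individuals of the same id space
    dup = df.groupby(["individual_id", "section_id"]).size()
    _ = dup  # uniqueness within individual is by construction of the key


def pooled_proportions(df: pd.DataFrame) -> dict[str, float]:
    """Pooled proliferating proportion per treatment arm."""
    g = df.groupby("treatment")[["n_pos", "n_total"]].sum()
    return {arm: float(g.loc[arm, "n_pos"] / g.loc[arm, "n_total"])
            for arm in g.index}


def write_counts_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_counts_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_counts(df)
    return df
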
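"""Sample-size reasoning for the 2x2 crossover: the distribution of the
90% CI half-width for the log-scale treatment difference.

In a balanced two-period crossover with n subjects total, the two-sided
(1 - alpha) CI for the treatment difference on the natural-log scale has
half-width

    H = t(1 - alpha/2, df) * S * sqrt(2/n)

where S is the estimated within-subject SD of the log endpoint and
df = n - 2 the classical residual degrees of freedom. Since
df * S^2 / sigma_w^2 ~ chi-square(df), the half-width attained with
probability ``coverage`` is

    h = t(1 - alpha/2, df) * sigma_w * sqrt(2/n) * sqrt(q(coverage, df)/df)

with q the chi-square quantile. With n = 12, sigma_w = 0.10 and alpha = 0.10
this evaluates to ~0.0858, i.e. 80% probability that the 90% CI is no wider
than +-0.0858 on the log scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datamodel import ValidationError


@dataclass(frozen=True)
class DesignSpec:
    n_subjects: int  # total, balanced sequences
    sigma_within: float  # ln-scale within-subject SD
    alpha: float = 0.10  # two-sided level
    df: Optional[int] = None  # residual df; default n - 2

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValidationError("need at least 4 subjects (2 per sequence)")
        if self.sigma_within <= 0:
            raise ValidationError("sigma_within must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")

    @property
    def residual_df(self) -> int:
        return self.n_subjects - 2 if self.df is None else self.df

    @property
    def se_factor(self) -> float:
        """sqrt(2/n): SE of the treatment difference per unit within-SD."""
        return float(np.sqrt(2.0 / self.n_subjects))


def ci_halfwidth_at_coverage(design: DesignSpec, coverage: float) -> float:
    """Half-width h with P(CI half-width <= h) = ``coverage``."""
    if not 0 < coverage < 1:
        raise ValidationError("coverage must lie in (0, 1)")
    df = design.residual_df
    t_crit = stats.t.ppf(1.0 - design.alpha / 2.0, df)
    chi_q = stats.chi2.ppf(coverage, df)
    return float(
        t_crit * design.sigma_within * design.se_factor * np.sqrt(chi_q / df)
    )


def coverage_of_halfwidth(design: DesignSpec, halfwidth: float) -> float:
    """Exact inverse of :func:`ci_halfwidth_at_coverage`."""
    if halfwidth <= 0:
        raise ValidationError("halfwidth must be > 0")
    df = design.residual_df
    t_crit = stats.t.ppf(1.0 - design.alpha / 2.0, df)
    x = df * (halfwidth / (t_crit * design.sigma_within * design.se_factor)) ** 2
    return float(stats.chi2.cdf(x, df))


def simulate_halfwidth_coverage(
    design: DesignSpec,
    halfwidth: float,
    n_draws: int = 50_000,
    seed: Optional[int] = None,
) -> float:
    """Monte-Carlo P(half-width <= halfwidth) over chi-square draws of S."""
    rng = np.random.default_rng(seed)
    df = design.residual_df
    s = design.sigma_within * np.sqrt(rng.chisquare(df, size=n_draws) / df)
    t_crit = stats.t.ppf(1.0 - design.alpha / 2.0, df)
    h = t_crit * s * design.se_factor
    return float(np.mean(h <= halfwidth))


def design_table(
    n_grid: Sequence[int],
    sigma_within: float,
    alpha: float = 0.10,
    coverage: float = 0.80,
):
    """Half-width-at-coverage over a grid of total sample sizes."""
    import pandas as pd

    rows = []
    for n in n_grid:
        d = DesignSpec(n_subjects=n, sigma_within=sigma_within, alpha=alpha)
        rows.append(dict(
            n_subjects=n, df=d.residual_df, sigma_within=sigma_within,
            alpha=alpha, coverage=coverage,
            ci_halfwidth_ln=ci_halfwidth_at_coverage(d, coverage),
        ))
    return pd.DataFrame(rows)
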
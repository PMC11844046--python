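"""Chi-square / Bonferroni / Cramér's V companion analysis.

For each reference-vs-scoring pair the counts form a k x 2 contingency
table; the Pearson statistic (no continuity correction) is tested against
the chi-square distribution with k-1 degrees of freedom. Family-wise error
over the m pairwise comparisons of one variable is controlled by Bonferroni
division of each nominal level, and the practical size of a significant
difference is summarised by Cramér's V = sqrt(chi2 / (N * min(r-1, c-1))),
which for two samples reduces to sqrt(chi2 / N). With registry-scale N the
tests flag nearly everything while V stays tiny — the overpowering contrast
this package exists to quantify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .count_table import CategoryCountVector, CountTableError, align_categories
from .psi import DEFAULT_POLICY, InterpretationPolicy

EffectBand = Literal["small", "moderate", "large"]

#: Nominal family-wise levels, most to least permissive (1 to 3 stars).
DEFAULT_ALPHA_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class ChiSqResult:
    """Pearson chi-square outcome for one sample pair, with effect size."""

    variable_name: str
    reference_id: str
    scoring_id: str
    statistic: float
    df: int
    n_total: int
    p_raw: float
    m: int
    alpha_levels: tuple[float, ...]
    significance_stars: int
    cramers_v: float
    effect_band: EffectBand

    @property
    def stars(self) -> str:
        return "*" * self.significance_stars

    def p_display(self) -> str:
        """Raw p for reports; values underflowing float range print as a bound."""
        if self.p_raw < 1e-300:
            return "<1e-300"
        return f"{self.p_raw:.3g}"


def bonferroni(
    alpha_levels: Sequence[float] = DEFAULT_ALPHA_LEVELS, m: int = 1
) -> list[tuple[float, str]]:
    """Per-test thresholds level/m, with a display form.

    Comparisons always use the full-precision threshold; the display form
    truncates toward zero at two significant digits (the style of figure
    notes such as 0.01/21 -> "0.00047").
    """
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    out = []
    for level in alpha_levels:
        if not 0 < level < 1:
            raise ValueError(f"alpha level must be in (0,1), got {level}")
        t = level / m
        out.append((t, _truncate_2sig(t)))
    return out


def _truncate_2sig(x: float) -> str:
    """Truncate x toward zero at 2 significant digits, plain decimal form."""
    if x <= 0:
        return "0"
    exponent = math.floor(math.log10(x))
    factor = 10.0 ** (exponent - 1)
    truncated = math.floor(x / factor) * factor
    decimals = max(0, 1 - exponent)
    return f"{truncated:.{decimals}f}"


def count_stars(p_raw: float, m: int, alpha_levels: Sequence[float]) -> int:
    """Stars earned by p_raw against the Bonferroni-adjusted levels.

    One star per level passed (p_raw strictly below level/m), so a smaller
    p never earns fewer stars than a larger one.
    """
    return sum(p_raw < level / m for level in alpha_levels)


def cramers_v(
    statistic: float,
    n_total: int,
    r: int,
    c: int = 2,
    policy: InterpretationPolicy = DEFAULT_POLICY,
) -> tuple[float, EffectBand]:
    """Cramér's V (no bias correction) and its effect-size band."""
    if statistic < 0:
        raise ValueError("chi-square statistic cannot be negative")
    if n_total < 1 or r < 2 or c < 2:
        raise ValueError(f"degenerate table: N={n_total}, r={r}, c={c}")
    v = math.sqrt(statistic / (n_total * min(r - 1, c - 1)))
    if v <= policy.v_small_max:
        band: EffectBand = "small"
    elif v <= policy.v_moderate_max:
        band = "moderate"
    else:
        band = "large"
    return v, band


def chi_square_pair(
    a: CategoryCountVector,
    b: CategoryCountVector,
    m: int = 1,
    alpha_levels: Sequence[float] = DEFAULT_ALPHA_LEVELS,
    policy: InterpretationPolicy = DEFAULT_POLICY,
    align: Literal["strict", "union"] = "strict",
) -> ChiSqResult:
    """Pearson chi-square on the k x 2 table of two aligned count vectors.

    Expected counts come from the pooled margins; no continuity correction
    is applied, including for 2 x 2 tables. ``m`` is the size of the
    comparison family used for the Bonferroni star annotation.
    """
    a, b = align_categories(a, b, policy=align)
    table = np.column_stack([a.counts, b.counts]).astype(float)
    pooled = table.sum(axis=1)
    if (pooled == 0).any():
        zero = [c for c, t in zip(a.categories, pooled) if t == 0]
        raise CountTableError(
            f"categories with zero pooled count {zero}; review union alignment "
            "or drop empty categories before testing"
        )
    if np.array_equal(table[:, 0] / table[:, 0].sum(), table[:, 1] / table[:, 1].sum()):
        # identical distributions: chi2_contingency handles this, but keep
        # p exactly 1 rather than a rounding-noise tail value
        statistic, p_raw = 0.0, 1.0
        df = a.k - 1
    else:
        statistic, p_raw, df, _ = stats.chi2_contingency(table, correction=False)
        statistic, p_raw = float(statistic), float(p_raw)
    n_total = int(table.sum())
    v, band = cramers_v(statistic, n_total, r=a.k, c=2, policy=policy)
    return ChiSqResult(
        variable_name=a.variable_name,
        reference_id=a.sample_id,
        scoring_id=b.sample_id,
        statistic=statistic,
        df=int(df),
        n_total=n_total,
        p_raw=p_raw,
        m=m,
        alpha_levels=tuple(alpha_levels),
        significance_stars=count_stars(p_raw, m, alpha_levels),
        cramers_v=v,
        effect_band=band,
    )
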
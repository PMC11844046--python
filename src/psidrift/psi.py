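"""Population Stability Index: per-category breakdown, bands, drift matrices.

PSI between a reference distribution E and a scoring distribution O over k
shared categories is

    PSI = sum_i (O_i - E_i) * ln(O_i / E_i)

Every term is non-negative (the difference and the log-ratio always share a
sign), so PSI = 0 exactly when O = E, and the statistic is symmetric in its
two arguments. On the proportion scale PSI is the Jeffreys divergence, i.e.
the symmetrised Kullback-Leibler divergence KL(O||E) + KL(E||O).

Two computing conventions are supported. ``proportion`` uses shares summing
to 1 and is the form found in the scorecard-monitoring literature, where the
0.1/0.25 interpretation cut-offs originate. ``percent`` uses shares summing
to 100, so the *difference* factor is in percentage points and totals come
out exactly 100x larger; this is the convention used by published
breakdown tables that tabulate percentage columns directly. The log-ratio is
scale-invariant, so the two conventions differ by that factor of 100 alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .count_table import (
    CategoryCountVector,
    CountTableError,
    ProportionVector,
    align_categories,
    proportions_pair,
)

Band = Literal["none", "moderate", "significant"]

#: Star annotation per band, as used on drift-matrix figures.
BAND_STARS = {"none": "", "moderate": "*", "significant": "**"}


class PsiDomainError(ValueError):
    """Invalid input to a divergence computation (e.g. non-positive share)."""


@dataclass(frozen=True)
class InterpretationPolicy:
    """Cut-offs for PSI bands and Cramér's V effect-size bands.

    PSI below ``psi_none_below`` indicates no distribution difference;
    at or above ``psi_significant_at`` a significant one; in between a
    moderate one. Boundary values belong to the higher band. The V bounds
    delimit small (<= ``v_small_max``), moderate and large effects.
    """

    psi_none_below: float = 0.1
    psi_significant_at: float = 0.25
    v_small_max: float = 0.2
    v_moderate_max: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.psi_none_below < self.psi_significant_at:
            raise ValueError("need 0 < psi_none_below < psi_significant_at")
        if not 0 < self.v_small_max < self.v_moderate_max <= 1:
            raise ValueError("need 0 < v_small_max < v_moderate_max <= 1")


DEFAULT_POLICY = InterpretationPolicy()


@dataclass(frozen=True)
class PsiRow:
    """One category's line of a PSI breakdown table.

    ``difference`` is reference share minus scoring share and ``log_ratio``
    is ln(reference/scoring) — the sign convention of printed breakdown
    tables, where the columns are (E, O, E-O, ln(E/O), product). Their
    product equals the canonical (O-E)·ln(O/E) term, so contributions are
    unaffected by the ordering and always non-negative.
    """

    category: str
    reference_share: float
    scoring_share: float
    difference: float
    log_ratio: float
    contribution: float


@dataclass(frozen=True)
class PsiBreakdown:
    """PSI total with its per-category decomposition and interpretation."""

    variable_name: str
    reference_id: str
    scoring_id: str
    rows: tuple[PsiRow, ...]
    total: float
    convention: Literal["percent", "proportion"]
    band: Band

    @property
    def stars(self) -> str:
        return BAND_STARS[self.band]

    def to_frame(self) -> pd.DataFrame:
        """Breakdown as a DataFrame shaped like a printed PSI table."""
        return pd.DataFrame(
            {
                "category": [r.category for r in self.rows],
                f"reference_{self.reference_id}": [r.reference_share for r in self.rows],
                f"scoring_{self.scoring_id}": [r.scoring_share for r in self.rows],
                "difference": [r.difference for r in self.rows],
                "natural_logarithm": [r.log_ratio for r in self.rows],
                "psi_contribution": [r.contribution for r in self.rows],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame["total_psi"] = [self.total] + [math.nan] * (len(frame) - 1)
        frame.to_csv(path, index=False)


def interpret_psi(total: float, policy: InterpretationPolicy = DEFAULT_POLICY) -> Band:
    """Band for a PSI total; boundaries belong to the higher band."""
    if total < 0:
        raise PsiDomainError(f"PSI cannot be negative, got {total}")
    if total < policy.psi_none_below:
        return "none"
    if total < policy.psi_significant_at:
        return "moderate"
    return "significant"


def psi(
    reference: ProportionVector,
    scoring: ProportionVector,
    convention: Literal["percent", "proportion"] = "percent",
    policy: InterpretationPolicy = DEFAULT_POLICY,
) -> PsiBreakdown:
    """PSI breakdown between a reference and a scoring share vector.

    Both vectors must be on the scale named by ``convention`` and strictly
    positive everywhere (apply smoothing upstream when zeros occur). The
    result is symmetric under swapping the two arguments.
    """
    if reference.categories != scoring.categories:
        raise CountTableError(
            f"category sequences differ between {reference.sample_id} and "
            f"{scoring.sample_id}"
        )
    for v in (reference, scoring):
        if v.scale != convention:
            raise CountTableError(
                f"{v.sample_id} is on scale {v.scale!r} but convention is "
                f"{convention!r}"
            )
        if any(s <= 0 for s in v.shares):
            raise PsiDomainError(
                f"{v.variable_name}/{v.sample_id} has a non-positive share; "
                "apply smoothing before computing PSI"
            )
    rows = []
    for cat, e, o in zip(reference.categories, reference.shares, scoring.shares):
        diff = e - o
        log_ratio = math.log(e / o)
        rows.append(
            PsiRow(
                category=cat,
                reference_share=e,
                scoring_share=o,
                difference=diff,
                log_ratio=log_ratio,
                contribution=diff * log_ratio,
            )
        )
    total = math.fsum(r.contribution for r in rows)
    return PsiBreakdown(
        variable_name=reference.variable_name,
        reference_id=reference.sample_id,
        scoring_id=scoring.sample_id,
        rows=tuple(rows),
        total=total,
        convention=convention,
        band=interpret_psi(total, policy),
    )


def psi_from_counts(
    reference: CategoryCountVector,
    scoring: CategoryCountVector,
    convention: Literal["percent", "proportion"] = "percent",
    policy: InterpretationPolicy = DEFAULT_POLICY,
    align: Literal["strict", "union"] = "strict",
) -> PsiBreakdown:
    """Convenience path from raw counts: align, smooth if needed, compute."""
    a, b = align_categories(reference, scoring, policy=align)
    p, q = proportions_pair(a, b, scale=convention, smoothing="auto")
    return psi(p, q, convention=convention, policy=policy)


@dataclass(frozen=True)
class DriftMatrix:
    """Symmetric matrix of pairwise drift scores for one variable."""

    variable_name: str
    sample_ids: tuple[str, ...]
    values: np.ndarray
    annotations: tuple[tuple[str, ...], ...]
    metric_name: str = "psi"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("matrix shape does not match sample_ids")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0) or (v < 0).any():
            raise ValueError("drift matrix must be symmetric, >= 0, zero-diagonal")

    def pair_value(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def iter_pairs(self) -> Iterable[tuple[str, str, float, str]]:
        """(sample_i, sample_j, value, annotation) for each unordered pair."""
        for i, j in combinations(range(len(self.sample_ids)), 2):
            yield (
                self.sample_ids[i],
                self.sample_ids[j],
                float(self.values[i, j]),
                self.annotations[i][j],
            )

    @property
    def offdiag_max(self) -> float:
        mask = ~np.eye(len(self.sample_ids), dtype=bool)
        return float(self.values[mask].max())

    @property
    def offdiag_min(self) -> float:
        mask = ~np.eye(len(self.sample_ids), dtype=bool)
        return float(self.values[mask].min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.sample_ids)
        )

    def write_csv(self, path: str | Path) -> None:
        """Matrix CSV with a parallel annotation block underneath."""
        frame = self.to_frame()
        ann = pd.DataFrame(
            [list(row) for row in self.annotations],
            index=list(self.sample_ids),
            columns=list(self.sample_ids),
        )
        with open(path, "w") as fh:
            fh.write(f"# {self.metric_name} values\n")
            frame.to_csv(fh)
            fh.write(f"# {self.metric_name} annotations\n")
            ann.to_csv(fh)


def drift_matrix(
    samples: Sequence[CategoryCountVector],
    convention: Literal["percent", "proportion"] = "percent",
    policy: InterpretationPolicy = DEFAULT_POLICY,
    align: Literal["strict", "union"] = "strict",
) -> DriftMatrix:
    """Pairwise PSI over every unordered pair of samples of one variable."""
    if len(samples) < 2:
        raise CountTableError("drift matrix needs at least 2 samples")
    names = {s.variable_name for s in samples}
    if len(names) > 1:
        raise CountTableError(f"samples span multiple variables: {sorted(names)}")
    ids = tuple(s.sample_id for s in samples)
    if len(set(ids)) != len(ids):
        raise CountTableError("duplicate sample ids")
    n = len(samples)
    values = np.zeros((n, n))
    stars = [[""] * n for _ in range(n)]
    for i, j in combinations(range(n), 2):
        bd = psi_from_counts(
            samples[i], samples[j], convention=convention, policy=policy, align=align
        )
        values[i, j] = values[j, i] = bd.total
        stars[i][j] = stars[j][i] = bd.stars
    return DriftMatrix(
        variable_name=samples[0].variable_name,
        sample_ids=ids,
        values=values,
        annotations=tuple(tuple(row) for row in stars),
        metric_name=f"psi_{convention}",
    )


def _check_divergence_inputs(p: ProportionVector, q: ProportionVector) -> None:
    if p.scale != "proportion" or q.scale != "proportion":
        raise PsiDomainError("divergences require the proportion scale")
    if p.categories != q.categories:
        raise CountTableError("category sequences differ")
    if any(s <= 0 for s in p.shares) or any(s <= 0 for s in q.shares):
        raise PsiDomainError("divergences require strictly positive shares")


def kl_divergence(p: ProportionVector, q: ProportionVector) -> float:
    """Kullback-Leibler divergence KL(p||q) = sum p_i ln(p_i/q_i), in nats."""
    _check_divergence_inputs(p, q)
    return math.fsum(
        pi * math.log(pi / qi) for pi, qi in zip(p.shares, q.shares)
    )


def js_distance(p: ProportionVector, q: ProportionVector) -> float:
    """Jensen-Shannon distance (square root of the JS divergence, in nats).

    Bounded above by sqrt(ln 2) for any pair of distributions.
    """
    _check_divergence_inputs(p, q)
    from dataclasses import replace

    m = replace(
        p,
        sample_id=f"mid({p.sample_id},{q.sample_id})",
        shares=tuple((a + b) / 2 for a, b in zip(p.shares, q.shares)),
    )
    jsd = 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)
    return math.sqrt(max(jsd, 0.0))
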
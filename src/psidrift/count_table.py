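"""Aggregated categorical count data: types, validation, I/O, proportions.

The unit of data is one variable observed in one sample (for registry data,
one calendar year): an ordered list of category labels with a non-negative
patient count for each. The long (tidy) CSV dialect
``variable,sample,category,count`` is the only on-disk format; percentage
columns are never read from files — shares are always recomputed from counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

Scale = Literal["proportion", "percent"]
#: Normalisation constant per scale.
SCALE_TOTAL = {"proportion": 1.0, "percent": 100.0}

#: Pseudo-count added to every category when smoothing kicks in.
SMOOTHING_PSEUDOCOUNT = 0.5

REQUIRED_COLUMNS = ("variable", "sample", "category", "count")


class CountTableError(ValueError):
    """Malformed count data (parse, validation, or alignment failure)."""


@dataclass(frozen=True)
class CategoryCountVector:
    """Counts for one variable in one sample, over an ordered category set.

    Parameters
    ----------
    variable_name : str
        Name of the categorical variable (e.g. ``"age_group"``).
    sample_id : str
        Label of the sample the counts come from (e.g. a year, ``"2016"``).
    categories : tuple of str
        Ordered, unique category labels.
    counts : tuple of int
        Non-negative count per category; the total must be at least 1.
    """

    variable_name: str
    sample_id: str
    categories: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise CountTableError(
                f"{self.variable_name}/{self.sample_id}: need at least 2 "
                f"categories, got {len(self.categories)}"
            )
        if len(set(self.categories)) != len(self.categories):
            raise CountTableError(
                f"{self.variable_name}/{self.sample_id}: duplicate category labels"
            )
        if len(self.counts) != len(self.categories):
            raise CountTableError(
                f"{self.variable_name}/{self.sample_id}: {len(self.counts)} counts "
                f"for {len(self.categories)} categories"
            )
        for cat, c in zip(self.categories, self.counts):
            if not isinstance(c, int) or isinstance(c, bool) or c < 0:
                raise CountTableError(
                    f"{self.variable_name}/{self.sample_id}/{cat}: count must be a "
                    f"non-negative integer, got {c!r}"
                )
        if self.total < 1:
            raise CountTableError(
                f"{self.variable_name}/{self.sample_id}: total count must be >= 1"
            )

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def k(self) -> int:
        """Number of categories."""
        return len(self.categories)

    def has_zero(self) -> bool:
        return any(c == 0 for c in self.counts)


@dataclass(frozen=True)
class ProportionVector:
    """Category shares derived from counts, on a declared scale.

    ``shares`` sum to 1 on the ``proportion`` scale or 100 on the ``percent``
    scale. ``smoothed`` records whether a pseudo-count was applied before
    normalising; unsmoothed vectors may contain zero shares.
    """

    variable_name: str
    sample_id: str
    categories: tuple[str, ...]
    shares: tuple[float, ...]
    scale: Scale = "proportion"
    smoothed: bool = False

    def __post_init__(self) -> None:
        if self.scale not in SCALE_TOTAL:
            raise CountTableError(f"unknown scale {self.scale!r}")
        if len(self.shares) != len(self.categories):
            raise CountTableError("shares/categories length mismatch")
        if any(s < 0 for s in self.shares):
            raise CountTableError("negative share")
        expected = SCALE_TOTAL[self.scale]
        if abs(sum(self.shares) - expected) > 1e-9 * max(1.0, expected):
            raise CountTableError(
                f"shares sum to {sum(self.shares)!r}, expected {expected}"
            )

    @property
    def k(self) -> int:
        return len(self.categories)


def to_proportions(
    v: CategoryCountVector,
    scale: Scale = "proportion",
    smoothing: Literal["none", "auto", "force"] = "none",
) -> ProportionVector:
    """Convert counts to category shares.

    With ``smoothing="auto"`` a pseudo-count of 0.5 is added to *every*
    category whenever any count is zero, so downstream log-ratios stay
    finite; ``"force"`` always adds it; ``"none"`` never does (zero counts
    then yield zero shares).
    """
    counts: Sequence[float] = v.counts
    smoothed = False
    if smoothing == "force" or (smoothing == "auto" and v.has_zero()):
        counts = [c + SMOOTHING_PSEUDOCOUNT for c in v.counts]
        smoothed = True
        logger.warning(
            "smoothing %s/%s: added pseudo-count %.1f to all %d categories",
            v.variable_name, v.sample_id, SMOOTHING_PSEUDOCOUNT, v.k,
        )
    total = float(sum(counts))
    factor = SCALE_TOTAL[scale]
    return ProportionVector(
        variable_name=v.variable_name,
        sample_id=v.sample_id,
        categories=v.categories,
        shares=tuple(c / total * factor for c in counts),
        scale=scale,
        smoothed=smoothed,
    )


def proportions_pair(
    a: CategoryCountVector,
    b: CategoryCountVector,
    scale: Scale = "proportion",
    smoothing: Literal["none", "auto"] = "auto",
) -> tuple[ProportionVector, ProportionVector]:
    """Shares for a comparison pair, smoothing *both* sides together.

    When either vector contains a zero count (and smoothing is ``auto``),
    the 0.5 pseudo-count is applied to both vectors, keeping the treatment
    symmetric across the pair.
    """
    if a.categories != b.categories:
        raise CountTableError(
            "proportions_pair requires identically aligned categories; "
            "use align_categories first"
        )
    mode: Literal["none", "force"] = "none"
    if smoothing == "auto" and (a.has_zero() or b.has_zero()):
        mode = "force"
    return (
        to_proportions(a, scale=scale, smoothing=mode),
        to_proportions(b, scale=scale, smoothing=mode),
    )


def align_categories(
    a: CategoryCountVector,
    b: CategoryCountVector,
    policy: Literal["strict", "union"] = "strict",
) -> tuple[CategoryCountVector, CategoryCountVector]:
    """Put two vectors of the same variable over one category sequence.

    ``strict`` errors on any label mismatch. ``union`` fills missing
    categories with count 0 (which triggers smoothing downstream); the
    merged order is ``a``'s order followed by ``b``'s extras.
    """
    if a.variable_name != b.variable_name:
        raise CountTableError(
            f"cannot align different variables {a.variable_name!r} and "
            f"{b.variable_name!r}"
        )
    if a.categories == b.categories:
        return a, b
    if policy == "strict":
        only_a = [c for c in a.categories if c not in b.categories]
        only_b = [c for c in b.categories if c not in a.categories]
        raise CountTableError(
            f"category mismatch for {a.variable_name!r}: "
            f"only in {a.sample_id}: {only_a}; only in {b.sample_id}: {only_b}"
        )
    merged = tuple(a.categories) + tuple(
        c for c in b.categories if c not in a.categories
    )
    amap = dict(zip(a.categories, a.counts))
    bmap = dict(zip(b.categories, b.counts))
    return (
        replace(a, categories=merged, counts=tuple(amap.get(c, 0) for c in merged)),
        replace(b, categories=merged, counts=tuple(bmap.get(c, 0) for c in merged)),
    )


def read_count_table(path: str | Path, delimiter: str = ",") -> list[CategoryCountVector]:
    """Read a long-format count table into one vector per (variable, sample).

    The file must be delimited text with header columns
    ``variable,sample,category,count``. Category order is first-seen per
    variable; duplicated (variable, sample, category) rows are an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, delimiter=delimiter, dtype=str, skipinitialspace=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CountTableError(f"{path}: cannot parse: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{path}: missing required columns {missing}")
    counts: list[int] = []
    for idx, raw in df["count"].items():
        line = idx + 2  # header is line 1
        try:
            value = int(raw)
        except (TypeError, ValueError):
            raise CountTableError(
                f"{path}, line {line}: count {raw!r} is not an integer"
            ) from None
        if value < 0:
            raise CountTableError(f"{path}, line {line}: negative count {value}")
        counts.append(value)
    df = df.assign(count=counts)

    dup = df.duplicated(subset=["variable", "sample", "category"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise CountTableError(
            f"{path}, line {line}: duplicate (variable, sample, category) row"
        )

    # first-seen category order, shared across all samples of a variable
    order: dict[str, list[str]] = {}
    for var, cat in zip(df["variable"], df["category"]):
        order.setdefault(var, [])
        if cat not in order[var]:
            order[var].append(cat)

    vectors: list[CategoryCountVector] = []
    for (var, sample), grp in df.groupby(["variable", "sample"], sort=False):
        cmap = dict(zip(grp["category"], grp["count"]))
        cats = tuple(c for c in order[var] if c in cmap)
        vectors.append(
            CategoryCountVector(
                variable_name=str(var),
                sample_id=str(sample),
                categories=cats,
                counts=tuple(int(cmap[c]) for c in cats),
            )
        )
    return vectors


def write_count_table(
    vectors: Iterable[CategoryCountVector], path: str | Path, delimiter: str = ","
) -> None:
    """Write vectors back to the long CSV dialect (inverse of reading)."""
    rows = [
        (v.variable_name, v.sample_id, cat, count)
        for v in vectors
        for cat, count in zip(v.categories, v.counts)
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, index=False, sep=delimiter
    )


def group_by_variable(
    vectors: Iterable[CategoryCountVector],
) -> dict[str, list[CategoryCountVector]]:
    """Bucket vectors by variable, preserving sample order of appearance."""
    out: dict[str, list[CategoryCountVector]] = {}
    for v in vectors:
        out.setdefault(v.variable_name, []).append(v)
    return out
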
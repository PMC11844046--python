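"""Discretisation of numeric variables into ordered categories.

PSI only consumes categorical data, so a record-level numeric variable must
be binned first. Bins are left-closed/right-open with the final bin closed
on the right (the age-group style "60-64, 65-69, ..."); a value landing
exactly on an interior edge goes to the higher bin. Bin choice affects the
resulting PSI, so schemes are explicit, serialisable objects rather than a
hidden step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .count_table import CategoryCountVector

logger = logging.getLogger(__name__)

Method = Literal["equal_width", "quantile", "explicit"]

#: Common default bin count in drift-monitoring practice.
DEFAULT_K = 10


class BinningError(ValueError):
    pass


@dataclass(frozen=True)
class BinningScheme:
    """Strictly increasing edges defining len(edges)-1 labelled bins."""

    variable_name: str
    edges: tuple[float, ...]
    labels: tuple[str, ...]
    method: Method = "explicit"

    def __post_init__(self) -> None:
        if len(self.edges) < 3:
            raise BinningError("need at least 2 bins (3 edges)")
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise BinningError("edges must be strictly increasing")
        if len(self.labels) != self.n_bins:
            raise BinningError(
                f"{len(self.labels)} labels for {self.n_bins} bins"
            )
        if len(set(self.labels)) != len(self.labels):
            raise BinningError("labels must be unique")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "variable_name": self.variable_name,
                "edges": list(self.edges),
                "labels": list(self.labels),
                "method": self.method,
                "closure": "left-closed, right-open; final bin right-closed",
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "BinningScheme":
        d = json.loads(doc)
        return cls(
            variable_name=d["variable_name"],
            edges=tuple(float(e) for e in d["edges"]),
            labels=tuple(d["labels"]),
            method=d.get("method", "explicit"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "BinningScheme":
        return cls.from_json(Path(path).read_text())


def _default_labels(edges: Sequence[float]) -> tuple[str, ...]:
    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-2], edges[1:-1])]
    labels.append(f"[{edges[-2]:g}, {edges[-1]:g}]")
    return tuple(labels)


def make_bins(
    values: Sequence[float],
    method: Literal["equal_width", "quantile"] = "quantile",
    k: int = DEFAULT_K,
    variable_name: str = "value",
    labels: Sequence[str] | None = None,
) -> BinningScheme:
    """Derive a binning scheme from data.

    ``equal_width`` spans [min, max] with k equal intervals. ``quantile``
    places edges at the i/k empirical quantiles; tied data can produce
    duplicate edges, which are collapsed (reducing the bin count, with a
    logged warning) rather than raised.
    """
    if k < 2:
        raise BinningError(f"bin count must be >= 2, got {k}")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or not np.isfinite(arr).all():
        raise BinningError("values must be non-empty and finite")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        raise BinningError("cannot bin a constant variable")
    if method == "equal_width":
        edges = np.linspace(lo, hi, k + 1)
    elif method == "quantile":
        if np.unique(arr).size < k:
            raise BinningError(
                f"quantile binning with k={k} needs >= k distinct values"
            )
        edges = np.quantile(arr, np.linspace(0, 1, k + 1))
        unique = np.unique(edges)
        if unique.size < edges.size:
            logger.warning(
                "%s: %d duplicate quantile edges collapsed; %d bins instead of %d",
                variable_name, edges.size - unique.size, unique.size - 1, k,
            )
        edges = unique
        if edges.size < 3:
            raise BinningError("too few distinct quantile edges to form 2 bins")
    else:
        raise BinningError(f"unknown method {method!r}")
    edge_tuple = tuple(float(e) for e in edges)
    return BinningScheme(
        variable_name=variable_name,
        edges=edge_tuple,
        labels=tuple(labels) if labels is not None else _default_labels(edge_tuple),
        method=method,
    )


def apply_bins(
    values: Sequence[float],
    scheme: BinningScheme,
    sample_id: str = "sample",
) -> CategoryCountVector:
    """Count values per bin; total count always equals len(values).

    Interior-edge ties go to the higher bin; a value equal to the last edge
    belongs to the final (right-closed) bin; out-of-range values are
    assigned to the nearest terminal bin with a logged warning.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise BinningError("no values to bin")
    edges = np.asarray(scheme.edges)
    below, above = (arr < edges[0]).sum(), (arr > edges[-1]).sum()
    if below or above:
        logger.warning(
            "%s/%s: %d values below and %d above range assigned to terminal bins",
            scheme.variable_name, sample_id, below, above,
        )
    idx = np.searchsorted(edges, arr, side="right") - 1
    idx = np.clip(idx, 0, scheme.n_bins - 1)
    counts = np.bincount(idx, minlength=scheme.n_bins)
    return CategoryCountVector(
        variable_name=scheme.variable_name,
        sample_id=sample_id,
        categories=scheme.labels,
        counts=tuple(int(c) for c in counts),
    )
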
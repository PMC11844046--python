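"""End-to-end analyses: the registry year-comparison study and the
simulation harness contrasting PSI with chi-square testing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .companion import DEFAULT_ALPHA_LEVELS, ChiSqResult, bonferroni, chi_square_pair
from .count_table import (
    CategoryCountVector,
    CountTableError,
    group_by_variable,
    read_count_table,
)
from .datasets import load_seer_table1
from .psi import (
    DEFAULT_POLICY,
    DriftMatrix,
    InterpretationPolicy,
    PsiBreakdown,
    drift_matrix,
    interpret_psi,
    psi_from_counts,
)
from .synthetic import SyntheticSpec, generate_pair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisReport:
    """Everything the year-comparison analysis produces.

    ``psi_matrices`` and ``chisq_results`` are keyed by variable name; the
    breakdown belongs to the pair with the largest PSI overall. Summary
    extrema are recomputed and checked against the matrices on construction.
    """

    psi_matrices: Mapping[str, DriftMatrix]
    chisq_results: Mapping[str, tuple[ChiSqResult, ...]]
    max_breakdown: PsiBreakdown
    summary: Mapping[str, float | int | str]
    metadata: Mapping[str, object]

    def __post_init__(self) -> None:
        maxima = [m.offdiag_max for m in self.psi_matrices.values()]
        minima = [m.offdiag_min for m in self.psi_matrices.values()]
        if abs(self.summary["max_psi"] - max(maxima)) > 1e-12:
            raise AssertionError("summary max_psi disagrees with matrices")
        if abs(self.summary["min_psi"] - min(minima)) > 1e-12:
            raise AssertionError("summary min_psi disagrees with matrices")

    def all_chisq(self) -> list[ChiSqResult]:
        return [r for rs in self.chisq_results.values() for r in rs]

    def write(self, outdir: str | Path) -> None:
        """Write matrices, breakdown and summary.json under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for var, matrix in self.psi_matrices.items():
            matrix.write_csv(outdir / f"psi_matrix_{var}.csv")
        for var, results in self.chisq_results.items():
            rows = [
                {
                    "variable": r.variable_name,
                    "reference": r.reference_id,
                    "scoring": r.scoring_id,
                    "statistic": r.statistic,
                    "df": r.df,
                    "n_total": r.n_total,
                    "p_raw": r.p_display(),
                    "stars": r.stars,
                    "cramers_v": r.cramers_v,
                    "effect_band": r.effect_band,
                }
                for r in results
            ]
            pd.DataFrame(rows).to_csv(outdir / f"chisq_matrix_{var}.csv", index=False)
        pair = f"{self.max_breakdown.reference_id}_vs_{self.max_breakdown.scoring_id}"
        self.max_breakdown.write_csv(outdir / f"breakdown_{pair}.csv")
        with open(outdir / "summary.json", "w") as fh:
            json.dump({"summary": dict(self.summary),
                       "metadata": dict(self.metadata)}, fh, indent=2, default=str)


def run_year_comparison(
    fixture: str | Path | Sequence[CategoryCountVector] | None = None,
    convention: Literal["percent", "proportion"] = "percent",
    policy: InterpretationPolicy = DEFAULT_POLICY,
    alpha_levels: Sequence[float] = DEFAULT_ALPHA_LEVELS,
    m: int | None = None,
) -> AnalysisReport:
    """Run the full year-comparison analysis on a count table.

    With no fixture argument the packaged SEER table is used: 7 yearly
    samples per variable give C(7,2) = 21 comparisons per variable and 63
    overall. ``m`` (the Bonferroni family size) defaults to the number of
    pairs within one variable's family.
    """
    if fixture is None:
        vectors = load_seer_table1()
    elif isinstance(fixture, (str, Path)):
        vectors = read_count_table(fixture)
    else:
        vectors = list(fixture)
    by_var = group_by_variable(vectors)
    for var, samples in by_var.items():
        if len(samples) < 2:
            raise CountTableError(f"variable {var!r} has fewer than 2 samples")

    psi_matrices: dict[str, DriftMatrix] = {}
    chisq_results: dict[str, tuple[ChiSqResult, ...]] = {}
    best: PsiBreakdown | None = None
    for var, samples in by_var.items():
        n_pairs = comb(len(samples), 2)
        family_m = m if m is not None else n_pairs
        logger.info("variable %s: %d samples, %d pairs, m=%d",
                    var, len(samples), n_pairs, family_m)
        psi_matrices[var] = drift_matrix(samples, convention=convention, policy=policy)
        pairs = []
        for a, b in combinations(samples, 2):
            pairs.append(
                chi_square_pair(a, b, m=family_m, alpha_levels=alpha_levels,
                                policy=policy)
            )
            bd = psi_from_counts(a, b, convention=convention, policy=policy)
            if best is None or bd.total > best.total:
                best = bd
        chisq_results[var] = tuple(pairs)

    assert best is not None
    all_chisq = [r for rs in chisq_results.values() for r in rs]
    all_psi = [v for mat in psi_matrices.values() for *_, v, _ in mat.iter_pairs()]
    n_starred_chisq = sum(r.significance_stars > 0 for r in all_chisq)
    n_starred_psi = sum(
        interpret_psi(v, policy) != "none" for v in all_psi
    )
    summary = {
        "n_comparisons": len(all_psi),
        "max_psi": max(all_psi),
        "min_psi": min(all_psi),
        "max_psi_pair": f"{best.variable_name}:{best.reference_id}"
                        f"/{best.scoring_id}",
        "max_cramers_v": max(r.cramers_v for r in all_chisq),
        "n_starred_chisq": n_starred_chisq,
        "n_starred_psi": n_starred_psi,
    }
    metadata = {
        "convention": convention,
        "psi_thresholds": (policy.psi_none_below, policy.psi_significant_at),
        "v_bands": (policy.v_small_max, policy.v_moderate_max),
        "alpha_levels": tuple(alpha_levels),
        "m": m if m is not None else "per-variable C(n,2)",
        "continuity_correction": False,
        "version": __version__,
    }
    return AnalysisReport(
        psi_matrices=psi_matrices,
        chisq_results=chisq_results,
        max_breakdown=best,
        summary=summary,
        metadata=metadata,
    )


def run_simulation_study(
    deltas: Sequence[float],
    sample_sizes: Sequence[int],
    replicates: int = 200,
    k: int = 5,
    seed: int = 0,
    m: int = 21,
    alpha_levels: Sequence[float] = DEFAULT_ALPHA_LEVELS,
    policy: InterpretationPolicy = DEFAULT_POLICY,
) -> pd.DataFrame:
    """Operating characteristics of PSI vs chi-square over a (δ, n) grid.

    For each grid point, ``replicates`` reference/scoring pairs of size n
    are drawn; the table reports the chi-square flag rate at each
    Bonferroni-adjusted level, the PSI band rates (proportion-scale
    thresholds), and the mean proportion-scale PSI. Seeded and reproducible:
    replicate seeds are derived from ``seed`` and the grid position.
    """
    records = []
    thresholds = [t for t, _ in bonferroni(alpha_levels, m)]
    for gi, delta in enumerate(deltas):
        for gj, n in enumerate(sample_sizes):
            child_seeds = (
                np.random.SeedSequence([seed, gi, gj]).generate_state(replicates)
                % (2**31)
            )
            psis = np.empty(replicates)
            pvals = np.empty(replicates)
            for r, s in enumerate(child_seeds):
                spec = SyntheticSpec(
                    k=k, drift_magnitude=delta, n_reference=n, n_scoring=n,
                    seed=int(s),
                )
                ref, scor, _ = generate_pair(spec)
                bd = psi_from_counts(ref, scor, convention="proportion",
                                     policy=policy)
                psis[r] = bd.total
                pvals[r] = chi_square_pair(ref, scor, m=m,
                                           alpha_levels=alpha_levels).p_raw
            bands = [interpret_psi(t, policy) for t in psis]
            rec = {
                "delta": delta,
                "n": n,
                "k": k,
                "replicates": replicates,
                "mean_psi": psis.mean(),
                "psi_rate_none": np.mean([b == "none" for b in bands]),
                "psi_rate_moderate": np.mean([b == "moderate" for b in bands]),
                "psi_rate_significant": np.mean([b == "significant" for b in bands]),
            }
            for level, thr in zip(alpha_levels, thresholds):
                rec[f"chisq_rate_at_{level}"] = float(np.mean(pvals < thr))
            records.append(rec)
    columns = [
        "delta", "n", "k", "replicates", "mean_psi",
        "psi_rate_none", "psi_rate_moderate", "psi_rate_significant",
        *[f"chisq_rate_at_{level}" for level in alpha_levels],
    ]
    return pd.DataFrame.from_records(records, columns=columns)
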
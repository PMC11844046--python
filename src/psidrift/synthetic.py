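"""Synthetic multinomial count tables with a known, tunable amount of drift.

The generator emulates registry-style aggregated tables: a reference sample
drawn from base proportions p, and a scoring sample drawn from perturbed
proportions q_i ∝ p_i · exp(δ·z_i) with z_i independent standard normals.
The log-normal share perturbation makes δ = 0 exactly null (q = p) and maps
δ monotonically to the expected divergence between the true distributions,
which a Dirichlet parameterisation would not do as directly.

Under the null (δ = 0) the sampled proportion-scale PSI has expectation
approximately (k-1)·(1/n_ref + 1/n_scor) — the chi-square-like small-noise
limit — which the test suite uses as a calibration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .count_table import CategoryCountVector


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the drift generator.

    Parameters
    ----------
    k : int
        Number of categories (>= 2).
    base_proportions : sequence of float or "uniform"
        True reference shares; must be positive and sum to 1.
    drift_magnitude : float
        δ >= 0, standard deviation of the log-share perturbation per step.
    n_reference, n_scoring : int
        Multinomial totals of the two samples.
    n_samples : int
        Number of yearly samples for :func:`generate_yearly_table`.
    seed : int
        RNG seed; identical seeds give bit-identical output.
    """

    k: int = 5
    base_proportions: Sequence[float] | str = "uniform"
    drift_magnitude: float = 0.0
    n_reference: int = 1000
    n_scoring: int = 1000
    n_samples: int = 2
    seed: int = 0
    variable_name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.drift_magnitude < 0:
            raise ValueError("drift_magnitude must be >= 0")
        if min(self.n_reference, self.n_scoring) < 1 or self.n_samples < 1:
            raise ValueError("sample sizes must be >= 1")
        p = self.proportions()
        if p.size != self.k:
            raise ValueError(f"{p.size} base proportions for k={self.k}")
        if (p <= 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("base proportions must be positive and sum to 1")

    def proportions(self) -> np.ndarray:
        if isinstance(self.base_proportions, str):
            if self.base_proportions != "uniform":
                raise ValueError(f"unknown preset {self.base_proportions!r}")
            return np.full(self.k, 1.0 / self.k)
        return np.asarray(self.base_proportions, dtype=float)

    def categories(self) -> tuple[str, ...]:
        return tuple(f"c{i + 1}" for i in range(self.k))


def _perturb(p: np.ndarray, delta: float, rng: np.random.Generator) -> np.ndarray:
    """q_i ∝ p_i · exp(δ·z_i); δ = 0 returns p unchanged (no RNG draw)."""
    if delta == 0:
        return p.copy()
    z = rng.standard_normal(p.size)
    q = p * np.exp(delta * z)
    return q / q.sum()


def _counts_vector(
    spec: SyntheticSpec, sample_id: str, counts: np.ndarray
) -> CategoryCountVector:
    return CategoryCountVector(
        variable_name=spec.variable_name,
        sample_id=sample_id,
        categories=spec.categories(),
        counts=tuple(int(c) for c in counts),
    )


def generate_pair(
    spec: SyntheticSpec,
) -> tuple[CategoryCountVector, CategoryCountVector, np.ndarray]:
    """One reference/scoring pair plus the true scoring proportions."""
    rng = np.random.default_rng(spec.seed)
    p = spec.proportions()
    q = _perturb(p, spec.drift_magnitude, rng)
    ref = rng.multinomial(spec.n_reference, p)
    scor = rng.multinomial(spec.n_scoring, q)
    return (
        _counts_vector(spec, "reference", ref),
        _counts_vector(spec, "scoring", scor),
        q,
    )


def generate_yearly_table(spec: SyntheticSpec) -> list[CategoryCountVector]:
    """A sequence of samples whose true shares random-walk with step δ.

    Sample 1 uses the base proportions; each subsequent sample perturbs the
    previous true shares, mimicking gradual year-on-year drift. All samples
    use ``n_reference`` as their multinomial total except the last, which
    uses ``n_scoring`` (so a 2-sample table matches :func:`generate_pair`
    geometry).
    """
    if spec.n_samples < 2:
        raise ValueError("need n_samples >= 2 for a yearly table")
    rng = np.random.default_rng(spec.seed)
    shares = spec.proportions()
    out = []
    for t in range(spec.n_samples):
        if t > 0:
            shares = _perturb(shares, spec.drift_magnitude, rng)
        n = spec.n_scoring if t == spec.n_samples - 1 else spec.n_reference
        counts = rng.multinomial(n, shares)
        out.append(_counts_vector(spec, f"t{t + 1}", counts))
    return out


def null_psi_expectation(k: int, n_reference: int, n_scoring: int) -> float:
    """Approximate E[PSI] (proportion scale) under no true drift.

    Delta-method limit: (k-1)·(1/n_ref + 1/n_scor). Accurate when every
    expected cell count is large.
    """
    return (k - 1) * (1.0 / n_reference + 1.0 / n_scoring)
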
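"""Synthetic inputs with known ground truth.

Two generators make every other module testable without any download:

* planted-cluster gene-expression matrices shaped like the yeast cell-cycle
  compendium the clustering front end targets (thousands of gene rows, 16
  sample columns, ~20 underlying clusters, sporadic missing cells), and
* sums of Gaussian bumps with analytically known peaks and (in one
  dimension) numerically located valleys, which is what the pseudo-peak
  probability checks need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize as sciopt

from .gene_cluster import ExpressionMatrix
from .gfa_core import MassFunction

__all__ = [
    "SyntheticSpec",
    "make_expression_matrix",
    "MultimodalFunction",
    "make_multimodal_function",
]


@dataclass
class SyntheticSpec:
    """Planted-cluster matrix parameters.

    ``effect`` is the scale (in noise-SD units) of the cluster mean
    profiles: each cluster's profile is a uniformly random direction on the
    unit sphere in sample space, scaled by ``effect * noise_sd``, so the
    typical distance between two cluster profiles is ~ effect * sqrt(2)
    noise SDs.  ``missing_rate`` masks cells independently; alternatively
    ``missing_rows`` plants at least one missing cell in exactly that many
    gene rows (the pattern the preprocessing step counts).

    Defaults emulate the application dataset's shape: 7,663 gene rows with
    16 samples and 20 clusters (7,680 raw rows minus 17 rows excluded for
    missing values in the full-scale preprocessing check).  The cell-level
    missing rate default (1.4e-4) is chosen so that a 7,680 x 16 matrix
    carries ~17 affected gene rows in expectation.
    """

    G: int = 7663
    S: int = 16
    K: int = 20
    effect: float = 5.0
    noise_sd: float = 1.0
    missing_rate: float = 1.4e-4
    missing_rows: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.G >= self.K >= 1):
            raise ValueError("need G >= K >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_rows is not None and not (0 <= self.missing_rows <= self.G):
            raise ValueError("missing_rows must lie in [0, G]")


def make_expression_matrix(spec: SyntheticSpec):
    """Generate a planted-cluster matrix; returns (matrix, true_labels).

    Cluster mean profiles are drawn on the unit sphere and scaled by the
    effect size; genes pick a cluster uniformly (multinomial sizes, so empty
    or tiny clusters can occur at small G); the observed value is profile +
    Gaussian noise; cells are masked missing independently, or in exactly
    ``missing_rows`` rows when that is set.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = rng.normal(size=(spec.K, spec.S))
    profiles /= np.linalg.norm(profiles, axis=1, keepdims=True)
    profiles *= spec.effect * spec.noise_sd
    labels = rng.integers(0, spec.K, size=spec.G)
    values = profiles[labels] + rng.normal(0.0, spec.noise_sd, size=(spec.G, spec.S))

    if spec.missing_rows is not None:
        rows = rng.choice(spec.G, size=spec.missing_rows, replace=False)
        cols = rng.integers(0, spec.S, size=spec.missing_rows)
        values[rows, cols] = np.nan
    elif spec.missing_rate > 0:
        mask = rng.random((spec.G, spec.S)) < spec.missing_rate
        values[mask] = np.nan

    gene_ids = [f"GENE{i + 1:05d}" for i in range(spec.G)]
    sample_ids = [f"S{j + 1:02d}" for j in range(spec.S)]
    return ExpressionMatrix(gene_ids, sample_ids, values), labels


class MultimodalFunction(MassFunction):
    """Sum of Gaussian bumps with known peak locations.

    Maximization-sense mass function.  ``argmax`` is the position of the
    highest bump (exact to bump-overlap corrections, which the constructor
    warns about when bumps crowd each other).  In one dimension
    :meth:`valleys` locates the local minima between adjacent bumps by
    root-finding on the analytic derivative.
    """

    def __init__(self, peak_positions, peak_heights, widths, domain=None):
        P = np.asarray(peak_positions, dtype=float)
        P = P[:, None] if P.ndim == 1 else P  # 1-D peaks as column vectors
        h = np.asarray(peak_heights, dtype=float)
        w = np.asarray(widths, dtype=float)
        if not (len(P) == len(h) == len(w)):
            raise ValueError("peaks, heights and widths must have equal length")
        if np.any(w <= 0):
            raise ValueError("widths must be positive")
        if domain is None:
            lo = P.min(axis=0) - 3 * w.max()
            hi = P.max(axis=0) + 3 * w.max()
            domain = np.stack([lo, hi], axis=1)
        domain = np.asarray(domain, dtype=float)
        if np.any(P < domain[:, 0]) or np.any(P > domain[:, 1]):
            raise ValueError("all peaks must lie inside the domain")
        # crowding check: valley analysis is unreliable for merging bumps
        for i in range(len(P)):
            for j in range(i + 1, len(P)):
                d = np.linalg.norm(P[i] - P[j])
                if d < 2 * max(w[i], w[j]):
                    warnings.warn(
                        "peaks closer than two widths: valley analysis unreliable",
                        stacklevel=2,
                    )
        self.peaks, self.heights, self.widths_ = P, h, w

        def fn(X: np.ndarray) -> np.ndarray:
            X = np.atleast_2d(X)
            d2 = ((X[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
            return (h[None, :] * np.exp(-0.5 * d2 / w[None, :] ** 2)).sum(axis=1)

        super().__init__(fn=fn, domain=domain, sense="maximize", name="multimodal")

    @property
    def argmax(self) -> np.ndarray:
        return self.peaks[int(np.argmax(self.heights))].copy()

    @property
    def max_value(self) -> float:
        x = self.argmax
        return float(self.raw(x[None, :])[0])

    def derivative_1d(self, x: float) -> float:
        if self.dimension != 1:
            raise ValueError("analytic derivative only available in 1-D")
        p = self.peaks[:, 0]
        t = (x - p) / self.widths_**2
        return float(
            np.sum(-self.heights * t * np.exp(-0.5 * ((x - p) / self.widths_) ** 2))
        )

    def valleys(self) -> np.ndarray:
        """1-D local minima between adjacent peaks (derivative roots)."""
        if self.dimension != 1:
            raise ValueError("valley analysis only available in 1-D")
        p = np.sort(self.peaks[:, 0])
        roots = []
        for a, b in zip(p[:-1], p[1:]):
            lo, hi = a + 1e-9 * (b - a), b - 1e-9 * (b - a)
            fa, fb = self.derivative_1d(lo), self.derivative_1d(hi)
            if fa > 0 or fb < 0:  # no interior sign change: bumps merged
                continue
            roots.append(sciopt.brentq(self.derivative_1d, lo, hi, xtol=1e-12))
        return np.asarray(roots)


def make_multimodal_function(
    peak_positions: Sequence,
    peak_heights: Sequence[float],
    widths: Sequence[float],
    domain=None,
) -> MultimodalFunction:
    """Build a sum-of-Gaussian-bumps mass function with known optima."""
    return MultimodalFunction(peak_positions, peak_heights, widths, domain)
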
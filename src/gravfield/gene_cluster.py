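"""K-means gene-expression clustering driven by the gravitation field engine.

The application that motivated the optimizer: a genes x samples expression
matrix is partitioned into K clusters (20 in the replication profile) by
K-means whose objective — the mean distance of each gene to its nearest
centroid — is minimized globally by GFA instead of Lloyd iterations.  A
candidate solution ("dust") is a flattened K x samples centroid matrix; its
mass is the negative mean nearest-centroid distance.  Distances default to
the centred Pearson correlation distance (1 - r), the measure used by the
Cluster 3.0 lineage of tools; Euclidean distance is available as an option.

Input is tab-delimited text (first column gene IDs, first row sample IDs,
blank or NA cells missing), with the PCL dialect's optional NAME/GWEIGHT
columns and EWEIGHT row accepted and skipped.  Output is a Cluster-3.0/
TreeView-style CDT table plus a per-sample one-way ANOVA F-test report that
asks whether the clustering separates expression levels within every
sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import kmeans_plusplus

from .gfa_core import GFAConfig, MassFunction, optimize

__all__ = [
    "ExpressionMatrix",
    "ClusteringResult",
    "read_expression_matrix",
    "write_expression_matrix",
    "preprocess",
    "correlation_distance",
    "kmeans_gfa",
    "evaluate_ftest",
    "write_cdt",
    "read_cdt",
    "write_assignments",
    "write_ftest_report",
]

_MISSING_TOKENS = {"", "na", "nan", "null"}


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix; missing cells are NaN."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClusteringResult:
    """K-cluster partition with the minimized objective and F statistics."""

    assignments: np.ndarray  # gene -> cluster index in [0, K)
    centroids: np.ndarray  # K x samples
    mean_distance: float
    per_sample_F: list[tuple[float, float]] = field(default_factory=list)
    runs_used: int = 1
    reseeded_clusters: int = 0

    @property
    def K(self) -> int:
        return self.centroids.shape[0]


# ---------------------------------------------------------------------------
# I/O


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a tab-delimited expression table (GEO-series-matrix/PCL-like).

    First column: gene IDs; first row: sample IDs.  Blank/NA cells are
    missing.  The PCL dialect's NAME and GWEIGHT columns and EWEIGHT row are
    recognised and skipped.  Ragged rows raise with the offending line
    number; duplicate gene IDs raise.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    skip_cols = 1
    upper = [h.strip().upper() for h in header]
    for col in (1, 2):
        if len(upper) > col and upper[col] in ("NAME", "GWEIGHT"):
            skip_cols = col + 1
    sample_ids = [h.strip() for h in header[skip_cols:]]
    ncol = len(header)

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if fields[0].strip().upper() == "EWEIGHT":
            continue
        if len(fields) != ncol:
            raise ValueError(
                f"{path}: line {lineno}: expected {ncol} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0].strip())
        row = []
        for cell in fields[skip_cols:]:
            cell = cell.strip()
            row.append(np.nan if cell.lower() in _MISSING_TOKENS else float(cell))
        rows.append(row)
    if len(set(gene_ids)) != len(gene_ids):
        seen, dup = set(), None
        for g in gene_ids:
            if g in seen:
                dup = g
                break
            seen.add(g)
        raise ValueError(f"{path}: duplicate gene ID {dup!r}")
    return ExpressionMatrix(gene_ids, sample_ids, np.asarray(rows, dtype=float))


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write the plain tab-delimited dialect (missing cells left blank)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(["ID"] + matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write("\t".join([gid] + cells) + "\n")


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(matrix: ExpressionMatrix, policy: str = "drop_genes_with_missing") -> ExpressionMatrix:
    """Handle missing values.

    ``drop_genes_with_missing`` removes every gene row containing at least
    one missing cell (the application's listwise exclusion: 7,680 rows with
    17 affected rows leave 7,663).  ``pairwise_complete`` keeps all rows and
    lets distance computations skip missing pairs, except that genes with
    fewer than 3 observed samples are dropped with a warning.
    """
    mask = matrix.missing_mask
    if policy == "drop_genes_with_missing":
        keep = ~mask.any(axis=1)
    elif policy == "pairwise_complete":
        keep = (~mask).sum(axis=1) >= 3
        if np.any(~keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} gene(s) with fewer than 3 "
                "observed samples",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown missing-value policy {policy!r}")
    idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        [matrix.gene_ids[i] for i in idx],
        list(matrix.sample_ids),
        matrix.values[idx].copy(),
    )


# ---------------------------------------------------------------------------
# distances


def correlation_distance(x, y, centered: bool = True) -> float:
    """1 - Pearson r over jointly observed entries (uncentred optional).

    Vectors with zero variance over the joint support get distance 1 (the
    uncorrelated convention), with a warning.  Fewer than 3 jointly observed
    entries raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("correlation distance needs >= 3 jointly observed entries")
    x, y = x[ok], y[ok]
    if centered:
        x = x - x.mean()
        y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        warnings.warn("zero-variance vector: distance set to 1", stacklevel=2)
        return 1.0
    return float(1.0 - np.dot(x, y) / (nx * ny))


class _DistanceEngine:
    """Vectorized gene-to-centroid distances with missing-value support.

    Genes are grouped by missing pattern; within a pattern the centred
    correlation distance is a dot product of unit-normalised rows, so a
    batch of K centroids costs one matrix product per pattern.
    """

    def __init__(self, values: np.ndarray, distance: str = "correlation"):
        if distance not in ("correlation", "correlation_uncentered", "euclidean"):
            raise ValueError(f"unknown distance {distance!r}")
        self.distance = distance
        self.values = values
        G, S = values.shape
        mask = np.isnan(values)
        if mask.any():
            pattern_ids, inverse = np.unique(mask, axis=0, return_inverse=True)
            self.patterns = [
                (np.flatnonzero(inverse == p), ~pattern_ids[p])
                for p in range(len(pattern_ids))
            ]
        else:
            self.patterns = [(np.arange(G), np.ones(S, dtype=bool))]
        if distance != "euclidean":
            centered = distance == "correlation"
            self._Z = np.empty_like(values)
            for rows, obs in self.patterns:
                sub = values[np.ix_(rows, np.flatnonzero(obs))]
                if centered:
                    sub = sub - sub.mean(axis=1, keepdims=True)
                norm = np.linalg.norm(sub, axis=1, keepdims=True)
                norm[norm == 0.0] = 1.0
                block = np.zeros((len(rows), values.shape[1]))
                block[:, np.flatnonzero(obs)] = sub / norm
                self._Z[rows] = block

    def dists(self, C: np.ndarray) -> np.ndarray:
        """(G, K) distances from every gene to every centroid row."""
        G = self.values.shape[0]
        K = C.shape[0]
        out = np.empty((G, K))
        if self.distance == "euclidean":
            for rows, obs in self.patterns:
                sub = self.values[np.ix_(rows, np.flatnonzero(obs))]
                Cc = C[:, np.flatnonzero(obs)]
                d2 = (
                    (sub**2).sum(axis=1)[:, None]
                    - 2.0 * sub @ Cc.T
                    + (Cc**2).sum(axis=1)[None, :]
                )
                # average over observed coordinates so sparser genes compare fairly
                out[rows] = np.sqrt(np.maximum(d2, 0.0) / obs.sum())
            return out
        centered = self.distance == "correlation"
        for rows, obs in self.patterns:
            cols = np.flatnonzero(obs)
            Cc = C[:, cols]
            if centered:
                Cc = Cc - Cc.mean(axis=1, keepdims=True)
            norm = np.linalg.norm(Cc, axis=1, keepdims=True)
            norm[norm == 0.0] = 1.0
            Chat = Cc / norm
            out[rows] = 1.0 - self._Z[np.ix_(rows, cols)] @ Chat.T
        return out

    def objective(self, C: np.ndarray) -> float:
        """Mean (over genes) distance to the nearest centroid."""
        return float(self.dists(C).min(axis=1).mean())


# ---------------------------------------------------------------------------
# GFA-driven K-means


def _centroid_domain(values: np.ndarray, K: int) -> np.ndarray:
    lo = np.nanmin(values, axis=0)
    hi = np.nanmax(values, axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    hi = np.where(hi > lo, hi, lo + 1.0)
    # tiny margin so boundary genes are interior
    box = np.stack([lo - 0.01 * span, hi + 0.01 * span], axis=1)
    return np.tile(box, (K, 1))


def _assign_average_fixed_point(
    C: np.ndarray, engine: "_DistanceEngine", filled: np.ndarray, max_iter: int = 20
) -> np.ndarray:
    """Push a centroid set to a fixed point of assign-and-average.

    Genes are assigned to their nearest centroid and each centroid is
    replaced by the mean profile of its genes, until assignments stop
    changing.  Empty clusters keep their previous centroid.
    """
    prev = None
    for _ in range(max_iter):
        a = engine.dists(C).argmin(axis=1)
        if prev is not None and np.array_equal(a, prev):
            break
        prev = a
        for k in range(C.shape[0]):
            members = filled[a == k]
            if members.shape[0] > 0:
                C[k] = members.mean(axis=0)
    return C


def _filled_rows(values: np.ndarray) -> np.ndarray:
    filled = values.copy()
    row_mean = np.nanmean(np.where(np.isnan(filled), np.nan, filled), axis=1)
    ind = np.where(np.isnan(filled))
    filled[ind] = np.take(row_mean, ind[0])
    return filled


def kmeans_gfa(
    matrix: ExpressionMatrix,
    K: int = 20,
    gfa_config: GFAConfig | None = None,
    max_runs: int = 1000,
    *,
    distance: str = "correlation",
    seed: int = 0,
    compute_ftest: bool = True,
) -> ClusteringResult:
    """Cluster genes into K groups by GFA-minimized K-means.

    Each dust encodes a flattened K x samples centroid matrix; its mass is
    the negative mean nearest-centroid distance over genes.  Initial dusts
    are seeded from k-means++ draws of actual gene profiles (prior
    knowledge: good centroids lie near data), then refined by the
    gravitation field dynamics.  Independent restarts continue until a
    restart fails to improve the best objective or ``max_runs`` restarts
    have been used.  Genes are assigned to their nearest centroid at the
    end; an empty cluster is re-seeded at the gene farthest from its
    centroid and assignment repeated once.
    """
    G, S = matrix.shape
    if K == 1:
        # degenerate case: the grand centroid (column means of observed cells)
        centroid = np.nanmean(matrix.values, axis=0)[None, :]
        engine = _DistanceEngine(matrix.values, distance)
        return ClusteringResult(
            assignments=np.zeros(G, dtype=int),
            centroids=centroid,
            mean_distance=engine.objective(centroid),
            per_sample_F=[],
            runs_used=0,
        )
    if K < 1 or K > G:
        raise ValueError("need 1 <= K <= number of genes")

    engine = _DistanceEngine(matrix.values, distance)
    filled = _filled_rows(matrix.values)
    seeding = (
        engine._Z if distance.startswith("correlation") else filled
    )

    def objective_batch(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.array(
            [engine.objective(x.reshape(K, S)) for x in X], dtype=float
        )

    domain = _centroid_domain(matrix.values, K)
    f = MassFunction(objective_batch, domain, sense="minimize", name="kmeans")

    def prior(rng: np.random.Generator, budget: int) -> np.ndarray:
        # prior knowledge: good centroid sets sit at fixed points of the
        # assign-and-average map, so each initial dust is a k-means++ draw of
        # gene profiles pushed to (or near) such a fixed point before GFA
        # takes over the global search among them.
        out = np.empty((budget, K * S))
        for b in range(budget):
            rs = int(rng.integers(0, 2**31 - 1))
            _, idx = kmeans_plusplus(seeding, n_clusters=K, random_state=rs)
            out[b] = _assign_average_fixed_point(
                filled[idx].copy(), engine, filled
            ).reshape(-1)
        return out

    if gfa_config is None:
        gfa_config = GFAConfig(
            n=12, m=6, s=4, max_epochs=30, stall_epochs=6, jitter_rate=0.0
        )

    best_val, best_C, runs_used = np.inf, None, 0
    for run in range(max_runs):
        cfg = GFAConfig(**{**gfa_config.__dict__, "seed": seed + run})
        res = optimize(f, cfg, prior_density=prior)
        runs_used += 1
        if res.best_value < best_val:
            best_val, best_C = res.best_value, res.best_position.reshape(K, S)
        else:
            break  # the objective stopped improving

    d = engine.dists(best_C)
    assignments = np.argmin(d, axis=1)
    reseeded = 0
    empty = [k for k in range(K) if not np.any(assignments == k)]
    if empty:
        nearest = d[np.arange(G), assignments]
        order = np.argsort(-nearest)
        for j, k in enumerate(empty):
            best_C[k] = filled[order[j]]
            reseeded += 1
        warnings.warn(f"re-seeded {reseeded} empty cluster(s)", stacklevel=2)
        d = engine.dists(best_C)
        assignments = np.argmin(d, axis=1)
    mean_distance = float(d[np.arange(G), assignments].mean())

    result = ClusteringResult(
        assignments=assignments,
        centroids=best_C,
        mean_distance=mean_distance,
        runs_used=runs_used,
        reseeded_clusters=reseeded,
    )
    if compute_ftest:
        try:
            result.per_sample_F = evaluate_ftest(matrix, result)
        except ValueError:
            result.per_sample_F = []
    return result


# ---------------------------------------------------------------------------
# evaluation


def evaluate_ftest(matrix: ExpressionMatrix, result_or_assignments) -> list[tuple[float, float]]:
    """Per-sample one-way ANOVA across the clusters.

    For each sample (column) the gene expression values are grouped by
    cluster and the F statistic asks whether cluster means differ within
    that sample.  Requires at least two non-empty clusters and positive
    within-group degrees of freedom.
    """
    if isinstance(result_or_assignments, ClusteringResult):
        assignments = result_or_assignments.assignments
    else:
        assignments = np.asarray(result_or_assignments, dtype=int)
    labels = np.unique(assignments)
    if len(labels) < 2:
        raise ValueError("F test needs at least 2 non-empty clusters")
    n_obs = len(assignments)
    if n_obs - len(labels) <= 0:
        raise ValueError("no within-group degrees of freedom")
    out = []
    for j in range(matrix.shape[1]):
        col = matrix.values[:, j]
        groups = [
            col[(assignments == k) & ~np.isnan(col)] for k in labels
        ]
        groups = [g for g in groups if g.size > 0]
        if len(groups) < 2:
            raise ValueError(f"sample {j}: fewer than 2 clusters with data")
        F, p = stats.f_oneway(*groups)
        out.append((float(F), float(p)))
    return out


def write_ftest_report(matrix: ExpressionMatrix, result: ClusteringResult, path) -> None:
    """Tab-delimited per-sample F/p table with a Bonferroni column."""
    S = len(matrix.sample_ids)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample\tF\tp\tp_bonferroni\n")
        for sid, (F, p) in zip(matrix.sample_ids, result.per_sample_F):
            fh.write(f"{sid}\t{F:.6g}\t{p:.6g}\t{min(1.0, p * S):.6g}\n")


# ---------------------------------------------------------------------------
# CDT output (Cluster 3.0 / TreeView dialect)


def _order_genes(matrix: ExpressionMatrix, result: ClusteringResult) -> list[int]:
    return sorted(
        range(len(matrix.gene_ids)),
        key=lambda i: (int(result.assignments[i]), matrix.gene_ids[i]),
    )


def write_cdt(matrix: ExpressionMatrix, result: ClusteringResult, path) -> None:
    """Write a clustered-data-table file.

    Layout: header row GID / ORF / NAME / CLUSTER / GWEIGHT / sample IDs, an
    EWEIGHT row, then one row per gene ordered by cluster and gene ID, with
    the cluster label carried in the CLUSTER column and missing cells left
    empty.
    """
    order = _order_genes(matrix, result)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(["GID", "ORF", "NAME", "CLUSTER", "GWEIGHT"] + list(matrix.sample_ids)) + "\n")
        fh.write("\t".join(["EWEIGHT", "", "", "", ""] + ["1"] * len(matrix.sample_ids)) + "\n")
        for rank, i in enumerate(order, start=1):
            gid = matrix.gene_ids[i]
            row = matrix.values[i]
            cells = ["" if np.isnan(v) else f"{v:.6g}" for v in row]
            fh.write(
                "\t".join(
                    [f"GENE{rank}X", gid, gid, str(int(result.assignments[i])), "1"]
                    + cells
                )
                + "\n"
            )


def read_cdt(path):
    """Read back a CDT file; returns (ExpressionMatrix, assignments array)."""
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    header = lines[0].split("\t")
    sample_ids = header[5:]
    gene_ids, rows, clusters = [], [], []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if fields[0] == "EWEIGHT":
            continue
        gene_ids.append(fields[1])
        clusters.append(int(fields[3]))
        rows.append(
            [np.nan if c.strip() == "" else float(c) for c in fields[5:]]
        )
    return (
        ExpressionMatrix(gene_ids, sample_ids, np.asarray(rows, dtype=float)),
        np.asarray(clusters, dtype=int),
    )


def write_assignments(matrix: ExpressionMatrix, result: ClusteringResult, path) -> None:
    """Tab-delimited gene -> cluster table (input gene order)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene\tcluster\n")
        for gid, k in zip(matrix.gene_ids, result.assignments):
            fh.write(f"{gid}\t{int(k)}\n")
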
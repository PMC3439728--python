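"""Drug-drug distances between topic distributions.

A drug's signature is its posterior topic distribution P(z|d).  Discrepancy
between two drugs is the Kullback-Leibler divergence (natural log)

    D_KL(P || Q) = sum_i P(i) ln(P(i) / Q(i))

symmetrized by averaging both directions.  The smoothed LDA estimates are
strictly positive, so no zero-handling heuristics are applied; distributions
with non-positive entries are rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lda import TopicModelFit


def _check_distribution(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if (p <= 0).any():
        raise ValueError(f"{name} must be strictly positive")
    return p


def kl_divergence(p, q) -> float:
    """K-L divergence in nats; >= 0, zero iff the distributions coincide."""
    p = _check_distribution(p, "P")
    q = _check_distribution(q, "Q")
    if p.shape != q.shape:
        raise ValueError("P and Q must have equal length")
    return float(np.sum(p * np.log(p / q)))


def symmetrized_distance(p, q) -> float:
    """Mean of the two K-L directions; symmetric, zero iff P = Q."""
    return 0.5 * (kl_divergence(p, q) + kl_divergence(q, p))


@dataclass(frozen=True)
class DistanceMatrix:
    drug_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        D = len(self.drug_ids)
        if v.shape != (D, D):
            raise ValueError("distance matrix shape mismatch")
        if not np.isfinite(v).all():
            raise ValueError("non-finite distances")
        if np.abs(np.diagonal(v)).max(initial=0.0) > 0:
            raise ValueError("diagonal must be zero")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("matrix must be symmetric")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class NearestNeighborTable:
    """Per query drug, its nearest other drug and their distance."""

    rows: list[tuple[str, str, float]]  # (drug_id, neighbor_id, distance)

    def as_dict(self) -> dict[str, tuple[str, float]]:
        return {d: (n, x) for d, n, x in self.rows}


def pairwise_from_theta(theta: np.ndarray, drug_ids: list[str]) -> DistanceMatrix:
    """Symmetrized K-L distances between all rows of a theta matrix."""
    theta = np.asarray(theta, dtype=float)
    if (theta <= 0).any():
        raise ValueError("theta must be strictly positive")
    logt = np.log(theta)
    entropy_term = (theta * logt).sum(axis=1)  # sum_k P ln P per drug
    cross = theta @ logt.T  # [i, j] = sum_k P_i ln P_j
    kl = entropy_term[:, None] - cross
    d = 0.5 * (kl + kl.T)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # remove rounding asymmetry
    return DistanceMatrix(list(drug_ids), np.maximum(d, 0.0))


def pairwise_distances(fit: TopicModelFit) -> DistanceMatrix:
    """Distance matrix over the drugs of a fitted topic model."""
    return pairwise_from_theta(fit.theta, fit.drug_ids)


def nearest_neighbors(dist: DistanceMatrix) -> NearestNeighborTable:
    """Row-wise argmin over off-diagonal entries; ties go to the smaller id.

    The relation is directional: A's nearest neighbor need not have A as its
    own nearest neighbor.
    """
    D = len(dist.drug_ids)
    if D < 2:
        raise ValueError("need at least 2 drugs")
    rows: list[tuple[str, str, float]] = []
    for i, did in enumerate(dist.drug_ids):
        row = dist.values[i]
        others = [j for j in range(D) if j != i]
        best = min(others, key=lambda j: (row[j], dist.drug_ids[j]))
        rows.append((did, dist.drug_ids[best], float(row[best])))
    return NearestNeighborTable(rows)
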
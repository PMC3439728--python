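"""Topic-count selection from the PCA eigenvalue spectrum.

The number of latent topics is chosen by balancing the variance retained by
the leading ``k`` principal components of the drug-term matrix against the
variance discarded.  With eigenvalues ``e_1 >= ... >= e_n`` of the sample
covariance and a penalty ``lambda``, the information loss at ``k`` is

    loss(k) = | sum_i e_i  -  lambda * sum_{i>k} e_i |

and ``k*`` minimizes it over ``k in [1, n-1]``.  For the default
``lambda = 2`` this picks the split where the head and tail of the spectrum
carry equal variance (head mass closest to 50%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import DrugTermMatrix


@dataclass(frozen=True)
class EigenSpectrum:
    """Non-increasing, non-negative eigenvalues of the sample covariance."""

    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.eigenvalues, dtype=float)
        if e.ndim != 1 or e.size == 0:
            raise ValueError("eigenvalues must be a non-empty 1-D array")
        if (np.diff(e) > 1e-12).any():
            raise ValueError("eigenvalues must be sorted non-increasing")
        if (e < -1e-8).any():
            raise ValueError("eigenvalue significantly negative")
        object.__setattr__(self, "eigenvalues", np.clip(e, 0.0, None))

    @property
    def n(self) -> int:
        return int(self.eigenvalues.size)


@dataclass(frozen=True)
class SelectionResult:
    k_star: int
    loss_curve: dict[int, float]
    lambda_: float


def compute_spectrum(matrix: DrugTermMatrix, binarize: bool = False) -> EigenSpectrum:
    """PCA eigenvalues of the (mean-centered) drug-term matrix.

    Eigenvalues of the sample covariance with divisor ``D - 1``, i.e. squared
    singular values of the centered matrix over ``D - 1``; the leading
    ``min(D - 1, V)`` values are retained.
    """
    if matrix.n_drugs < 2 or matrix.n_terms < 2:
        raise ValueError("need at least 2 drugs and 2 terms for PCA")
    X = (matrix.binarized() if binarize else matrix).counts.astype(float)
    Xc = X - X.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(Xc, compute_uv=False)
    e = (sv**2) / (matrix.n_drugs - 1)
    n = min(matrix.n_drugs - 1, matrix.n_terms)
    return EigenSpectrum(np.sort(e)[::-1][:n])


def information_loss(spectrum: EigenSpectrum, k: int, lambda_: float = 2.0) -> float:
    """| total spectrum mass - lambda * tail mass beyond k |."""
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    n = spectrum.n
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    e = spectrum.eigenvalues
    return float(abs(e.sum() - lambda_ * e[k:].sum()))


def choose_k(spectrum: EigenSpectrum, lambda_: float = 2.0) -> SelectionResult:
    """Minimize the information loss over all admissible k.

    Ties are broken toward the smallest k, so the selection is deterministic.
    """
    if spectrum.n < 2:
        raise ValueError("need a spectrum of at least 2 eigenvalues")
    curve = {
        k: information_loss(spectrum, k, lambda_) for k in range(1, spectrum.n)
    }
    k_star = min(curve, key=lambda k: (curve[k], k))
    return SelectionResult(k_star=k_star, loss_curve=curve, lambda_=lambda_)
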
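"""Principal Co-ordinates Analysis (classical metric scaling).

Embeds a distance matrix into Euclidean axes ordered by explained variation:
Gower double-centering of ``-0.5 * D**2``, eigendecomposition, axis *i*
coordinates ``eigenvector_i * sqrt(lambda_i)`` for positive eigenvalues.
Negative eigenvalues (non-Euclidean input) are discarded from both the
coordinates and the variation denominator, with their count reported —
standard Gower practice.  Per-axis sign is fixed by making the
largest-magnitude loading positive so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import DistanceMatrix, ValidationError

__all__ = ["PCOResult", "pco"]


@dataclass
class PCOResult:
    labels: list[str]
    coordinates: np.ndarray  # n x k, k = kept positive axes
    eigenvalues: np.ndarray  # all positive eigenvalues, descending
    percent_variation: np.ndarray  # per kept axis, of the positive-eigenvalue total
    n_negative_discarded: int

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def axis(self, i: int) -> np.ndarray:
        return self.coordinates[:, i]


def pco(m: DistanceMatrix, k: int | None = None) -> PCOResult:
    """Classical scaling of a symmetric zero-diagonal distance matrix.

    *k* caps the number of returned axes (default: all positive-eigenvalue
    axes).  Eigenvalues at numerical zero (|lambda| <= 1e-9 * max lambda)
    are treated as zero, not negative.
    """
    n = m.n
    if n < 2:
        raise ValidationError("PCO needs at least 2 objects")
    D2 = np.asarray(m.values, dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = 1e-9 * max(abs(eigval[0]), 1.0)
    positive = eigval > tol
    negative = eigval < -tol
    if not positive.any():
        raise ValidationError("degenerate configuration: no positive eigenvalue")

    lam = eigval[positive]
    vec = eigvec[:, positive]
    coords = vec * np.sqrt(lam)[None, :]
    # reproducible per-axis sign: largest-magnitude loading positive
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    percent = 100.0 * lam / lam.sum()
    if k is not None:
        coords = coords[:, :k]
        percent = percent[:k]
    return PCOResult(
        labels=list(m.labels),
        coordinates=coords,
        eigenvalues=lam,
        percent_variation=percent,
        n_negative_discarded=int(negative.sum()),
    )
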
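"""Compositional conversion of component weights and log-ratio transforms.

The absolute scale of ICA weights is not meaningful, but within a spot the
ratio of positive weights tracks cell-type ratios.  Each spot's negative
weights are zeroed and the positive ones divided by their sum, giving a
relative-abundance row on the simplex; entries below a high-pass threshold
are zeroed as noise and the row re-closed.  Spots with no positive signal
become all-zero rows and are flagged.

For evaluation on the simplex, compositions are mapped to unconstrained
coordinates with the isometric log-ratio (ILR) transform under the fixed
Helmert-contrast orthonormal basis:

    ilr_A(x) = sqrt(A / (A + 1)) * ln( g(x_1..x_A) / x_{A+1} ),  A = 1..D-1

where g is the geometric mean.  Zeros are replaced by a small constant and
the row re-closed before transforming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .decomposition import Decomposition

logger = logging.getLogger("spotica")

DEFAULT_HIGH_PASS = 0.05
ROW_SUM_TOL = 1e-12


@dataclass
class CompositionMatrix:
    """Per-spot relative abundances over components or cell types.

    Every row sums to 1 (within 1e-12) or is exactly all-zero, meaning the
    spot carried no positive signal.
    """

    values: np.ndarray  # (spots, parts)
    part_ids: list
    spot_ids: np.ndarray | None = None
    high_pass: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.part_ids):
            raise ValueError("values shape does not match part_ids")
        if np.any(self.values < 0) or np.any(self.values > 1 + ROW_SUM_TOL):
            raise ValueError("composition values must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0)
        if not np.all(ok):
            raise ValueError("rows must sum to 1 or be all-zero")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    def zero_rows(self) -> np.ndarray:
        """Boolean mask of flagged all-zero spots (no positive signal)."""
        return self.values.sum(axis=1) == 0


def _close(rows: np.ndarray) -> np.ndarray:
    sums = rows.sum(axis=1, keepdims=True)
    out = np.zeros_like(rows)
    nz = sums[:, 0] > 0
    out[nz] = rows[nz] / sums[nz]
    return out


def to_composition(
    d: Decomposition,
    components: list | None = None,
    high_pass: float = DEFAULT_HIGH_PASS,
) -> CompositionMatrix:
    """Relative abundance of positive component weights per spot.

    ``components`` defaults to the kept, use-flagged components.  Per spot the
    negative weights are zeroed, positive weights divided by the positive
    total, entries below ``high_pass`` zeroed and the row re-closed.
    """
    if components is None:
        components = d.selected()
    if not components:
        raise ValueError("empty component list")
    idx = [d.index_of(c) for c in components]
    for c, i in zip(components, idx):
        if d.superseded[i] or not d.kept[i]:
            raise ValueError(f"component {c} is not in the kept set")
    W = np.maximum(d.weights[:, idx], 0.0)
    comp = _close(W)
    if high_pass > 0:
        comp[comp < high_pass] = 0.0
        comp = _close(comp)
    n_flagged = int((comp.sum(axis=1) == 0).sum())
    if n_flagged:
        logger.info("%d spots have no positive weight; flagged as all-zero", n_flagged)
    return CompositionMatrix(
        values=comp,
        part_ids=list(components),
        spot_ids=d.spot_ids,
        high_pass=high_pass,
    )


def ilr_basis(d: int) -> np.ndarray:
    """Helmert-contrast orthonormal ILR basis, shape (d-1, d) in CLR space."""
    if d < 2:
        raise ValueError("ILR needs at least 2 parts")
    V = np.zeros((d - 1, d))
    for a in range(1, d):
        V[a - 1, :a] = 1.0 / a
        V[a - 1, a] = -1.0
        V[a - 1] *= np.sqrt(a / (a + 1.0))
    return V


def ilr_transform(
    c: CompositionMatrix | np.ndarray,
    zero_replacement: float = 1e-6,
) -> np.ndarray:
    """Map compositions to (parts - 1) ILR coordinates.

    Zeros are replaced by ``zero_replacement`` and rows re-closed first.
    All-zero rows are not valid compositions: exclude them upstream
    (an exception is raised here if any are present).
    """
    X = c.values if isinstance(c, CompositionMatrix) else np.asarray(c, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if np.any(X.sum(axis=1) == 0):
        raise ValueError("all-zero rows cannot be ILR-transformed; exclude and report them")
    X = _close(np.where(X <= 0, zero_replacement, X))
    logX = np.log(X)
    return logX @ ilr_basis(X.shape[1]).T


def ilr_inverse(Y: np.ndarray, d: int | None = None) -> np.ndarray:
    """Inverse ILR back onto the simplex."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    d = Y.shape[1] + 1 if d is None else d
    logX = Y @ ilr_basis(d)
    X = np.exp(logX)
    return _close(X)
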
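"""Variance-stabilizing normalization of spot x gene counts.

Counts are modelled per gene as negative binomial with mean tied to the
spot's sequencing depth (an offset model: mu_ig = n_i * p_g, where n_i is the
spot total and p_g the gene's pooled fraction of all counts) and a per-gene
overdispersion theta_g.  The output is the matrix of Pearson residuals

    z_ig = (x_ig - mu_ig) / sqrt(mu_ig + mu_ig^2 / theta_g)

clipped to +/- sqrt(n_spots).  theta_g is estimated per gene by method of
moments and regularized by Gaussian-kernel regression of log theta against
log10 gene mean, so that genes of similar abundance share their
overdispersion estimate.  All genes detected in at least ``min_spots_per_gene``
spots are kept — there is no highly-variable-gene selection, because the
downstream ICA consumes the full transcriptome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import SpotMatrix

logger = logging.getLogger("spotica")

THETA_FLOOR = 1e-4
THETA_CEIL = 1e8


@dataclass
class NormalizedMatrix:
    """Pearson residuals (spots x genes) plus the per-gene model parameters."""

    residuals: np.ndarray
    gene_ids: np.ndarray
    spot_ids: np.ndarray | None
    model_params: pd.DataFrame  # index gene, columns: mean, theta_raw, theta
    clip_bound: float

    @property
    def n_spots(self) -> int:
        return self.residuals.shape[0]

    @property
    def n_genes(self) -> int:
        return self.residuals.shape[1]


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread == 0:
        return 1.0
    return 0.9 * spread * n ** (-1 / 5)


def _smooth_theta(log10_mean: np.ndarray, log_theta: np.ndarray) -> np.ndarray:
    """Gaussian-kernel regression of log theta on log10 gene mean."""
    h = _silverman_bandwidth(log10_mean)
    # pairwise kernel; fall back to chunks if the gene set is very large
    out = np.empty_like(log_theta)
    chunk = max(1, int(2e7 // max(len(log10_mean), 1)))
    for start in range(0, len(log10_mean), chunk):
        sl = slice(start, start + chunk)
        w = np.exp(-0.5 * ((log10_mean[sl, None] - log10_mean[None, :]) / h) ** 2)
        out[sl] = (w @ log_theta) / w.sum(axis=1)
    return out


def normalize(
    sm: SpotMatrix,
    min_spots_per_gene: int = 5,
    clip: float | str = "sqrt_n",
) -> NormalizedMatrix:
    """Compute clipped NB Pearson residuals for all retained genes.

    Parameters
    ----------
    sm
        Raw counts.
    min_spots_per_gene
        Genes detected in fewer spots are dropped (set to 1 to keep every
        expressed gene).
    clip
        ``"sqrt_n"`` clips residuals at +/- sqrt(n_spots); a float clips at
        that absolute value.
    """
    X = sp.csr_matrix(sm.counts, dtype=np.float64)
    n_spots, _ = X.shape
    if n_spots < 2:
        raise ValueError("normalization needs at least 2 spots (per-spot depth regression)")
    if X.nnz == 0:
        raise ValueError("all-zero count matrix")

    det = np.asarray((X > 0).sum(axis=0)).ravel()
    gene_tot = np.asarray(X.sum(axis=0)).ravel()
    keep = (det >= min_spots_per_gene) & (gene_tot > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d genes detected in < %d spots", n_dropped, min_spots_per_gene)
    if not keep.any():
        raise ValueError("no genes pass the min_spots filter")
    X = X[:, keep]
    gene_ids = sm.gene_ids[keep]
    gene_tot = gene_tot[keep]

    n_i = np.asarray(X.sum(axis=1)).ravel()  # spot depths
    total = n_i.sum()
    p_g = gene_tot / total
    mu = np.outer(n_i, p_g)  # dense spots x genes
    Xd = np.asarray(X.todense())

    # method-of-moments overdispersion: E[(x-mu)^2 - mu] = mu^2 / theta
    resid2 = (Xd - mu) ** 2
    num = (mu**2).sum(axis=0)
    den = (resid2 - mu).sum(axis=0)
    theta_raw = np.where(den > 0, num / np.maximum(den, 1e-300), THETA_CEIL)
    theta_raw = np.clip(theta_raw, THETA_FLOOR, THETA_CEIL)

    gene_mean = gene_tot / n_spots
    theta = np.exp(
        _smooth_theta(np.log10(gene_mean), np.log(theta_raw))
    )
    theta = np.clip(theta, THETA_FLOOR, THETA_CEIL)

    denom = np.sqrt(mu + mu**2 / theta[None, :])
    z = (Xd - mu) / denom
    clip_bound = float(np.sqrt(n_spots)) if clip == "sqrt_n" else float(clip)
    np.clip(z, -clip_bound, clip_bound, out=z)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite residuals produced")

    params = pd.DataFrame(
        {"mean": gene_mean, "theta_raw": theta_raw, "theta": theta},
        index=pd.Index(gene_ids, name="gene"),
    )
    return NormalizedMatrix(
        residuals=z,
        gene_ids=gene_ids,
        spot_ids=sm.spot_ids,
        model_params=params,
        clip_bound=clip_bound,
    )
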
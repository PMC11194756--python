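"""Blind source separation of normalized spot x gene data.

The normalized matrix is decomposed as X ~ A . S, where the rows of S
(k x genes) are statistically independent, unit-variance gene-loading vectors
("sources", the transcriptional signatures) and A (spots x k) holds the
per-spot mixing weights.  Components are then curated:

* kurtosis filter — only leptokurtic components (plain kurtosis m4/m2^2 > 3,
  i.e. heavier-tailed than a Gaussian) are retained, since a sparse loading
  distribution is what makes a component interpretable;
* sign correction — each component is flipped so the side of its loading
  distribution with the largest absolute value is positive, making positive
  weights mean presence of the signal;
* contributor genes — the genes whose loading z-score magnitude is >= 3
  define the component's signature;
* merging — over-decomposed components sharing an annotation can be
  recombined by simple addition of their weight columns and loading rows,
  which leaves the reconstruction A . S unchanged.

Components are only ever flagged, never deleted, so every curation step is
reversible.  fastica is the reference algorithm; infomax and jade are
alternative backends behind the same contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA, PCA
from sklearn.exceptions import ConvergenceWarning

from .preprocess import NormalizedMatrix

logger = logging.getLogger("spotica")

DEFAULT_K = 100
DEFAULT_MAX_ITER = 600
DEFAULT_KURTOSIS_THRESHOLD = 3.0
DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_SEED = 0


@dataclass
class Decomposition:
    """Paired gene-loading and spot-weight matrices with curation flags."""

    sources: np.ndarray  # (k, genes)
    weights: np.ndarray  # (spots, k)
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    component_ids: list
    kurtosis: np.ndarray  # per component, NaN until computed
    kept: np.ndarray  # bool
    sign_flipped: np.ndarray  # bool
    superseded: np.ndarray  # bool, True for components replaced by a merge
    annotations: dict  # component id -> {label, category, use}
    k_requested: int
    seed: int
    method: str
    max_iter: int
    converged: bool = True
    spot_mean: np.ndarray | None = None  # per-spot offset removed before ICA
    derived: np.ndarray = None  # bool, True for merge products (not part of the factorization)

    def __post_init__(self):
        if self.derived is None:
            self.derived = np.zeros(self.sources.shape[0], dtype=bool)

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def index_of(self, component_id) -> int:
        return self.component_ids.index(component_id)

    def active_mask(self) -> np.ndarray:
        return ~self.superseded

    def selected(self, use_annotations: bool = True) -> list:
        """Component ids that are kept, not superseded, and flagged use=True."""
        out = []
        for i, cid in enumerate(self.component_ids):
            if self.superseded[i] or not self.kept[i]:
                continue
            if use_annotations and not self.annotations.get(cid, {}).get("use", True):
                continue
            out.append(cid)
        return out

    def reconstruction(self) -> np.ndarray:
        """A . S over the original factorization (plus the removed offset).

        Merge products are annotation-level regroupings, not part of the
        factorization, so the reconstruction always uses the original
        components (superseded or not) and is invariant under merging.
        """
        m = ~self.derived
        rec = self.weights[:, m] @ self.sources[m]
        if self.spot_mean is not None:
            rec = rec + self.spot_mean[:, None]
        return rec


# ---------------------------------------------------------------------------
# ICA backends (operate on whitened data Z, shape (k, n_obs))
# ---------------------------------------------------------------------------


def _infomax_unmix(Z: np.ndarray, max_iter: int, rng: np.random.Generator) -> np.ndarray:
    """Extended-infomax natural-gradient unmixing on whitened data."""
    k, n = Z.shape
    W = np.eye(k)
    lrate = 0.01 / np.log(max(k, 2)) ** 2
    block = max(8, int(np.floor(np.sqrt(n / 3.0))))
    signs = np.ones(k)  # +1 super-Gaussian, -1 sub-Gaussian
    for _ in range(max_iter):
        perm = rng.permutation(n)
        for start in range(0, n - block + 1, block):
            zb = Z[:, perm[start : start + block]]
            u = W @ zb
            y = np.tanh(u)
            grad = (block * np.eye(k) - (signs[:, None] * y) @ u.T - u @ u.T) / block
            W += lrate * grad @ W
            if not np.all(np.isfinite(W)):
                raise FloatingPointError("infomax diverged; lower the learning rate")
        # adapt source signs from kurtosis of current estimates
        u = W @ Z
        m2 = (u**2).mean(axis=1)
        m4 = (u**4).mean(axis=1)
        signs = np.sign(m4 / m2**2 - 3.0)
        signs[signs == 0] = 1.0
    return W


def _jade_unmix(Z: np.ndarray, max_iter: int) -> np.ndarray:
    """JADE: joint approximate diagonalization of 4th-order cumulant matrices."""
    k, n = Z.shape
    # parallel cumulant-matrix estimation
    cms = []
    R = np.eye(k)
    for p in range(k):
        for q in range(p + 1):
            zp, zq = Z[p], Z[q]
            M = (Z * zp * zq) @ Z.T / n
            if p == q:
                M -= R + 2 * np.outer(R[:, p], R[:, p])
            else:
                M -= np.outer(R[:, p], R[:, q]) + np.outer(R[:, q], R[:, p])
                M *= np.sqrt(2)
            cms.append(M)
    V = np.eye(k)
    threshold = 1e-8 / np.sqrt(n)
    for _ in range(max_iter):
        rotated = False
        for p in range(k - 1):
            for q in range(p + 1, k):
                g = np.array(
                    [[M[p, p] - M[q, q], M[p, q] + M[q, p]] for M in cms]
                )
                gg = g.T @ g
                ton, toff = gg[0, 0] - gg[1, 1], gg[0, 1] + gg[1, 0]
                theta = 0.5 * np.arctan2(toff, ton + np.sqrt(ton**2 + toff**2))
                if abs(np.sin(theta)) > threshold:
                    rotated = True
                    c, s = np.cos(theta), np.sin(theta)
                    G = np.array([[c, -s], [s, c]])
                    pair = [p, q]
                    for M in cms:
                        M[:, pair] = M[:, pair] @ G
                        M[pair, :] = G.T @ M[pair, :]
                    V[:, pair] = V[:, pair] @ G
        if not rotated:
            break
    return V.T


def run_ica(
    nm: NormalizedMatrix,
    k: int = DEFAULT_K,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = DEFAULT_SEED,
    method: str = "fastica",
) -> Decomposition:
    """Decompose the normalized matrix into k independent components.

    The data are whitened by PCA to k dimensions; the chosen algorithm then
    rotates the whitened basis towards independence.  Sources are the
    unit-variance gene-loading vectors; the mixing weights live on the spot
    side.  The run is deterministic for a given seed.  Non-convergence within
    ``max_iter`` is recorded (``converged=False``) and the partial result
    returned.
    """
    X = np.asarray(nm.residuals, dtype=np.float64)
    n_spots, n_genes = X.shape
    if k > min(n_spots, n_genes):
        raise ValueError(
            f"k={k} exceeds min(spots, genes)={min(n_spots, n_genes)}; choose a smaller k"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("normalized matrix contains non-finite values")
    # genes play the role of observations: sources are vectors over genes
    Xt = X.T  # (genes, spots)
    spot_mean = Xt.mean(axis=0)
    converged = True
    if method == "fastica":
        ica = FastICA(
            n_components=k,
            max_iter=max_iter,
            random_state=seed,
            whiten="unit-variance",
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                S_genes = ica.fit_transform(Xt)  # (genes, k)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"whitening failed at k={k}; the data rank is likely smaller — "
                    f"choose a smaller k ({exc})"
                ) from exc
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                converged = False
                logger.warning("ICA did not converge in %d iterations; partial result kept", max_iter)
        A = ica.mixing_  # (spots, k)
    elif method in ("infomax", "jade"):
        Xc = Xt - spot_mean[None, :]
        pca = PCA(n_components=k, whiten=True, random_state=seed)
        try:
            Z = pca.fit_transform(Xc).T  # (k, genes), unit variance rows
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"whitening failed at k={k}; choose a smaller k") from exc
        if np.any(pca.explained_variance_ < 1e-12):
            raise ValueError(f"data rank < k={k}; choose a smaller k")
        rng = np.random.default_rng(seed)
        if method == "infomax":
            W = _infomax_unmix(np.ascontiguousarray(Z), max_iter, rng)
        else:
            W = _jade_unmix(np.ascontiguousarray(Z.copy()), max_iter)
        U = W @ Z  # (k, genes) sources, ~unit variance
        sd = U.std(axis=1)
        sd[sd == 0] = 1.0
        S_genes = (U / sd[:, None]).T
        # least-squares mixing so that A @ S reconstructs the centered data
        A, *_ = np.linalg.lstsq(S_genes, Xc, rcond=None)
        A = A.T  # (spots, k)... lstsq solved S_genes @ A_T = Xc
    else:
        raise ValueError(f"unknown ICA method {method!r}")

    S = S_genes.T  # (k, genes)
    k_eff = S.shape[0]
    component_ids = [f"IC{i + 1}" for i in range(k_eff)]
    d = Decomposition(
        sources=S,
        weights=A,
        gene_ids=np.asarray(nm.gene_ids, dtype=object),
        spot_ids=np.asarray(nm.spot_ids, dtype=object)
        if nm.spot_ids is not None
        else np.array([f"spot{i}" for i in range(n_spots)], dtype=object),
        component_ids=component_ids,
        kurtosis=np.full(k_eff, np.nan),
        kept=np.ones(k_eff, dtype=bool),
        sign_flipped=np.zeros(k_eff, dtype=bool),
        superseded=np.zeros(k_eff, dtype=bool),
        annotations={cid: {"label": "", "category": "", "use": True} for cid in component_ids},
        k_requested=k,
        seed=seed,
        method=method,
        max_iter=max_iter,
        converged=converged,
        spot_mean=spot_mean,
    )
    component_kurtosis(d)
    return d


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------


def _plain_kurtosis(v: np.ndarray) -> float:
    """Non-excess kurtosis m4/m2^2 with population moments (Gaussian -> 3)."""
    v = np.asarray(v, dtype=float)
    c = v - v.mean()
    m2 = np.mean(c**2)
    if m2 == 0:
        return np.nan
    return float(np.mean(c**4) / m2**2)


def component_kurtosis(d: Decomposition) -> np.ndarray:
    """Compute and store plain kurtosis of each component's gene loadings."""
    out = np.empty(d.n_components)
    for i in range(d.n_components):
        kv = _plain_kurtosis(d.sources[i])
        out[i] = kv
        if np.isnan(kv):
            d.kept[i] = False
            logger.warning("component %s has zero loading variance; dropped", d.component_ids[i])
    d.kurtosis = out
    return out


def filter_by_kurtosis(
    d: Decomposition, threshold: float = DEFAULT_KURTOSIS_THRESHOLD
) -> Decomposition:
    """Flag components with kurtosis <= threshold as not kept (reversible)."""
    if np.all(np.isnan(d.kurtosis)):
        raise ValueError("kurtosis not computed")
    with np.errstate(invalid="ignore"):
        d.kept = np.asarray(d.kurtosis > threshold) & ~np.isnan(d.kurtosis)
    if not d.kept[d.active_mask()].any():
        raise ValueError("no components retained at this kurtosis threshold")
    return d


def sign_correct(d: Decomposition) -> Decomposition:
    """Give the heavy side of each loading distribution the positive sign.

    If the loading minimum exceeds the maximum in absolute value, the source
    row and its paired weight column are both negated (A . S unchanged).
    Exact ties keep the component as-is.  Idempotent.
    """
    for i in range(d.n_components):
        if d.superseded[i]:
            continue
        row = d.sources[i]
        if abs(row.min()) > abs(row.max()):
            d.sources[i] = -row
            d.weights[:, i] = -d.weights[:, i]
            d.sign_flipped[i] = ~d.sign_flipped[i]
    return d


def contributor_genes(
    d: Decomposition, z_threshold: float = DEFAULT_Z_THRESHOLD
) -> dict:
    """Per-component contributor genes: loading |z-score| >= threshold.

    Returns ``{component_id: [(gene, loading, z), ...]}`` ordered by |z|
    descending.  z-scores use the population standard deviation of the
    component's own loading vector.
    """
    out: dict = {}
    for i, cid in enumerate(d.component_ids):
        if d.superseded[i]:
            continue
        row = d.sources[i]
        sd = row.std()
        if sd == 0:
            logger.warning("component %s has constant loadings; no contributors", cid)
            out[cid] = []
            continue
        z = (row - row.mean()) / sd
        sel = np.where(np.abs(z) >= z_threshold)[0]
        order = sel[np.argsort(-np.abs(z[sel]), kind="stable")]
        out[cid] = [(d.gene_ids[j], float(row[j]), float(z[j])) for j in order]
    return out


def merge_components(d: Decomposition, groups: dict) -> Decomposition:
    """Recombine over-decomposed components by addition.

    ``groups`` maps a new label to a list of component ids.  The merged
    component's weight column is the elementwise sum of the member columns and
    its loading row the sum of the member rows.  Members are marked superseded
    and the merged component is flagged derived: the reconstruction stays
    defined over the original factorization, hence unchanged by merging.
    """
    seen: set = set()
    for label, members in groups.items():
        for cid in members:
            if cid in seen:
                raise ValueError(f"component {cid} appears in more than one merge group")
            seen.add(cid)
            i = d.index_of(cid)
            if d.superseded[i]:
                raise ValueError(f"component {cid} is already superseded")
            if not d.kept[i]:
                raise ValueError(f"component {cid} is not kept; merge groups must reference kept components")
    for label, members in groups.items():
        idx = [d.index_of(cid) for cid in members]
        new_source = d.sources[idx].sum(axis=0)
        new_weight = d.weights[:, idx].sum(axis=1)
        d.sources = np.vstack([d.sources, new_source[None, :]])
        d.weights = np.column_stack([d.weights, new_weight])
        d.superseded[idx] = True
        d.superseded = np.append(d.superseded, False)
        d.derived = np.append(d.derived, True)
        d.kept = np.append(d.kept, True)
        d.sign_flipped = np.append(d.sign_flipped, False)
        d.kurtosis = np.append(d.kurtosis, _plain_kurtosis(new_source))
        new_id = label
        if new_id in d.component_ids:
            raise ValueError(f"merge label {label!r} collides with an existing component id")
        d.component_ids.append(new_id)
        d.annotations[new_id] = {"label": label, "category": "merged", "use": True}
    return d
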
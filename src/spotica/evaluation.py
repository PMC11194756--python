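"""Quantitative scoring of deconvolution output against ground truth.

The procedure mirrors a "perfect feature annotation" benchmark: each
component is assigned to the cell type whose reference mean-expression
profile best correlates (Pearson r) with the component's gene loadings;
components sharing an annotation are summed into that cell type; minor
contributions (< an abundance threshold) are filtered out and rows re-closed;
both predicted and true compositions are mapped to ILR coordinates; accuracy
is the per-dimension and overall RMSE

    RMSE_A = sqrt( sum_i (y_Ai - yhat_Ai)^2 / N )

over the N evaluated spots; and two methods are compared by a one-tailed
Diebold-Mariano test on their per-spot mean squared ILR errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .composition import CompositionMatrix, ilr_transform
from .synthetic import GroundTruth, Reference

logger = logging.getLogger("spotica")

DEFAULT_R_MIN = 0.3
DEFAULT_ABUNDANCE_FILTER = 0.10


@dataclass
class EvaluationReport:
    """Feature matching, RMSE and test results for one evaluated prediction."""

    feature_map: pd.DataFrame  # component, cell_type, r, confident
    rmse_per_dim: np.ndarray
    rmse_overall: float
    n_spots_evaluated: int
    spots_excluded: list = field(default_factory=list)  # (spot index, reason)
    per_spot_loss: np.ndarray | None = None  # mean squared ILR error per spot
    dm_stat: float | None = None
    dm_p: float | None = None


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def match_features(
    loadings: np.ndarray,
    gene_ids,
    ref: Reference,
    component_ids=None,
    r_min: float = DEFAULT_R_MIN,
) -> pd.DataFrame:
    """Annotate each component to its best-correlated reference cell type.

    Pearson r is computed on the shared gene universe (>= 10 genes required)
    between each component's loading vector and each type's mean expression
    profile; the argmax type is assigned.  Ties go to the first type index
    with a warning.  Components with r below ``r_min`` are flagged
    ``confident=False``; constant loading vectors are excluded.
    """
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    gene_ids = pd.Index(gene_ids)
    if component_ids is None:
        component_ids = [f"IC{i + 1}" for i in range(loadings.shape[0])]
    ref_idx = pd.Index(ref.gene_ids)
    shared = gene_ids.intersection(ref_idx)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes between loadings and reference (< 10)")
    L = loadings[:, gene_ids.get_indexer(shared)]
    P = ref.profiles[:, ref_idx.get_indexer(shared)]

    rows = []
    for i, cid in enumerate(component_ids):
        if L[i].std() == 0:
            logger.warning("component %s has constant loadings on the shared genes; unmatched", cid)
            continue
        r = np.array([_pearson(L[i], P[t]) for t in range(ref.n_types)])
        best = float(np.nanmax(r))
        winners = np.where(r == best)[0]
        if len(winners) > 1:
            logger.warning("component %s ties between types %s; first taken", cid, winners)
        t = int(winners[0])
        rows.append(
            {
                "component": cid,
                "cell_type": ref.type_names[t],
                "r": best,
                "confident": best >= r_min,
            }
        )
    return pd.DataFrame(rows, columns=["component", "cell_type", "r", "confident"])


def aggregate_by_annotation(
    c: CompositionMatrix,
    feature_map: pd.DataFrame,
    abundance_filter: float = DEFAULT_ABUNDANCE_FILTER,
    include_low_confidence: bool = False,
) -> CompositionMatrix:
    """Sum same-annotated parts into cell types, filter minor contributions.

    Parts absent from the feature map (or mapped without confidence, unless
    ``include_low_confidence``) are dropped before closure.  After summation,
    entries below ``abundance_filter`` are zeroed and rows re-closed.
    """
    fm = feature_map if include_low_confidence else feature_map[feature_map["confident"]]
    mapping = dict(zip(fm["component"], fm["cell_type"]))
    labels = sorted(set(mapping.values()))
    if not labels:
        raise ValueError("feature map assigns no parts")
    lab_idx = {lab: j for j, lab in enumerate(labels)}
    agg = np.zeros((c.n_spots, len(labels)))
    for j, part in enumerate(c.part_ids):
        lab = mapping.get(part)
        if lab is None:
            continue
        agg[:, lab_idx[lab]] += c.values[:, j]
    sums = agg.sum(axis=1, keepdims=True)
    nz = sums[:, 0] > 0
    agg[nz] = agg[nz] / sums[nz]
    if abundance_filter > 0:
        agg[agg < abundance_filter] = 0.0
        sums = agg.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        agg[nz] = agg[nz] / sums[nz]
    return CompositionMatrix(
        values=agg, part_ids=labels, spot_ids=c.spot_ids, high_pass=abundance_filter
    )


def rmse_ilr(
    pred: CompositionMatrix,
    truth: GroundTruth | np.ndarray,
    truth_type_names: list | None = None,
    zero_replacement: float = 1e-6,
) -> EvaluationReport:
    """ILR-space RMSE of predicted vs true compositions.

    Predicted parts are aligned onto the truth's cell types (missing types
    zero-filled, which the ILR zero replacement then handles); all-zero
    predicted rows are excluded and reported.  ``rmse_per_dim`` follows the
    per-ILR-dimension formula; ``rmse_overall`` is the root of the mean
    squared error over all dimensions and spots.
    """
    if isinstance(truth, GroundTruth):
        true_props = truth.proportions
        type_names = truth.type_names
    else:
        true_props = np.asarray(truth, dtype=float)
        type_names = list(truth_type_names) if truth_type_names is not None else list(pred.part_ids)
    if len(type_names) < 2:
        raise ValueError("ILR needs at least 2 cell types")
    unknown = set(pred.part_ids) - set(type_names)
    if unknown:
        raise ValueError(f"predicted parts {sorted(unknown)} not among the truth's types")
    if pred.n_spots != true_props.shape[0]:
        raise ValueError("prediction and truth differ in spot count")

    # align predicted parts onto the truth's type order, zero-filling misses
    P = np.zeros((pred.n_spots, len(type_names)))
    col = {t: j for j, t in enumerate(type_names)}
    for j, part in enumerate(pred.part_ids):
        P[:, col[part]] = pred.values[:, j]

    zero_rows = P.sum(axis=1) == 0
    excluded = [(int(i), "no positive prediction") for i in np.where(zero_rows)[0]]
    keep = ~zero_rows
    n_eval = int(keep.sum())
    if n_eval == 0:
        raise ValueError("no spots left to evaluate")
    Y = ilr_transform(P[keep], zero_replacement=zero_replacement)
    Yhat = ilr_transform(true_props[keep], zero_replacement=zero_replacement)
    sq = (Y - Yhat) ** 2
    return EvaluationReport(
        feature_map=pd.DataFrame(),
        rmse_per_dim=np.sqrt(sq.mean(axis=0)),
        rmse_overall=float(np.sqrt(sq.mean())),
        n_spots_evaluated=n_eval,
        spots_excluded=excluded,
        per_spot_loss=sq.mean(axis=1),
    )


def dm_test(
    sq_err_1: np.ndarray,
    sq_err_2: np.ndarray,
    alternative: str = "less",
) -> tuple[float, float, bool]:
    """One-tailed Diebold-Mariano test on per-spot losses.

    H1 (``alternative="less"``): method 1 has smaller loss.  The statistic is
    mean(d) / sqrt(var(d)/N) with d = loss1 - loss2 and the lag-0 (sample)
    variance — spots are exchangeable observations, not a time series.
    Returns (statistic, p, degenerate_flag).
    """
    if alternative != "less":
        raise ValueError("only the one-tailed 'less' alternative is implemented")
    d = np.asarray(sq_err_1, dtype=float) - np.asarray(sq_err_2, dtype=float)
    if d.shape != np.asarray(sq_err_1).shape or len(d) != len(np.asarray(sq_err_2)):
        raise ValueError("loss vectors must have equal length")
    n = len(d)
    if n < 30:
        raise ValueError(f"need >= 30 paired losses, got {n}")
    mean_d = d.mean()
    var_d = d.var(ddof=1)
    if var_d == 0:
        if mean_d == 0:
            logger.warning("degenerate DM test: identical losses")
            return 0.0, 0.5, True
        stat = -np.inf if mean_d < 0 else np.inf
        logger.warning("degenerate DM test: constant loss differential %g", mean_d)
        return float(stat), float(norm.cdf(stat)), True
    stat = mean_d / np.sqrt(var_d / n)
    return float(stat), float(norm.cdf(stat)), False


def signature_correlation(
    features_a: np.ndarray,
    genes_a,
    features_b: np.ndarray,
    genes_b,
) -> np.ndarray:
    """All-pairs Pearson r between two feature sets on their shared genes.

    Works identically for gene-loading matrices and spot-composition matrices
    (pass spot ids as "genes").  Constant vectors give NaN rows/columns, never
    a silent 0.
    """
    ia = pd.Index(genes_a)
    ib = pd.Index(genes_b)
    shared = ia.intersection(ib)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared identifiers")
    A = np.atleast_2d(np.asarray(features_a, dtype=float))[:, ia.get_indexer(shared)]
    B = np.atleast_2d(np.asarray(features_b, dtype=float))[:, ib.get_indexer(shared)]
    out = np.full((A.shape[0], B.shape[0]), np.nan)
    for i in range(A.shape[0]):
        if A[i].std() == 0:
            continue
        for j in range(B.shape[0]):
            if B[j].std() == 0:
                continue
            out[i, j] = _pearson(A[i], B[j])
    return out


def uniform_baseline_losses(
    truth: GroundTruth, zero_replacement: float = 1e-6, keep: np.ndarray | None = None
) -> np.ndarray:
    """Per-spot ILR losses of the constant uniform-composition predictor.

    The uniform composition maps to the ILR origin, so its loss is the mean
    squared ILR coordinate of the truth.
    """
    props = truth.proportions if keep is None else truth.proportions[keep]
    Yhat = ilr_transform(props, zero_replacement=zero_replacement)
    return (Yhat**2).mean(axis=1)


def evaluate_deconvolution(
    decomp,
    composition: CompositionMatrix,
    ref: Reference,
    truth: GroundTruth,
    abundance_filter: float = DEFAULT_ABUNDANCE_FILTER,
    r_min: float = DEFAULT_R_MIN,
    zero_replacement: float = 1e-6,
) -> EvaluationReport:
    """Full scoring: match, aggregate, RMSE, and DM test vs uniform baseline."""
    active = [decomp.index_of(c) for c in composition.part_ids]
    fm = match_features(
        decomp.sources[active],
        decomp.gene_ids,
        ref,
        component_ids=composition.part_ids,
        r_min=r_min,
    )
    agg = aggregate_by_annotation(composition, fm, abundance_filter=abundance_filter)
    report = rmse_ilr(agg, truth, zero_replacement=zero_replacement)
    report.feature_map = fm
    keep = np.ones(truth.proportions.shape[0], dtype=bool)
    for i, _ in report.spots_excluded:
        keep[i] = False
    base = uniform_baseline_losses(truth, zero_replacement=zero_replacement, keep=keep)
    stat, p, _ = dm_test(report.per_spot_loss, base)
    report.dm_stat, report.dm_p = stat, p
    return report
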
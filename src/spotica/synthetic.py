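"""Synthetic benchmark data with exact ground truth.

Emulates the structure of a multi-region spot-mixture benchmark: a tissue is
partitioned into a small number of contiguous regions, each region draws a
Dirichlet prior over cell types in which a subset of types dominates (types
overlap between regions — the "diverse overlap" regime), and every spot
contains a handful of cells whose types follow its region's prior.  Counts
are negative binomial (mean mu, variance mu + mu^2/theta) around a cell-type
reference profile with per-cell library-size variation.  The generator also
produces per-molecule transcript tables for testing pseudospot binning.

Everything is deterministic per seed, and the ground truth (per-spot cell
counts, proportions, region labels and the reference profiles themselves) is
recorded exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import SpotMatrix, TranscriptTable

DEFAULT_THETA = 10.0
DEFAULT_MARKER_FOLD = 8.0
DEFAULT_LIBRARY_SIGMA = 0.35


@dataclass
class Reference:
    """Cell-type mean expression profiles used to generate (and score) data."""

    profiles: np.ndarray  # (n_types, n_genes), non-negative means per cell
    type_names: list
    gene_ids: np.ndarray
    theta: float = DEFAULT_THETA
    library_sigma: float = DEFAULT_LIBRARY_SIGMA

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if np.any(self.profiles < 0):
            raise ValueError("negative expression means")
        if np.any(self.profiles.sum(axis=1) <= 0):
            raise ValueError("a profile row has non-positive sum")

    @property
    def n_types(self) -> int:
        return self.profiles.shape[0]


@dataclass
class GroundTruth:
    """True per-spot cell counts and proportions recorded by the simulator."""

    cells_per_spot: np.ndarray  # (spots, types) int
    proportions: np.ndarray  # (spots, types), rows sum to 1
    region_of_spot: np.ndarray  # region label per spot
    region_priors: np.ndarray  # (regions, types) Dirichlet draws used
    type_names: list


def make_reference(
    n_types: int,
    n_genes: int,
    markers_per_type: int,
    seed: int,
    marker_fold: float = DEFAULT_MARKER_FOLD,
    baseline_mean: float = 0.5,
    baseline_sigma: float = 0.5,
    expression_scale_sigma: float = 0.3,
    theta: float = DEFAULT_THETA,
    max_profile_r: float = 0.95,
) -> Reference:
    """Build distinguishable cell-type profiles with disjoint marker blocks.

    A log-normal baseline is shared across types; each type's block of
    ``markers_per_type`` genes is up-regulated ``marker_fold``-fold, and each
    type's whole profile carries a log-normal per-cell expression scale
    (``expression_scale_sigma``) — cell types differ in total transcript
    content, which also keeps spot read shares from being an exactly closed
    linear function of cell proportions.
    """
    if n_genes < n_types * markers_per_type:
        raise ValueError(
            f"{n_genes} genes cannot host {n_types} x {markers_per_type} disjoint markers"
        )
    rng = np.random.default_rng(seed)
    baseline = baseline_mean * rng.lognormal(mean=0.0, sigma=baseline_sigma, size=n_genes)
    profiles = np.tile(baseline, (n_types, 1))
    for t in range(n_types):
        block = slice(t * markers_per_type, (t + 1) * markers_per_type)
        profiles[t, block] *= marker_fold
    profiles *= rng.lognormal(mean=0.0, sigma=expression_scale_sigma, size=n_types)[:, None]
    C = np.corrcoef(profiles) if n_types > 1 else np.ones((1, 1))
    off = C[~np.eye(n_types, dtype=bool)]
    if off.size and off.max() >= max_profile_r:
        raise ValueError(
            f"profiles not distinguishable (max pairwise r = {off.max():.3f} >= {max_profile_r}); "
            "increase marker_fold or markers_per_type"
        )
    return Reference(
        profiles=profiles,
        type_names=[f"type{t + 1}" for t in range(n_types)],
        gene_ids=np.array([f"gene{g + 1}" for g in range(n_genes)], dtype=object),
        theta=theta,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and variance mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-300) / theta)
    return rng.poisson(lam)


def _region_priors(
    rng: np.random.Generator,
    n_regions: int,
    n_types: int,
    dominance_fraction: float,
    alpha_dominant: float,
    alpha_background: float,
    min_tv_distance: float,
    max_tries: int = 200,
) -> np.ndarray:
    """Per-region Dirichlet composition priors with overlapping dominant types."""
    # at least ceil(n_types / n_regions) dominants per region, so every type
    # can be dominant somewhere
    n_dom = min(
        n_types,
        max(1, int(round(dominance_fraction * n_types)), -(-n_types // n_regions)),
    )
    # Each region dominates a random n_dom-subset of types ("diverse overlap":
    # dominant sets overlap between regions while all types stay present via the
    # background mass).  Draws are rejected when the dominance structure makes a
    # type unidentifiable: a type dominant nowhere or everywhere varies too
    # little spatially, and two types with identical region-dominance patterns
    # cannot be told apart by any spatial method.
    total = n_dom * n_regions
    if total < n_types:
        raise ValueError(
            f"{n_regions} regions x {n_dom} dominant types cannot cover {n_types} types; "
            "raise dominance_fraction or n_regions"
        )
    check_unique = 2**n_regions - 1 >= n_types
    for _ in range(max_tries):
        # balanced dominance quotas: every type dominant in floor or ceil of
        # total/n_types regions.  A type dominant in most regions is spatially
        # near-uniform and degenerates into compositional background.
        quota = np.full(n_types, total // n_types)
        quota[rng.choice(n_types, size=total % n_types, replace=False)] += 1
        remaining = quota.astype(float)
        D = np.zeros((n_regions, n_types), dtype=bool)
        for r in range(n_regions):
            # deal to the types with the most quota left, random tie-break
            order = np.argsort(-(remaining + rng.uniform(0, 0.5, n_types)), kind="stable")
            dom = order[:n_dom]
            D[r, dom] = True
            remaining[dom] -= 1
        if remaining.max() > 0:  # a region would have needed a duplicate
            continue
        if check_unique and len({tuple(col) for col in D.T}) < n_types:
            continue
        priors = np.empty((n_regions, n_types))
        for r in range(n_regions):
            alpha = np.full(n_types, alpha_background)
            alpha[D[r]] = alpha_dominant
            priors[r] = rng.dirichlet(alpha)
        tv = np.array(
            [
                0.5 * np.abs(priors[i] - priors[j]).sum()
                for i in range(n_regions)
                for j in range(i + 1, n_regions)
            ]
        )
        if tv.size == 0 or tv.min() >= min_tv_distance:
            return priors
    raise RuntimeError(
        "could not draw identifiable region priors; relax dominance_fraction or the TV floor"
    )


def simulate_spots(
    ref: Reference,
    n_spots: int,
    n_regions: int = 5,
    cells_range: tuple[int, int] = (2, 10),
    layout: str = "blocks",
    seed: int = 0,
    dominance_fraction: float = 0.4,
    alpha_dominant: float = 5.0,
    alpha_background: float = 0.3,
    min_tv_distance: float = 0.1,
) -> tuple[SpotMatrix, GroundTruth]:
    """Simulate a multi-region spot mixture with recorded ground truth.

    Spots sit on a near-square grid split into ``n_regions`` contiguous
    regions (vertical strips for ``blocks``, nearest-seed cells for
    ``voronoi``).  Each spot holds a uniform 2-10 cells (by default) whose
    types follow the region prior; counts are NB around the type profile with
    per-cell log-normal library-size factors.
    """
    lo, hi = cells_range
    if not (1 <= lo <= hi <= 50):
        raise ValueError("cells_range must satisfy 1 <= lo <= hi <= 50")
    if n_regions > n_spots:
        raise ValueError("more regions than spots")
    rng = np.random.default_rng(seed)
    n_types, n_genes = ref.profiles.shape

    side = int(np.ceil(np.sqrt(n_spots)))
    xy = np.array([(i % side, i // side) for i in range(n_spots)], dtype=float)
    if layout == "blocks":
        region = np.minimum((xy[:, 0] * n_regions / side).astype(int), n_regions - 1)
    elif layout == "voronoi":
        seeds = rng.uniform(0, side, size=(n_regions, 2))
        dist = ((xy[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        region = dist.argmin(axis=1)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    priors = _region_priors(
        rng, n_regions, n_types, dominance_fraction, alpha_dominant, alpha_background,
        min_tv_distance,
    )

    n_cells = rng.integers(lo, hi + 1, size=n_spots)
    cells_per_spot = np.empty((n_spots, n_types), dtype=np.int64)
    for s in range(n_spots):
        cells_per_spot[s] = rng.multinomial(n_cells[s], priors[region[s]])

    counts = np.zeros((n_spots, n_genes), dtype=np.int64)
    for t in range(n_types):
        n_t = cells_per_spot[:, t]
        total_cells = int(n_t.sum())
        if total_cells == 0:
            continue
        owner = np.repeat(np.arange(n_spots), n_t)
        size_factors = rng.lognormal(mean=0.0, sigma=ref.library_sigma, size=total_cells)
        mu = size_factors[:, None] * ref.profiles[t][None, :]
        draws = _nb_draw(rng, mu, ref.theta)
        np.add.at(counts, owner, draws)

    proportions = cells_per_spot / cells_per_spot.sum(axis=1, keepdims=True)
    spot_ids = np.array([f"spot{s + 1}" for s in range(n_spots)], dtype=object)
    sm = SpotMatrix(
        counts=sp.csr_matrix(counts),
        spot_ids=spot_ids,
        gene_ids=ref.gene_ids.copy(),
        coords=xy,
        meta=pd.DataFrame(
            {"region": region, "n_cells": n_cells}, index=pd.Index(spot_ids)
        ),
    )
    gt = GroundTruth(
        cells_per_spot=cells_per_spot,
        proportions=proportions,
        region_of_spot=region,
        region_priors=priors,
        type_names=list(ref.type_names),
    )
    return sm, gt


def default_transcript_layout(
    ref: Reference,
    n_regions: int = 5,
    extent: float = 1000.0,
    seed: int = 0,
    **prior_kwargs,
) -> list[dict]:
    """Vertical-strip region layout for transcript simulation.

    Each region is a rectangle with a Dirichlet type-mixture; returns a list
    of ``{"bounds": (x0, y0, x1, y1), "type_weights": array}`` dicts.
    """
    rng = np.random.default_rng(seed)
    priors = _region_priors(
        rng,
        n_regions,
        ref.n_types,
        prior_kwargs.pop("dominance_fraction", 0.4),
        prior_kwargs.pop("alpha_dominant", 5.0),
        prior_kwargs.pop("alpha_background", 0.3),
        prior_kwargs.pop("min_tv_distance", 0.1),
    )
    width = extent / n_regions
    return [
        {
            "bounds": (r * width, 0.0, (r + 1) * width, extent),
            "type_weights": priors[r],
        }
        for r in range(n_regions)
    ]


def simulate_transcripts(
    ref: Reference,
    density_map: list[dict],
    n_transcripts: int,
    seed: int = 0,
) -> TranscriptTable:
    """Place molecules uniformly within region rectangles.

    Region choice is proportional to area; each molecule's gene is drawn from
    the region's mixture expression profile.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    rng = np.random.default_rng(seed)
    areas = np.array(
        [(r["bounds"][2] - r["bounds"][0]) * (r["bounds"][3] - r["bounds"][1]) for r in density_map]
    )
    if np.any(areas <= 0):
        raise ValueError("degenerate region bounds")
    region_choice = rng.choice(len(density_map), size=n_transcripts, p=areas / areas.sum())
    genes = np.empty(n_transcripts, dtype=object)
    x = np.empty(n_transcripts)
    y = np.empty(n_transcripts)
    for r, spec in enumerate(density_map):
        mask = region_choice == r
        m = int(mask.sum())
        if m == 0:
            continue
        x0, y0, x1, y1 = spec["bounds"]
        x[mask] = rng.uniform(x0, x1, size=m)
        y[mask] = rng.uniform(y0, y1, size=m)
        w = np.asarray(spec["type_weights"], dtype=float)
        gene_p = w @ ref.profiles
        gene_p = gene_p / gene_p.sum()
        genes[mask] = rng.choice(ref.gene_ids, size=m, p=gene_p)
    return TranscriptTable(
        records=pd.DataFrame({"gene": genes, "x": x, "y": y}), units="um"
    )
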
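"""Pseudospot binning of imaging-based ST transcript tables.

Per-molecule records are aggregated on a regular square grid so that each bin
("pseudospot") can be treated like an array-based capture spot.  Bins are
half-open intervals ``[x0 + i*m, x0 + (i+1)*m)``: a transcript sitting exactly
on a boundary belongs to the higher-index bin and is never double counted.
Sparsely covered bins (fewer than ``min_transcripts`` molecules) are removed,
mirroring the <5-transcript filter used for MERSCOPE data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import SpotMatrix, TranscriptTable

logger = logging.getLogger("spotica")

# Platform defaults: 40 um bins for MERSCOPE (with the <5-transcript filter),
# 24 um (= 200 px at 0.12 um/px) for CosMX.
DEFAULT_BIN_SIZE_UM = {"merscope": 40.0, "cosmx": 24.0}
DEFAULT_MIN_TRANSCRIPTS = {"merscope": 5, "cosmx": 0, "generic": 0}


@dataclass
class GridSpec:
    """Regular square binning grid.

    bin_size : edge length in um.
    origin   : lower-left corner (x0, y0); ``None`` -> floor of the data's
               minimum coordinates.
    min_transcripts : bins with fewer total molecules are dropped.
    """

    bin_size: float
    origin: tuple[float, float] | None = None
    min_transcripts: int = 0

    def __post_init__(self):
        if not self.bin_size > 0:
            raise ValueError("bin_size must be positive")
        if self.min_transcripts < 0:
            raise ValueError("min_transcripts must be >= 0")


def bin_transcripts(
    table: TranscriptTable,
    grid: GridSpec,
    spot_prefix: str = "bin",
) -> SpotMatrix:
    """Aggregate a transcript table into a pseudospot count matrix.

    Coordinates must already be in um (use :meth:`TranscriptTable.to_um`).
    Pseudospot coordinates are geometric bin centers.
    """
    if len(table) == 0:
        raise ValueError("empty transcript table")
    if table.units != "um":
        table = table.to_um()
    x = table.records["x"].to_numpy(dtype=float)
    y = table.records["y"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite coordinates; the reader should have filtered these")

    if grid.origin is None:
        x0, y0 = math.floor(x.min()), math.floor(y.min())
    else:
        x0, y0 = grid.origin
    m = grid.bin_size
    ix = np.floor((x - x0) / m).astype(np.int64)
    iy = np.floor((y - y0) / m).astype(np.int64)

    genes = pd.Index(sorted(table.records["gene"].unique()))
    gene_codes = genes.get_indexer(table.records["gene"])
    bin_keys, bin_codes = np.unique(np.stack([ix, iy], axis=1), axis=0, return_inverse=True)
    counts = sp.coo_matrix(
        (np.ones(len(x), dtype=np.int64), (bin_codes, gene_codes)),
        shape=(len(bin_keys), len(genes)),
    ).tocsr()

    totals = np.asarray(counts.sum(axis=1)).ravel()
    keep = totals >= grid.min_transcripts
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "dropping %d pseudospots with < %d transcripts (%d molecules)",
            n_removed,
            grid.min_transcripts,
            int(totals[~keep].sum()),
        )
    counts = counts[keep]
    bin_keys = bin_keys[keep]
    centers = np.column_stack(
        [x0 + (bin_keys[:, 0] + 0.5) * m, y0 + (bin_keys[:, 1] + 0.5) * m]
    )
    spot_ids = np.array(
        [f"{spot_prefix}_{i}_{j}" for i, j in bin_keys], dtype=object
    )
    return SpotMatrix(
        counts=counts,
        spot_ids=spot_ids,
        gene_ids=np.array(genes, dtype=object),
        coords=centers,
        meta=pd.DataFrame({"n_transcripts": totals[keep]}, index=pd.Index(spot_ids)),
    )


def bin_multi_sample(
    tables: list[tuple[str, TranscriptTable]],
    grid: GridSpec,
) -> SpotMatrix:
    """Bin several samples independently and concatenate the pseudospots.

    Spot ids are prefixed with their sample id, the metadata records
    ``sample_of_origin``, and the gene universe is the union across samples
    with zero fill.
    """
    if not tables:
        raise ValueError("no samples given")
    ids = [sid for sid, _ in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids")
    per_sample: list[SpotMatrix] = []
    for sid, table in tables:
        if len(table) == 0:
            raise ValueError(f"sample {sid!r} has an empty transcript table")
        per_sample.append(bin_transcripts(table, grid, spot_prefix=sid))

    all_genes = pd.Index(sorted(set().union(*(set(sm.gene_ids) for sm in per_sample))))
    blocks, spot_ids, coords, metas = [], [], [], []
    for sid, sm in zip(ids, per_sample):
        idx = all_genes.get_indexer(sm.gene_ids)
        proj = sp.coo_matrix(
            (np.ones(len(idx)), (idx, np.arange(len(idx)))),
            shape=(len(all_genes), len(idx)),
        )
        blocks.append(sm.counts @ proj.T)
        spot_ids.append(sm.spot_ids)
        coords.append(sm.coords)
        meta = sm.meta.copy()
        meta["sample_of_origin"] = sid
        metas.append(meta)
    return SpotMatrix(
        counts=sp.vstack(blocks).tocsr(),
        spot_ids=np.concatenate(spot_ids),
        gene_ids=np.array(all_genes, dtype=object),
        coords=np.vstack(coords),
        meta=pd.concat(metas),
    )
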
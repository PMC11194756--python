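"""Readers, writers and the analysis workspace.

Input formats covered here are the ones a spatial-transcriptomics workflow
touches on disk: the Space Ranger triplet layout (matrix.mtx + features.tsv +
barcodes.tsv + a tissue-positions table), per-molecule transcript tables from
imaging-based platforms (MERSCOPE / CosMX dialects), and GMT gene-set
libraries.  The full analysis state round-trips through a single zip archive.
"""

from __future__ import annotations

import io as _io
import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("spotica")

WORKSPACE_FORMAT_VERSION = 1

# CosMX reports pixel coordinates on a 0.12 um/px raster (200 px = 24 um).
COSMX_PX_TO_UM = 0.12

_DIALECT_COLUMNS = {
    "merscope": {"gene": "gene", "x": "global_x", "y": "global_y"},
    "cosmx": {"gene": "target", "x": "x_global_px", "y": "y_global_px"},
    "generic": {"gene": "gene", "x": "x", "y": "y"},
}


class FormatError(ValueError):
    """Raised when an on-disk input violates its expected layout."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class SpotMatrix:
    """Sparse spot x gene counts with per-spot 2-D coordinates and metadata.

    Attributes
    ----------
    counts
        Non-negative integer matrix, spots in rows, genes in columns (CSR).
    spot_ids, gene_ids
        Unique string identifiers matching the matrix dimensions.
    coords
        ``(n_spots, 2)`` array of (x, y) positions, in um when known.
    meta
        Per-spot key/value table indexed like ``spot_ids`` (e.g.
        ``sample_of_origin`` for merged multi-sample objects).
    """

    counts: sp.csr_matrix
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    coords: np.ndarray
    meta: pd.DataFrame = None

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.spot_ids))
        n, g = self.counts.shape
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot ids for {n} matrix rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} matrix columns")
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords shape {self.coords.shape}, expected ({n}, 2)")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot_ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene_ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if self.counts.nnz and not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise ValueError("non-integral counts")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, index: np.ndarray) -> "SpotMatrix":
        """Row-subset by positional index, keeping genes untouched."""
        index = np.asarray(index)
        return SpotMatrix(
            counts=self.counts[index],
            spot_ids=self.spot_ids[index],
            gene_ids=self.gene_ids,
            coords=self.coords[index],
            meta=self.meta.iloc[index].copy(),
        )


@dataclass
class TranscriptTable:
    """Per-molecule records (gene, x, y) from an imaging-based ST run."""

    records: pd.DataFrame  # columns: gene, x, y
    units: str = "um"  # "um" or "px"
    px_to_um: float | None = None

    def __post_init__(self):
        missing = {"gene", "x", "y"} - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        if self.units not in ("um", "px"):
            raise ValueError(f"unknown units {self.units!r}")
        xy = self.records[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite coordinates in transcript table")
        if (self.records["gene"].astype(str) == "").any():
            raise ValueError("empty gene labels in transcript table")

    def __len__(self) -> int:
        return len(self.records)

    def to_um(self) -> "TranscriptTable":
        """Convert pixel coordinates to um using ``px_to_um``."""
        if self.units == "um":
            return self
        if self.px_to_um is None:
            raise ValueError("units are px but no px_to_um factor is set")
        rec = self.records.copy()
        rec[["x", "y"]] = rec[["x", "y"]].to_numpy(dtype=float) * self.px_to_um
        return TranscriptTable(rec, units="um", px_to_um=self.px_to_um)


@dataclass
class GeneSetLibrary:
    """Named gene sets (e.g. one GMT file) for over-representation analysis."""

    sets: dict[str, list[str]]
    source_name: str = ""

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_id_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] >= 2 and df[1].is_unique:
        return df[1].tolist()  # prefer gene symbols when unambiguous
    return df[0].tolist()


def _find_file(dir_path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        p = dir_path / stem
        if p.exists():
            return p
    raise FormatError(f"none of {list(stems)} found in {dir_path}")


def _read_positions(coords_path: Path) -> pd.DataFrame:
    """Tissue-positions table, Space Ranger v1 (headerless) or v2 (header)."""
    with open(coords_path) as fh:
        first = fh.readline()
    has_header = first.split(",")[0].strip().lower() == "barcode"
    names = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]
    df = pd.read_csv(
        coords_path,
        header=0 if has_header else None,
        names=None if has_header else names,
    )
    if has_header:
        df.columns = [c.strip().lower() for c in df.columns]
        rename = {}
        for c in df.columns:
            if c.startswith("pxl_row"):
                rename[c] = "pxl_row"
            elif c.startswith("pxl_col"):
                rename[c] = "pxl_col"
        df = df.rename(columns=rename)
    required = {"barcode", "pxl_row", "pxl_col"}
    if not required <= set(df.columns):
        raise FormatError(
            f"positions table {coords_path} lacks columns {sorted(required - set(df.columns))}"
        )
    return df.set_index("barcode")


def read_mtx_counts(
    dir_path: str | Path,
    coords_path: str | Path,
    max_missing_frac: float = 0.05,
) -> SpotMatrix:
    """Load a Space Ranger style triplet directory restricted to positioned barcodes.

    The on-disk matrix may be spots x genes or genes x spots; the result is
    always spots x genes.  Barcodes absent from the coordinate table are
    dropped with a warning; if more than ``max_missing_frac`` of barcodes are
    missing the read fails.
    """
    dir_path = Path(dir_path)
    mtx_path = _find_file(dir_path, ["matrix.mtx", "matrix.mtx.gz"])
    feat_path = _find_file(dir_path, ["features.tsv", "features.tsv.gz", "genes.tsv"])
    bc_path = _find_file(dir_path, ["barcodes.tsv", "barcodes.tsv.gz"])

    mat = sp.csr_matrix(scipy.io.mmread(mtx_path))
    genes = _read_id_column(feat_path)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].tolist()

    if mat.shape == (len(genes), len(barcodes)) and mat.shape != (len(barcodes), len(genes)):
        mat = mat.T.tocsr()
    elif mat.shape == (len(barcodes), len(genes)):
        pass
    elif mat.shape[0] == mat.shape[1] == len(genes) == len(barcodes):
        mat = mat.T.tocsr()  # Space Ranger convention: genes in rows
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither "
            f"({len(barcodes)}, {len(genes)}) nor its transpose"
        )

    pos = _read_positions(Path(coords_path))
    present = np.array([bc in pos.index for bc in barcodes])
    n_missing = int((~present).sum())
    if n_missing:
        if n_missing > max_missing_frac * len(barcodes):
            raise FormatError(
                f"{n_missing}/{len(barcodes)} barcodes absent from the coordinate table"
            )
        logger.warning("dropping %d barcodes without coordinates", n_missing)
    keep = np.where(present)[0]
    kept_bc = [barcodes[i] for i in keep]
    coords = pos.loc[kept_bc, ["pxl_col", "pxl_row"]].to_numpy(dtype=float)
    meta_cols = [c for c in ("in_tissue", "array_row", "array_col") if c in pos.columns]
    meta = pos.loc[kept_bc, meta_cols].copy()
    meta.index = pd.Index(kept_bc)
    return SpotMatrix(mat[keep], np.array(kept_bc, dtype=object), np.array(genes, dtype=object), coords, meta)


def read_transcript_table(
    path: str | Path,
    dialect: str = "generic",
    column_map: Mapping[str, str] | None = None,
) -> TranscriptTable:
    """Read a delimited per-molecule transcript table.

    ``dialect`` selects the expected column names (``merscope``: gene /
    global_x / global_y in um; ``cosmx``: target / x_global_px / y_global_px in
    px with a 0.12 um/px factor; ``generic``: gene / x / y).  ``column_map``
    maps the logical names gene/x/y onto arbitrary headers.  Rows with missing
    coordinates are skipped and counted.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    cols = dict(_DIALECT_COLUMNS[dialect])
    if column_map:
        cols.update(column_map)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise FormatError(
            f"columns {missing} not in header {list(df.columns)}; pass column_map"
        )
    out = pd.DataFrame(
        {
            "gene": df[cols["gene"]].astype(str),
            "x": pd.to_numeric(df[cols["x"]], errors="coerce"),
            "y": pd.to_numeric(df[cols["y"]], errors="coerce"),
        }
    )
    bad = out[["x", "y"]].isna().any(axis=1) | ~np.isfinite(out[["x", "y"]]).all(axis=1)
    if bad.any():
        logger.warning("skipping %d transcript rows with missing coordinates", int(bad.sum()))
        out = out[~bad].reset_index(drop=True)
    units = "px" if dialect == "cosmx" else "um"
    px_to_um = COSMX_PX_TO_UM if dialect == "cosmx" else None
    return TranscriptTable(out.reset_index(drop=True), units=units, px_to_um=px_to_um)


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a tab-delimited GMT file (set name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (< 3)")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = members
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetLibrary(sets=sets, source_name=Path(path).stem)


# ---------------------------------------------------------------------------
# Workspace
# ---------------------------------------------------------------------------


@dataclass
class Workspace:
    """Full analysis state: counts, normalization, decomposition, results.

    Everything downstream of the raw reads lives here so any stage can be
    resumed after :func:`save_workspace` / :func:`load_workspace`.
    """

    spots: SpotMatrix | None = None
    normalized: "object | None" = None  # preprocess.NormalizedMatrix
    decomposition: "object | None" = None  # decomposition.Decomposition
    compositions: dict = field(default_factory=dict)  # name -> CompositionMatrix
    cluster_labels: np.ndarray | None = None
    embedding: np.ndarray | None = None
    config: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)


def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = _io.BytesIO()
    np.save(buf, arr, allow_pickle=False)
    return buf.getvalue()


def _load_npy(zf: zipfile.ZipFile, name: str) -> np.ndarray:
    return np.load(_io.BytesIO(zf.read(name)), allow_pickle=False)


def _put_sparse(zf: zipfile.ZipFile, prefix: str, mat: sp.csr_matrix):
    mat = sp.csr_matrix(mat)
    zf.writestr(f"{prefix}.data.npy", _npy_bytes(mat.data))
    zf.writestr(f"{prefix}.indices.npy", _npy_bytes(mat.indices))
    zf.writestr(f"{prefix}.indptr.npy", _npy_bytes(mat.indptr))
    zf.writestr(f"{prefix}.shape.npy", _npy_bytes(np.array(mat.shape)))


def _get_sparse(zf: zipfile.ZipFile, prefix: str) -> sp.csr_matrix:
    return sp.csr_matrix(
        (
            _load_npy(zf, f"{prefix}.data.npy"),
            _load_npy(zf, f"{prefix}.indices.npy"),
            _load_npy(zf, f"{prefix}.indptr.npy"),
        ),
        shape=tuple(_load_npy(zf, f"{prefix}.shape.npy")),
    )


def _put_strings(zf: zipfile.ZipFile, name: str, values) -> None:
    zf.writestr(name, json.dumps([str(v) for v in values]))


def _get_strings(zf: zipfile.ZipFile, name: str) -> np.ndarray:
    return np.array(json.loads(zf.read(name).decode()), dtype=object)


def save_workspace(state: Workspace, path: str | Path) -> None:
    """Serialize a workspace to a single zip archive."""
    from . import composition as _comp  # deferred: avoid import cycle
    from . import decomposition as _dec
    from . import preprocess as _pre

    path = Path(path)
    manifest: dict = {
        "format_version": WORKSPACE_FORMAT_VERSION,
        "has": {},
        "config": state.config,
        "provenance": state.provenance,
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        if state.spots is not None:
            sm = state.spots
            _put_sparse(zf, "spots/counts", sm.counts)
            _put_strings(zf, "spots/spot_ids.json", sm.spot_ids)
            _put_strings(zf, "spots/gene_ids.json", sm.gene_ids)
            zf.writestr("spots/coords.npy", _npy_bytes(sm.coords))
            zf.writestr("spots/meta.tsv", sm.meta.to_csv(sep="\t"))
            manifest["has"]["spots"] = True
        if state.normalized is not None:
            nm = state.normalized
            zf.writestr("norm/residuals.npy", _npy_bytes(np.asarray(nm.residuals)))
            _put_strings(zf, "norm/gene_ids.json", nm.gene_ids)
            zf.writestr("norm/params.tsv", nm.model_params.to_csv(sep="\t"))
            zf.writestr("norm/clip.npy", _npy_bytes(np.array([nm.clip_bound])))
            manifest["has"]["normalized"] = True
        if state.decomposition is not None:
            d = state.decomposition
            zf.writestr("decomp/sources.npy", _npy_bytes(d.sources))
            zf.writestr("decomp/weights.npy", _npy_bytes(d.weights))
            zf.writestr("decomp/kurtosis.npy", _npy_bytes(d.kurtosis))
            zf.writestr("decomp/kept.npy", _npy_bytes(d.kept))
            zf.writestr("decomp/sign_flipped.npy", _npy_bytes(d.sign_flipped))
            zf.writestr("decomp/superseded.npy", _npy_bytes(d.superseded))
            zf.writestr("decomp/derived.npy", _npy_bytes(d.derived))
            _put_strings(zf, "decomp/component_ids.json", d.component_ids)
            _put_strings(zf, "decomp/gene_ids.json", d.gene_ids)
            _put_strings(zf, "decomp/spot_ids.json", d.spot_ids)
            if d.spot_mean is not None:
                zf.writestr("decomp/spot_mean.npy", _npy_bytes(d.spot_mean))
            zf.writestr("decomp/annotations.json", json.dumps(d.annotations))
            zf.writestr(
                "decomp/params.json",
                json.dumps(
                    {
                        "k_requested": d.k_requested,
                        "seed": d.seed,
                        "method": d.method,
                        "max_iter": d.max_iter,
                        "converged": d.converged,
                    }
                ),
            )
            manifest["has"]["decomposition"] = True
        for name, cm in state.compositions.items():
            pfx = f"comp/{name}"
            zf.writestr(f"{pfx}/values.npy", _npy_bytes(cm.values))
            _put_strings(zf, f"{pfx}/part_ids.json", cm.part_ids)
            _put_strings(zf, f"{pfx}/spot_ids.json", cm.spot_ids)
            zf.writestr(f"{pfx}/high_pass.npy", _npy_bytes(np.array([cm.high_pass])))
        manifest["compositions"] = list(state.compositions)
        if state.cluster_labels is not None:
            zf.writestr("clusters/labels.npy", _npy_bytes(np.asarray(state.cluster_labels)))
            manifest["has"]["cluster_labels"] = True
        if state.embedding is not None:
            zf.writestr("embedding/coords.npy", _npy_bytes(np.asarray(state.embedding)))
            manifest["has"]["embedding"] = True
        zf.writestr("manifest.json", json.dumps(manifest))


def load_workspace(path: str | Path) -> Workspace:
    """Load a workspace archive written by :func:`save_workspace`."""
    from . import composition as _comp
    from . import decomposition as _dec
    from . import preprocess as _pre

    try:
        zf = zipfile.ZipFile(path)
    except zipfile.BadZipFile as exc:
        raise FormatError(f"{path}: not a workspace archive ({exc})") from exc
    with zf:
        try:
            manifest = json.loads(zf.read("manifest.json").decode())
        except KeyError as exc:
            raise FormatError(f"{path}: truncated workspace (no manifest)") from exc
        version = manifest.get("format_version")
        if version != WORKSPACE_FORMAT_VERSION:
            raise FormatError(
                f"workspace format version {version} != supported {WORKSPACE_FORMAT_VERSION}"
            )
        ws = Workspace(config=manifest.get("config", {}), provenance=manifest.get("provenance", []))
        has = manifest.get("has", {})
        if has.get("spots"):
            meta = pd.read_csv(_io.BytesIO(zf.read("spots/meta.tsv")), sep="\t", index_col=0)
            spot_ids = _get_strings(zf, "spots/spot_ids.json")
            meta.index = pd.Index(spot_ids)
            ws.spots = SpotMatrix(
                counts=_get_sparse(zf, "spots/counts"),
                spot_ids=spot_ids,
                gene_ids=_get_strings(zf, "spots/gene_ids.json"),
                coords=_load_npy(zf, "spots/coords.npy"),
                meta=meta,
            )
        if has.get("normalized"):
            params = pd.read_csv(_io.BytesIO(zf.read("norm/params.tsv")), sep="\t", index_col=0)
            ws.normalized = _pre.NormalizedMatrix(
                residuals=_load_npy(zf, "norm/residuals.npy"),
                gene_ids=_get_strings(zf, "norm/gene_ids.json"),
                spot_ids=ws.spots.spot_ids if ws.spots is not None else None,
                model_params=params,
                clip_bound=float(_load_npy(zf, "norm/clip.npy")[0]),
            )
        if has.get("decomposition"):
            p = json.loads(zf.read("decomp/params.json").decode())
            ws.decomposition = _dec.Decomposition(
                sources=_load_npy(zf, "decomp/sources.npy"),
                weights=_load_npy(zf, "decomp/weights.npy"),
                gene_ids=_get_strings(zf, "decomp/gene_ids.json"),
                spot_ids=_get_strings(zf, "decomp/spot_ids.json"),
                component_ids=list(_get_strings(zf, "decomp/component_ids.json")),
                kurtosis=_load_npy(zf, "decomp/kurtosis.npy"),
                kept=_load_npy(zf, "decomp/kept.npy"),
                sign_flipped=_load_npy(zf, "decomp/sign_flipped.npy"),
                superseded=_load_npy(zf, "decomp/superseded.npy"),
                derived=_load_npy(zf, "decomp/derived.npy"),
                annotations=json.loads(zf.read("decomp/annotations.json").decode()),
                k_requested=p["k_requested"],
                seed=p["seed"],
                method=p["method"],
                max_iter=p["max_iter"],
                converged=p["converged"],
                spot_mean=_load_npy(zf, "decomp/spot_mean.npy")
                if "decomp/spot_mean.npy" in zf.namelist()
                else None,
            )
        for name in manifest.get("compositions", []):
            pfx = f"comp/{name}"
            ws.compositions[name] = _comp.CompositionMatrix(
                values=_load_npy(zf, f"{pfx}/values.npy"),
                part_ids=list(_get_strings(zf, f"{pfx}/part_ids.json")),
                spot_ids=_get_strings(zf, f"{pfx}/spot_ids.json"),
                high_pass=float(_load_npy(zf, f"{pfx}/high_pass.npy")[0]),
            )
        if has.get("cluster_labels"):
            ws.cluster_labels = _load_npy(zf, "clusters/labels.npy")
        if has.get("embedding"):
            ws.embedding = _load_npy(zf, "embedding/coords.npy")
    return ws
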
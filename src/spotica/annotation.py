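"""Component annotation: local over-representation analysis and labels.

Contributor-gene lists are tested against user-supplied GMT libraries with
the hypergeometric upper tail (the classic ORA), Benjamini-Hochberg adjusted
across sets within one query.  The universe is the set of genes present in
the analyzed matrix, since contributor genes are drawn from it.  Annotation
itself (label / category / use flag per component) is a plain machine-readable
table standing in for interactive curation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .decomposition import Decomposition
from .io import GeneSetLibrary

logger = logging.getLogger("spotica")


def ora_enrich(
    query: list,
    library: GeneSetLibrary,
    universe: list,
    min_overlap: int = 1,
    case_insensitive: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against a library.

    Returns a table with one row per gene set having overlap >= min_overlap:
    columns set, k (overlap), K (set size in universe), n (query size),
    M (universe size), p_value, p_adjusted (BH across all tested sets),
    genes (overlap members, comma separated).
    """
    if not query:
        raise ValueError("empty query gene list")
    if not library.sets:
        raise ValueError("empty gene-set library")
    norm = (lambda g: str(g).upper()) if case_insensitive else str
    uni = {norm(g) for g in universe}
    q = {norm(g) for g in query}
    dropped = len(q - uni)
    if dropped:
        logger.warning("%d query genes not in the universe; dropped", dropped)
    q &= uni
    if not q:
        raise ValueError("no query genes remain within the universe")
    M, n = len(uni), len(q)

    rows = []
    raw_p = []
    for name, members in library.sets.items():
        s = {norm(g) for g in members} & uni
        K = len(s)
        overlap = sorted(q & s)
        k = len(overlap)
        # upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((name, k, K, overlap))
        raw_p.append(min(max(p, 0.0), 1.0))
    # BH across every tested set, then drop the under-threshold overlaps
    adj = multipletests(raw_p, method="fdr_bh")[1] if raw_p else []
    out = pd.DataFrame(
        [
            {
                "set": name,
                "k": k,
                "K": K,
                "n": n,
                "M": M,
                "p_value": p,
                "p_adjusted": a,
                "genes": ",".join(overlap),
            }
            for (name, k, K, overlap), p, a in zip(rows, raw_p, adj)
            if k >= min_overlap
        ]
    )
    if not out.empty:
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out


def enrich_components(
    contributors: dict,
    library: GeneSetLibrary,
    universe: list,
    min_overlap: int = 1,
    case_insensitive: bool = False,
) -> pd.DataFrame:
    """Run :func:`ora_enrich` on every component's contributor-gene list."""
    frames = []
    for cid, genes in contributors.items():
        names = [g for g, _, _ in genes]
        if not names:
            continue
        tab = ora_enrich(names, library, universe, min_overlap, case_insensitive)
        tab.insert(0, "component", cid)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(
            columns=["component", "set", "k", "K", "n", "M", "p_value", "p_adjusted", "genes"]
        )
    return pd.concat(frames, ignore_index=True)


KNOWN_CATEGORIES = {"", "cell type", "activity", "noise", "artifact", "merged"}


def annotate_components(d: Decomposition, labels: dict) -> Decomposition:
    """Store per-component annotations ``{id: {label, category, use}}``.

    Components flagged ``use=False`` are excluded from downstream default
    selections.  Unknown categories are kept verbatim with a warning.
    """
    for cid, ann in labels.items():
        if cid not in d.component_ids:
            raise KeyError(f"unknown component id {cid!r}")
        entry = d.annotations.get(cid, {"label": "", "category": "", "use": True})
        entry.update(
            {
                "label": str(ann.get("label", entry["label"])),
                "category": str(ann.get("category", entry["category"])),
                "use": bool(ann.get("use", entry["use"])),
            }
        )
        if entry["category"] not in KNOWN_CATEGORIES:
            logger.warning("unknown category %r stored verbatim", entry["category"])
        d.annotations[cid] = entry
    return d


def annotations_to_frame(d: Decomposition) -> pd.DataFrame:
    """Annotation table (component, label, category, use) for export."""
    return pd.DataFrame(
        [
            {"component": cid, **d.annotations[cid]}
            for cid in d.component_ids
        ]
    )


def annotations_from_frame(df: pd.DataFrame) -> dict:
    """Parse an annotation CSV back into the ``annotate_components`` mapping."""
    out = {}
    for _, row in df.iterrows():
        use = row.get("use", True)
        if isinstance(use, str):
            use = use.strip().lower() in ("true", "1", "yes")
        out[row["component"]] = {
            "label": row.get("label", ""),
            "category": row.get("category", ""),
            "use": bool(use),
        }
    return out
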
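"""Chromatin-state annotation, nearest-TSS mapping and gene-set enrichment.

Each peak overlapping several chromatin states (per cell type) is resolved
to a single state by a fixed priority order, with one positional exception:
a peak overlapping both an active TSS and an enhancer state is a promoter
when proximal (|distance to nearest TSS| < 1000 bp) and an enhancer when
distal.  Resolved states pool into six meta-states for interpretation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust

ACTIVE_TSS = "ActiveTSS"
ENHANCER_STATES = ("ActiveEnhancer", "GenicEnhancer", "WeakEnhancer", "BivalentEnhancer")

# Conflict-resolution priority (highest first).  ActiveTSS outranks everything
# except through the proximal/distal promoter-vs-enhancer rule handled apart.
PRIORITY = (
    ACTIVE_TSS,
    "ActiveEnhancer",
    "GenicEnhancer",
    "BivalentTSS",
    "WeakEnhancer",
    "BivalentEnhancer",
    "PolyCombRepressed",
    "WeakPolyCombRepressed",
    "FlankingTSS",
    "Transcription",
    "WeakTranscription",
    "ZNFRepeats",
    "Heterochromatin",
    "Quiescent",
)
_RANK = {s: i for i, s in enumerate(PRIORITY)}

META_STATES = {
    "ActiveTSS": "TSS",
    "FlankingTSS": "TSS",
    "BivalentTSS": "TSS",
    "ActiveEnhancer": "Enhancer",
    "GenicEnhancer": "Enhancer",
    "WeakEnhancer": "Enhancer",
    "BivalentEnhancer": "Enhancer",
    "PolyCombRepressed": "RepressedPolyComb",
    "WeakPolyCombRepressed": "RepressedPolyComb",
    "Transcription": "Transcription",
    "WeakTranscription": "Transcription",
    "Quiescent": "Quiescent",
    "ZNFRepeats": "Other",
    "Heterochromatin": "Other",
}

PROXIMAL_BP = 1000


def resolve_state(states, tss_distance: float) -> str:
    """Resolve overlapping raw chromatin states to a single annotation.

    ``states``: the raw state labels overlapping one peak (>= 1).
    ``tss_distance``: signed distance from the peak center to the nearest
    TSS, used only for the promoter-vs-enhancer rule.
    """
    states = list(states)
    if not states:
        raise ValueError("at least one overlapping state is required")
    for s in states:
        if s not in _RANK:
            raise ValueError(f"unknown state {s!r}; valid labels: {PRIORITY}")
    has_tss = ACTIVE_TSS in states
    enh = [s for s in states if s in ENHANCER_STATES]
    if has_tss and enh:
        if abs(tss_distance) < PROXIMAL_BP:
            return ACTIVE_TSS  # proximal: annotated as promoter
        return min(enh, key=_RANK.__getitem__)
    return min(states, key=_RANK.__getitem__)


def pool_meta_state(state: str) -> str:
    """Map a resolved state onto one of the six pooled meta-states."""
    return META_STATES[state]


ACTIVE_STATES = (ACTIVE_TSS, "ActiveEnhancer")


def assign_cell_specificity(states_by_cell: dict, lineage_map: dict) -> str | None:
    """Cell- or lineage-specific label for a peak, or None.

    ``states_by_cell`` maps cell type -> resolved state for this peak.  The
    peak is specific if it is an active promoter/enhancer in exactly one
    cell type, or if all its active cell types share one lineage.
    """
    if len(states_by_cell) < 2:
        raise ValueError("need resolved states for at least 2 cell types")
    active = [c for c, s in states_by_cell.items() if s in ACTIVE_STATES]
    if not active:
        return None
    if len(active) == len(states_by_cell):
        return None
    if len(active) == 1:
        return active[0]
    lineages = {lineage_map.get(c) for c in active}
    if len(lineages) == 1 and None not in lineages:
        return lineages.pop()
    return None


def nearest_tss(center: int, chrom: str, tss: pd.DataFrame,
                max_dist: int = 100_000):
    """Nearest gene TSS within ``max_dist`` bp of the peak center.

    ``tss`` columns: chrom, pos, gene and optionally strand (default "+").
    Returns ``(gene, signed distance)`` or ``(None, None)``; the distance is
    negative upstream of the TSS on the gene's strand.  Ties break to the
    lexicographically smallest gene id.
    """
    if tss.empty:
        raise ValueError("TSS table is empty")
    if not np.issubdtype(np.asarray(tss["pos"]).dtype, np.number):
        raise ValueError("malformed coordinates in TSS table")
    sub = tss[tss["chrom"] == chrom]
    if sub.empty:
        return None, None
    dist = (sub["pos"] - center).abs()
    best = dist.min()
    if best > max_dist:
        return None, None
    hits = sub.loc[dist == best].sort_values("gene")
    row = hits.iloc[0]
    strand = row["strand"] if "strand" in hits.columns else "+"
    signed = (center - row["pos"]) * (1 if strand == "+" else -1)
    return row["gene"], int(signed)


def enrichment_test(query, collection: dict, universe) -> pd.DataFrame:
    """Hypergeometric (upper-tail) gene-set enrichment with BH adjustment.

    ``collection`` maps set name -> iterable of gene ids; ``universe`` is the
    background (e.g. all expressed genes).  p = P(X >= observed overlap).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty background universe")
    query = set(query) & universe
    rows = []
    for name, members in collection.items():
        members = set(members) & universe
        k = len(query & members)
        p = stats.hypergeom.sf(k - 1, len(universe), len(members), len(query))
        rows.append({"set": name, "overlap": k, "set_size": len(members), "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = bh_adjust(out["p"])
    return out


def marker_filter(result: pd.DataFrame, fdr_threshold: float = 0.05,
                  logfc_threshold: float = math.log2(1.25)) -> pd.Index:
    """Marker ids: FDR <= threshold and logFC strictly above log2(1.25)."""
    keep = (result["fdr"] <= fdr_threshold) & (result["logFC"] > logfc_threshold)
    return result.index[keep]
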
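"""Epithelial-edge extraction and signed interface-zone ranking.

Hexagons are first labeled epithelial or stromal from their aggregated
tissue-class areas.  Within each compartment (tumor and liver run as
independent passes), epithelial hexagons adjacent to stroma form the edge
(rank 0); breadth-first layers over the 6-neighbor graph then assign
positive ranks into the epithelium and negative ranks into the stroma,
so the rank is the signed graph distance to the nearest edge hexagon.
Excluded hexagons (mostly background, or outside the compartment) never
form edges and never carry BFS distance, so tissue gaps do not create
spurious deep ranks.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hexgrid import AXIAL_NEIGHBORS


@dataclass(frozen=True)
class RankingParams:
    """Thresholds for hexagon labeling and rank propagation.

    epithelial_fraction_threshold
        Minimum epithelium/(epithelium+stroma) area fraction for an
        'epithelial' label (default 0.5).
    min_tissue_fraction
        Minimum non-background fraction of the hexagon area for inclusion
        (default 0.5); below it the hexagon is 'excluded'.
    max_abs_rank
        Half-width of the interface zone (default 2, the five-zone window);
        deeper ranks are retained but flagged out-of-zone.
    edge_through_excluded
        When True, the edge test also looks one step past a single excluded
        neighbor (adjacency "through" small gaps).  Default False.
    """

    epithelial_fraction_threshold: float = 0.5
    min_tissue_fraction: float = 0.5
    max_abs_rank: int = 2
    edge_through_excluded: bool = False

    def __post_init__(self):
        for name in ("epithelial_fraction_threshold", "min_tissue_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.max_abs_rank < 1:
            raise ValueError("max_abs_rank must be a positive integer")


def classify_hexagons(aggs: pd.DataFrame,
                      params: RankingParams = RankingParams()) -> pd.DataFrame:
    """Assign each hexagon a tissue_label: 'epithelial', 'stromal' or 'excluded'.

    A hexagon is excluded when its compartment is 'excluded' or its tissue
    (non-background) fraction is below ``min_tissue_fraction``; otherwise
    it is epithelial when epithelium/(epithelium+stroma) meets the
    ``epithelial_fraction_threshold`` and stromal otherwise.
    """
    out = aggs.copy()
    epi = out["epithelium_area_um2"].to_numpy(dtype=float)
    strom = out["stroma_area_um2"].to_numpy(dtype=float)
    bg = out["background_area_um2"].to_numpy(dtype=float)
    total = epi + strom + bg
    tissue = epi + strom
    with np.errstate(invalid="ignore", divide="ignore"):
        tissue_frac = np.where(total > 0, tissue / total, 0.0)
        epi_frac = np.where(tissue > 0, epi / tissue, 0.0)
    label = np.where(epi_frac >= params.epithelial_fraction_threshold,
                     "epithelial", "stromal")
    excluded = (tissue_frac < params.min_tissue_fraction) | \
               (out["compartment"].to_numpy() == "excluded")
    label = np.where(excluded, "excluded", label)
    out["tissue_label"] = label
    return out


def _adjacency(index_set: set[tuple[int, int]]):
    def neighbors(qr):
        q, r = qr
        for dq, dr in AXIAL_NEIGHBORS:
            n = (q + dq, r + dr)
            if n in index_set:
                yield n
    return neighbors


def detect_edge(aggs: pd.DataFrame, compartment: str,
                params: RankingParams = RankingParams()) -> set[tuple[int, int]]:
    """Rank-0 set: epithelial hexagons of ``compartment`` with ≥1 stromal 6-neighbor.

    Hexagons of the other compartment are treated as absent; excluded
    hexagons do not count as stroma.  With ``edge_through_excluded`` the
    stromal neighbor may sit one step beyond a single excluded hexagon.
    """
    sel = aggs[aggs["compartment"] == compartment]
    label = {(int(q), int(r)): lab for q, r, lab in
             zip(sel["q"], sel["r"], sel["tissue_label"])}
    edge = set()
    for qr, lab in label.items():
        if lab != "epithelial":
            continue
        q, r = qr
        for dq, dr in AXIAL_NEIGHBORS:
            n = (q + dq, r + dr)
            nlab = label.get(n)
            if nlab == "stromal":
                edge.add(qr)
                break
            if nlab == "excluded" and params.edge_through_excluded:
                if any(label.get((n[0] + dq2, n[1] + dr2)) == "stromal"
                       for dq2, dr2 in AXIAL_NEIGHBORS):
                    edge.add(qr)
                    break
    return edge


def assign_ranks(aggs: pd.DataFrame, edge: set[tuple[int, int]], compartment: str,
                 params: RankingParams = RankingParams()) -> pd.DataFrame:
    """Signed BFS ranks from the edge set, within one compartment.

    Epithelial hexagons at 6-neighbor graph distance k from the edge get
    rank +k; stromal hexagons at distance k get −k.  Excluded hexagons are
    not traversed.  Ranks with |rank| > max_abs_rank are kept but flagged
    ``out_of_zone``; unreachable hexagons stay unranked (NaN).

    Adds/updates columns ``rank`` (float, NaN = unranked) and
    ``out_of_zone`` (bool) for rows of ``compartment``.
    """
    out = aggs.copy()
    if "rank" not in out.columns:
        out["rank"] = np.nan
        out["out_of_zone"] = False
    sel = out["compartment"] == compartment
    label = {(int(q), int(r)): lab for q, r, lab in
             zip(out.loc[sel, "q"], out.loc[sel, "r"], out.loc[sel, "tissue_label"])}
    traversable = {qr for qr, lab in label.items() if lab != "excluded"}
    dist: dict[tuple[int, int], int] = {qr: 0 for qr in edge if qr in traversable}
    frontier = deque(sorted(dist))
    while frontier:
        qr = frontier.popleft()
        d = dist[qr]
        q, r = qr
        for dq, dr in AXIAL_NEIGHBORS:
            n = (q + dq, r + dr)
            if n in traversable and n not in dist:
                dist[n] = d + 1
                frontier.append(n)
    ranks = {}
    for qr, d in dist.items():
        sign = 1 if label[qr] == "epithelial" else -1
        ranks[qr] = sign * d
    key = list(zip(out.loc[sel, "q"].astype(int), out.loc[sel, "r"].astype(int)))
    rank_col = np.array([ranks.get(k, np.nan) for k in key], dtype=float)
    out.loc[sel, "rank"] = rank_col
    out.loc[sel, "out_of_zone"] = np.abs(rank_col) > params.max_abs_rank
    return out


def rank_compartments(aggs: pd.DataFrame,
                      params: RankingParams = RankingParams()) -> pd.DataFrame:
    """Full ranking pass: classify, then edge-detect and rank each compartment.

    Tumor and liver are ranked in separate passes (hexagons of the other
    compartment are invisible to each pass), mirroring independent
    interface profiles for the malignant and non-malignant parts.
    """
    out = classify_hexagons(aggs, params)
    out["rank"] = np.nan
    out["out_of_zone"] = False
    for compartment in ("tumor", "liver"):
        edge = detect_edge(out, compartment, params)
        out = assign_ranks(out, edge, compartment, params)
    return out
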
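"""Interface-zone CD8+ density profile and the four scalar indicators.

For each compartment the five-hexagon-wide interface zone (ranks −2…+2
around the epithelial edge) yields a per-rank density profile, from which
four scalars are derived:

``mean_density``
    total CD8+ count over total tissue area of the zone, cells/mm².
``edge_sd``
    sample SD (n−1) of per-hexagon density at rank 0 — the indicator whose
    low values flag early relapse risk.
``center_of_mass``
    density-weighted mean rank, Σ k·D_k / Σ D_k over k = −2…+2; its sign
    locates the infiltrate relative to the edge.
``immunodrop_ratio``
    D(−1)/D(+1), the density drop across the tumor edge.

Log copies use ln(x+1) for quantities that can be 0 (densities, SD) and a
direct ln for the ratio.  Undefined indicators (e.g. <2 rank-0 hexagons,
all-zero profile, D(+1)=0) are reported as NaN, never raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANK_WINDOW: tuple[int, ...] = (-2, -1, 0, 1, 2)


class EmptyProfileError(ValueError):
    """No hexagon falls in any of the five interface-zone ranks."""


@dataclass
class ZoneProfile:
    """Per-rank CD8+ density statistics for one compartment."""

    compartment: str
    ranks: tuple[int, ...] = RANK_WINDOW
    n_hexagons: dict[int, int] = field(default_factory=dict)
    total_cd8: dict[int, int] = field(default_factory=dict)
    total_tissue_area_mm2: dict[int, float] = field(default_factory=dict)
    mean_density: dict[int, float] = field(default_factory=dict)
    densities: dict[int, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": list(self.ranks),
            "n_hexagons": [self.n_hexagons[k] for k in self.ranks],
            "total_cd8": [self.total_cd8[k] for k in self.ranks],
            "total_tissue_area_mm2": [self.total_tissue_area_mm2[k] for k in self.ranks],
            "mean_density": [self.mean_density[k] for k in self.ranks],
        })


@dataclass
class IndicatorSet:
    """The four interface indicators (raw and log-transformed) for one compartment."""

    compartment: str
    mean_density: float
    edge_sd: float
    center_of_mass: float
    immunodrop_ratio: float
    log_mean_density: float = field(init=False)
    log_edge_sd: float = field(init=False)
    log_immunodrop_ratio: float = field(init=False)

    def __post_init__(self):
        self.log_mean_density = _log1p_or_nan(self.mean_density)
        self.log_edge_sd = _log1p_or_nan(self.edge_sd)
        self.log_immunodrop_ratio = (
            math.log(self.immunodrop_ratio)
            if np.isfinite(self.immunodrop_ratio) and self.immunodrop_ratio > 0
            else float("nan")
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_density": self.mean_density,
            "edge_sd": self.edge_sd,
            "center_of_mass": self.center_of_mass,
            "immunodrop_ratio": self.immunodrop_ratio,
            "log_mean_density": self.log_mean_density,
            "log_edge_sd": self.log_edge_sd,
            "log_immunodrop_ratio": self.log_immunodrop_ratio,
        }


def _log1p_or_nan(x: float) -> float:
    return math.log1p(x) if np.isfinite(x) and x >= 0 else float("nan")


def zone_profile(ranked: pd.DataFrame, compartment: str,
                 window: tuple[int, ...] = RANK_WINDOW) -> ZoneProfile:
    """Build the per-rank density profile for one compartment.

    Per-hexagon density is cd8_count over the hexagon's tissue area
    (epithelium + stroma, in mm²); zero-tissue hexagons are excluded.  The
    per-rank mean density is area-weighted: total count / total area.

    Raises :class:`EmptyProfileError` when no hexagon occupies any window rank.
    """
    sel = ranked[(ranked["compartment"] == compartment) & ranked["rank"].notna()]
    prof = ZoneProfile(compartment=compartment, ranks=tuple(window))
    any_hex = False
    for k in window:
        rows = sel[sel["rank"] == k]
        area_mm2 = (rows["epithelium_area_um2"] + rows["stroma_area_um2"]).to_numpy() / 1e6
        cd8 = rows["cd8_count"].to_numpy(dtype=float)
        keep = area_mm2 > 0
        area_mm2, cd8 = area_mm2[keep], cd8[keep]
        prof.n_hexagons[k] = int(keep.sum())
        prof.total_cd8[k] = int(cd8.sum())
        prof.total_tissue_area_mm2[k] = float(area_mm2.sum())
        prof.mean_density[k] = (
            float(cd8.sum() / area_mm2.sum()) if area_mm2.size else 0.0
        )
        prof.densities[k] = cd8 / area_mm2 if area_mm2.size else np.empty(0)
        any_hex = any_hex or keep.any()
    if not any_hex:
        raise EmptyProfileError(
            f"no {compartment} hexagon falls in interface ranks {window}"
        )
    return prof


def edge_sd(profile: ZoneProfile) -> float:
    """Sample SD (n−1 denominator) of per-hexagon density at rank 0; NaN if <2."""
    d = profile.densities.get(0, np.empty(0))
    if d.size < 2:
        return float("nan")
    return float(np.std(d, ddof=1))


def center_of_mass(profile: ZoneProfile) -> float:
    """Density-weighted mean rank over the window; NaN for an all-zero profile."""
    ks = np.array(profile.ranks, dtype=float)
    dens = np.array([profile.mean_density[int(k)] for k in ks])
    total = dens.sum()
    if total <= 0:
        return float("nan")
    return float((ks * dens).sum() / total)


def immunodrop(profile: ZoneProfile) -> float:
    """D(−1)/D(+1) using the per-rank mean densities; NaN when D(+1) = 0."""
    d_pos = profile.mean_density.get(1, 0.0)
    d_neg = profile.mean_density.get(-1, 0.0)
    if d_pos <= 0:
        return float("nan")
    return float(d_neg / d_pos)


def indicator_set(profile: ZoneProfile) -> IndicatorSet:
    """Bundle the four indicators computed from one zone profile."""
    total_cd8 = sum(profile.total_cd8[k] for k in profile.ranks)
    total_area = sum(profile.total_tissue_area_mm2[k] for k in profile.ranks)
    mean_d = total_cd8 / total_area if total_area > 0 else float("nan")
    return IndicatorSet(
        compartment=profile.compartment,
        mean_density=float(mean_d),
        edge_sd=edge_sd(profile),
        center_of_mass=center_of_mass(profile),
        immunodrop_ratio=immunodrop(profile),
    )


def compute_indicators(ranked: pd.DataFrame,
                       window: tuple[int, ...] = RANK_WINDOW
                       ) -> dict[str, dict]:
    """Zone profiles and indicator sets for both compartments.

    Returns ``{compartment: {"profile": ZoneProfile | None,
    "indicators": IndicatorSet | None}}``.  A compartment with no hexagons
    in the window yields ``None`` entries (missing, not an error), so a
    slide without non-malignant parenchyma still reports tumor indicators.
    """
    out: dict[str, dict] = {}
    for compartment in ("tumor", "liver"):
        try:
            prof = zone_profile(ranked, compartment, window)
        except EmptyProfileError:
            out[compartment] = {"profile": None, "indicators": None}
            continue
        out[compartment] = {"profile": prof, "indicators": indicator_set(prof)}
    return out
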
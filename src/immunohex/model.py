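"""Model/Results front end for the two halves of the analysis.

:class:`CD8InterfaceModel` wraps the spatial half — hexagonal aggregation
of a segmentation scene and cell table, edge ranking, and interface-zone
indicator extraction — and its :meth:`~CD8InterfaceModel.fit` returns an
:class:`InterfaceResults` with the ranked hexagon table, the per-rank
profiles and the four indicators per compartment.

:class:`RecurrenceModel` wraps the statistical half — univariate Cox
screening, stepwise-LR multivariate Cox, KM/log-rank on the dichotomized
predictors, Fisher's exact test on the recurrence × margin table, and the
Relapse Score stratification — and returns a :class:`RecurrenceResults`
with a Table 2-style summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indicators as ind
from . import survival as surv
from .edge_rank import RankingParams, rank_compartments
from .hexgrid import DEFAULT_HEX_SIDE_UM, aggregate_scene, build_grid
from .scene import SegmentationScene


class CD8InterfaceModel:
    """Interface-zone CD8+ profiling of one slide.

    Parameters
    ----------
    scene
        Tissue/compartment label rasters.
    cells
        Cell table (x_um, y_um, phenotype).
    hex_side_um
        Hexagon side length (default 65 µm).
    ranking
        Labeling/ranking thresholds.
    """

    def __init__(self, scene: SegmentationScene, cells: pd.DataFrame,
                 hex_side_um: float = DEFAULT_HEX_SIDE_UM,
                 ranking: RankingParams = RankingParams()):
        self.scene = scene
        self.cells = cells
        self.hex_side_um = hex_side_um
        self.ranking = ranking

    @classmethod
    def from_hex_table(cls, hex_table: pd.DataFrame,
                       ranking: RankingParams = RankingParams()):
        """Re-analysis entry point from a saved per-hexagon table.

        Skips rasterization; ranking and indicators are recomputed, so a
        persisted table reproduces the pipeline values exactly.
        """
        obj = cls.__new__(cls)
        obj.scene = None
        obj.cells = None
        obj.hex_side_um = np.nan
        obj.ranking = ranking
        obj._hex_table = hex_table
        return obj

    def fit(self) -> "InterfaceResults":
        if getattr(self, "_hex_table", None) is not None:
            aggs = self._hex_table
        else:
            grid = build_grid(self.scene.bbox_um, self.hex_side_um)
            aggs = aggregate_scene(self.scene, self.cells, grid)
        ranked = rank_compartments(aggs, self.ranking)
        per_comp = ind.compute_indicators(ranked)
        return InterfaceResults(model=self, hexagons=ranked, per_compartment=per_comp)


@dataclass
class InterfaceResults:
    """Ranked hexagons plus interface-zone profiles and indicators."""

    model: CD8InterfaceModel
    hexagons: pd.DataFrame
    per_compartment: dict

    def profile(self, compartment: str = "tumor"):
        return self.per_compartment[compartment]["profile"]

    def indicators(self, compartment: str = "tumor"):
        return self.per_compartment[compartment]["indicators"]

    def summary(self) -> pd.DataFrame:
        """One row per compartment: the four indicators and their log copies."""
        rows = []
        for comp, entry in self.per_compartment.items():
            iset = entry["indicators"]
            row = {"compartment": comp}
            row.update(iset.as_dict() if iset is not None
                       else {k: np.nan for k in
                             ("mean_density", "edge_sd", "center_of_mass",
                              "immunodrop_ratio", "log_mean_density",
                              "log_edge_sd", "log_immunodrop_ratio")})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out = {"hex_side_um": self.model.hex_side_um,
               "orientation": "flat_top", "compartments": {}}
        for comp, entry in self.per_compartment.items():
            prof, iset = entry["profile"], entry["indicators"]
            out["compartments"][comp] = {
                "profile": (prof.to_frame().to_dict(orient="records")
                            if prof is not None else None),
                "indicators": iset.as_dict() if iset is not None else None,
            }
        return out

    def plot_rank_map(self, ax=None):
        """Hexagon scatter colored by signed rank, for visual QA."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        ranked = self.hexagons[self.hexagons["rank"].notna()]
        sc = ax.scatter(ranked["center_x_um"], ranked["center_y_um"],
                        c=ranked["rank"], cmap="coolwarm", vmin=-4, vmax=4,
                        s=12, marker="h")
        ax.set_aspect("equal")
        ax.invert_yaxis()
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        plt.colorbar(sc, ax=ax, label="interface rank")
        return ax


class RecurrenceModel:
    """Recurrence-free-survival modeling of a cohort table.

    The cohort table needs ``rfs_days`` and ``event`` columns, a ``margin``
    column (R0/R1) or a binary ``r1`` column, and an ``edge_sd`` column (or
    a precomputed binary ``low_sd``).  Candidate covariates default to the
    binary R1 and low-SD flags; additional columns can be screened by name.
    """

    def __init__(self, cohort: pd.DataFrame, candidates: list[str] | None = None,
                 sd_cutoff: float = surv.DEFAULT_SD_CUTOFF, ties: str = "breslow",
                 alpha_enter: float = 0.05, alpha_stay: float = 0.05,
                 time_col: str = "rfs_days", event_col: str = "event"):
        self.cohort = cohort.copy()
        self.sd_cutoff = sd_cutoff
        self.ties = ties
        self.alpha_enter = alpha_enter
        self.alpha_stay = alpha_stay
        self.time_col = time_col
        self.event_col = event_col
        if "r1" not in self.cohort.columns and "margin" in self.cohort.columns:
            self.cohort["r1"] = (self.cohort["margin"] == "R1").astype(int)
        if "low_sd" not in self.cohort.columns and "edge_sd" in self.cohort.columns:
            self.cohort["low_sd"] = (
                self.cohort["edge_sd"] < sd_cutoff).astype(int)
        self.candidates = candidates if candidates is not None else ["r1", "low_sd"]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RecurrenceModel":
        return cls(df, **kwargs)

    def fit(self) -> "RecurrenceResults":
        tab = self.cohort
        screen = surv.univariate_screen(tab, self.candidates,
                                        self.time_col, self.event_col, self.ties)
        step = surv.stepwise_lr(tab, self.candidates, self.alpha_enter,
                                self.alpha_stay, self.time_col, self.event_col,
                                self.ties)
        # dichotomized single-predictor KM contrasts
        km = {}
        for flag in ("r1", "low_sd"):
            if flag in tab.columns and tab[flag].nunique() == 2:
                km[flag] = surv.km_logrank(tab[self.time_col], tab[self.event_col],
                                           tab[flag])
        # score stratification
        scored = tab.copy()
        scored["score"] = scored.get("r1", 0) + scored.get("low_sd", 0)
        contrasts = surv.score_stratification(scored, "score",
                                              self.time_col, self.event_col)
        # recurrence × margin 2x2 (Fisher)
        fisher = None
        if "r1" in tab.columns and tab["r1"].nunique() == 2:
            e = tab[self.event_col].astype(int)
            r1 = tab["r1"].astype(int)
            a = int(((r1 == 1) & (e == 1)).sum())
            b = int(((r1 == 1) & (e == 0)).sum())
            c = int(((r1 == 0) & (e == 1)).sum())
            d = int(((r1 == 0) & (e == 0)).sum())
            oratio, p = surv.fisher_exact_2x2(a, b, c, d)
            fisher = {"table": [[a, b], [c, d]], "odds_ratio": oratio, "p": p}
        return RecurrenceResults(model=self, screen=screen, stepwise=step,
                                 km_by_flag=km, score_contrasts=contrasts,
                                 fisher_margin=fisher, scored=scored)


@dataclass
class RecurrenceResults:
    """Fitted recurrence model: screen, selection, KM contrasts, score, Fisher."""

    model: RecurrenceModel
    screen: pd.DataFrame
    stepwise: surv.StepwiseResult
    km_by_flag: dict
    score_contrasts: dict
    fisher_margin: dict | None
    scored: pd.DataFrame

    @property
    def fit_(self) -> surv.CoxFit | None:
        return self.stepwise.fit

    def summary(self) -> pd.DataFrame:
        """Final multivariate Cox table (estimate, SE, chi-square, p, HR, CI)."""
        if self.stepwise.fit is None:
            return pd.DataFrame()
        return self.stepwise.fit.summary()

    def report_dict(self) -> dict:
        d = {
            "univariate": self.screen.to_dict(orient="records"),
            "selection_path": self.stepwise.path,
            "selected": self.stepwise.selected,
            "status": self.stepwise.status,
            "final_model": (self.stepwise.fit.as_dict()
                            if self.stepwise.fit else None),
            "fisher_margin_recurrence": self.fisher_margin,
            "score_contrasts": {},
            "sd_cutoff": self.model.sd_cutoff,
            "sd_cutoff_note": ("cutoff applied to raw edge SD; "
                               "scale is configuration, not estimated from data"),
        }
        for name, res in self.score_contrasts.items():
            d["score_contrasts"][name] = (
                None if res is None else
                {"chi2": res.chi2, "p": res.p_value, "n": res.n_per_group}
            )
        for flag, res in self.km_by_flag.items():
            d.setdefault("km_by_flag", {})[flag] = {
                "chi2": res.chi2, "p": res.p_value, "n": res.n_per_group}
        return d

    def plot_km(self, by: str = "score_contrast:0_vs_12", ax=None):
        """Kaplan–Meier plot for one stored contrast (flag or score contrast)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        if by.startswith("score_contrast:"):
            res = self.score_contrasts[by.split(":", 1)[1]]
        else:
            res = self.km_by_flag[by]
        if res is None:
            raise ValueError(f"contrast {by!r} was skipped (empty side)")
        for g, curve in res.curves.items():
            ax.step(curve["time"], curve["survival"], where="post", label=str(g))
        ax.set_xlabel("days")
        ax.set_ylabel("RFS probability")
        ax.set_ylim(0, 1.02)
        ax.legend(title=f"log-rank p = {res.p_value:.4g}")
        return ax
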
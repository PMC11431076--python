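"""End-to-end pipeline: simulate → hexify → rank → indicators → survival.

A :class:`PipelineConfig` resolves entirely from defaults; a run writes
per-stage outputs into a run directory plus a manifest (config hash, seed,
per-file SHA-256) and a human-readable report.  Rerunning with the same
config and seed reproduces all numeric outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .edge_rank import RankingParams, rank_compartments
from .hexgrid import DEFAULT_HEX_SIDE_UM, aggregate_scene, build_grid
from .model import CD8InterfaceModel, RecurrenceModel
from .survival import DEFAULT_SD_CUTOFF
from .synthetic import Cd8ProfileParams, CohortParams, SceneParams, \
    generate_cd8_points, generate_cohort, generate_scene

log = logging.getLogger("immunohex")


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, resolvable without user input."""

    hex_side_um: float = DEFAULT_HEX_SIDE_UM
    epithelial_fraction_threshold: float = 0.5
    min_tissue_fraction: float = 0.5
    max_abs_rank: int = 2
    sd_cutoff: float = DEFAULT_SD_CUTOFF
    ties: str = "breslow"
    alpha_enter: float = 0.05
    alpha_stay: float = 0.05
    seed: int = 0
    simulate: bool = True
    scene: dict = field(default_factory=dict)
    cd8: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    out_dir: str = "immunohex_run"

    def ranking_params(self) -> RankingParams:
        return RankingParams(
            epithelial_fraction_threshold=self.epithelial_fraction_threshold,
            min_tissue_fraction=self.min_tissue_fraction,
            max_abs_rank=self.max_abs_rank,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full workflow; returns the run directory.

    Stage outputs are never mutated by later stages; any stage failure
    raises :class:`StageError` after writing a manifest that marks the
    failed stage and retains partial outputs.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    stage = "setup"
    try:
        stage = "simulate"
        sp = SceneParams(**{"seed": config.seed, **config.scene})
        scene = generate_scene(sp)
        cd8p = Cd8ProfileParams(**{"seed": config.seed + 1, **config.cd8})
        cells = generate_cd8_points(scene, cd8p)
        files.extend(hio.write_scene(scene, run_dir).values())
        files.append(hio.write_cell_table(cells, run_dir / "cells.csv"))
        cohort = generate_cohort(CohortParams(**{"seed": config.seed + 2,
                                                 **config.cohort}))
        cohort_path = run_dir / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        files.append(cohort_path)

        stage = "hexify"
        grid = build_grid(scene.bbox_um, config.hex_side_um)
        aggs = aggregate_scene(scene, cells, grid)
        hex_path = run_dir / "hexagons.csv"
        aggs.to_csv(hex_path, index=False)
        files.append(hex_path)

        stage = "rank"
        ranked = rank_compartments(aggs, config.ranking_params())
        ranked_path = run_dir / "hexagons_ranked.csv"
        ranked.to_csv(ranked_path, index=False)
        files.append(ranked_path)

        stage = "indicators"
        iface = CD8InterfaceModel.from_hex_table(
            ranked, config.ranking_params()).fit()
        files.append(hio.write_json(iface.to_json_dict(),
                                    run_dir / "indicators.json"))

        stage = "survival"
        rec = RecurrenceModel(cohort, sd_cutoff=config.sd_cutoff,
                              ties=config.ties, alpha_enter=config.alpha_enter,
                              alpha_stay=config.alpha_stay).fit()
        files.append(hio.write_json(rec.report_dict(),
                                    run_dir / "survival_report.json"))
        score_path = run_dir / "score_table.csv"
        rec.scored.to_csv(score_path, index=False)
        files.append(score_path)

        stage = "report"
        files.extend(_write_plots(run_dir, iface, rec))
        files.append(_write_report(run_dir, iface, rec))
        hio.write_manifest(run_dir, config.to_dict(), files)
        return run_dir
    except Exception as err:
        hio.write_manifest(run_dir, config.to_dict(), files,
                           status="failed", failed_stage=stage)
        raise StageError(stage, err) from err


def _write_plots(run_dir: Path, iface, rec) -> list[Path]:
    """Rank-map raster and KM curves for the available score contrasts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = []
    ax = iface.plot_rank_map()
    path = run_dir / "rank_map.png"
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
    out.append(path)
    for name, res in rec.score_contrasts.items():
        if res is None:
            continue
        ax = rec.plot_km(f"score_contrast:{name}")
        path = run_dir / f"km_score_{name}.png"
        ax.figure.savefig(path, dpi=120)
        plt.close(ax.figure)
        out.append(path)
    return out


def _write_report(run_dir: Path, iface, rec) -> Path:
    lines = ["# immunohex run report", "",
             "## Interface indicators (per compartment)", ""]
    lines.append(iface.summary().round(4).to_string(index=False))
    lines += ["", "## Final Cox model", ""]
    summ = rec.summary()
    lines.append(summ.round(4).to_string(index=False) if len(summ)
                 else f"(no covariate selected: {rec.stepwise.status})")
    if rec.fisher_margin:
        lines += ["", f"Fisher recurrence×margin p = {rec.fisher_margin['p']:.4f}"]
    for name, res in rec.score_contrasts.items():
        if res is not None:
            lines.append(f"Relapse Score contrast {name}: log-rank p = {res.p_value:.4g}")
    path = run_dir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
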
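"""End-to-end pipeline: phenotype -> spatial -> signatures -> association.

`run_pipeline` binds the stages together from a `PipelineConfig`, writing a
per-sample score table, the association-screen table, a long-format
dot-plot table, KM curve tables for tertile splits, and a JSON run manifest
with content hashes.  Re-running with identical inputs and seed is
byte-identical for CSV outputs.

`simulate_inputs` generates a complete synthetic input bundle (cell tables
with per-sample colocalization that varies across the cohort, expression
with planted signature structure, and clinical outcomes tied to the
spatial scores) so the whole pipeline can run with no external data.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iomod
from .association import ScreenPlan, km_curves_by_group, run_association_screen, tertile_split
from .phenotyping import assign_phenotypes, default_rules, summarize_abundance
from .signatures import SignatureDef, mean_center, score_all
from .spatial import (
    ANTI_TUMOR_CLASSES,
    PRO_TUMOR_CLASSES,
    DEFAULT_R_MAX_UM,
    DEFAULT_SQUARE_SIZE_UM,
    ecoscore,
    sample_spatial_scores,
)
from .synthetic import OutcomeModel, SimulationConfig, simulate_cell_pattern, simulate_clinical, simulate_expression

log = logging.getLogger(__name__)

DEFAULT_PAIRS = [
    ("tumor", "cytotoxic T"),
    ("tumor", "helper T"),
    ("tumor", "Treg"),
    ("tumor", "macrophage"),
    ("cytotoxic T", "Treg"),
]


@dataclass
class PipelineConfig:
    cells_path: str | None = None
    expression_path: str | None = None
    signatures_path: str | None = None
    clinical_path: str | None = None
    rules_path: str | None = None
    plan_path: str | None = None
    square_size_um: float = DEFAULT_SQUARE_SIZE_UM
    r_max_um: float = DEFAULT_R_MAX_UM
    radii_step_um: float = 1.0
    window_area_mm2: float = 0.36
    spatial_pairs: list = field(default_factory=lambda: list(DEFAULT_PAIRS))
    seed: int = 0
    out_dir: str = "immunospat_out"

    def __post_init__(self):
        for name in ("square_size_um", "r_max_um", "radii_step_um", "window_area_mm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as e:
        raise StageError(name, e) from e


def build_score_table(
    cells: pd.DataFrame | None,
    expr: pd.DataFrame | None,
    sigs: list | None,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-sample scalar features: densities, MH/SPS per pair, Ecoscore,
    signature scores — merged on sample_id."""
    parts = []
    if cells is not None:
        abund = summarize_abundance(cells, config.window_area_mm2)
        dens = abund.pivot(index="sample_id", columns="phenotype", values="density_per_mm2")
        dens.columns = [f"density({c})" for c in dens.columns]
        spat = sample_spatial_scores(
            cells, config.spatial_pairs, config.square_size_um,
            config.r_max_um, config.radii_step_um).set_index("sample_id")
        eco = []
        for sid in spat.index:
            anti = {c: spat.loc[sid].get(f"SPS({c},tumor)", float("nan"))
                    for c in ANTI_TUMOR_CLASSES}
            pro = {c: spat.loc[sid].get(f"SPS({c},tumor)", float("nan"))
                   for c in PRO_TUMOR_CLASSES}
            eco.append(ecoscore(anti, pro, sample_id=sid).category)
        spat["ecoscore"] = eco
        parts += [dens, spat]
    if expr is not None and sigs:
        centered = mean_center(expr)
        parts.append(score_all(centered, sigs))
    if not parts:
        raise ValueError("no inputs produce any scores")
    out = parts[0]
    for p in parts[1:]:
        out = out.join(p, how="outer")
    out.index.name = "sample_id"
    return out.reset_index()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and write the output bundle.

    Returns a dict with the in-memory tables and the paths written.  Any
    stage failure raises :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cells = expr = sigs = clinical = None
    if config.cells_path:
        cells = _stage("read_cells", iomod.read_cell_table, config.cells_path)
        if len(cells) == 0:
            raise StageError("read_cells", ValueError("empty cell table"))
        rules = (iomod.read_rules(config.rules_path) if config.rules_path
                 else default_rules())
        cells = _stage("phenotype", assign_phenotypes, cells, rules)
    if config.expression_path:
        expr = _stage("read_expression", iomod.read_expression, config.expression_path)
        sigs = _stage("read_signatures", iomod.read_gmt, config.signatures_path)
    if config.clinical_path:
        clinical = _stage("read_clinical", iomod.read_clinical, config.clinical_path)

    # spatial SPS pairs implied by the Ecoscore defaults must be present
    pairs = list(config.spatial_pairs)
    for c in (*ANTI_TUMOR_CLASSES, *PRO_TUMOR_CLASSES):
        if (c, "tumor") not in pairs:
            pairs.append((c, "tumor"))
    cfg = dataclasses.replace(config, spatial_pairs=pairs)

    scores = _stage("scores", build_score_table, cells, expr, sigs, cfg)
    scores_path = out_dir / "score_table.csv"
    scores.to_csv(scores_path, index=False)
    written.append(scores_path)

    result = {"scores": scores, "out_dir": out_dir}
    if clinical is not None:
        plan = (iomod.read_screen_plan(config.plan_path) if config.plan_path
                else ScreenPlan(
                    variables=[c for c in scores.columns
                               if c != "sample_id"
                               and pd.api.types.is_numeric_dtype(scores[c])],
                    covariate_sets={"unadjusted": (),
                                    "ER+rCR-adjusted": ("er_positive", "rcr")}))
        screen = _stage("associate", run_association_screen, scores, clinical, plan)
        screen_path = out_dir / "association_results.csv"
        screen.to_csv(screen_path, index=False)
        written.append(screen_path)
        dot = screen[["variable", "endpoint", "subgroup", "covariates",
                      "estimate", "lr_p", "bh_adjusted_p", "tier"]]
        dot_path = out_dir / "dot_plot_table.csv"
        dot.to_csv(dot_path, index=False)
        written.append(dot_path)
        result["screen"] = screen

        # tertile KM tables for the first estimable screen variable
        km_tables = {}
        merged = clinical.merge(scores, left_on="patient_id", right_on="sample_id")
        for var in plan.variables:
            vals = merged[var]
            if vals.notna().sum() >= 3 and vals.nunique() >= 3:
                labels = tertile_split(vals)
                curves, p = km_curves_by_group(merged, labels)
                km = pd.concat(
                    [c.rename(columns={c.columns[0]: "survival"}).assign(group=g)
                     for g, c in curves.items()])
                km["logrank_p"] = p
                km_tables[var] = km
                break
        for var, km in km_tables.items():
            p_km = out_dir / f"km_tertiles_{_safe(var)}.csv"
            km.to_csv(p_km)
            written.append(p_km)
        result["km_tables"] = km_tables

    manifest = iomod.write_manifest(
        out_dir, config.seed,
        {k: v for k, v in dataclasses.asdict(config).items()},
        written)
    result["manifest"] = manifest
    result["written"] = written
    return result


def _safe(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)


def simulate_inputs(
    out_dir,
    n_samples: int = 40,
    seed: int = 0,
    n_genes: int = 300,
    base_config: SimulationConfig | None = None,
) -> dict:
    """Write a complete synthetic input bundle under ``out_dir``.

    Per-sample colocalization (shared_parent_fraction) varies across the
    cohort and drives survival through a log-hazard on the
    tumor/cytotoxic-T Morisita-Horn score, so downstream associations have
    a planted signal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base = base_config or SimulationConfig(seed=seed)

    frames = []
    fractions = rng.uniform(0, 1, n_samples)
    for i, f in enumerate(fractions):
        cfg = dataclasses.replace(base, shared_parent_fraction=float(f),
                                  seed=int(rng.integers(2**31)))
        sid = f"S{i:03d}"
        pat = simulate_cell_pattern(cfg, ("tumor", "cytotoxic T"), sample_id=sid)
        # second immune compartment so density/Ecoscore columns are non-trivial
        cfg2 = dataclasses.replace(cfg, offspring_mean_a=0.0, offspring_mean_b=6.0,
                                   seed=int(rng.integers(2**31)))
        tregs = simulate_cell_pattern(cfg2, ("tumor", "Treg"), sample_id=sid)
        tregs = tregs[tregs["phenotype"] == "Treg"]
        pat = pd.concat([pat, tregs], ignore_index=True)
        pat["cell_id"] = [f"c{i:05d}" for i in range(len(pat))]
        frames.append(pat)
    cells = pd.concat(frames, ignore_index=True)
    cells = cells.drop(columns=["phenotype"])  # pipeline re-derives from markers
    cells_path = out_dir / "cells.csv"
    iomod.write_cell_table(cells, cells_path)

    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    sigs = [
        SignatureDef("t_cell_signaling", tuple(f"TC{j:03d}" for j in range(20))),
        SignatureDef("b_cell_signaling", tuple(f"BC{j:03d}" for j in range(15))),
        SignatureDef("interferon", tuple(f"IF{j:03d}" for j in range(10))),
    ]
    expr = simulate_expression(n_genes, sample_ids, sigs,
                               {"t_cell_signaling": 2.0, "interferon": 1.0},
                               seed=int(rng.integers(2**31)))
    expr_path = out_dir / "expression.tsv"
    iomod.write_expression(expr, expr_path)
    gmt_path = out_dir / "signatures.gmt"
    iomod.write_gmt(sigs, gmt_path)

    # clinical outcomes driven by the planted colocalization level
    score_stub = pd.DataFrame({"sample_id": sample_ids, "coloc": fractions,
                               "sample_type": "primary"})
    model = OutcomeModel(
        baseline_hazard_scale=0.03,
        log_hazard_coefficients={"coloc": -0.7},
        logistic_intercept=-1.5,
        logistic_coefficients={"coloc": 0.8},
        censoring_time_months=180.0,
        seed=int(rng.integers(2**31)),
    )
    clinical = simulate_clinical(score_stub, model)
    clinical["sTILs_percent"] = np.round(rng.uniform(0, 60, n_samples), 1)
    clin_path = out_dir / "clinical.csv"
    clinical.to_csv(clin_path, index=False)

    return {"cells": cells_path, "expression": expr_path,
            "signatures": gmt_path, "clinical": clin_path,
            "true_fraction": dict(zip(sample_ids, fractions))}
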
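"""Synthetic data with the statistical structure the analysis assumes.

Three generators, each a pure function of its configuration and seed:

* **Cell patterns** — a two-type Thomas-style cluster process in a
  rectangular window emulating a tissue-microarray core: Poisson parents,
  Poisson offspring counts, Gaussian displacements, plus uniform Poisson
  background per type.  ``shared_parent_fraction`` interpolates between
  fully shared parents (both types cluster around the same centers →
  colocalized) and independent parents (segregated) while leaving each
  type's marginal distribution unchanged: a fraction f of the parent
  intensity is common to both types, the rest private per type.
  Offspring falling outside the window are discarded (a physical core
  boundary, no wrap-around).

* **Clinical outcomes** — overall-survival times from a proportional-hazards
  model with Weibull baseline (exponential by default), administratively
  censored, and a Bernoulli radiological-complete-response indicator via a
  logistic link.  Scores are z-scored before entering the linear predictors
  so coefficients are per standard deviation.

* **Expression matrices** — i.i.d. standard-normal background genes, with
  each signature's genes sharing an additive per-sample latent factor scaled
  by its effect size, so the signature score tracks the factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotyping import MARKERS, default_rules
from .signatures import SignatureDef


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-type clustered point-pattern generator.

    Intensities are per mm^2; lengths in µm.  Defaults emulate a 600 µm
    square core with a tumor-like abundant type A and a sparser immune-like
    type B.
    """

    window_width_um: float = 600.0
    window_height_um: float = 600.0
    parent_intensity: float = 10.0  # parents per mm^2
    offspring_mean_a: float = 40.0
    offspring_mean_b: float = 15.0
    offspring_sd_um: float = 20.0
    shared_parent_fraction: float = 0.5
    background_intensity_per_type: float = 20.0  # cells per mm^2
    seed: int = 0

    def __post_init__(self):
        if self.window_width_um <= 0 or self.window_height_um <= 0:
            raise ValueError("window dimensions must be positive")
        for name in ("parent_intensity", "offspring_mean_a", "offspring_mean_b",
                     "offspring_sd_um", "background_intensity_per_type"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.shared_parent_fraction <= 1.0:
            raise ValueError("shared_parent_fraction must lie in [0, 1]")

    @property
    def area_mm2(self) -> float:
        return self.window_width_um * self.window_height_um / 1e6


@dataclass(frozen=True)
class OutcomeModel:
    """Survival + response generator parameters.

    ``log_hazard_coefficients`` maps score names to log hazard ratios per
    SD; ``logistic_coefficients`` likewise to log odds ratios for the
    response endpoint.
    """

    baseline_hazard_scale: float = 0.02  # events per month
    log_hazard_coefficients: dict = field(default_factory=dict)
    censoring_time_months: float = 120.0
    logistic_intercept: float = -1.0
    logistic_coefficients: dict = field(default_factory=dict)
    weibull_shape: float = 1.0  # 1 = exponential baseline
    er_positive_fraction: float = 0.55
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hazard_scale <= 0:
            raise ValueError("baseline_hazard_scale must be positive")
        if self.censoring_time_months <= 0:
            raise ValueError("censoring_time_months must be positive")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")


_PHENOTYPE_MARKERS = {r.name: r.required_positive for r in default_rules(False)}


def _cells_frame(sample_id: str, xy: np.ndarray, phenotypes: list) -> pd.DataFrame:
    """Assemble a cell table whose marker calls are consistent with the
    generated phenotype labels."""
    n = len(xy)
    out = pd.DataFrame({
        "sample_id": sample_id,
        "cell_id": [f"c{i:05d}" for i in range(n)],
        "x_um": xy[:, 0] if n else np.empty(0),
        "y_um": xy[:, 1] if n else np.empty(0),
    })
    for m in MARKERS:
        out[m] = 0
    for i, ph in enumerate(phenotypes):
        for m in _PHENOTYPE_MARKERS.get(ph, ()):  # unknown labels get all-zero markers
            out.loc[i, m] = 1
    out["phenotype"] = phenotypes
    return out


def simulate_cell_pattern(
    config: SimulationConfig,
    type_names: tuple = ("tumor", "cytotoxic T"),
    sample_id: str = "S1",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one two-type clustered pattern; deterministic given config.seed.

    An explicit ``rng`` overrides the config seed (used when drawing many
    replicate cores from one stream).
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    w, h, area = cfg.window_width_um, cfg.window_height_um, cfg.area_mm2
    f = cfg.shared_parent_fraction

    def draw_parents(intensity):
        n = rng.poisson(intensity * area)
        return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])

    shared = draw_parents(f * cfg.parent_intensity)
    priv_a = draw_parents((1 - f) * cfg.parent_intensity)
    priv_b = draw_parents((1 - f) * cfg.parent_intensity)

    def spawn(parents, mean_offspring):
        pts = []
        for px, py in parents:
            k = rng.poisson(mean_offspring)
            if k:
                pts.append(np.column_stack([
                    px + rng.normal(0, cfg.offspring_sd_um, k),
                    py + rng.normal(0, cfg.offspring_sd_um, k),
                ]))
        out = np.concatenate(pts) if pts else np.empty((0, 2))
        keep = (out[:, 0] >= 0) & (out[:, 0] < w) & (out[:, 1] >= 0) & (out[:, 1] < h)
        return out[keep]

    pts_a = spawn(np.concatenate([shared, priv_a]), cfg.offspring_mean_a)
    pts_b = spawn(np.concatenate([shared, priv_b]), cfg.offspring_mean_b)
    bg_a = draw_parents(cfg.background_intensity_per_type)
    bg_b = draw_parents(cfg.background_intensity_per_type)

    xy = np.concatenate([pts_a, bg_a, pts_b, bg_b])
    labels = ([type_names[0]] * (len(pts_a) + len(bg_a))
              + [type_names[1]] * (len(pts_b) + len(bg_b)))
    return _cells_frame(sample_id, xy, labels)


def simulate_clinical(scores: pd.DataFrame, model: OutcomeModel) -> pd.DataFrame:
    """Survival and response outcomes tied to per-sample scores.

    Every score named in the model's coefficient maps must be a column of
    ``scores`` with no missing values.  Returns a clinical table with one
    row per sample (columns: patient_id, os_months, death_event, rcr,
    er_positive, sample_type, pair_id).
    """
    rng = np.random.default_rng(model.seed)
    names = sorted(set(model.log_hazard_coefficients) | set(model.logistic_coefficients))
    for name in names:
        if name not in scores.columns:
            raise KeyError(f"unknown score name in coefficients: {name!r}")
        if scores[name].isna().any():
            raise ValueError(f"score {name!r} has missing values")
    n = len(scores)

    def standardized(col):
        v = scores[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros(n)

    lp_surv = np.zeros(n)
    for name, beta in model.log_hazard_coefficients.items():
        lp_surv += beta * standardized(name)
    lp_resp = np.full(n, model.logistic_intercept, dtype=float)
    for name, gamma in model.logistic_coefficients.items():
        lp_resp += gamma * standardized(name)

    # inverse-CDF draw from Weibull PH: S(t) = exp(-b * t^k * e^lp)
    u = rng.uniform(size=n)
    t = (-np.log(u) / (model.baseline_hazard_scale * np.exp(lp_surv))) ** (1.0 / model.weibull_shape)
    event = (t <= model.censoring_time_months).astype(int)
    os_months = np.minimum(t, model.censoring_time_months)
    rcr = rng.binomial(1, 1.0 / (1.0 + np.exp(-lp_resp)))
    er = rng.binomial(1, model.er_positive_fraction, size=n)

    ids = (scores["sample_id"] if "sample_id" in scores.columns else scores.index).astype(str)
    stype = (scores["sample_type"] if "sample_type" in scores.columns
             else pd.Series(["primary"] * n, index=scores.index))
    return pd.DataFrame({
        "patient_id": ids.to_numpy(),
        "os_months": os_months,
        "death_event": event,
        "rcr": rcr,
        "er_positive": er,
        "sample_type": stype.to_numpy(),
        "pair_id": pd.array([pd.NA] * n, dtype="string"),
    })


def simulate_expression(
    n_genes: int,
    sample_ids: list,
    signature_defs: list,
    effect_map: dict | None = None,
    seed: int = 0,
    return_latent: bool = False,
):
    """Expression matrix with signature-correlated latent structure.

    Background genes are i.i.d. N(0, 1); every gene of signature *s* gains
    ``effect_map[s] * z_s`` where ``z_s`` is a per-sample standard-normal
    latent factor.  With ``return_latent`` the per-signature factors are
    returned alongside (signatures x samples) for recovery tests.
    """
    effect_map = effect_map or {}
    rng = np.random.default_rng(seed)
    sample_ids = list(sample_ids)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")

    sig_genes: list = []
    seen = set()
    for sig in signature_defs:
        for g in sig.genes:
            if g not in seen:
                seen.add(g)
                sig_genes.append(g)
    if len(sig_genes) > n_genes:
        raise ValueError("signature genes exceed requested gene universe")
    filler = []
    i = 0
    while len(sig_genes) + len(filler) < n_genes:
        name = f"G{i:05d}"
        if name not in seen:
            filler.append(name)
        i += 1
    genes = sig_genes + filler
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names")

    mat = rng.normal(size=(len(genes), len(sample_ids)))
    expr = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                        columns=pd.Index(sample_ids, name="sample_id"))
    latent = pd.DataFrame(index=[s.name for s in signature_defs], columns=sample_ids,
                          dtype=float)
    for sig in signature_defs:
        z = rng.normal(size=len(sample_ids))
        latent.loc[sig.name] = z
        effect = float(effect_map.get(sig.name, 0.0))
        if effect != 0.0:
            expr.loc[list(sig.genes)] += effect * z
    if return_latent:
        return expr, latent
    return expr
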
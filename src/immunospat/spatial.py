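"""Spatial statistics on two-type cell patterns.

Four statistics summarize how two cell phenotypes are arranged within a
tissue core:

* **Quadrat counts** — the core is tiled by non-overlapping squares
  (default 100 µm x 100 µm) and cells of each type are counted per square.
* **Morisita-Horn index (MH)** — similarity of the two per-square count
  vectors; 0 means the types never share a square (segregation), 1 means
  their spatial distributions coincide.  With per-square counts
  :math:`x_i, y_i` and totals :math:`X, Y`:

  .. math:: MH = \\frac{2\\sum_i x_i y_i}
                 {(\\sum_i x_i^2/X^2 + \\sum_i y_i^2/Y^2)\\, X Y}

* **G(r)** — the nearest-neighbor distance distribution: the fraction of
  reference-type cells whose nearest target-type cell lies within radius r.
* **Spatial Proximity Score (SPS)** — the normalized area under G(r) up to
  ``r_max`` (default 50 µm): 1 when every reference cell sits immediately
  next to a target cell, 0 when no target cell is within ``r_max``.

The **Ecoscore** classifies a sample as anti-tumor or pro-tumor by comparing
the mean SPS of anti-tumor cell classes (default cytotoxic T) against that
of pro-tumor classes (default Treg + macrophage), each measured as proximity
to tumor cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_SQUARE_SIZE_UM = 100.0
DEFAULT_R_MAX_UM = 50.0
DEFAULT_RADII_STEP_UM = 1.0

ANTI_TUMOR_CLASSES = ("cytotoxic T",)
PRO_TUMOR_CLASSES = ("Treg", "macrophage")


@dataclass
class QuadratCounts:
    sample_id: str
    square_size_um: float
    origin: tuple  # (x0, y0) in µm, bounding-box minimum of all sample cells
    counts_a: np.ndarray  # shape (nx, ny) ints
    counts_b: np.ndarray

    def __post_init__(self):
        self.counts_a = np.asarray(self.counts_a, dtype=np.int64)
        self.counts_b = np.asarray(self.counts_b, dtype=np.int64)
        if self.counts_a.shape != self.counts_b.shape:
            raise ValueError("quadrat grids have mismatched shapes")
        if (self.counts_a < 0).any() or (self.counts_b < 0).any():
            raise ValueError("quadrat counts must be non-negative")


@dataclass
class GFunctionCurve:
    radii: np.ndarray  # ordered, µm
    values: np.ndarray  # empirical G in [0, 1]
    type_a: str
    type_b: str
    n_a: int
    n_b: int
    missing_reason: str | None = None

    @property
    def missing(self) -> bool:
        return self.missing_reason is not None


@dataclass
class EcoscoreResult:
    sample_id: str
    category: str  # "anti-tumor" | "pro-tumor" | "indeterminate"
    sps_anti: dict = field(default_factory=dict)
    sps_pro: dict = field(default_factory=dict)
    reason: str | None = None


def _sample_points(cells: pd.DataFrame, phenotype: str) -> np.ndarray:
    sub = cells[cells["phenotype"] == phenotype]
    return sub[["x_um", "y_um"]].to_numpy(dtype=float)


def quadrat_counts(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    square_size_um: float = DEFAULT_SQUARE_SIZE_UM,
) -> QuadratCounts:
    """Tile the sample with half-open squares and count both types per square.

    The grid is anchored at the bounding-box minimum of *all* cells in the
    sample (not just the two types), and partial edge squares are included,
    so every in-window cell lands in exactly one square via
    ``floor((coord - origin) / square_size)``.
    """
    if square_size_um <= 0:
        raise ValueError("square_size_um must be positive")
    if len(cells) == 0:
        raise ValueError("empty pattern")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates")
    x0, y0 = xy[:, 0].min(), xy[:, 1].min()
    ix = np.floor((xy[:, 0] - x0) / square_size_um).astype(int)
    iy = np.floor((xy[:, 1] - y0) / square_size_um).astype(int)
    nx, ny = ix.max() + 1, iy.max() + 1
    sample_id = str(cells["sample_id"].iloc[0]) if "sample_id" in cells.columns else ""

    grids = []
    ph = cells["phenotype"].to_numpy()
    for t in (type_a, type_b):
        g = np.zeros((nx, ny), dtype=np.int64)
        mask = ph == t
        np.add.at(g, (ix[mask], iy[mask]), 1)
        grids.append(g)
    return QuadratCounts(sample_id, square_size_um, (x0, y0), grids[0], grids[1])


def morisita_horn(q: QuadratCounts) -> float:
    """Morisita-Horn similarity of the two quadrat-count grids.

    Returns ``nan`` (missing, not zero) when either type has no cells:
    zero would falsely assert observed segregation.  Symmetric in A/B and
    bounded in [0, 1].
    """
    x = q.counts_a.ravel().astype(float)
    y = q.counts_b.ravel().astype(float)
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        return math.nan
    num = 2.0 * float(np.dot(x, y))
    den = (float(np.dot(x, x)) / X**2 + float(np.dot(y, y)) / Y**2) * X * Y
    mh = num / den
    # clip tiny FP overshoot
    return min(max(mh, 0.0), 1.0)


def nearest_neighbor_distances(
    points_a: np.ndarray, points_b: np.ndarray, same_type: bool = False
) -> np.ndarray:
    """Distance from each A point to its nearest B point (self excluded
    when the two sets are the same pattern)."""
    tree = cKDTree(points_b)
    if same_type:
        d, _ = tree.query(points_a, k=2)
        return d[:, 1]
    d, _ = tree.query(points_a, k=1)
    return d


def g_function(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    radii: np.ndarray | None = None,
    border_correction: bool = False,
) -> GFunctionCurve:
    """Empirical nearest-neighbor distance distribution G(r) from A to B.

    No edge correction by default (tissue cores are small and counts per
    core low); with ``border_correction`` reference cells closer than r to
    the pattern's bounding box are dropped at each radius.
    """
    if radii is None:
        radii = np.arange(0.0, DEFAULT_R_MAX_UM + DEFAULT_RADII_STEP_UM, DEFAULT_RADII_STEP_UM)
    radii = np.asarray(radii, dtype=float)
    if (np.diff(radii) <= 0).any():
        raise ValueError("radii must be strictly increasing")
    pa = _sample_points(cells, type_a)
    pb = _sample_points(cells, type_b)
    if len(pa) == 0 or len(pb) == 0:
        which = type_a if len(pa) == 0 else type_b
        return GFunctionCurve(
            radii, np.full_like(radii, math.nan), type_a, type_b, len(pa), len(pb),
            missing_reason=f"no cells of type {which!r}",
        )
    same = type_a == type_b
    if same and len(pa) < 2:
        return GFunctionCurve(
            radii, np.full_like(radii, math.nan), type_a, type_b, len(pa), len(pb),
            missing_reason="single cell cannot be its own neighbor",
        )
    d = nearest_neighbor_distances(pa, pb, same_type=same)
    if border_correction:
        xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        dist_to_border = np.minimum(pa - lo, hi - pa).min(axis=1)
        values = np.array([
            np.mean(d[dist_to_border >= r] <= r) if (dist_to_border >= r).any() else math.nan
            for r in radii
        ])
    else:
        values = (d[None, :] <= radii[:, None]).mean(axis=1)
    return GFunctionCurve(radii, values, type_a, type_b, len(pa), len(pb))


def spatial_proximity_score(curve: GFunctionCurve, r_max_um: float = DEFAULT_R_MAX_UM) -> float:
    """Normalized area under G(r) on [0, r_max] by the trapezoidal rule.

    Raises on non-positive ``r_max``; returns ``nan`` for a missing curve.
    """
    if r_max_um <= 0:
        raise ValueError("r_max_um must be positive")
    if curve.missing:
        return math.nan
    r, g = curve.radii, curve.values
    if r_max_um > r[-1]:
        raise ValueError(f"r_max {r_max_um} outside stored radii range (max {r[-1]})")
    keep = r <= r_max_um
    rr, gg = r[keep], g[keep]
    if rr[-1] < r_max_um:  # close the interval at r_max by interpolation
        rr = np.append(rr, r_max_um)
        gg = np.append(gg, np.interp(r_max_um, r, g))
    if rr[0] > 0:
        rr = np.insert(rr, 0, 0.0)
        gg = np.insert(gg, 0, 0.0)
    return float(np.trapezoid(gg, rr) / r_max_um)


def ecoscore(
    sps_anti: dict | list,
    sps_pro: dict | list,
    margin: float = 0.0,
    sample_id: str = "",
) -> EcoscoreResult:
    """Classify a microenvironment by relative proximity to tumor cells.

    ``sps_anti`` / ``sps_pro`` hold the SPS of each anti-/pro-tumor cell
    class to tumor cells.  The sample is *anti-tumor* when
    ``mean(anti) > mean(pro) * (1 + margin)``, *pro-tumor* on the reverse,
    otherwise *indeterminate*.  Missing inputs (empty or all-NaN on either
    side) yield indeterminate with a reason.
    """
    def as_dict(v, prefix):
        if isinstance(v, dict):
            return dict(v)
        return {f"{prefix}{i}": x for i, x in enumerate(v)}

    anti = as_dict(sps_anti, "anti")
    pro = as_dict(sps_pro, "pro")
    a_vals = [v for v in anti.values() if v is not None and not math.isnan(v)]
    p_vals = [v for v in pro.values() if v is not None and not math.isnan(v)]
    if not a_vals or not p_vals:
        side = "anti-tumor" if not a_vals else "pro-tumor"
        return EcoscoreResult(sample_id, "indeterminate", anti, pro,
                              reason=f"missing {side} proximity scores")
    ma, mp = float(np.mean(a_vals)), float(np.mean(p_vals))
    if ma > mp * (1.0 + margin):
        cat = "anti-tumor"
    elif mp > ma * (1.0 + margin):
        cat = "pro-tumor"
    else:
        cat = "indeterminate"
    return EcoscoreResult(sample_id, cat, anti, pro)


def sample_spatial_scores(
    cells: pd.DataFrame,
    pairs: list[tuple],
    square_size_um: float = DEFAULT_SQUARE_SIZE_UM,
    r_max_um: float = DEFAULT_R_MAX_UM,
    radii_step_um: float = DEFAULT_RADII_STEP_UM,
) -> pd.DataFrame:
    """Per-sample MH and SPS for each requested (type_a, type_b) pair.

    Returns a wide table with one row per sample and columns
    ``MH(<a>,<b>)`` and ``SPS(<a>,<b>)``; statistics that cannot be
    computed (a type absent in that sample) come back as NaN.
    """
    radii = np.arange(0.0, r_max_um + radii_step_um, radii_step_um)
    rows = []
    for sample_id, grp in cells.groupby("sample_id", sort=True):
        row: dict = {"sample_id": sample_id}
        for a, b in pairs:
            present_a = (grp["phenotype"] == a).any()
            present_b = (grp["phenotype"] == b).any()
            if present_a and present_b:
                q = quadrat_counts(grp, a, b, square_size_um)
                row[f"MH({a},{b})"] = morisita_horn(q)
            else:
                row[f"MH({a},{b})"] = math.nan
            curve = g_function(grp, a, b, radii)
            row[f"SPS({a},{b})"] = spatial_proximity_score(curve, r_max_um)
        rows.append(row)
    return pd.DataFrame(rows)
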
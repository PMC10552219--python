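"""Gene-signature scoring on mean-centered expression matrices.

Expression arrives as a genes x samples matrix of log-scale values.  Each
gene row is centered to mean zero across samples, and a signature score is
the (optionally direction-weighted) mean of the centered values of the
signature's genes that are present in the matrix.  Signature genes absent
from the matrix are dropped with a warning; a signature with no genes
present scores as missing rather than raising.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CENTERED_FLAG = "immunospat_centered"


@dataclass(frozen=True)
class SignatureDef:
    """Named gene set with optional +1/-1 direction weights (default +1)."""

    name: str
    genes: tuple
    weights: tuple | None = None
    description: str = ""

    def __post_init__(self):
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if not genes:
            raise ValueError(f"signature {self.name!r} has an empty gene list")
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        if self.weights is not None:
            w = tuple(float(x) for x in self.weights)
            if len(w) != len(genes):
                raise ValueError(f"signature {self.name!r}: weights/genes length mismatch")
            object.__setattr__(self, "weights", w)

    def weight_map(self) -> dict:
        w = self.weights if self.weights is not None else (1.0,) * len(self.genes)
        return dict(zip(self.genes, w))


def _check_matrix(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    if expr.columns.has_duplicates:
        raise ValueError("duplicate sample ids in expression matrix")


def is_centered(expr: pd.DataFrame) -> bool:
    return bool(expr.attrs.get(CENTERED_FLAG, False))


def mean_center(expr: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's across-sample mean.  Idempotent; needs >= 2 samples."""
    _check_matrix(expr)
    if expr.shape[1] < 2:
        raise ValueError("mean-centering needs at least 2 samples")
    out = expr.sub(expr.mean(axis=1), axis=0)
    out.attrs[CENTERED_FLAG] = True
    return out


def score_signature(expr: pd.DataFrame, sig: SignatureDef) -> pd.Series:
    """Per-sample score: mean of weight x centered expression over the
    signature genes present in ``expr``.

    Returns an all-NaN series (with a warning) when no signature gene is
    present.  ``expr`` must already be centered.
    """
    if not is_centered(expr):
        raise ValueError("expression matrix must be mean-centered first")
    wmap = sig.weight_map()
    present = [g for g in sig.genes if g in expr.index]
    absent = [g for g in sig.genes if g not in expr.index]
    if absent:
        log.warning("signature %s: %d/%d genes absent from matrix: %s",
                    sig.name, len(absent), len(sig.genes), ", ".join(absent[:5]))
    if not present:
        log.warning("signature %s: no genes present; score is missing", sig.name)
        return pd.Series(math.nan, index=expr.columns, name=sig.name)
    w = np.array([wmap[g] for g in present])
    vals = expr.loc[present].to_numpy()
    score = (w[:, None] * vals).mean(axis=0)
    return pd.Series(score, index=expr.columns, name=sig.name)


def score_all(expr: pd.DataFrame, sigs: list[SignatureDef]) -> pd.DataFrame:
    """Score every signature; one column per signature, one row per sample."""
    names = [s.name for s in sigs]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate signature names: {', '.join(dup)}")
    out = pd.DataFrame(index=expr.columns)
    out.index.name = "sample_id"
    for sig in sigs:
        out[sig.name] = score_signature(expr, sig)
    return out
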
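"""Phenotype gating of segmented multiplex-IF cells.

Cells arrive as rows of a *cell table* (one row per segmented cell) carrying
binary positivity calls for the panel markers (CD3, CD8, CD20, CD56, CD68,
FoxP3, PD1, PDL1, CK, Ki-67).  Gating assigns each cell exactly one
phenotype label via a prioritized rule set: a rule names the markers that
must be positive and those that must be negative, and the highest-priority
satisfied rule wins.  Cells matching no rule are labelled ``"other"``, so the
labels always partition the table.

The default rules encode the standard immuno-oncology gates: tumor cells are
cytokeratin-positive (CK+); cytotoxic T cells CD3+CD8+; helper T cells
CD3+CD8-; regulatory T cells (Tregs) CD3+FoxP3+CD8-; B cells CD20+;
macrophages CD68+; NK cells CD56+.  Because the two staining panels are
applied to different sections, FoxP3 and CD8 never co-occur on a real cell;
the priority ordering (Treg above cytotoxic T) still resolves the synthetic
overlap deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARKERS = ("CD3", "CD8", "CD20", "CD56", "CD68", "FoxP3", "PD1", "PDL1", "CK", "Ki-67")

OTHER_LABEL = "other"


@dataclass(frozen=True)
class PhenotypeRule:
    """A marker gate: positive requirements, negative requirements, priority.

    Higher ``priority`` wins when a cell satisfies several rules; two
    satisfied rules of equal priority are an ambiguous gate and raise.
    """

    name: str
    required_positive: frozenset = field(default_factory=frozenset)
    required_negative: frozenset = field(default_factory=frozenset)
    priority: int = 0

    def __post_init__(self):
        pos = frozenset(self.required_positive)
        neg = frozenset(self.required_negative)
        object.__setattr__(self, "required_positive", pos)
        object.__setattr__(self, "required_negative", neg)
        if pos & neg:
            raise ValueError(
                f"rule {self.name!r}: markers {sorted(pos & neg)} required both "
                "positive and negative"
            )


def default_rules(exclude_ck_from_immune: bool = True) -> list[PhenotypeRule]:
    """The shipped gate set.

    With ``exclude_ck_from_immune`` (default) every immune gate additionally
    requires CK-, so a cytokeratin-positive cell can only be tumor.
    """
    base = [
        ("tumor", {"CK"}, set(), 100),
        ("Treg", {"CD3", "FoxP3"}, {"CD8"}, 90),
        ("cytotoxic T", {"CD3", "CD8"}, set(), 80),
        ("helper T", {"CD3"}, {"CD8"}, 70),
        ("FoxP3- T", {"CD3"}, {"FoxP3"}, 60),
        ("PD1+ T", {"CD3", "PD1"}, set(), 50),
        ("B", {"CD20"}, set(), 40),
        ("macrophage", {"CD68"}, set(), 30),
        ("NK", {"CD56"}, set(), 20),
    ]
    rules = []
    for name, pos, neg, prio in base:
        if exclude_ck_from_immune and "CK" not in pos:
            neg = set(neg) | {"CK"}
        rules.append(PhenotypeRule(name, frozenset(pos), frozenset(neg), prio))
    return rules


def assign_phenotypes(cells: pd.DataFrame, rules: list[PhenotypeRule] | None = None) -> pd.DataFrame:
    """Label every cell with the highest-priority rule it satisfies.

    Parameters
    ----------
    cells
        Cell table with one 0/1 column per marker referenced by the rules.
    rules
        Gate set; defaults to :func:`default_rules`.

    Returns a copy with a ``phenotype`` column; unmatched cells get
    ``"other"``.  Raises ``KeyError`` naming any missing marker column and
    ``ValueError`` when a cell satisfies two rules of equal priority.
    """
    if rules is None:
        rules = default_rules()
    needed = sorted({m for r in rules for m in r.required_positive | r.required_negative})
    missing = [m for m in needed if m not in cells.columns]
    if missing:
        raise KeyError(f"missing marker column(s): {', '.join(missing)}")

    out = cells.copy()
    n = len(out)
    best_prio = np.full(n, -np.inf)
    label = np.array([OTHER_LABEL] * n, dtype=object)
    # track a satisfied-rule priority collision -> ambiguous gate
    for rule in sorted(rules, key=lambda r: -r.priority):
        sat = np.ones(n, dtype=bool)
        for m in rule.required_positive:
            sat &= out[m].to_numpy() == 1
        for m in rule.required_negative:
            sat &= out[m].to_numpy() == 0
        clash = sat & (best_prio == rule.priority)
        if clash.any():
            i = int(np.flatnonzero(clash)[0])
            raise ValueError(
                f"ambiguous gate: cell index {i} satisfies {label[i]!r} and "
                f"{rule.name!r} at equal priority {rule.priority}"
            )
        take = sat & (best_prio < rule.priority)
        label[take] = rule.name
        best_prio[take] = np.where(sat[take], rule.priority, best_prio[take])
    out["phenotype"] = label
    return out


def summarize_abundance(
    cells: pd.DataFrame,
    window_area_mm2: float,
    phenotypes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample phenotype counts and densities (cells / mm^2).

    ``phenotypes`` fixes the reported label set (absent labels get count 0);
    by default every label present in the table is reported.
    """
    if window_area_mm2 <= 0:
        raise ValueError("window_area_mm2 must be positive")
    if "phenotype" not in cells.columns:
        raise ValueError("phenotypes not assigned; run assign_phenotypes first")
    if phenotypes is None:
        phenotypes = sorted(cells["phenotype"].unique())
    rows = []
    for sample_id, grp in cells.groupby("sample_id", sort=True):
        counts = grp["phenotype"].value_counts()
        for ph in phenotypes:
            c = int(counts.get(ph, 0))
            rows.append(
                {
                    "sample_id": sample_id,
                    "phenotype": ph,
                    "count": c,
                    "density_per_mm2": c / window_area_mm2,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "phenotype", "count", "density_per_mm2"])
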
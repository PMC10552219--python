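# immunospat

Spatial immune-microenvironment scoring and outcome association for
multiplex-immunofluorescence (mIF) cell tables, aimed at translational
breast-cancer studies that relate the arrangement of immune and tumor cells
in tissue to survival and treatment response.

Starting from per-cell segmentation tables (coordinates in µm plus binary
marker calls for CD3, CD8, CD20, CD56, CD68, FoxP3, PD1, PDL1, CK, Ki-67),
the package:

1. **Gates phenotypes** — prioritized marker rules assign each cell one
   label (tumor = CK+, cytotoxic T = CD3+CD8+, helper T = CD3+CD8−,
   Treg = CD3+FoxP3+CD8−, B = CD20+, macrophage = CD68+, NK = CD56+, …) and
   summarizes per-sample densities (cells/mm²).
2. **Scores spatial co-occurrence** — the core is tiled with 100 µm × 100 µm
   quadrats; for two phenotypes with per-square counts *xᵢ*, *yᵢ* and totals
   *X*, *Y* the **Morisita–Horn index** is

   MH = 2 Σᵢ xᵢyᵢ / ((Σᵢ xᵢ²/X² + Σᵢ yᵢ²/Y²) · X·Y) ∈ [0, 1],

   0 = the types never share a square, 1 = identical spatial distribution.
   The nearest-neighbor distance distribution **G(r)** (fraction of
   reference cells with a target cell within r) is summarized as the
   **Spatial Proximity Score** SPS = (1/r_max)∫₀^{r_max} G(r) dr, and the
   **Ecoscore** labels a sample anti- or pro-tumor by comparing mean SPS of
   cytotoxic T cells vs Tregs + macrophages to the tumor compartment.
3. **Scores gene signatures** — genes × samples expression is per-gene
   mean-centered and each GMT signature scored as the (direction-weighted)
   mean of its centered genes.
4. **Associates features with outcome** — per-unit Cox hazard ratios for
   overall survival and logistic odds ratios for radiological complete
   response, each with a likelihood-ratio p-value (1 df), subgroup and
   adjustment sweeps, Benjamini–Hochberg correction over the whole screen,
   tertile Kaplan–Meier curves with log-rank tests, reverse-KM median
   follow-up, paired primary-vs-metastasis contrasts, and Spearman
   correlation/cluster maps.
5. **Simulates everything** — a Thomas-style two-type cluster process with a
   tunable shared-parent fraction (0 = segregated, 1 = colocalized),
   proportional-hazards survival tied to scores, and expression matrices
   with planted signature factors, so the full pipeline is testable with no
   external data.

## Worked example

```python
import numpy as np
from immunospat import (SimulationConfig, simulate_cell_pattern,
                        quadrat_counts, morisita_horn,
                        g_function, spatial_proximity_score)

cfg = SimulationConfig(shared_parent_fraction=1.0, offspring_sd_um=10,
                       background_intensity_per_type=0.5, seed=3)
cells = simulate_cell_pattern(cfg)          # tumor + cytotoxic T pattern
q = quadrat_counts(cells, "tumor", "cytotoxic T", square_size_um=100)
print(round(morisita_horn(q), 3))           # 1.0  (fully shared parents)

curve = g_function(cells, "cytotoxic T", "tumor")
print(round(spatial_proximity_score(curve, r_max_um=50), 3))  # 0.915
```

With fully shared cluster parents every T cell sits inside a tumor cluster:
the quadrat distributions coincide (MH = 1.0) and nearly the whole area
under G(r) up to 50 µm is filled (SPS ≈ 0.92). Re-running with
`shared_parent_fraction=0` drives both toward 0 (e.g. MH ≈ 0.1 on average).

The same stages run from the shell:

```bash
immunospat simulate --seed 1 --n-samples 40 --out-dir sim/
immunospat run --cells sim/cells.csv --expression sim/expression.tsv \
    --gmt sim/signatures.gmt --clinical sim/clinical.csv \
    --seed 1 --out-dir out/
```

which writes `score_table.csv` (one row per sample: densities, MH/SPS per
phenotype pair, Ecoscore, signature scores), `association_results.csv`
(estimate, LR p, BH-adjusted p, significance tier per screen cell),
a dot-plot table, tertile KM tables, and a `manifest.json` with content
hashes — rerunning with the same seed is byte-identical.

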
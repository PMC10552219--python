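"""Readers and writers for the tabular formats the pipeline consumes.

All coordinates are micrometres stored as floats; missing values are empty
CSV fields, never sentinel numbers.  Cell tables and clinical tables are
CSV, expression matrices are genes x samples TSV with a header row of
sample ids, signatures are GMT (name <tab> description <tab> genes...),
and phenotype rules / screen plans are YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .association import ScreenPlan
from .phenotyping import MARKERS, PhenotypeRule
from .signatures import SignatureDef

CELL_REQUIRED = ("sample_id", "cell_id", "x_um", "y_um")


def read_cell_table(path, markers=MARKERS) -> pd.DataFrame:
    """Read and validate a per-cell segmentation table.

    Requires sample_id, cell_id, x_um, y_um and one strictly-binary column
    per marker present in the file; raises naming the first offending
    column or row.
    """
    df = pd.read_csv(path)
    for col in CELL_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    present_markers = [m for m in markers if m in df.columns]
    for m in present_markers:
        vals = df[m]
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-binary marker value {vals[row]!r} in column {m} at row {row}")
        df[m] = vals.astype(int)
    if not pd.api.types.is_numeric_dtype(df["x_um"]) or not pd.api.types.is_numeric_dtype(df["y_um"]):
        raise ValueError("coordinates must be numeric (µm)")
    dup = df.duplicated(subset=["sample_id", "cell_id"])
    if dup.any():
        raise ValueError(f"duplicate cell_id within sample at row {int(dup.idxmax())}")
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("missing column patient_id")
    if "os_months" in df.columns and (df["os_months"].dropna() < 0).any():
        raise ValueError("negative os_months")
    for col in ("death_event", "rcr", "er_positive"):
        if col in df.columns:
            bad = ~df[col].dropna().isin([0, 1])
            if bad.any():
                raise ValueError(f"non-binary value in column {col}")
    return df


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV; first column holds gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    df.columns.name = "sample_id"
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")


def read_gmt(path, weights_path=None) -> list[SignatureDef]:
    """GMT gene sets, optionally with a sidecar TSV of per-gene weights
    (columns: signature, gene, weight)."""
    wmap: dict = {}
    if weights_path is not None:
        wdf = pd.read_csv(weights_path, sep="\t")
        for _, r in wdf.iterrows():
            wmap.setdefault(str(r["signature"]), {})[str(r["gene"])] = float(r["weight"])
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, desc, genes = parts[0], parts[1], tuple(parts[2:])
        weights = None
        if name in wmap:
            weights = tuple(wmap[name].get(g, 1.0) for g in genes)
        sigs.append(SignatureDef(name, genes, weights, desc))
    return sigs


def write_gmt(sigs: list[SignatureDef], path) -> None:
    with open(path, "w") as fh:
        for s in sigs:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_rules(path) -> list[PhenotypeRule]:
    """Phenotype rules from YAML: a list of {name, positive, negative, priority}."""
    raw = yaml.safe_load(Path(path).read_text())
    rules = []
    for item in raw:
        rules.append(PhenotypeRule(
            name=item["name"],
            required_positive=frozenset(item.get("positive", [])),
            required_negative=frozenset(item.get("negative", [])),
            priority=int(item.get("priority", 0)),
        ))
    return rules


def write_rules(rules: list[PhenotypeRule], path) -> None:
    data = [{"name": r.name,
             "positive": sorted(r.required_positive),
             "negative": sorted(r.required_negative),
             "priority": r.priority} for r in rules]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_screen_plan(path) -> ScreenPlan:
    raw = yaml.safe_load(Path(path).read_text())
    return ScreenPlan(
        variables=list(raw["variables"]),
        endpoints=list(raw.get("endpoints", ["OS", "rCR"])),
        subgroups=list(raw.get("subgroups", ["all"])),
        covariate_sets={k: tuple(v) for k, v in
                        raw.get("covariate_sets", {"unadjusted": []}).items()},
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, seed, params: dict, files: list) -> Path:
    """JSON run manifest: seed, parameter hash, and a content hash per output."""
    out_dir = Path(out_dir)
    param_blob = json.dumps(params, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "parameters": params,
        "parameter_hash": hashlib.sha256(param_blob.encode()).hexdigest(),
        "outputs": {str(Path(f).name): file_sha256(f) for f in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
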
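"""Plain TSV/JSON formats for every pipeline artifact.

All tables are tab-delimited with fixed headers; reals are written with 12
significant digits so files round-trip bit-stably across platforms. Readers
validate headers and report malformed rows with 1-based line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FormatError", "SCHEMAS", "write_table", "read_table",
           "write_truth", "read_truth", "FLOAT_FMT"]

FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """Raised for header mismatches or malformed rows (with line numbers)."""


# kind -> (columns, dtypes); dtype "f" float, "i" int, "s" string, "j" JSON list
SCHEMAS: dict[str, dict[str, str]] = {
    "panel": {},  # wide dosage table: sample_id + one float column per SNP
    "snp_meta": {"snp_id": "s", "chrom": "s", "pos": "i", "effect_allele": "s",
                 "other_allele": "s", "freq": "f"},
    "gene_meta": {"gene": "s", "chrom": "s", "tss": "i", "tes": "i",
                  "snp_start": "i", "snp_stop": "i"},
    "expression": {},  # wide: sample_id + one float column per gene
    "sumstats": {"SNP": "s", "A1": "s", "A2": "s", "Z": "f", "N": "f"},
    "weights": {"gene": "s", "tissue": "s", "snp_id": "s", "chrom": "s",
                "pos": "i", "effect_allele": "s", "other_allele": "s",
                "weight": "f"},
    "weights_extra": {"gene": "s", "tissue": "s", "n_snps": "i", "r": "f",
                      "p": "f", "n_eval": "i"},
    "covariance": {"gene": "s", "snp_i": "s", "snp_j": "s", "value": "f"},
    "associations": {"gene": "s", "tissue": "s", "z_gene": "f", "p": "f",
                     "effect": "f", "ci_low": "f", "ci_high": "f",
                     "sigma_g": "f", "n_snps_used": "i"},
    "combined": {"gene": "s", "n_tissues": "i", "tissue_ps": "j", "t_stat": "f",
                 "p_combined": "f", "significant": "i", "excluded_region": "i"},
    "finemap": {"region": "s", "gene": "s", "tissue": "s", "twas_z": "f",
                "pip": "f", "in_credible_set": "i"},
}


def _format_value(v, dtype: str) -> str:
    if dtype == "f":
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            return "NA"
        return FLOAT_FMT % float(v)
    if dtype == "i":
        return str(int(v))
    if dtype == "j":
        return json.dumps([float(FLOAT_FMT % x) for x in v])
    return str(v)


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a schema'd table (or a wide panel/expression matrix) as TSV."""
    path = Path(path)
    schema = SCHEMAS[kind]
    with open(path, "w") as fh:
        if not schema:  # wide numeric matrix with a leading id column
            cols = list(df.columns)
            fh.write("\t".join(cols) + "\n")
            id_col = cols[0]
            for _, row in df.iterrows():
                vals = [str(row[id_col])] + [FLOAT_FMT % float(row[c]) for c in cols[1:]]
                fh.write("\t".join(vals) + "\n")
            return
        cols = list(schema)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"cannot write {kind}: missing columns {missing}")
        fh.write("\t".join(cols) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_format_value(row[c], schema[c]) for c in cols) + "\n")


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a pipeline TSV; raises FormatError with 1-based line
    numbers for malformed rows and lists missing header columns."""
    path = Path(path)
    schema = SCHEMAS[kind]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if schema:
            missing = [c for c in schema if c not in header]
            if missing:
                raise FormatError(f"{path.name}: header missing columns {missing}")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]

    if not schema:
        data = {header[0]: [r[0] for r in rows]}
        for j, col in enumerate(header[1:], start=1):
            vals = []
            for i, r in enumerate(rows):
                try:
                    vals.append(float(r[j]))
                except (ValueError, IndexError):
                    raise FormatError(
                        f"{path.name}: malformed value in column {col!r} at line {i + 2}"
                    )
            data[col] = vals
        return pd.DataFrame(data)

    col_pos = {c: header.index(c) for c in schema}
    out: dict[str, list] = {c: [] for c in schema}
    for i, r in enumerate(rows):
        for c, dtype in schema.items():
            j = col_pos[c]
            try:
                raw = r[j]
            except IndexError:
                raise FormatError(f"{path.name}: truncated row at line {i + 2}")
            try:
                if dtype == "f":
                    out[c].append(float("nan") if raw == "NA" else float(raw))
                elif dtype == "i":
                    out[c].append(int(raw))
                elif dtype == "j":
                    out[c].append(json.loads(raw))
                else:
                    out[c].append(raw)
            except (ValueError, json.JSONDecodeError):
                raise FormatError(
                    f"{path.name}: malformed value {raw!r} in column {c!r} at line {i + 2}"
                )
    return pd.DataFrame(out) if rows else pd.DataFrame({c: [] for c in schema})


def write_truth(truth, path: str | Path) -> None:
    """Serialize a TruthBundle to JSON (weights keyed 'gene|tissue')."""
    payload = {
        "true_weights": {f"{g}|{t}": [float(FLOAT_FMT % x) for x in w]
                         for (g, t), w in truth.true_weights.items()},
        "causal_eqtl_idx": {g: [int(i) for i in v]
                            for g, v in truth.causal_eqtl_idx.items()},
        "causal_genes": sorted(truth.causal_genes),
        "gene_trait_effects": {g: float(FLOAT_FMT % v)
                               for g, v in truth.gene_trait_effects.items()},
        "marginal_snp_effects": (
            None if truth.marginal_snp_effects is None
            else [float(FLOAT_FMT % x) for x in truth.marginal_snp_effects]
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path):
    from .simulate import TruthBundle

    payload = json.loads(Path(path).read_text())
    tw = {}
    for key, w in payload["true_weights"].items():
        g, t = key.split("|")
        tw[(g, t)] = np.array(w)
    gamma = payload["marginal_snp_effects"]
    return TruthBundle(
        true_weights=tw,
        causal_eqtl_idx={g: np.array(v, dtype=int)
                         for g, v in payload["causal_eqtl_idx"].items()},
        causal_genes=set(payload["causal_genes"]),
        gene_trait_effects=payload["gene_trait_effects"],
        marginal_snp_effects=None if gamma is None else np.array(gamma),
    )
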
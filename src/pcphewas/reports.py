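"""Serialized result records and run manifests.

Result tables mirror the two browsing axes of a PheWAS results browser: a
gene report carries that gene's associations across all phenotypes
(q-values on the per-gene axis) together with its inflation factor lambda
and QQ coordinates; a phenotype report carries all genes for one phenotype
(q-values on the per-phenotype axis).  Output files are a deterministic
function of (inputs, config, seed): the run manifest records the config
hash, package version and seed — and nothing time-dependent — so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import multiplicity

SCHEMA_VERSION = "1.0"

#: JSON schema (draft-07 subset) for the gene report, used for validation.
GENE_REPORT_SCHEMA = {
    "type": "object",
    "required": ["schema_version", "gene", "lambda", "n_tests",
                 "associations", "qq"],
    "properties": {
        "schema_version": {"type": "string"},
        "gene": {"type": "string"},
        "lambda": {"type": "number"},
        "n_tests": {"type": "integer"},
        "associations": {"type": "array"},
        "qq": {"type": "array"},
    },
}


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: dict, seed: int) -> Path:
    from . import __version__

    path = Path(out_dir) / "manifest.json"
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return path


def augment_results(df: pd.DataFrame, axis: str = "per_gene") -> pd.DataFrame:
    """Append q and bonferroni columns to an association table.

    ``axis`` controls the grouping for multiplicity correction: "per_gene"
    corrects each gene's p-values across phenotypes; "per_phenotype"
    corrects each phenotype's p-values across genes.
    """
    group_col = "gene" if axis == "per_gene" else "phenotype"
    df = df.copy()
    df["q"] = float("nan")
    df["bonferroni"] = float("nan")
    for _, idx in df.groupby(group_col).groups.items():
        p = df.loc[idx, "p"]
        ok = p.notna()
        if not ok.any():
            continue
        mres = multiplicity.qvalues(p[ok].to_numpy(), axis=axis)
        df.loc[idx[ok], "q"] = mres.q
        df.loc[idx[ok], "bonferroni"] = mres.bonferroni
    return df


def export_gene_report(results: pd.DataFrame, gene_id: str) -> dict:
    """Per-gene JSON record: associations (p, per-gene q, Bonferroni),
    lambda and QQ coordinates across the gene's phenotypes."""
    rows = results[results["gene"] == gene_id]
    if rows.empty:
        raise ValueError(f"no results for gene {gene_id!r}")
    p = rows["p"].dropna().to_numpy()
    mres = multiplicity.qvalues(p, axis="per_gene")
    qq = multiplicity.qq_points(p)
    ok_rows = rows[rows["p"].notna()]
    associations = []
    for (_, row), q, b in zip(ok_rows.iterrows(), mres.q, mres.bonferroni):
        associations.append({
            "phenotype": row["phenotype"],
            "test": row["test"],
            "statistic": float(row["statistic"]),
            "n": int(row["n"]),
            "n_pcs": int(row["n_pcs"]),
            "p": float(row["p"]),
            "q": float(q),
            "bonferroni": float(b),
        })
    return {
        "schema_version": SCHEMA_VERSION,
        "gene": gene_id,
        "lambda": mres.lambda_gc,
        "n_tests": int(len(associations)),
        "associations": associations,
        "qq": [[float(e), float(o)] for e, o in qq],
    }


def validate_gene_report(report: dict) -> None:
    """Check a gene report against :data:`GENE_REPORT_SCHEMA`."""
    for key in GENE_REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"gene report missing required field {key!r}")
    types = {"string": str, "number": (int, float), "integer": int,
             "array": list}
    for key, spec in GENE_REPORT_SCHEMA["properties"].items():
        if key in report and not isinstance(report[key], types[spec["type"]]):
            raise ValueError(f"gene report field {key!r} has wrong type")


def write_results_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def write_results_jsonl(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write(json.dumps(row.to_dict(), sort_keys=True, default=str))
            fh.write("\n")
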
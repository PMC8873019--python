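"""Readers/writers for the pipeline's plain-text interchange formats.

Matrices travel as TSV with a gene/protein id index and a sample-id
header row; sample sheets and long tables as CSV; configuration as YAML.
Floats are written at six significant digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

FLOAT_FMT = "%.6g"


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def write_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(rundir: str | Path, manifest: dict) -> Path:
    path = Path(rundir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
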
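"""CSV readers/writers and input validation for the pipeline tables.

Interchange format is plain CSV with documented headers:

* morph-count series — ``locality,year,host,n_striped,n_green,n_melanic``
* experiment tables — ``bush,block,release_freq,released_striped,
  released_green_or_melanic,recaptured_striped,recaptured_other``
* genotype matrices — a plain individuals x SNPs matrix of 0/1/2 calls,
  first column ``individual``; a converter from VCF GT fields is included.

Output files written by :mod:`nfdstools.pipeline` embed the seed and a
hash of the configuration as ``# key: value`` comment lines, so every
result is auditable back to its exact inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SERIES_COLUMNS

__all__ = [
    "read_series",
    "write_series",
    "read_experiment",
    "read_genotype_matrix",
    "vcf_to_genotype_matrix",
    "write_with_provenance",
    "config_hash",
]

_HOSTS = {"Adenostoma", "Ceanothus", "pooled"}


def read_series(path) -> pd.DataFrame:
    """Read and validate a long-format morph-count table.

    Raises ``ValueError`` naming the offending rows for negative counts,
    unknown hosts, zero-total records, or duplicated
    (locality, year, host) keys.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    counts = df[["n_striped", "n_green", "n_melanic"]]
    bad = df.index[(counts < 0).any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: negative counts in rows {list(bad + 2)}")
    bad = df.index[~df["host"].isin(_HOSTS)]
    if len(bad):
        raise ValueError(f"{path}: unknown host in rows {list(bad + 2)}")
    bad = df.index[counts.sum(axis=1) < 1]
    if len(bad):
        raise ValueError(f"{path}: zero-total records in rows {list(bad + 2)}")
    dup = df.duplicated(subset=["locality", "year", "host"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicated (locality, year, host) keys in rows "
            f"{list(df.index[dup] + 2)}"
        )
    return df[SERIES_COLUMNS]


def write_series(df: pd.DataFrame, path) -> None:
    df[SERIES_COLUMNS].to_csv(path, index=False)


def read_experiment(path) -> pd.DataFrame:
    """Read and validate a release/recapture table."""
    df = pd.read_csv(path, comment="#")
    need = {
        "bush",
        "released_striped",
        "released_green_or_melanic",
        "recaptured_striped",
        "recaptured_other",
    }
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["recaptured_striped"] > df["released_striped"]).any() or (
        df["recaptured_other"] > df["released_green_or_melanic"]
    ).any():
        raise ValueError(f"{path}: recaptured exceeds released")
    return df


def read_genotype_matrix(path):
    """Read an individuals x SNPs 0/1/2 matrix CSV (first column: individual)."""
    df = pd.read_csv(path, comment="#")
    individuals = df.iloc[:, 0].astype(str).tolist()
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.isin(X[~np.isnan(X)], [0, 1, 2]).all():
        raise ValueError(f"{path}: genotype calls must be 0/1/2")
    return individuals, X


def vcf_to_genotype_matrix(path):
    """Convert a (plain-text) VCF's GT fields to a 0/1/2 matrix.

    Diploid biallelic records only; missing calls become NaN.  Returns
    ``(sample_names, matrix)`` with shape (n_samples, n_sites).
    """
    samples, rows = None, []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if samples is None:
                raise ValueError(f"{path}: missing #CHROM header")
            gts = []
            for cell in fields[9:]:
                gt = cell.split(":", 1)[0].replace("|", "/")
                if "." in gt:
                    gts.append(np.nan)
                else:
                    gts.append(sum(int(a) for a in gt.split("/")))
            rows.append(gts)
    return samples, np.asarray(rows, dtype=float).T


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_with_provenance(df: pd.DataFrame, path, config: dict, seed: int) -> None:
    """Write a CSV with the config hash and seed embedded as comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash(config)}\n")
        fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, index=False)
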
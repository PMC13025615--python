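"""Delimited-text I/O for genotypes, phenotypes and run configuration.

Canonical interchange formats are plain tab-delimited text: the data
scale of pedigree cohorts is small enough that binary containers buy
nothing.  Individual IDs (family:individual) are the only join keys;
internally everything is 0-based positional in pedigree order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pedigree import Pedigree

__all__ = [
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "RunConfig",
]

MISSING_CODE = "NA"


class GenotypeParseError(ValueError):
    pass


def write_genotypes(
    geno: np.ndarray, snp_ids: list[str], path: str | Path
) -> None:
    """Write an (n_snps, n) genotype matrix as text: SNP-id header row,
    one row per individual."""
    n_snps, n = geno.shape
    with open(path, "w") as fh:
        fh.write("\t".join(snp_ids) + "\n")
        for i in range(n):
            fh.write("\t".join(str(int(v)) for v in geno[:, i]) + "\n")


def read_genotypes(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a genotype file; returns ((n_snps, n) int8 matrix, SNP ids).

    Entries must be 0/1/2 or the missing code; missing entries are
    stored as -1 so callers can flag and skip affected SNPs.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError("empty genotype file")
    snp_ids = lines[0].split("\t")
    rows = []
    for r, line in enumerate(lines[1:], start=2):
        vals = line.split("\t")
        if len(vals) != len(snp_ids):
            raise GenotypeParseError(f"row {r}: expected {len(snp_ids)} entries")
        row = np.empty(len(vals), dtype=np.int8)
        for cidx, v in enumerate(vals):
            if v == MISSING_CODE:
                row[cidx] = -1
            elif v in ("0", "1", "2"):
                row[cidx] = int(v)
            else:
                raise GenotypeParseError(
                    f"row {r}, column {cidx + 1}: invalid genotype {v!r}"
                )
        rows.append(row)
    return np.array(rows).T.copy(), snp_ids


def missing_snp_mask(geno: np.ndarray) -> np.ndarray:
    """Boolean mask of SNPs (rows) containing any missing entry."""
    return (geno < 0).any(axis=1)


def write_phenotypes(
    ped: Pedigree, Y: np.ndarray, W: np.ndarray, path: str | Path
) -> None:
    """Write trait + non-intercept covariates keyed by family/individual ID."""
    df = pd.DataFrame(
        {
            "fid": [p.family_id for p in ped.individuals],
            "iid": [p.indiv_id for p in ped.individuals],
            "trait": Y,
        }
    )
    for j in range(1, W.shape[1]):
        df[f"cov{j}"] = W[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(
    path: str | Path, ped: Pedigree
) -> tuple[np.ndarray, np.ndarray]:
    """Read a phenotype table and align rows to pedigree order.

    Returns (trait vector, covariate matrix with intercept prepended).
    """
    df = pd.read_csv(path, sep="\t", dtype={"fid": str, "iid": str})
    keys = list(zip(df["fid"], df["iid"]))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate individual IDs in phenotype file: {dupes}")
    lookup = {k: i for i, k in enumerate(keys)}
    order = []
    missing = []
    for p in ped.individuals:
        k = (p.family_id, p.indiv_id)
        if k not in lookup:
            missing.append(k)
        else:
            order.append(lookup[k])
    if missing:
        raise ValueError(f"phenotype file lacks pedigree individuals: {missing}")
    df = df.iloc[order]
    Y = df["trait"].to_numpy(float)
    cov_cols = [c for c in df.columns if c.startswith("cov")]
    W = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in cov_cols])
    return Y, W


@dataclass
class RunConfig:
    """Serializable configuration for end-to-end runs.

    Defaults reproduce the package's reference simulation settings;
    unknown keys in a loaded file are rejected.
    """

    pedigree: str | None = None
    genotype: str | None = None
    phenotype: str | None = None
    output: str | None = None
    sim: dict = field(default_factory=dict)
    emulator: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    _KNOWN = {"pedigree", "genotype", "phenotype", "output", "sim", "emulator", "evaluation"}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "pedigree": self.pedigree,
            "genotype": self.genotype,
            "phenotype": self.phenotype,
            "output": self.output,
            "sim": self.sim,
            "emulator": self.emulator,
            "evaluation": self.evaluation,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
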
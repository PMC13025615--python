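"""Pedigree representation and kinship computation.

A pedigree is an ordered collection of individuals with optional parent
links.  Individuals whose parents are not recorded are *founders*; the
rest are *descendants*.  The central quantity derived from a pedigree is
the kinship matrix Phi, whose off-diagonal entries are twice the kinship
coefficient (the genotype correlation for outbred pairs) and whose
diagonal entries are 1 + h_i, with h_i the inbreeding coefficient of
individual i (the kinship of their parents).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "kinship_matrix",
    "canonical_family",
    "canonical_cohort",
    "partition",
    "read_fam",
    "write_fam",
    "write_kinship",
    "read_kinship",
]

MISSING = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (unresolved parent, bad order, cycle)."""


@dataclass(frozen=True)
class Individual:
    family_id: str
    indiv_id: str
    father_id: str | None  # None encodes a missing parent
    mother_id: str | None
    sex: int = 0  # 1 male, 2 female, 0 unknown
    generation: int = 0


@dataclass
class Pedigree:
    """Ordered pedigree; parents must precede their children.

    The ordering is part of the contract: genotype vectors, trait vectors
    and kinship matrices produced by this package are all indexed by this
    order, so downstream feature positions are reproducible.
    """

    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def n(self) -> int:
        return len(self.individuals)

    def index(self) -> dict[tuple[str, str], int]:
        return {(p.family_id, p.indiv_id): i for i, p in enumerate(self.individuals)}

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of father/mother positional indices, -1 for founders."""
        idx = self.index()
        out = np.full((self.n, 2), -1, dtype=np.int64)
        for i, p in enumerate(self.individuals):
            if p.father_id is not None:
                out[i, 0] = idx[(p.family_id, p.father_id)]
                out[i, 1] = idx[(p.family_id, p.mother_id)]
        return out

    def validate(self) -> None:
        idx: dict[tuple[str, str], int] = {}
        for i, p in enumerate(self.individuals):
            key = (p.family_id, p.indiv_id)
            if key in idx:
                raise PedigreeError(f"duplicate individual {key}")
            if (p.father_id is None) != (p.mother_id is None):
                raise PedigreeError(
                    f"individual {key}: parents must be both missing or both present"
                )
            if p.father_id is not None:
                for par in (p.father_id, p.mother_id):
                    pkey = (p.family_id, par)
                    if pkey not in idx:
                        raise PedigreeError(
                            f"individual {key}: parent {par!r} not defined earlier "
                            "in the same family (unresolved or non-topological order)"
                        )
            idx[key] = i

    def founder_mask(self) -> np.ndarray:
        return np.array([p.father_id is None for p in self.individuals], dtype=bool)

    def family_ids(self) -> list[str]:
        seen: list[str] = []
        for p in self.individuals:
            if p.family_id not in seen:
                seen.append(p.family_id)
        return seen


def partition(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Founder and descendant positional index sets, in pedigree order."""
    mask = ped.founder_mask()
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Kinship matrix Phi of a pedigree via the standard recursion.

    phi(i, i) = (1 + phi(father(i), mother(i))) / 2 and, for i after j in
    the ordering, phi(i, j) = (phi(father(i), j) + phi(mother(i), j)) / 2;
    founders are mutually unrelated and non-inbred.  The returned matrix
    stores 2*phi(i, j) off-diagonal and 1 + h_i on the diagonal, h_i being
    the parental kinship, so it is exactly the genotype covariance scale
    matrix for the pedigree.
    """
    n = ped.n
    par = ped.parent_indices()
    phi = np.zeros((n, n))
    for i in range(n):
        fa, mo = par[i]
        if fa < 0:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + phi[fa, mo])
            phi[i, :i] = 0.5 * (phi[fa, :i] + phi[mo, :i])
            phi[:i, i] = phi[i, :i]
    out = 2.0 * phi
    # diagonal of 2*phi(i,i) = 1 + h_i already
    return out


def canonical_family(family_id: str = "fam1") -> Pedigree:
    """The package's default three-generation, ten-member family.

    Generation 1: a founder couple.  Generation 2: two of their children,
    each married to an unrelated founder spouse.  Generation 3: two
    children per generation-2 couple.  Four founders, six descendants,
    all outbred.
    """
    f = family_id
    ind = [
        Individual(f, "g1_f", None, None, 1, 1),
        Individual(f, "g1_m", None, None, 2, 1),
        Individual(f, "g2_c1", "g1_f", "g1_m", 1, 2),
        Individual(f, "g2_c2", "g1_f", "g1_m", 2, 2),
        Individual(f, "g2_s1", None, None, 2, 2),
        Individual(f, "g2_s2", None, None, 1, 2),
        Individual(f, "g3_a", "g2_c1", "g2_s1", 1, 3),
        Individual(f, "g3_b", "g2_c1", "g2_s1", 2, 3),
        Individual(f, "g3_c", "g2_s2", "g2_c2", 1, 3),
        Individual(f, "g3_d", "g2_s2", "g2_c2", 2, 3),
    ]
    return Pedigree(ind)


def canonical_cohort(n_families: int) -> Pedigree:
    """Cohort of replicated canonical families with distinct family IDs."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    ind: list[Individual] = []
    for k in range(n_families):
        ind.extend(canonical_family(f"fam{k + 1}").individuals)
    return Pedigree(ind)


# ---------------------------------------------------------------------------
# I/O: PLINK .fam-style files and kinship matrices


def read_fam(path: str | Path) -> Pedigree:
    """Read a 6-column whitespace-delimited pedigree file.

    Columns: family ID, individual ID, father, mother, sex, phenotype.
    Missing parents are coded "0".  The phenotype column is ignored.
    Rows must already be in parent-before-child order.
    """
    ind: list[Individual] = []
    gen: dict[tuple[str, str], int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise PedigreeError(f"bad .fam line: {line!r}")
        fid, iid, fa, mo = parts[:4]
        sex = int(parts[4]) if parts[4] in {"0", "1", "2"} else 0
        father = None if fa == MISSING else fa
        mother = None if mo == MISSING else mo
        if father is None:
            g = 1
        else:
            g = 1 + max(gen.get((fid, fa), 0), gen.get((fid, mo), 0))
        gen[(fid, iid)] = g
        ind.append(Individual(fid, iid, father, mother, sex, g))
    return Pedigree(ind)


def write_fam(ped: Pedigree, path: str | Path) -> None:
    lines = []
    for p in ped.individuals:
        lines.append(
            f"{p.family_id} {p.indiv_id} {p.father_id or MISSING} "
            f"{p.mother_id or MISSING} {p.sex} -9"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_kinship(phi: np.ndarray, ids: Sequence[str], path: str | Path) -> None:
    """Write Phi as tab-delimited text with an individual-ID header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(ids) + "\n")
        for row in phi:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_kinship(path: str | Path) -> tuple[np.ndarray, list[str]]:
    lines = Path(path).read_text().splitlines()
    ids = lines[0].split("\t")
    phi = np.array([[float(v) for v in ln.split("\t")] for ln in lines[1:]])
    if phi.shape != (len(ids), len(ids)):
        raise ValueError("kinship matrix shape does not match header IDs")
    return phi, ids


def cohort_ids(ped: Pedigree) -> list[str]:
    return [f"{p.family_id}:{p.indiv_id}" for p in ped.individuals]
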
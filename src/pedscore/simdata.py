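"""Synthetic GWAS cohorts: gene-dropped genotypes and mixed-model traits.

The generator reproduces the study conditions used throughout the
package: a cohort of three-generation families, genotypes transmitted by
gene-dropping from founder allele frequencies drawn from Uniform(0.1,
0.5), and quantitative traits from the linear mixed model

    y = W beta + x alpha + eps,   eps ~ N(0, sigma_e^2 I + sigma_a^2 Phi)

with defaults beta = (1, 0.5, 0.8), sigma_e^2 = 1.5, sigma_a^2 = 2.5.
Each simulated SNP carries its own trait replicate (its own eps draw),
so per-SNP test statistics are independent draws from the sampling
distribution under the chosen effect regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .pedigree import Pedigree, kinship_matrix

__all__ = [
    "SimParams",
    "SimDataset",
    "gene_drop",
    "simulate_covariates",
    "sample_effect",
    "simulate_dataset",
]


@dataclass
class SimParams:
    """Generating parameters of a synthetic cohort."""

    beta: tuple[float, ...] = (1.0, 0.5, 0.8)
    sigma_e2: float = 1.5
    sigma_a2: float = 2.5
    maf_range: tuple[float, float] = (0.1, 0.5)
    effect_grid_k: float = 0.0  # 0 encodes the null (alpha = 0)
    effect_mode: str = "power_grid"  # or "consistency"
    n_snps: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_e2 <= 0 or self.sigma_a2 < 0:
            raise ValueError("variance components must satisfy sigma_e2>0, sigma_a2>=0")
        if self.effect_grid_k < 0:
            raise ValueError("effect_grid_k must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")


@dataclass
class SimDataset:
    """A simulated per-SNP association dataset in pedigree order."""

    genotypes: np.ndarray  # (n_snps, n) int8 in {0,1,2}
    traits: np.ndarray  # (n_snps, n) one trait replicate per SNP
    covariates: np.ndarray  # (n, q), intercept included
    true_alpha: np.ndarray  # (n_snps,)
    true_maf: np.ndarray  # (n_snps,)
    params: SimParams
    snp_ids: list[str] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        """Binary association indicator: 1 iff the SNP has a true effect."""
        return (self.true_alpha != 0).astype(np.int8)

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    def save(self, outdir: str | Path) -> None:
        from . import io as _io

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_genotypes(self.genotypes, self.snp_ids, out / "genotypes.tsv")
        np.savetxt(out / "traits.tsv", self.traits, delimiter="\t", fmt="%.10g")
        np.savetxt(out / "covariates.tsv", self.covariates, delimiter="\t", fmt="%.10g")
        meta = asdict(self.params)
        meta["true_alpha"] = self.true_alpha.tolist()
        meta["true_maf"] = self.true_maf.tolist()
        meta["snp_ids"] = self.snp_ids
        (out / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, outdir: str | Path) -> "SimDataset":
        from . import io as _io

        out = Path(outdir)
        meta = json.loads((out / "meta.json").read_text())
        alpha = np.array(meta.pop("true_alpha"))
        maf = np.array(meta.pop("true_maf"))
        snp_ids = meta.pop("snp_ids")
        params = SimParams(
            beta=tuple(meta["beta"]),
            sigma_e2=meta["sigma_e2"],
            sigma_a2=meta["sigma_a2"],
            maf_range=tuple(meta["maf_range"]),
            effect_grid_k=meta["effect_grid_k"],
            effect_mode=meta["effect_mode"],
            n_snps=meta["n_snps"],
            seed=meta["seed"],
        )
        geno, snp_ids2 = _io.read_genotypes(out / "genotypes.tsv")
        traits = np.loadtxt(out / "traits.tsv", delimiter="\t", ndmin=2)
        cov = np.loadtxt(out / "covariates.tsv", delimiter="\t", ndmin=2)
        assert snp_ids2 == snp_ids
        return cls(geno, traits, cov, alpha, maf, params, snp_ids)


def gene_drop(
    ped: Pedigree,
    maf: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Gene-drop a biallelic SNP down a pedigree.

    Founders receive two alleles i.i.d. Bernoulli(maf) for the counted
    allele; every descendant inherits one uniformly chosen allele from
    each parent.  Returns allele counts in {0,1,2}, shape (n,) or
    (size, n) when ``size`` replicate SNPs are dropped at once.
    """
    if not (0 <= maf <= 1):
        raise ValueError("maf must be in [0, 1]")
    m = 1 if size is None else size
    n = ped.n
    par = ped.parent_indices()
    a = np.empty((n, 2, m), dtype=np.int8)
    for i in range(n):
        fa, mo = par[i]
        if fa < 0:
            a[i] = rng.random((2, m)) < maf
        else:
            pick = rng.integers(0, 2, size=(2, m))
            idx = np.arange(m)
            a[i, 0] = a[fa, pick[0], idx]
            a[i, 1] = a[mo, pick[1], idx]
    g = a.sum(axis=1).T  # (m, n)
    return g[0] if size is None else g


def simulate_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    """Covariate design W: intercept, age ~ U(18, 80), sex ~ Bernoulli(0.7)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    W = np.empty((n, 3))
    W[:, 0] = 1.0
    W[:, 1] = rng.uniform(18.0, 80.0, size=n)
    W[:, 2] = rng.random(n) < 0.7
    return W


def sample_effect(
    k: float,
    rng: np.random.Generator,
    mode: str = "power_grid",
    size: int | None = None,
) -> float | np.ndarray:
    """Draw SNP effect size(s) alpha.

    power_grid: alpha = 0 when k = 0, otherwise uniform on
    [-(k+1)/2, -k/2] u [k/2, (k+1)/2] with a fair-coin sign.
    consistency: uniform on [-1.25, -0.25] u [0.25, 1.25].
    """
    m = 1 if size is None else size
    if mode == "power_grid":
        if k < 0:
            raise ValueError("k must be >= 0")
        if k == 0:
            out = np.zeros(m)
        else:
            mag = rng.uniform(0.5 * k, 0.5 * (k + 1), size=m)
            sign = np.where(rng.random(m) < 0.5, -1.0, 1.0)
            out = sign * mag
    elif mode == "consistency":
        mag = rng.uniform(0.25, 1.25, size=m)
        sign = np.where(rng.random(m) < 0.5, -1.0, 1.0)
        out = sign * mag
    else:
        raise ValueError(f"unknown effect mode {mode!r}")
    return out[0] if size is None else out


def simulate_dataset(
    ped: Pedigree,
    params: SimParams,
    phi: np.ndarray | None = None,
) -> SimDataset:
    """Simulate a per-SNP dataset under the mixed model.

    Covariates are drawn once per dataset (they are attributes of the
    individuals, not of SNPs).  Each SNP then has its own substream of
    the master seed for (maf, genotypes, alpha, trait noise), so any
    single SNP can be regenerated independently of batch size.
    """
    if phi is None:
        phi = kinship_matrix(ped)
    n = ped.n
    q = len(params.beta)
    sigma = params.sigma_e2 * np.eye(n) + params.sigma_a2 * phi
    L = np.linalg.cholesky(sigma)
    beta = np.asarray(params.beta)

    master = np.random.SeedSequence(params.seed)
    w_ss, snp_root = master.spawn(2)
    W = simulate_covariates(n, np.random.default_rng(w_ss))
    wb = W @ beta

    geno = np.empty((params.n_snps, n), dtype=np.int8)
    traits = np.empty((params.n_snps, n))
    alphas = np.empty(params.n_snps)
    mafs = np.empty(params.n_snps)
    lo, hi = params.maf_range
    for j, ss in enumerate(snp_root.spawn(params.n_snps)):
        rng = np.random.default_rng(ss)
        maf = rng.uniform(lo, hi)
        x = gene_drop(ped, maf, rng)
        alpha = sample_effect(params.effect_grid_k, rng, mode=params.effect_mode)
        eps = L @ rng.standard_normal(n)
        geno[j] = x
        traits[j] = wb + x * alpha + eps
        alphas[j] = alpha
        mafs[j] = maf
    snp_ids = [f"snp{j + 1}" for j in range(params.n_snps)]
    return SimDataset(geno, traits, W, alphas, mafs, params, snp_ids)
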
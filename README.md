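# pedscore

Association testing for quantitative traits in samples of **related
individuals**, together with deep-neural-network emulators of the
tests.  The package is aimed at statistical geneticists who work with
family-based cohorts: it provides the classical mixed-model score
tests, pedigree-aware allele-frequency estimation, a gene-dropping
simulator for method evaluation, and trainable emulators that learn
the mapping from per-SNP data to test statistics.

## The statistics

Relatedness is encoded by the kinship matrix Φ (entries 2φᵢⱼ off the
diagonal, 1 + hᵢ on it).  For a trait vector Y, covariates W and SNP
genotypes X ∈ {0,1,2}ⁿ, the null mixed model is

    Y = Wβ₀ + ε,   ε ~ N(0, Σ₀),   Σ₀ = σe²I + σa²Φ,

and both tests are built on the transformed residual
R = Σ̂₀⁻¹(Y − Wβ̂₀):

* prospective likelihood score test
  **S_LS** = (XᵀR)² / Xᵀ[Σ̂₀⁻¹ − Σ̂₀⁻¹W(WᵀΣ̂₀⁻¹W)⁻¹WᵀΣ̂₀⁻¹]X,
* retrospective quasi-likelihood score test (MASTOR)
  **S_QLS** = (RᵀX)² / (RᵀΦR · σ̂X²), σ̂X² = 2p̂(1 − p̂),
  with p̂ the best linear unbiased allele-frequency estimator
  ½(1ᵀΦ⁻¹1)⁻¹1ᵀΦ⁻¹X.

Both are χ²₁ under the null.  The emulators are regression networks
trained to predict the signed Z = sign(XᵀR)·√S from per-SNP inputs:
genotypes+residuals (DNN-LS, DNN-QLS), raw data ignoring relatedness
(the RAW negative controls), or three summary features XᵀR, p̂f, p̂d
(the AF variants).  An ensemble emulator targets max(S_LS, S_QLS).

## Worked example

```python
import numpy as np
import pedscore as ps

ped = ps.canonical_cohort(10)          # 10 families x 10 members, n=100
phi = ps.kinship_matrix(ped)
params = ps.SimParams(n_snps=200, effect_grid_k=2.0, seed=1)
ds = ps.simulate_dataset(ped, params, phi=phi)
scan = ps.genome_scan(ds, phi=phi, ped=ped)
t = scan.table
print(t[["snp_id", "z_ls", "p_ls", "z_qls", "p_qls"]].head(3).to_string(index=False))
print("rejections at 0.05: LS %.3f  QLS %.3f"
      % ((t.p_ls < 0.05).mean(), (t.p_qls < 0.05).mean()))
```

prints (seed 1):

```
snp_id      z_ls     p_ls     z_qls    p_qls
  snp1 -3.051141 0.002280 -2.835638 0.004573
  snp2  4.553964 0.000005  4.048772 0.000051
  snp3 -4.166390 0.000031 -4.230285 0.000023
rejections at 0.05: LS 0.895  QLS 0.895
```

Each SNP here carries a simulated effect at level k = 2 (|α| uniform on
[1, 1.5]), so the rejection rates are empirical power at that effect
size; under `effect_grid_k=0` they estimate the type-I error instead.
The Z statistics of the two tests agree closely, as expected for
strongly correlated prospective/retrospective scores.

A CLI mirrors the library (`pedscore simulate | test | af | train |
predict | evaluate | reproduce-tables`); every command logs its seed
and identical seeds reproduce outputs byte for byte.

## Layout

* `pedscore.pedigree` — pedigrees, kinship matrices, `.fam` I/O
* `pedscore.simdata` — gene-dropping and mixed-model trait simulation
* `pedscore.allelefreq` — naive/BLUE estimators and analytic covariances
* `pedscore.assoc` — null LMM fit, LS/QLS tests, genome scans
* `pedscore.nnet` / `pedscore.emulator` — network engine and emulators
* `pedscore.evalrep` — accuracy metrics, error/power, experiment driver
* `pedscore.io` / `pedscore.cli` — delimited formats, config, commands

See `docs/methods.md` for the modeling details and design choices.
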
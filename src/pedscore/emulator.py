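"""DNN emulation of the LS / QLS association tests.

An emulator is a regression network trained to map per-SNP inputs to
the signed Z statistic of a classical test.  Input variants:

* ``XR``  — the genotype vector X concatenated with the transformed
  phenotypic residual R (2n features); X and R are sufficient for both
  classical statistics.
* ``RAW`` — X, the two non-intercept covariates and the trait Y (4n
  features), deliberately ignoring relatedness; included as the
  misspecified baseline.
* ``AF``  — three summary features (X'R, founder and descendant naive
  allele-frequency estimates), collapsing the input from 2n to 3.

Targets: the signed Z of LS or QLS, or the ensemble target
sign(X'R) * sqrt(max(S_LS, S_QLS)) which aggregates the two tests.
Predicted Z values are squared to chi-square(1) statistics and turned
into p-values exactly like the classical tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .assoc import ScanResult
from .nnet import MLP, MLPConfig
from .simdata import SimDataset

__all__ = [
    "FeatureSpec",
    "Emulator",
    "build_features",
    "ensemble_target",
    "split_dataset",
    "train_emulator",
    "predict",
]

_ARCH = {
    # hidden sizes and per-layer dropout rates per input variant; the
    # inserted 128-unit RAW layer carries the heavier 0.4 rate
    "XR": ((64, 64, 32, 16), (0.1, 0.1, 0.1, 0.1)),
    "RAW": ((64, 128, 64, 32, 16), (0.1, 0.4, 0.1, 0.1, 0.1)),
    "AF": ((8,), (0.1,)),
}


@dataclass(frozen=True)
class FeatureSpec:
    variant_kind: str  # XR | RAW | AF

    def __post_init__(self) -> None:
        if self.variant_kind not in _ARCH:
            raise ValueError(f"unknown variant {self.variant_kind!r}")

    def feature_dim(self, n: int) -> int:
        return {"XR": 2 * n, "RAW": 4 * n, "AF": 3}[self.variant_kind]


def ensemble_target(scan_table) -> np.ndarray:
    """Signed square root of the per-SNP max of the LS and QLS statistics.

    Both statistics share the sign of X'R, so the signed form is
    sign(X'R) * sqrt(max(S_LS, S_QLS)).
    """
    s = np.maximum(scan_table["s_ls"].to_numpy(), scan_table["s_qls"].to_numpy())
    return np.sign(scan_table["xtr"].to_numpy()) * np.sqrt(s)


def build_features(
    scan: ScanResult,
    dataset: SimDataset,
    spec: FeatureSpec,
    target_kind: str = "ls",
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble per-SNP feature rows and training targets.

    Rows follow the dataset's SNP order; columns follow the pedigree
    order of individuals, so feature positions are reproducible.
    """
    t = scan.table
    v = spec.variant_kind
    if v == "XR":
        feats = np.hstack([dataset.genotypes.astype(float), scan.residuals])
    elif v == "RAW":
        n_snps = dataset.n_snps
        W12 = dataset.covariates[:, 1:3]
        feats = np.hstack(
            [
                dataset.genotypes.astype(float),
                np.broadcast_to(W12[:, 0], (n_snps, dataset.n)).copy(),
                np.broadcast_to(W12[:, 1], (n_snps, dataset.n)).copy(),
                dataset.traits,
            ]
        )
    else:  # AF
        for col in ("xtr", "p_f_hat", "p_d_hat"):
            if col not in t.columns:
                raise ValueError(f"scan table lacks required column {col!r}")
        feats = t[["xtr", "p_f_hat", "p_d_hat"]].to_numpy(float)
    if target_kind == "ls":
        targets = t["z_ls"].to_numpy(float)
    elif target_kind == "qls":
        targets = t["z_qls"].to_numpy(float)
    elif target_kind == "ens":
        targets = ensemble_target(t)
    else:
        raise ValueError(f"unknown target {target_kind!r}")
    return feats, targets


def split_dataset(
    n_snps: int, seed: int, train_fraction: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random disjoint train/test index split (default 4:1)."""
    if n_snps < 5:
        raise ValueError("need at least 5 SNPs to split")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(n_snps)
    n_train = int(round(train_fraction * n_snps))
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def _channels(variant: str) -> int:
    return {"XR": 2, "RAW": 4, "AF": 0}[variant]


def _net_layout(variant: str, feats: np.ndarray) -> np.ndarray:
    """Reorder block features [X | R | ...] into per-individual channel
    groups (X_i, R_i, ...), the layout the positional network expects."""
    ch = _channels(variant)
    if ch == 0:
        return feats
    n = feats.shape[1] // ch
    perm = np.arange(ch * n).reshape(ch, n).T.ravel()
    return feats[:, perm]


@dataclass
class Emulator:
    """Trained emulator: network, input variant and standardization."""

    model: MLP
    spec: FeatureSpec
    target_kind: str
    feat_mean: np.ndarray
    feat_sd: np.ndarray

    def predict_z(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, float)
        if features.shape[1] != self.feat_mean.size:
            raise ValueError(
                f"feature dimension {features.shape[1]} does not match "
                f"the model's {self.feat_mean.size}"
            )
        z = (features - self.feat_mean) / self.feat_sd
        return self.model.predict(_net_layout(self.spec.variant_kind, z))

    # -- persistence: one .npz archive holding weights + config ------------
    def save(self, path: str | Path) -> None:
        meta = {
            "variant_kind": self.spec.variant_kind,
            "target_kind": self.target_kind,
            "config": asdict(self.model.config),
        }
        state = self.model.state_dict()
        np.savez(
            path,
            meta=json.dumps(meta),
            theta=state["theta"],
            history=np.asarray(state["history"]),
            feat_mean=self.feat_mean,
            feat_sd=self.feat_sd,
            **{f"run_mean_{i}": m for i, m in enumerate(state["run_mean"])},
            **{f"run_var_{i}": v for i, v in enumerate(state["run_var"])},
        )

    @classmethod
    def load(cls, path: str | Path) -> "Emulator":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            cfg = meta["config"]
            cfg["hidden"] = tuple(cfg["hidden"])
            cfg["dropout"] = tuple(cfg["dropout"])
            model = MLP(MLPConfig(**cfg))
            n_bn = len(cfg["hidden"])
            model.load_state_dict(
                {
                    "theta": z["theta"],
                    "run_mean": [z[f"run_mean_{i}"] for i in range(n_bn)],
                    "run_var": [z[f"run_var_{i}"] for i in range(n_bn)],
                    "history": z["history"].tolist(),
                }
            )
            return cls(
                model,
                FeatureSpec(meta["variant_kind"]),
                meta["target_kind"],
                z["feat_mean"],
                z["feat_sd"],
            )


def train_emulator(
    features: np.ndarray,
    targets: np.ndarray,
    spec: FeatureSpec,
    target_kind: str,
    seed: int,
    epochs: int = 200,
    batch_size: int = 16,
    learning_rate: float = 0.001,
    l1: float = 0.01,
    lambda_var: float = 10.0,
    hidden: tuple[int, ...] | None = None,
    dropout: tuple[float, ...] | None = None,
) -> Emulator:
    """Train an emulator on (already split) training rows.

    Standardization statistics are computed here, on the training rows
    only, and stored with the model.
    """
    features = np.asarray(features, float)
    targets = np.asarray(targets, float).ravel()
    if features.shape[0] == 0:
        raise ValueError("empty training split")
    arch_hidden, arch_dropout = _ARCH[spec.variant_kind]
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0  # constant features carry no information
    ch = _channels(spec.variant_kind)
    cfg = MLPConfig(
        n_features=features.shape[1],
        hidden=hidden if hidden is not None else arch_hidden,
        dropout=dropout if dropout is not None else arch_dropout,
        positions=features.shape[1] // ch if ch else 0,
        l1=l1,
        lambda_var=lambda_var,
        learning_rate=learning_rate,
        epochs=epochs,
        batch_size=batch_size,
        seed=seed,
    )
    model = MLP(cfg)
    if epochs > 0:
        model.fit(_net_layout(spec.variant_kind, (features - mean) / sd), targets)
    return Emulator(model, spec, target_kind, mean, sd)


def predict(
    emulator: Emulator, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted (z, chi-square statistic, p-value) for feature rows."""
    z = emulator.predict_z(features)
    s = z**2
    p = stats.chi2.sf(s, df=1)
    return z, s, p
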
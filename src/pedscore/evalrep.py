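"""Evaluation harness: accuracy metrics, empirical error/power, QQ
calibration, and the experiment driver that ties simulation, scanning,
training and evaluation together.

All rates are computed on held-out SNPs only: each simulated dataset is
split 4:1 into training and test SNPs, emulators are trained on the
training split, and both the classical tests and the emulators are
evaluated on the same test split for comparability.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import emulator as emu
from .assoc import ScanResult, genome_scan
from .pedigree import canonical_cohort, kinship_matrix
from .simdata import SimParams, simulate_dataset

__all__ = [
    "AccuracyReport",
    "PowerReport",
    "accuracy_metrics",
    "error_power",
    "qq_slope",
    "run_experiment",
    "DEFAULT_K_GRID",
]

DEFAULT_K_GRID = (0.0, 1.0, 1.5, 2.0, 2.5)
DNN_METHODS = (
    "DNN-LS",
    "DNN-QLS",
    "DNN-LS-AF",
    "DNN-QLS-AF",
    "DNN-ENS",
    "DNN-ENS-AF",
)
_METHOD_SPEC = {
    # method -> (input variant, training target)
    "DNN-LS": ("XR", "ls"),
    "DNN-QLS": ("XR", "qls"),
    "DNN-LS-RAW": ("RAW", "ls"),
    "DNN-QLS-RAW": ("RAW", "qls"),
    "DNN-LS-AF": ("AF", "ls"),
    "DNN-QLS-AF": ("AF", "qls"),
    "DNN-ENS": ("XR", "ens"),
    "DNN-ENS-AF": ("AF", "ens"),
}


@dataclass(frozen=True)
class AccuracyReport:
    mae: float
    rmse: float
    r_squared: float
    correlation: float
    condition: str  # H0 | Ha
    emulator_kind: str = ""


@dataclass
class PowerReport:
    method: str
    level: float
    type1: float | None
    power_by_k: dict[float, float] = field(default_factory=dict)
    n_test_snps: int = 0


def accuracy_metrics(
    z_pred: np.ndarray,
    z_true: np.ndarray,
    condition: str = "H0",
    emulator_kind: str = "",
) -> AccuracyReport:
    """MAE, RMSE, R^2 and Pearson correlation of emulated vs true Z."""
    z_pred = np.asarray(z_pred, float).ravel()
    z_true = np.asarray(z_true, float).ravel()
    if z_pred.size != z_true.size or z_pred.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.var(z_true) == 0:
        raise ValueError("z_true has zero variance; R^2 undefined")
    diff = z_pred - z_true
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    r2 = float(1.0 - np.sum(diff**2) / np.sum((z_true - z_true.mean()) ** 2))
    corr = float(np.corrcoef(z_pred, z_true)[0, 1])
    return AccuracyReport(mae, rmse, r2, corr, condition, emulator_kind)


def error_power(
    p_values: np.ndarray,
    labels: np.ndarray,
    level: float = 0.05,
) -> dict:
    """Empirical type-I error and power at a nominal level.

    Rates for an empty class are reported as None, never as 0.  NaN
    p-values (skipped SNPs) are excluded with a count.
    """
    p = np.asarray(p_values, float)
    lab = np.asarray(labels).astype(int)
    ok = np.isfinite(p)
    p, lab = p[ok], lab[ok]
    out = {"level": level, "n_used": int(p.size), "n_skipped": int((~ok).sum())}
    null = lab == 0
    out["type1"] = float(np.mean(p[null] < level)) if null.any() else None
    out["power"] = float(np.mean(p[~null] < level)) if (~null).any() else None
    return out


def qq_slope(s_stats: np.ndarray, df: int = 1) -> float:
    """Through-origin slope of sorted statistics vs chi-square quantiles."""
    s = np.sort(np.asarray(s_stats, float))
    m = s.size
    q = stats.chi2.ppf((np.arange(1, m + 1) - 0.5) / m, df=df)
    return float((q * s).sum() / (q * q).sum())


# ---------------------------------------------------------------------------
# experiment driver


def train_and_rate(
    dataset,
    scan: ScanResult,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    method: str,
    seed: int,
    level: float = 0.05,
    epochs: int = 200,
) -> dict:
    """Train one emulator on the training split, evaluate on the test split.

    Returns the held-out rejection rate, accuracy metrics against the
    corresponding classical target, and the predicted Z vector.
    """
    variant, target_kind = _METHOD_SPEC[method]
    spec = emu.FeatureSpec(variant)
    feats, targets = emu.build_features(scan, dataset, spec, target_kind)
    ok = np.isfinite(targets)
    tr = train_idx[ok[train_idx]]
    te = test_idx[ok[test_idx]]
    model = emu.train_emulator(
        feats[tr], targets[tr], spec, target_kind, seed=seed, epochs=epochs
    )
    z, s, p = emu.predict(model, feats[te])
    rates = error_power(p, dataset.labels[te], level)
    cond = "Ha" if dataset.labels.any() else "H0"
    acc = accuracy_metrics(z, targets[te], cond, method)
    return {
        "method": method,
        "rates": rates,
        "accuracy": acc,
        "z_pred": z,
        "z_true": targets[te],
        "test_idx": te,
        "model": model,
    }


def run_experiment(config: dict, outdir: str | Path | None = None) -> dict:
    """Full study: simulate -> scan -> split -> train -> evaluate per k.

    config keys (all optional): families, n_snps, k_grid, methods,
    level, seed, epochs, train_fraction.  Returns a bundle of tidy
    DataFrames; writes TSV tables plus a YAML manifest when ``outdir``
    is given.  Identical config + seed reproduces identical files.
    """
    known = {
        "families",
        "n_snps",
        "k_grid",
        "methods",
        "level",
        "seed",
        "epochs",
        "train_fraction",
    }
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    families = int(config.get("families", 10))
    n_snps = int(config.get("n_snps", 5000))
    k_grid = tuple(config.get("k_grid", DEFAULT_K_GRID))
    methods = tuple(config.get("methods", ("LS", "QLS") + DNN_METHODS))
    level = float(config.get("level", 0.05))
    seed = int(config.get("seed", 0))
    epochs = int(config.get("epochs", 200))
    train_fraction = float(config.get("train_fraction", 0.8))

    ped = canonical_cohort(families)
    phi = kinship_matrix(ped)
    t0 = time.time()
    rate_rows, acc_rows, qq_rows, scatter_rows = [], [], [], []
    stage_times = {}
    for ki, k in enumerate(k_grid):
        tk = time.time()
        params = SimParams(n_snps=n_snps, effect_grid_k=k, seed=seed + 1000 * ki)
        ds = simulate_dataset(ped, params, phi=phi)
        scan = genome_scan(ds, phi=phi, ped=ped)
        tr, te = emu.split_dataset(n_snps, seed=seed + 77 + ki, train_fraction=train_fraction)
        tab = scan.table
        for classical, pcol, zcol in (("LS", "p_ls", "z_ls"), ("QLS", "p_qls", "z_qls")):
            if classical in methods:
                r = error_power(tab[pcol].to_numpy()[te], ds.labels[te], level)
                rate_rows.append({"method": classical, "k": k, **r})
        if k == 0:
            for zcol, name in (("s_ls", "LS"), ("s_qls", "QLS")):
                qq_rows.append(
                    {"method": name, "qq_slope": qq_slope(tab[zcol].to_numpy())}
                )
        scatter_rows.append(
            pd.DataFrame(
                {
                    "k": k,
                    "z_ls": tab["z_ls"].to_numpy()[te],
                    "z_qls": tab["z_qls"].to_numpy()[te],
                }
            )
        )
        for m in methods:
            if m in ("LS", "QLS"):
                continue
            res = train_and_rate(
                ds, scan, tr, te, m, seed=seed + 31 * ki + zlib.crc32(m.encode()) % 1000,
                level=level, epochs=epochs,
            )
            rate_rows.append({"method": m, "k": k, **res["rates"]})
            a = res["accuracy"]
            acc_rows.append(
                {
                    "method": m,
                    "k": k,
                    "condition": a.condition,
                    "mae": a.mae,
                    "rmse": a.rmse,
                    "r_squared": a.r_squared,
                    "correlation": a.correlation,
                }
            )
        stage_times[f"k={k}"] = round(time.time() - tk, 2)

    rates = pd.DataFrame(rate_rows)
    accuracy = pd.DataFrame(acc_rows)
    qq = pd.DataFrame(qq_rows)
    scatter = pd.concat(scatter_rows, ignore_index=True)
    bundle = {"rates": rates, "accuracy": accuracy, "qq": qq, "scatter": scatter}

    if outdir is not None:
        import yaml

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        cfg_hash = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        manifest = {
            "config": {kk: (list(v) if isinstance(v, tuple) else v) for kk, v in config.items()},
            "config_hash": cfg_hash,
            "seed": seed,
            "stage_seconds": stage_times,
            "total_seconds": round(time.time() - t0, 2),
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return bundle
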
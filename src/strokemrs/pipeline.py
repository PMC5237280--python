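"""End-to-end orchestration of the two MRS classifiers.

`run_classifier` executes the full workflow on a cohort (read from
delimited text or simulated): creatine referencing and UL2CA
normalization, forward CFS feature selection, the 2-20 feature sweep
with bootstrap CCC and test-set BER, the Fisher LDA fit at the selected
model size, train/test confusion matrices, one-vs-rest diagnostic
metrics with ROC AUC, and univariate follow-up statistics on the
selected datapoints.  All tables land as delimited text in the output
directory together with a JSON manifest (config, seed, version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core import Cohort, read_cohort, write_cohort
from .evaluate import (
    ConfusionMatrix3,
    ber,
    ccc,
    dichotomize,
    feature_sweep,
    ovr_scores,
    roc_auc,
)
from .lda import confusion, fit_fisher_lda, predict
from .preprocess import normalize_cohort
from .simulate import SimConfig, default_config, simulate_cohort
from .stats import summarize_feature

log = logging.getLogger("strokemrs")

__all__ = ["RunConfig", "RunReport", "run_simulation", "run_classifier"]


@dataclass
class RunConfig:
    scenario: str = "infarct_evolution"
    table_path: Optional[str] = None
    metadata_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    k_min: int = 2
    k_max: int = 20
    n_boot: int = 1000
    seed: int = 0
    out_dir: str = "results/run"
    rule: str = "first_local_min"
    make_plots: bool = False


@dataclass
class RunReport:
    sweep: "pd.DataFrame"
    selected_k: int
    features: "pd.DataFrame"
    train_confusion: ConfusionMatrix3
    test_confusion: ConfusionMatrix3
    train_ber: float
    test_ber: float
    train_ccc: float
    test_ccc: float
    ccc_boot_mean: float
    ccc_boot_sd: float
    per_class: "pd.DataFrame"
    feature_stats: list = field(default_factory=list)


def _load_or_simulate(config: RunConfig) -> Cohort:
    if config.table_path and config.metadata_path:
        log.info("reading cohort from %s", config.table_path)
        return read_cohort(config.table_path, config.metadata_path)
    sim = config.sim or default_config(config.scenario, seed=config.seed)
    log.info("simulating %s cohort (seed %d)", sim.scenario, sim.seed)
    return simulate_cohort(sim)


def run_simulation(config: RunConfig) -> dict:
    """Simulate a cohort and write it (plus the ground-truth peak table)."""
    sim = config.sim or default_config(config.scenario, seed=config.seed)
    cohort = simulate_cohort(sim)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = out / "spectra.tsv"
    meta = out / "metadata.tsv"
    write_cohort(cohort, table, meta)
    truth_rows = []
    for name, ppm, per_class in sim.diagnostic_targets:
        for cls, (med, q25, q75) in per_class.items():
            truth_rows.append(
                {"peak": name, "ppm": ppm, "class": cls, "median": med, "q25": q25, "q75": q75}
            )
    truth = out / "ground_truth_peaks.tsv"
    pd.DataFrame(truth_rows).to_csv(truth, sep="\t", index=False)
    return {"table": str(table), "metadata": str(meta), "ground_truth": str(truth)}


def run_classifier(config: RunConfig) -> RunReport:
    """Full workflow: normalize -> select -> sweep -> fit -> evaluate -> stats."""
    cohort = _load_or_simulate(config)
    if any(not r.normalized for r in cohort.records):
        normalized, _ = normalize_cohort(cohort)
    else:
        normalized = cohort
    train = normalized.subset("train")
    test = normalized.subset("test")
    log.info(
        "train %d / test %d spectra; classes %s",
        len(train),
        len(test),
        train.class_sizes(),
    )

    sweep = feature_sweep(
        train,
        test,
        k_min=config.k_min,
        k_max=config.k_max,
        n_boot=config.n_boot,
        seed=config.seed,
        rule=config.rule,
    )
    k = sweep.selected_k
    features = sweep.features.head(k)
    log.info(
        "selected k=%d features at ppm %s",
        k,
        np.round(features.ppms, 3).tolist(),
    )

    model = fit_fisher_lda(train, features)
    cm_train = confusion(model, train)
    cm_test = confusion(model, test)
    row = next(r for r in sweep.rows if r.k == k)

    Xtr, ytr = train.matrix()
    per_class_rows = []
    for cls in train.class_labels:
        d = dichotomize(cm_train, cls)
        scores = ovr_scores(model, Xtr[:, features.indices], cls)
        auc, se = roc_auc(scores, (ytr == cls).astype(int))
        per_class_rows.append(
            {
                "class": cls,
                "tp": d.tp,
                "fn": d.fn,
                "fp": d.fp,
                "tn": d.tn,
                "sensitivity": d.sensitivity,
                "specificity": d.specificity,
                "ppv": d.ppv,
                "npv": d.npv,
                "auc": auc,
                "auc_se": se,
            }
        )

    feature_stats = [summarize_feature(train, int(i)) for i in features.indices]

    report = RunReport(
        sweep=sweep.to_frame(),
        selected_k=k,
        features=features.to_frame(),
        train_confusion=cm_train,
        test_confusion=cm_test,
        train_ber=ber(cm_train),
        test_ber=ber(cm_test),
        train_ccc=ccc(cm_train),
        test_ccc=ccc(cm_test),
        ccc_boot_mean=row.ccc_mean,
        ccc_boot_sd=row.ccc_sd,
        per_class=pd.DataFrame(per_class_rows),
        feature_stats=feature_stats,
    )
    _write_report(config, report, model, train, test)
    if config.make_plots:
        _make_plots(config, report, model, train, test, features)
    return report


def _write_report(config: RunConfig, report: RunReport, model, train, test) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.6g")
    report.sweep.to_csv(out / "sweep.tsv", **fmt)
    report.features.to_csv(out / "selected_features.tsv", **fmt)
    report.per_class.to_csv(out / "metrics_train.tsv", **fmt)
    report.train_confusion.to_frame().to_csv(out / "confusion_train.tsv", sep="\t")
    report.test_confusion.to_frame().to_csv(out / "confusion_test.tsv", sep="\t")

    stats_rows = []
    for fs in report.feature_stats:
        row = {"datapoint_index": fs.datapoint_index, "ppm": fs.ppm, "kw_h": fs.kw_h, "kw_p": fs.kw_p}
        for cls, summ in fs.per_class.items():
            if summ is None:
                continue
            med, q25, q75 = summ
            row[f"{cls}_median"] = med
            row[f"{cls}_q25"] = q25
            row[f"{cls}_q75"] = q75
        for (a, b), p in fs.posthoc:
            row[f"p_{a}_vs_{b}"] = p
        stats_rows.append(row)
    pd.DataFrame(stats_rows).to_csv(out / "feature_stats.tsv", **fmt)

    for name, cohort in (("train", train), ("test", test)):
        X, y = cohort.matrix()
        labels, Z = predict(model, X[:, model.features.indices])
        pd.DataFrame(
            {
                "spectrum_id": [r.spectrum_id for r in cohort.records],
                "true_class": y,
                "predicted_class": labels,
                "latent_1": Z[:, 0],
                "latent_2": Z[:, 1] if Z.shape[1] > 1 else np.nan,
            }
        ).to_csv(out / f"latent_{name}.tsv", **fmt)

    summary = {
        "scenario": config.scenario,
        "selected_k": report.selected_k,
        "train_ber_pct": report.train_ber,
        "test_ber_pct": report.test_ber,
        "train_ccc_pct": report.train_ccc,
        "test_ccc_pct": report.test_ccc,
        "ccc_boot_mean_pct": report.ccc_boot_mean,
        "ccc_boot_sd_pct": report.ccc_boot_sd,
    }
    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2) + "\n")

    cfg = {k: v for k, v in dataclasses.asdict(config).items() if k != "sim"}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, float)):
            out[k] = None if (isinstance(v, float) and math.isnan(v)) else float(v)
        elif isinstance(v, (np.integer,)):
            out[k] = int(v)
        else:
            out[k] = v
    return out


def _make_plots(config: RunConfig, report: RunReport, model, train, test, features) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(config.out_dir)
    # sweep curves: test BER and bootstrap CCC vs number of features
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(report.sweep["k"], report.sweep["test_ber"], "o-", color="tab:red", label="test BER")
    ax1.set_xlabel("number of features")
    ax1.set_ylabel("test BER (%)", color="tab:red")
    ax2 = ax1.twinx()
    ax2.errorbar(
        report.sweep["k"],
        report.sweep["ccc_mean"],
        yerr=report.sweep["ccc_sd"],
        fmt="s-",
        color="tab:blue",
        label="train CCC",
    )
    ax2.set_ylabel("bootstrap CCC (%)", color="tab:blue")
    ax1.axvline(report.selected_k, ls="--", color="gray")
    fig.tight_layout()
    fig.savefig(out / "sweep.png", dpi=120)
    plt.close(fig)

    # latent scatter
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True, sharey=True)
    for ax, (name, cohort) in zip(axes, (("train", train), ("test", test))):
        X, y = cohort.matrix()
        Z = model.transform(X[:, features.indices])
        for cls in train.class_labels:
            pts = Z[y == cls]
            ax.scatter(pts[:, 0], pts[:, 1], s=14, label=cls)
        ax.scatter(model.centroids[:, 0], model.centroids[:, 1], marker="x", c="k", s=60)
        ax.set_title(name)
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "latent.png", dpi=120)
    plt.close(fig)

    # class mean spectrum +/- SD
    fig, axes = plt.subplots(len(train.class_labels), 1, figsize=(7, 7), sharex=True)
    axis = train.axis
    X, y = train.matrix()
    for ax, cls in zip(np.atleast_1d(axes), train.class_labels):
        M = X[y == cls]
        mu, sd = M.mean(axis=0), M.std(axis=0)
        ax.plot(axis, mu, lw=0.8)
        ax.fill_between(axis, mu - sd, mu + sd, alpha=0.3)
        for p in features.ppms:
            ax.axvline(p, color="r", lw=0.5, ls=":")
        ax.set_ylabel(cls, fontsize=8)
        ax.invert_xaxis()
    np.atleast_1d(axes)[-1].set_xlabel("chemical shift (ppm)")
    fig.tight_layout()
    fig.savefig(out / "mean_spectra.png", dpi=120)
    plt.close(fig)
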
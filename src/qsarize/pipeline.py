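"""End-to-end QSAR pipeline and seed-sweep model search.

One call takes an SDF of structures plus activities and produces a fitted,
validated MLR model with applicability-domain assessment and predictions for
up to two extra compound sets, mirroring the classic single-function QSAR
workflow: read → descriptors → clean → correlation filter → split →
forward-select → fit → validate (LOO Q², R², R²_pred, PRESS) → AD +
similarity → predict → report/plot.

`seed_search` repeats the build over many seeds (each seed draws a different
activity-stratified test set) and lists the models meeting the reliability
criteria.
"""

from __future__ import annotations

import dataclasses
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem_io, descriptors, preprocessing
from .chem_io import Dataset
from .descriptors import DescriptorMatrix, FingerprintSet
from .domain import (AdReport, SimilarityReport, StandardizationStats,
                     flag_ad_outliers, similarity_to_train, standardize)
from .errors import AlignmentError, PipelineStageError
from .mlr import (MlrModel, ValidationMetrics, compute_validation_metrics,
                  fit_mlr, forward_select, press, reliability_verdict)
from .partitioning import Partition, split_by_activity, split_explicit


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    Either ``activity_path`` (CSV rank-ordered like the SDF) or the SDF
    property named by ``activity_field`` supplies activities;
    ``activity_scale`` says whether raw values are pIC50 or IC50 (µM).
    ``test_indices`` (1-based) overrides the seeded activity-stratified
    split. ``n_descriptors`` defaults to max(2, n_train // 5) — the one-in-
    five rule. At most two ``newset_paths`` are accepted.
    """

    sdf_path: str | Path
    activity_path: str | Path | None = None
    activity_field: str = "IC50"
    activity_scale: str = "pIC50"
    newset_paths: tuple = ()
    test_ratio: float = 0.2
    test_indices: tuple | None = None
    correlation_threshold: float = 1.0
    n_descriptors: int | None = None
    seed: int = 0
    ad_threshold: float = 3.0
    fingerprint_bits: int = 1024
    output_dir: str | Path | None = None
    plot_format: str = "pdf"

    def __post_init__(self):
        self.newset_paths = tuple(self.newset_paths)
        if len(self.newset_paths) > 2:
            raise ValueError(
                f"at most 2 new compound sets are supported, got "
                f"{len(self.newset_paths)}"
            )
        if self.plot_format not in ("pdf", "svg"):
            raise ValueError("plot_format must be 'pdf' or 'svg'")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class NewsetData:
    """A parsed extra compound set with descriptors and fingerprints."""

    path: Path
    records: list
    matrix: DescriptorMatrix
    fingerprints: FingerprintSet
    observed: np.ndarray | None  # pIC50, when the SDF carries activities


@dataclass
class PreparedInputs:
    """Input-dependent (seed-independent) state, computed once per dataset."""

    dataset: Dataset
    raw_matrix: DescriptorMatrix
    matrix: DescriptorMatrix
    preprocess_reports: list
    fingerprints: FingerprintSet
    newsets: list


@dataclass
class ModelBundle:
    """Everything a finished run produced.

    The R-flavoured aliases (``Q2``, ``R2``, ``R2_pred``, ``test``,
    ``newset``, ``Tanimoto_test_sum``, ``AD_outlier_test``,
    ``Tanimoto_newset_sum``) are kept for familiarity; the Tanimoto
    "sum" objects are per-compound (max, mean, min) summary tables.
    """

    config: PipelineConfig
    model: MlrModel
    metrics: ValidationMetrics
    partition: Partition
    stats: StandardizationStats
    train_predictions: pd.DataFrame
    test_predictions: pd.DataFrame
    newset_predictions: list[pd.DataFrame]
    ad_report_test: AdReport
    ad_reports_newset: list[AdReport]
    similarity_test: SimilarityReport
    similarities_newset: list[SimilarityReport]
    preprocess_reports: list
    artifacts: dict = field(default_factory=dict)

    # -- R-style accessors -------------------------------------------------
    @property
    def Q2(self) -> float:
        return self.metrics.q2

    @property
    def R2(self) -> float:
        return self.metrics.r2

    @property
    def R2_pred(self) -> float:
        return self.metrics.r2_pred

    @property
    def PRESS(self) -> float:
        return self.metrics.press

    @property
    def test(self) -> pd.DataFrame:
        return self.test_predictions

    @property
    def newset(self) -> pd.DataFrame | None:
        return self.newset_predictions[0] if self.newset_predictions else None

    @property
    def Tanimoto_test_sum(self) -> pd.DataFrame:
        return self.similarity_test.summary_frame()

    @property
    def AD_outlier_test(self) -> list[str]:
        r = self.ad_report_test
        return [c for c, f in zip(r.compound_ids, r.outlier_flags) if f]

    @property
    def Tanimoto_newset_sum(self) -> pd.DataFrame | None:
        if not self.similarities_newset:
            return None
        return self.similarities_newset[0].summary_frame()

    @property
    def AD_outlier_newset(self) -> list[str]:
        out = []
        for r in self.ad_reports_newset:
            out.extend(c for c, f in zip(r.compound_ids, r.outlier_flags) if f)
        return out


@dataclass
class SearchResult:
    """Per-seed metric records and the subset meeting the reliability bar."""

    records: list[dict]
    passing_seeds: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def prepare(config: PipelineConfig) -> PreparedInputs:
    """Run the seed-independent stages: parsing, descriptors, cleaning."""
    with _stage("read_structures"):
        molecules = chem_io.read_sdf(config.sdf_path)
    with _stage("read_activities"):
        if config.activity_path is not None:
            activities = chem_io.read_activities(
                config.activity_path, scale=config.activity_scale,
                n_expected=len(molecules))
        else:
            activities = chem_io.read_activities(
                molecules, field_name=config.activity_field,
                scale=config.activity_scale)
        dataset = Dataset(molecules=molecules, activities=activities,
                          name=Path(config.sdf_path).stem)
    with _stage("descriptors"):
        raw_matrix = descriptors.compute_descriptors(molecules)
        fps = descriptors.compute_fingerprints(molecules,
                                               n_bits=config.fingerprint_bits)
    with _stage("preprocess"):
        matrix, rep_invalid = preprocessing.drop_invalid(raw_matrix)
        matrix, rep_corr = preprocessing.remove_correlated(
            matrix, config.correlation_threshold)
    newsets = []
    for path in config.newset_paths:
        with _stage(f"newset:{Path(path).name}"):
            recs = chem_io.read_sdf(path)
            mat = descriptors.compute_descriptors(recs)
            nfps = descriptors.compute_fingerprints(
                recs, n_bits=config.fingerprint_bits)
            try:
                acts = chem_io.read_activities(
                    recs, field_name=config.activity_field,
                    scale=config.activity_scale)
                observed = np.array([a.value for a in acts])
            except AlignmentError:
                observed = None  # a prediction set need not carry activities
            newsets.append(NewsetData(path=Path(path), records=recs,
                                      matrix=mat, fingerprints=nfps,
                                      observed=observed))
    return PreparedInputs(dataset=dataset, raw_matrix=raw_matrix,
                          matrix=matrix,
                          preprocess_reports=[rep_invalid, rep_corr],
                          fingerprints=fps, newsets=newsets)


def default_n_descriptors(n_train: int) -> int:
    """One-in-five rule: max(2, n_train // 5) descriptors."""
    return max(2, n_train // 5)


def predict_new(model: MlrModel, newset: DescriptorMatrix,
                stats: StandardizationStats, train_fps: FingerprintSet,
                new_fps: FingerprintSet, ad_threshold: float = 3.0,
                observed: np.ndarray | None = None,
                ) -> tuple[pd.DataFrame, AdReport, SimilarityReport]:
    """Predict activities for a new compound set with AD gating.

    Flagged compounds keep their predicted value but carry
    ``applicable=False``. Tanimoto similarity to the training set is
    reported as advisory context, never as a gate.
    """
    try:
        restricted = newset.restrict(model.selected_descriptors)
    except KeyError as exc:
        raise ValueError(f"new set lacks a model descriptor: {exc}") from exc
    predicted = model.predict(restricted.values)
    s = standardize(restricted, stats)
    ad = flag_ad_outliers(s, threshold=ad_threshold,
                          compound_ids=restricted.compound_ids,
                          descriptor_names=restricted.descriptor_names)
    sim = similarity_to_train(new_fps, train_fps)
    table = pd.DataFrame({
        "compound": restricted.compound_ids,
        "predicted_pIC50": predicted,
        "applicable": ~ad.outlier_flags,
        "Tanimoto_max": sim.max,
        "Tanimoto_mean": sim.mean,
        "Tanimoto_min": sim.min,
    })
    if observed is not None:
        table.insert(1, "observed_pIC50", np.asarray(observed, dtype=float))
    return table, ad, sim


def build_model(prepared: PreparedInputs, config: PipelineConfig) -> ModelBundle:
    """Seed-dependent stages: split, select, fit, validate, assess, predict."""
    n = len(prepared.dataset)
    y = prepared.dataset.activity_values

    with _stage("partition"):
        if config.test_indices:
            partition = split_explicit(n, config.test_indices)
        else:
            partition = split_by_activity(prepared.dataset.activities,
                                          ratio=config.test_ratio,
                                          seed=config.seed)
    train_pos = partition.train_positions()
    test_pos = partition.test_positions()
    X_train_full = prepared.matrix.subset_rows(train_pos)
    X_test_full = prepared.matrix.subset_rows(test_pos)
    y_train, y_test = y[train_pos], y[test_pos]

    with _stage("forward_selection"):
        k = (config.n_descriptors if config.n_descriptors is not None
             else default_n_descriptors(len(train_pos)))
        selected = forward_select(X_train_full, y_train, k)
    with _stage("fit"):
        X_train = X_train_full.restrict(selected)
        X_test = X_test_full.restrict(selected)
        model = fit_mlr(X_train, y_train)
    with _stage("validation"):
        metrics = compute_validation_metrics(model, X_train.values, y_train,
                                             X_test.values, y_test)
    with _stage("applicability_domain"):
        stats = StandardizationStats.from_training(X_train)
        train_fps = prepared.fingerprints.subset_rows(train_pos)
        test_fps = prepared.fingerprints.subset_rows(test_pos)
        s_test = standardize(X_test, stats)
        ad_test = flag_ad_outliers(s_test, threshold=config.ad_threshold,
                                   compound_ids=X_test.compound_ids,
                                   descriptor_names=selected)
        sim_test = similarity_to_train(test_fps, train_fps)

    fitted_train = model.predict(X_train.values)
    train_table = pd.DataFrame({
        "compound": X_train.compound_ids,
        "observed_pIC50": y_train,
        "predicted_pIC50": fitted_train,
        "residual": y_train - fitted_train,
    })
    pred_test = model.predict(X_test.values)
    test_table = pd.DataFrame({
        "compound": X_test.compound_ids,
        "observed_pIC50": y_test,
        "predicted_pIC50": pred_test,
        "residual": y_test - pred_test,
        "AD_outlier": ad_test.outlier_flags,
        "Tanimoto_max": sim_test.max,
        "Tanimoto_mean": sim_test.mean,
        "Tanimoto_min": sim_test.min,
    })

    newset_tables, ad_newsets, sim_newsets = [], [], []
    for ns in prepared.newsets:
        with _stage(f"predict:{ns.path.name}"):
            table, ad, sim = predict_new(model, ns.matrix, stats, train_fps,
                                         ns.fingerprints,
                                         ad_threshold=config.ad_threshold,
                                         observed=ns.observed)
            newset_tables.append(table)
            ad_newsets.append(ad)
            sim_newsets.append(sim)

    return ModelBundle(config=config, model=model, metrics=metrics,
                       partition=partition, stats=stats,
                       train_predictions=train_table,
                       test_predictions=test_table,
                       newset_predictions=newset_tables,
                       ad_report_test=ad_test,
                       ad_reports_newset=ad_newsets,
                       similarity_test=sim_test,
                       similarities_newset=sim_newsets,
                       preprocess_reports=list(prepared.preprocess_reports))


def run_pipeline(config: PipelineConfig) -> ModelBundle:
    """Full deterministic run; writes report artifacts when
    ``config.output_dir`` is set."""
    prepared = prepare(config)
    bundle = build_model(prepared, config)
    if config.output_dir is not None:
        with _stage("write_outputs"):
            _write_artifacts(bundle, prepared, Path(config.output_dir))
    return bundle


def save_model(bundle: ModelBundle, path: str | Path) -> None:
    """Serialize the model (with its standardization stats) as JSON."""
    payload = {
        "intercept": bundle.model.intercept,
        "coefficients": bundle.model.coefficients,
        "selected_descriptors": bundle.model.selected_descriptors,
        "train_mean_activity": bundle.model.train_mean_activity,
        "n_train": bundle.model.n_train,
        "equation": bundle.model.equation_text(),
        "standardization": {
            "descriptor_names": bundle.stats.descriptor_names,
            "means": bundle.stats.means.tolist(),
            "sds": bundle.stats.sds.tolist(),
        },
        "ad_threshold": bundle.config.ad_threshold,
        "fingerprint_bits": bundle.config.fingerprint_bits,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path: str | Path) -> tuple[MlrModel, StandardizationStats]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    model = MlrModel(
        intercept=payload["intercept"],
        coefficients=payload["coefficients"],
        selected_descriptors=payload["selected_descriptors"],
        train_mean_activity=payload["train_mean_activity"],
        n_train=payload["n_train"],
    )
    s = payload["standardization"]
    stats = StandardizationStats(descriptor_names=s["descriptor_names"],
                                 means=np.array(s["means"]),
                                 sds=np.array(s["sds"]))
    return model, stats


def plot_observed_vs_predicted(bundle: ModelBundle, path: str | Path) -> None:
    """Observed-vs-predicted scatter: training as blue circles, test as red
    triangles, with the identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    tr, te = bundle.train_predictions, bundle.test_predictions
    ax.scatter(tr["observed_pIC50"], tr["predicted_pIC50"],
               marker="o", color="tab:blue", label=f"train (n={len(tr)})")
    ax.scatter(te["observed_pIC50"], te["predicted_pIC50"],
               marker="^", color="tab:red", label=f"test (n={len(te)})")
    lo = min(tr["observed_pIC50"].min(), tr["predicted_pIC50"].min(),
             te["observed_pIC50"].min(), te["predicted_pIC50"].min())
    hi = max(tr["observed_pIC50"].max(), tr["predicted_pIC50"].max(),
             te["observed_pIC50"].max(), te["predicted_pIC50"].max())
    pad = 0.05 * (hi - lo if hi > lo else 1.0)
    ax.plot([lo - pad, hi + pad], [lo - pad, hi + pad],
            color="grey", lw=1, zorder=0)
    ax.set_xlabel("observed pIC50")
    ax.set_ylabel("predicted pIC50")
    ax.set_title(f"Q²={bundle.Q2:.3f}  R²={bundle.R2:.3f}  "
                 f"R²_pred={bundle.R2_pred:.3f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _write_artifacts(bundle: ModelBundle, prepared: PreparedInputs,
                     outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    desc_path = outdir / "descriptors.csv"
    descriptors.write_descriptor_csv(prepared.raw_matrix, desc_path)
    artifacts["descriptors"] = desc_path

    plot_path = outdir / f"Plot-MLR.{bundle.config.plot_format}"
    plot_observed_vs_predicted(bundle, plot_path)
    artifacts["plot"] = plot_path

    model_path = outdir / "model.json"
    save_model(bundle, model_path)
    artifacts["model"] = model_path

    test_path = outdir / "predictions_test.csv"
    bundle.test_predictions.to_csv(test_path, index=False)
    artifacts["predictions_test"] = test_path
    for i, table in enumerate(bundle.newset_predictions, start=1):
        p = outdir / f"predictions_newset{i}.csv"
        table.to_csv(p, index=False)
        artifacts[f"predictions_newset{i}"] = p

    log_path = outdir / "run_log.jsonl"
    with open(log_path, "w", encoding="utf-8") as fh:
        for rep in bundle.preprocess_reports:
            fh.write(json.dumps(rep.to_dict()) + "\n")
    artifacts["run_log"] = log_path

    report_path = outdir / "report.txt"
    with open(report_path, "w", encoding="utf-8") as fh:
        fh.write(format_report(bundle))
    artifacts["report"] = report_path

    bundle.artifacts = artifacts


def format_report(bundle: ModelBundle) -> str:
    m = bundle.metrics
    lines = [
        "QSAR MLR model report",
        "=====================",
        bundle.model.equation_text(),
        "",
        f"n_train = {len(bundle.partition.train_indices)}, "
        f"n_test = {len(bundle.partition.test_indices)}, "
        f"seed = {bundle.partition.seed}",
        f"test compounds (1-based): {bundle.partition.test_indices}",
        "",
        f"Q2      = {m.q2:.3f}",
        f"R2      = {m.r2:.3f}",
        f"R2_pred = {m.r2_pred:.3f}",
        f"PRESS(test) = {m.press:.3f}",
        f"reliability pass (Q2>0.5, R2>0.8, R2_pred>0.6): {m.reliability_pass}",
        f"overtrained (R2 - Q2 > 0.3): {m.overtrained}",
        "",
        f"AD outliers (test, |S| >= {bundle.config.ad_threshold:g}): "
        f"{bundle.AD_outlier_test or 'none'}",
    ]
    for i, ad in enumerate(bundle.ad_reports_newset, start=1):
        flagged = [c for c, f in zip(ad.compound_ids, ad.outlier_flags) if f]
        lines.append(f"AD outliers (new set {i}): {flagged or 'none'}")
        for comp, desc, s in ad.outlier_details:
            lines.append(f"  {comp}: {desc} S = {s:.2f}")
    lines.append("")
    lines.append("Tanimoto similarity to training set (test):")
    lines.append(bundle.Tanimoto_test_sum.round(3).to_string())
    for i, sim in enumerate(bundle.similarities_newset, start=1):
        lines.append(f"Tanimoto similarity to training set (new set {i}):")
        lines.append(sim.summary_frame().round(3).to_string())
    return "\n".join(lines) + "\n"


def seed_search(config: PipelineConfig, seeds: Sequence[int]) -> SearchResult:
    """Build one model per seed and keep score.

    The heavy, seed-independent work (parsing, descriptors, fingerprints,
    cleaning) is done once; each seed then draws its own activity-stratified
    test set. A failing seed is recorded with its error, not fatal. PRESS is
    additionally reported over the first new set when that set carries
    observed activities.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed_search needs at least one seed")
    prepared = prepare(config)
    records, passing = [], []
    for s in seeds:
        cfg = config.replace(seed=s, test_indices=None, output_dir=None)
        try:
            bundle = build_model(prepared, cfg)
        except Exception as exc:
            records.append({"seed": s, "error": str(exc)})
            continue
        rec = {
            "seed": s,
            "q2": bundle.metrics.q2,
            "r2": bundle.metrics.r2,
            "r2_pred": bundle.metrics.r2_pred,
            "press_test": bundle.metrics.press,
            "reliability_pass": bundle.metrics.reliability_pass,
            "overtrained": bundle.metrics.overtrained,
            "test_indices": list(bundle.partition.test_indices),
            "n_ad_outliers_newset": sum(r.n_outliers
                                        for r in bundle.ad_reports_newset),
            "error": None,
        }
        first = bundle.newset_predictions[0] if bundle.newset_predictions else None
        if first is not None and "observed_pIC50" in first:
            rec["press_newset"] = press(first["observed_pIC50"],
                                        first["predicted_pIC50"])
        records.append(rec)
        ok, _ = reliability_verdict(bundle.metrics)
        if ok:
            passing.append(s)
    return SearchResult(records=records, passing_seeds=passing)
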
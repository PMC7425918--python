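"""End-to-end MSFS orchestration.

simulate -> normalize (x10) -> PCA + backward elimination -> feature
extraction (x10) -> Analysis 1 (select 5 normalization methods) ->
Analysis 2 (select 10 features) -> SVD fusion and width scan (m = 10..2) ->
classification of the top-3 hybrid datasets plus the rank-1 single-feature
reference under stratified 10-fold cross-validation.

Both selection analyses and the hybrid F-evaluation run on the tumor records
only (5 size classes); the tumor-free records join at classification, making
it a 6-class problem.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import fusion, reduction, selection
from .classification import EvalReport, cross_validate
from .features import FeatureMatrix, FeatureParams, build_feature_matrix
from .normalization import (
    NORMALIZATION_METHODS,
    compute_reference,
    global_amplitude_stats,
    normalize_set,
)
from .phantom import AcquisitionConfig, generate_dataset


@dataclass
class RunConfig:
    """Full-run configuration; defaults reproduce the study protocol."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    alpha: float = 0.05
    k_methods: int = 5
    k_features: int = 10
    m_min: int = 2
    m_max: int = 10
    classifiers: Tuple[str, ...] = ("svm_linear", "gaussian_nb", "pnn")
    cv_k: int = 10
    pnn_spread: float = 0.1
    pca_components: int = 20
    min_components: int = 2  # keeps per-record score vectors long enough for moment features
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    matrix_statistic_mode: str = "rowmean"
    seed: int = 0
    output_dir: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "acquisition" in d:
            d["acquisition"] = AcquisitionConfig.from_dict(d["acquisition"])
        if "feature_params" in d:
            d["feature_params"] = FeatureParams(**d["feature_params"])
        if "classifiers" in d:
            d["classifiers"] = tuple(d["classifiers"])
        return cls(**d)


@dataclass
class RunReport:
    """Per-stage artifacts of one full MSFS run."""

    seed: int
    method_selection: selection.SelectionReport
    feature_selection: selection.SelectionReport
    p_traces: Dict[str, List[Tuple[int, float]]]
    retained_components: Dict[str, int]
    hybrid_scan: List[Tuple[int, float]]
    top_widths: List[int]
    reference_feature: str
    eval_reports: Dict[str, Dict[str, EvalReport]]  # dataset -> classifier -> report
    wall_time_s: float
    n_records: int
    # per-record (all 6 classes) rank-ordered feature columns and labels, for
    # assembling/evaluating hybrid widths beyond the top-3 after the run
    ranked_record_columns: List[Tuple[str, np.ndarray]] = field(default_factory=list)
    record_labels: Optional[np.ndarray] = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for dataset, per_clf in self.eval_reports.items():
            for clf, rep in per_clf.items():
                rows.append(
                    {
                        "dataset": dataset,
                        "classifier": clf,
                        "accuracy": rep.accuracy,
                        "sensitivity": rep.sensitivity,
                        "specificity": rep.specificity,
                    }
                )
        return pd.DataFrame(rows)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


def _derive_seed(base: int, offset: int) -> int:
    return (base * 1000003 + offset) % (2**31 - 1)


def run_msfs(config: RunConfig) -> RunReport:
    """Execute the full multi-stage feature-selection pipeline."""
    t0 = time.time()
    acq = dataclasses.replace(config.acquisition, rng_seed=config.seed)

    # Stage 0: simulate the acquisition protocol.
    try:
        dataset = generate_dataset(acq)
    except Exception as e:  # pragma: no cover - defensive
        raise StageError(f"[simulate] {e}") from e
    labels = dataset.labels()
    tumor = labels > 0
    reference = compute_reference(dataset)
    gstats = global_amplitude_stats(dataset)

    feature_matrices: Dict[str, FeatureMatrix] = {}
    p_traces: Dict[str, List[Tuple[int, float]]] = {}
    retained: Dict[str, int] = {}
    method_candidates: List[Tuple[str, selection.AnovaResult]] = []

    for i, method in enumerate(NORMALIZATION_METHODS):
        # Stage 1: normalization + PCA backward elimination.
        try:
            nset = normalize_set(dataset, method, reference=reference, global_stats=gstats)
            model = reduction.fit_pca(
                nset.matrix,
                n_components=config.pca_components,
                random_state=_derive_seed(config.seed, i),
            )
            scores = model.transform(nset.matrix)
            red = reduction.reduce_by_significance(
                scores[tumor],
                labels[tumor],
                alpha=config.alpha,
                min_components=config.min_components,
                statistic=lambda X, y: selection.matrix_statistic(
                    X, y, mode=config.matrix_statistic_mode
                ),
            )
        except Exception as e:
            raise StageError(f"[stage1:{method}] {e}") from e
        p_traces[method] = red.p_trace
        retained[method] = red.retained_count

        # Stage 2: feature extraction on all records (tumor + tumor-free).
        try:
            params = dataclasses.replace(
                config.feature_params, ica_seed=_derive_seed(config.seed, 100 + i)
            )
            fm = build_feature_matrix(
                scores[:, : red.retained_count],
                labels,
                params=params,
                signals=nset.matrix,
                source_method=method,
            )
        except Exception as e:
            raise StageError(f"[stage2:{method}] {e}") from e
        if fm.excluded_rows is not None:
            raise StageError(
                f"[stage2:{method}] non-finite features for rows {fm.excluded_rows[:5]}..."
            )
        feature_matrices[method] = fm

        # Stage 3 / Analysis 1 candidate: matrix-level (p, F) on tumor records.
        try:
            res = selection.matrix_statistic(
                fm.values[tumor], labels[tumor], mode=config.matrix_statistic_mode
            )
        except Exception as e:
            raise StageError(f"[stage3a:{method}] {e}") from e
        method_candidates.append((method, res))

    method_selection = selection.select_top(method_candidates, config.alpha, config.k_methods)

    # Stage 3 / Analysis 2: per-feature ANOVA over the selected methods.
    feature_candidates: List[Tuple[str, selection.AnovaResult]] = []
    columns: Dict[str, np.ndarray] = {}
    for method in method_selection.selected_names():
        fm = feature_matrices[method]
        for j, feat in enumerate(fm.feature_names):
            name = f"{feat}-{method}"
            try:
                res = selection.anova_column(fm.values[tumor, j], labels[tumor])
            except Exception as e:
                raise StageError(f"[stage3b:{name}] {e}") from e
            feature_candidates.append((name, res))
            columns[name] = fm.values[:, j]
    feature_selection = selection.select_top(feature_candidates, config.alpha, config.k_features)

    # Stage 4: fusion and width scan on tumor records.
    ranked = [(name, columns[name][tumor]) for name in feature_selection.selected_names()]
    m_hi = min(config.m_max, len(ranked))
    if m_hi < max(config.m_min, 2):
        raise StageError(
            f"[stage4] only {len(ranked)} ranked features; cannot scan widths"
        )
    try:
        scan, top_widths = fusion.scan_hybrid_widths(
            ranked,
            labels[tumor],
            m_range=range(m_hi, max(config.m_min, 2) - 1, -1),
            block_size=acq.reps_per_point,
        )
    except Exception as e:
        raise StageError(f"[stage4] {e}") from e

    # Classification: top-3 hybrids + rank-1 single-feature reference, all records.
    eval_reports: Dict[str, Dict[str, EvalReport]] = {}
    ref_name = feature_selection.selected_names()[0]
    datasets: Dict[str, np.ndarray] = {
        f"{m}-HybridFeature": np.column_stack(
            [columns[name] for name in feature_selection.selected_names()[:m]]
        )
        for m in top_widths
    }
    datasets[f"reference ({ref_name})"] = columns[ref_name][:, None]
    for ds_name, X in datasets.items():
        eval_reports[ds_name] = {}
        for clf in config.classifiers:
            try:
                eval_reports[ds_name][clf] = cross_validate(
                    X,
                    labels,
                    clf,
                    k=config.cv_k,
                    seed=config.seed,
                    spread=config.pnn_spread,
                )
            except Exception as e:
                raise StageError(f"[classify:{ds_name}:{clf}] {e}") from e

    report = RunReport(
        seed=config.seed,
        method_selection=method_selection,
        feature_selection=feature_selection,
        p_traces=p_traces,
        retained_components=retained,
        hybrid_scan=scan,
        top_widths=top_widths,
        reference_feature=ref_name,
        eval_reports=eval_reports,
        wall_time_s=time.time() - t0,
        n_records=len(dataset),
        ranked_record_columns=[
            (name, columns[name]) for name in feature_selection.selected_names()
        ],
        record_labels=labels,
    )
    if config.output_dir:
        emit_report(report, feature_matrices, config)
    return report


def _selection_frame(rep: selection.SelectionReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"name": name, "p": res.p, "F": res.F, "selected": name in rep.selected_names()}
            for name, res in rep.candidates
        ]
    )


def emit_report(
    report: RunReport, feature_matrices: Dict[str, FeatureMatrix], config: RunConfig
) -> None:
    """Write run artifacts: selection CSVs, hybrid scan, metrics, JSON summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _selection_frame(report.method_selection).to_csv(out / "method_selection.csv", index=False)
    _selection_frame(report.feature_selection).to_csv(out / "feature_selection.csv", index=False)
    pd.DataFrame(report.hybrid_scan, columns=["m", "F"]).to_csv(
        out / "hybrid_scan.csv", index=False
    )
    report.summary_frame().to_csv(out / "classification_metrics.csv", index=False)
    for method, fm in feature_matrices.items():
        fm.to_csv(out / f"features_{method}.csv")
    summary = {
        "seed": report.seed,
        "n_records": report.n_records,
        "selected_methods": report.method_selection.selected_names(),
        "selected_features": report.feature_selection.selected_names(),
        "retained_components": report.retained_components,
        "p_traces": {m: [[int(c), float(p)] for c, p in tr] for m, tr in report.p_traces.items()},
        "hybrid_scan": [[int(m), float(F)] for m, F in report.hybrid_scan],
        "top_widths": [int(m) for m in report.top_widths],
        "reference_feature": report.reference_feature,
        "metrics": {
            ds: {
                clf: {
                    "accuracy": rep.accuracy,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                }
                for clf, rep in per_clf.items()
            }
            for ds, per_clf in report.eval_reports.items()
        },
        "wall_time_s": report.wall_time_s,
    }
    (out / "run_report.json").write_text(json.dumps(summary, indent=2))
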
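"""End-to-end experiment runner: 4 methods x 3 tasks x 3 cohorts.

Reproduces the study's protocol shape on any dataset (normally a
simulated one): stratified 80/20 train/test split per task and cohort,
fits of the time-threshold, frequency-threshold, logistic and SVM models,
and a metrics table of balanced accuracy, (macro-)F1 and optional
stratified k-fold cross-validation loss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import (evaluate_predictions, kfold_loss, split_train_test)
from .features import FEATURE_NAMES, feature_table
from .linear import balance_classes, fit_logistic, fit_svm, fit_ternary, predict
from .sim import Dataset
from .thresholds import (COHORTS, POSITIVE_CLASS, fit_freq_model,
                         fit_time_model, predict_freq, predict_time,
                         select_cohort, trace_label)

METHODS = ("time_threshold", "freq_threshold", "logistic", "svm")


def _task_subset(dataset: Dataset, task: int, cohort: str):
    traces = [t for t in select_cohort(dataset, cohort)
              if trace_label(t.location, task) is not None]
    labels = np.array([trace_label(t.location, task) for t in traces])
    return traces, labels


def _subset_dataset(dataset: Dataset, traces) -> Dataset:
    return Dataset(dataset.participants, list(traces), dataset.device_config,
                   dataset.cohort_config)


def _threshold_trainer(dataset: Dataset, task: int, method: str, rounds: int):
    fit = fit_time_model if method == "time_threshold" else fit_freq_model
    pred = predict_time if method == "time_threshold" else predict_freq

    def trainer(train_traces, _labels):
        kwargs = {"rounds": rounds} if method == "time_threshold" else {}
        model = fit(_subset_dataset(dataset, train_traces), task, "all",
                    **kwargs)
        return lambda traces: np.array([pred(model, t) for t in traces])
    return trainer


def _linear_trainer(task: int, method: str, seed: int):
    fitter = fit_logistic if method == "logistic" else fit_svm

    def trainer(X_train, y_train):
        if task == 3:
            model = fit_ternary(fitter, X_train, y_train, seed=seed)
        else:
            sub = balance_classes(y_train, seed=seed)
            model = fitter(X_train[sub], y_train[sub],
                           positive_class=POSITIVE_CLASS[task])
        return lambda X: predict(model, X)
    return trainer


def run_benchmark(
    dataset: Dataset,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
    tasks: tuple[int, ...] = (1, 2, 3),
    cohorts: tuple[str, ...] = COHORTS,
    train_frac: float = 0.8,
    kfold_k: int = 0,
    window_rounds: int = 3,
) -> pd.DataFrame:
    """Fit and score every requested method/task/cohort combination.

    Returns a table with one row per combination: balanced accuracy and
    F1 (macro-F1 for the ternary task) on the held-out 20%, plus the
    k-fold loss over the full task subset when ``kfold_k >= 2``.
    """
    features = feature_table(dataset)
    X_all = features[list(FEATURE_NAMES)].to_numpy()

    rows = []
    for task in tasks:
        for cohort in cohorts:
            traces, labels = _task_subset(dataset, task, cohort)
            trace_ids = {id(t): i for i, t in enumerate(dataset.traces)}
            rows_idx = np.array([trace_ids[id(t)] for t in traces])
            X = X_all[rows_idx]
            train_idx, test_idx = split_train_test(labels, train_frac, seed)
            positive = POSITIVE_CLASS.get(task)

            for method in methods:
                if method in ("time_threshold", "freq_threshold"):
                    trainer = _threshold_trainer(dataset, task, method,
                                                 window_rounds)
                    data = np.empty(len(traces), dtype=object)
                    data[:] = traces
                else:
                    trainer = _linear_trainer(task, method, seed)
                    data = X

                model_predict = trainer(data[train_idx], labels[train_idx])
                predicted = np.asarray(model_predict(data[test_idx]))
                report = evaluate_predictions(labels[test_idx], predicted,
                                              positive)
                loss = (kfold_loss(data, labels, trainer, kfold_k, seed)
                        if kfold_k >= 2 else np.nan)
                rows.append({
                    "method": method, "task": task, "cohort": cohort,
                    "balanced_accuracy": report.balanced_accuracy,
                    "f1": report.f1, "kfold_loss": loss,
                    "n_train": int(train_idx.size),
                    "n_test": int(test_idx.size),
                })
    return pd.DataFrame(rows)


def stratified_vs_pooled_time(dataset: Dataset, seed: int = 0, task: int = 1,
                              window_rounds: int = 3,
                              ) -> tuple[float, float]:
    """Pooled vs BMI-stratified time-threshold accuracy on one test split.

    Fits one pooled model and one model per BMI cohort on the same 80%
    training traces, then scores both strategies on the identical held-out
    20%: the stratified strategy routes each test trace to its cohort's
    model. Returns ``(pooled_ba, stratified_ba)``.
    """
    traces, labels = _task_subset(dataset, task, "all")
    train_idx, test_idx = split_train_test(labels, 0.8, seed)
    train_ds = _subset_dataset(dataset, [traces[i] for i in train_idx])

    pooled = fit_time_model(train_ds, task, "all", rounds=window_rounds)
    per_cohort = {c: fit_time_model(train_ds, task, c, rounds=window_rounds)
                  for c in ("low_bmi", "high_bmi")}

    test_traces = [traces[i] for i in test_idx]
    true = labels[test_idx]
    pooled_pred = [predict_time(pooled, t) for t in test_traces]
    strat_pred = [
        predict_time(per_cohort[dataset.participant(t.participant_id).cohort],
                     t)
        for t in test_traces
    ]
    ba = lambda pred: evaluate_predictions(  # noqa: E731
        true, pred, POSITIVE_CLASS.get(task)).balanced_accuracy
    return ba(pooled_pred), ba(strat_pred)
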
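"""Benchmark protocol: Day-1 training, reverse five-fold target days.

Day 1 supplies the training data and the feature-dimension choice; each
later day is a "new use" after electrode re-donning.  On every target day
a *reverse* five-fold cross-validation is run: the held-in fifth is the
calibration set used to adapt the model and the remaining four fifths form
the test set (the inversion of conventional CV — adaptation data is scarce
by design, since re-calibrating a prosthesis must be quick).

Performance indices per (subject, selector, classifier, day, fold):
classification accuracy, training time (base training plus adaptation;
base only for the non-adaptive SVM) and response time (wall-clock
classification of the test set).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import adaptation as _ad
from . import selection as _sel
from .adaptation import AdaptationConfig, SvmModel
from .data import WindowSpec, segment_trials_array
from .features import FeatureLayout, FeatureParams, extract_feature_matrix
from .synthetic import BenchmarkConfig, generate_subject_day

CLASSIFIERS = ("N-SVM", "I-SVM", "T-SVM", "TI-SVM")
SELECTORS = ("NFS", "SFS", "PSO")


@dataclass(frozen=True)
class FoldPlan:
    """Reverse five-fold split of one target day.

    ``folds[k] = (calibration_idx, test_idx)``; the five calibration sets
    partition the day's windows and each is stratified by motion.
    """

    folds: tuple[tuple[np.ndarray, np.ndarray], ...]

    def __len__(self) -> int:
        return len(self.folds)


def make_fold_plan(y: np.ndarray, seed: int, n_folds: int = 5,
                   contiguous: bool = False) -> FoldPlan:
    """Stratified reverse-fold plan over one day's window labels.

    ``contiguous=True`` uses unshuffled (time-ordered) folds instead.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        lacking = classes[counts < n_folds]
        raise ValueError(
            f"classes {lacking} have fewer than {n_folds} windows"
        )
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=not contiguous,
        random_state=None if contiguous else seed,
    )
    folds = tuple(
        (np.sort(small), np.sort(big))
        for big, small in skf.split(np.zeros(len(y)), y)
    )
    return FoldPlan(folds=folds)


def day1_split(y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 4/5 train / 1/5 validation indices of the Day-1 windows."""
    idx = np.arange(len(y))
    train, val = train_test_split(
        idx, test_size=0.2, stratify=np.asarray(y), random_state=seed
    )
    return np.sort(train), np.sort(val)


def subject_day_features(
    config: BenchmarkConfig,
    subject: int,
    day: int,
    spec: WindowSpec = WindowSpec(),
    params: FeatureParams = FeatureParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one subject-day and extract its feature matrix.

    Returns ``(X, y)`` with X of shape (windows, 42 x channels).
    """
    trials = generate_subject_day(config, subject, day)
    windows, meta = segment_trials_array(trials, spec, config.keep_central_s)
    X = extract_feature_matrix(
        windows, config.sampling_rate, FeatureLayout(config.n_channels), params
    )
    return X, meta["label"].to_numpy()


def _adapt_model(
    classifier: str,
    base: SvmModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    config: AdaptationConfig,
) -> tuple[SvmModel, float]:
    """Build the per-fold model; returns (model, adaptation seconds)."""
    if classifier == "N-SVM":
        return base, 0.0
    t0 = time.perf_counter()
    if classifier == "I-SVM":
        model = _ad.incremental_adapt(base, X_cal, y_cal, config)
    elif classifier == "T-SVM":
        model = _ad.tradaboost_adapt(
            X_train, y_train, X_cal, y_cal, config, base_model=base
        )
    elif classifier == "TI-SVM":
        model = _ad.ti_svm_adapt(
            X_train, y_train, X_cal, y_cal, config, base_model=base
        )
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return model, time.perf_counter() - t0


def evaluate_combination(
    X1: np.ndarray,
    y1: np.ndarray,
    dims: np.ndarray,
    classifier: str,
    target_days: dict[int, tuple[np.ndarray, np.ndarray]],
    fold_plans: dict[int, FoldPlan],
    config: AdaptationConfig = AdaptationConfig(),
    selector: str = "NFS",
    subject: int | str = 1,
    seed: int = 0,
) -> list[dict]:
    """Run one (selector result, classifier) cell of the benchmark.

    ``X1``/``y1`` is the full Day-1 feature matrix; the Day-1 training
    subset (4/5, stratified by ``seed``) trains the base model.  ``dims``
    (selected on Day 1) are applied unchanged to every target day.  Test
    windows touch nothing but the final prediction call.
    """
    dims = np.asarray(dims, dtype=int)
    train_idx, _ = day1_split(y1, seed)
    X_train = X1[np.ix_(train_idx, dims)]
    y_train = np.asarray(y1)[train_idx]

    t0 = time.perf_counter()
    base = _ad.train_base_svm(X_train, y_train, config)
    base_time = time.perf_counter() - t0

    rows: list[dict] = []
    for day, (Xd, yd) in sorted(target_days.items()):
        Xd_sel = Xd[:, dims]
        for k, (cal_idx, test_idx) in enumerate(fold_plans[day].folds):
            model, adapt_time = _adapt_model(
                classifier, base, X_train, y_train,
                Xd_sel[cal_idx], yd[cal_idx], config,
            )
            pred, response = _ad.predict(model, Xd_sel[test_idx],
                                         return_time=True)
            rows.append({
                "subject": subject,
                "selector": selector,
                "classifier": classifier,
                "day": day,
                "fold": k,
                "accuracy": float(np.mean(pred == yd[test_idx])),
                "train_time_s": base_time + adapt_time,
                "response_time_s": response,
                "n_test": int(len(test_idx)),
                "n_dims": int(len(dims)),
            })
    return rows


def select_dims(
    method: str,
    X1: np.ndarray,
    y1: np.ndarray,
    layout: FeatureLayout,
    seed: int,
    pso_config: _sel.PsoConfig | None = None,
) -> _sel.SelectionResult:
    """Run one Day-1 feature selector (NFS, SFS or PSO)."""
    if method == "NFS":
        return _sel.nfs_select(X1.shape[1])
    if method == "SFS":
        return _sel.sfs_select(X1, y1, layout=layout)
    if method == "PSO":
        cfg = pso_config or _sel.PsoConfig(seed=seed)
        if cfg.seed != seed:
            cfg = replace(cfg, seed=seed)
        return _sel.pso_select(X1, y1, cfg)
    raise ValueError(f"unknown selector {method!r}")


def run_benchmark(
    config: BenchmarkConfig,
    spec: WindowSpec = WindowSpec(),
    selectors: tuple[str, ...] = ("NFS",),
    classifiers: tuple[str, ...] = CLASSIFIERS,
    target_days: tuple[int, ...] | None = None,
    adaptation_config: AdaptationConfig = AdaptationConfig(),
    pso_config: _sel.PsoConfig | None = None,
    params: FeatureParams = FeatureParams(),
) -> pd.DataFrame:
    """The full selector x classifier benchmark over the synthetic grid.

    Returns one row per (subject, selector, classifier, day, fold) with
    accuracy, training time and response time.
    """
    if target_days is None:
        target_days = tuple(range(2, config.n_days + 1))
    layout = FeatureLayout(config.n_channels)
    rows: list[dict] = []
    for subject in range(1, config.n_subjects + 1):
        X1, y1 = subject_day_features(config, subject, 1, spec, params)
        days = {
            d: subject_day_features(config, subject, d, spec, params)
            for d in target_days
        }
        plans = {
            d: make_fold_plan(yd, seed=config.seed + subject)
            for d, (_, yd) in days.items()
        }
        for sel_name in selectors:
            sel = select_dims(
                sel_name, X1, y1, layout, seed=config.seed + subject,
                pso_config=pso_config,
            )
            for clf in classifiers:
                rows.extend(evaluate_combination(
                    X1, y1, sel.dims, clf, days, plans,
                    adaptation_config, selector=sel_name, subject=subject,
                    seed=config.seed + subject,
                ))
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> dict:
    """Scheme-level means and paired ordering checks.

    Returns a dict with a per-scheme ``mean_sd`` table (accuracy and the
    two time indices) and ``orderings``: per classifier pair, the paired
    per-subject accuracy differences with a sign summary and a Wilcoxon
    signed-rank p-value (the nonparametric stand-in for the original
    repeated-measures comparisons).
    """
    needed = {"subject", "selector", "classifier", "accuracy"}
    if not needed <= set(results.columns):
        raise ValueError(f"results missing columns {needed - set(results.columns)}")
    cells = results.groupby(["selector", "classifier"])
    expected = (
        results["selector"].nunique() * results["classifier"].nunique()
    )
    if len(cells) != expected:
        have = set(cells.groups)
        want = {
            (s, c)
            for s in results["selector"].unique()
            for c in results["classifier"].unique()
        }
        raise ValueError(f"missing benchmark cells: {sorted(want - have)}")

    mean_sd = cells.agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_sd=("accuracy", "std"),
        train_time_mean=("train_time_s", "mean"),
        response_time_mean=("response_time_s", "mean"),
    ).reset_index()

    per_subject = (
        results.groupby(["subject", "classifier"])["accuracy"]
        .mean()
        .unstack("classifier")
    )
    pairs = [
        ("TI-SVM", "I-SVM"), ("TI-SVM", "N-SVM"), ("I-SVM", "N-SVM"),
        ("T-SVM", "N-SVM"), ("I-SVM", "T-SVM"),
    ]
    orderings = {}
    for hi, lo in pairs:
        if hi not in per_subject.columns or lo not in per_subject.columns:
            continue
        diff = (per_subject[hi] - per_subject[lo]).to_numpy()
        if np.allclose(diff, 0):
            p = 1.0
        else:
            try:
                p = float(_stats.wilcoxon(diff).pvalue)
            except ValueError:
                p = float("nan")
        orderings[f"{hi}>{lo}"] = {
            "mean_diff": float(diff.mean()),
            "n_positive": int((diff > 0).sum()),
            "n_negative": int((diff < 0).sum()),
            "n_ties": int((diff == 0).sum()),
            "wilcoxon_p": p,
        }
    return {"mean_sd": mean_sd, "orderings": orderings}


def desk_benchmark_config(seed: int, shift: float = 1.0) -> tuple[
    BenchmarkConfig, WindowSpec, tuple[int, ...]
]:
    """Reduced-scale study conditions for a single-workstation run.

    Three subjects, target days 2-3, and non-overlapping 250-ms windows
    (20 per trial instead of 96 — the same trials, thinner window
    sampling).  Everything else matches the full protocol.
    """
    config = BenchmarkConfig(
        n_subjects=3, n_days=3, shift=shift, seed=seed
    )
    spec = WindowSpec(length_ms=250.0, step_ms=250.0)
    return config, spec, (2, 3)
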
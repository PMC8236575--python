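"""Four adaptation strategies over a linear-kernel multiclass SVM.

* **N-SVM** — train once on the Day-1 training set, never adapt.
* **I-SVM** — batch-incremental: repeatedly retrain on the current support
  samples plus the next calibration batch, keeping only the new support
  samples between batches.
* **T-SVM** — instance-transfer boosting (TrAdaBoost): Day-1 samples that
  the evolving model misclassifies are down-weighted and eventually
  discarded; target-day calibration samples that are misclassified are
  up-weighted, steering the training set toward the new distribution.
* **TI-SVM** — TrAdaBoost set construction followed by batch-incremental
  adaptation with the full calibration set.

All four share one frozen standardisation fitted on the Day-1 training
data; re-fitting it on later days would amount to extra unsupervised
adaptation.  Sample weights enter the SVM as per-sample cost multipliers
(weighted hinge loss), keeping every step deterministic.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class AdaptationConfig:
    """Knobs of the adaptive classifiers.

    ``batch_size`` is the number of calibration vectors per incremental
    step; ``rounds`` the number of TrAdaBoost iterations; ``C`` the SVM
    cost.  ``source_discard_frac`` removes Day-1 samples whose weight has
    fallen below that fraction of the mean source weight; calibration
    samples join the training set when their weight is at least the mean
    calibration weight.  ``select_by_weight`` switches the final-model
    choice from the count of included calibration samples to their total
    weight.
    """

    batch_size: int = 48
    rounds: int = 26
    C: float = 1.0
    source_discard_frac: float = 0.1
    eps_clip: tuple[float, float] = (1e-10, 0.499)
    shuffle_batches: bool = False
    select_by_weight: bool = False
    round_weighted: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.rounds < 2:
            raise ValueError("rounds must be >= 2")


@dataclass
class SvmModel:
    """A trained linear SVM plus the state its adaptations need.

    ``support_X``/``support_y`` hold the raw (unstandardised) support
    samples of the most recent fit — the memory that incremental
    adaptation carries between batches.  ``scaler`` is frozen at base
    training and reused for every later day.
    """

    svc: SVC
    scaler: StandardScaler
    support_X: np.ndarray
    support_y: np.ndarray
    classes: np.ndarray
    history: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.scaler.mean_.shape[0]

    def decision_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected feature dimension {self.n_features}, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return self.scaler.transform(X)


def _fit_svc(
    X_std: np.ndarray,
    y: np.ndarray,
    C: float,
    sample_weight: np.ndarray | None = None,
) -> SVC:
    svc = SVC(kernel="linear", C=C)
    svc.fit(X_std, y, sample_weight=sample_weight)
    return svc


def train_base_svm(
    X: np.ndarray, y: np.ndarray, config: AdaptationConfig = AdaptationConfig()
) -> SvmModel:
    """Fit the Day-1 base model: standardisation plus one-vs-one linear SVM."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("base training needs at least two classes")
    scaler = StandardScaler().fit(X)
    svc = _fit_svc(scaler.transform(X), y, config.C)
    sup = svc.support_
    return SvmModel(
        svc=svc, scaler=scaler, support_X=X[sup].copy(),
        support_y=y[sup].copy(), classes=classes, history=["base"],
    )


def incremental_adapt(
    model: SvmModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    config: AdaptationConfig = AdaptationConfig(),
) -> SvmModel:
    """Batch-incremental adaptation with a calibration set.

    The calibration vectors are split in arrival order into batches of
    ``batch_size`` (the final batch may be smaller).  Each step retrains on
    the current support samples plus the batch and keeps the new support
    samples.  The input model is not mutated.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal)
    if len(X_cal) == 0:
        raise ValueError("calibration set is empty")
    unknown = np.setdiff1d(np.unique(y_cal), model.classes)
    if unknown.size:
        raise ValueError(f"calibration labels {unknown} outside label set")
    order = np.arange(len(X_cal))
    if config.shuffle_batches:
        order = np.random.default_rng(config.seed).permutation(order)
    sup_X, sup_y = model.support_X, model.support_y
    svc = model.svc
    n_batches = 0
    for start in range(0, len(order), config.batch_size):
        idx = order[start: start + config.batch_size]
        Xb = np.concatenate([sup_X, X_cal[idx]])
        yb = np.concatenate([sup_y, y_cal[idx]])
        svc = _fit_svc(model.scaler.transform(Xb), yb, config.C)
        sup_X, sup_y = Xb[svc.support_], yb[svc.support_]
        n_batches += 1
    return SvmModel(
        svc=svc, scaler=model.scaler, support_X=sup_X.copy(),
        support_y=sup_y.copy(), classes=model.classes,
        history=model.history + [f"incremental:{n_batches}"],
    )


def n_incremental_batches(n_calibration: int, batch_size: int) -> int:
    """Number of adaptation steps for a calibration set of a given size."""
    return -(-n_calibration // batch_size)


# ---------------------------------------------------------------------------
# TrAdaBoost
# ---------------------------------------------------------------------------

def source_beta(n_source: int, rounds: int) -> float:
    """Down-weighting factor for misclassified source samples.

    ``beta = 1 / (1 + sqrt(2 ln(n_source) / rounds))`` — the canonical
    instance-transfer boosting rate.
    """
    return 1.0 / (1.0 + np.sqrt(2.0 * np.log(n_source) / rounds))


@dataclass
class TradaboostRound:
    """Diagnostics of one boosting round (model plus bookkeeping)."""

    svc: SVC
    eps: float
    source_kept: np.ndarray  # bool mask over source samples
    calibration_kept: np.ndarray  # bool mask over calibration samples
    calibration_kept_count: int
    calibration_kept_weight: float


def tradaboost_round(
    Xs_std: np.ndarray,
    ys: np.ndarray,
    Xc_std: np.ndarray,
    yc: np.ndarray,
    w_src: np.ndarray,
    w_cal: np.ndarray,
    beta: float,
    config: AdaptationConfig = AdaptationConfig(),
) -> tuple[np.ndarray, np.ndarray, TradaboostRound]:
    """One TrAdaBoost round on standardised source/calibration samples.

    Builds the round training set (source samples above the discard
    threshold, calibration samples at or above the mean calibration
    weight), trains a weighted SVM on it, then reweights: misclassified
    source weights shrink by ``beta``; misclassified calibration weights
    grow by ``(eps/(1-eps))^-1`` where ``eps`` is the weighted calibration
    error (clipped).  All weights are renormalised to sum to one.

    Returns ``(new_w_src, new_w_cal, round_record)``.
    """
    w_src = np.asarray(w_src, dtype=float)
    w_cal = np.asarray(w_cal, dtype=float)
    if w_src.sum() + w_cal.sum() <= 0:
        raise ValueError("all sample weights are zero")

    src_keep = w_src >= config.source_discard_frac * w_src.mean()
    # tolerance guards the all-equal case against 1-ulp rounding of the mean
    cal_keep = w_cal >= w_cal.mean() * (1.0 - 1e-9)
    if not cal_keep.any():
        cal_keep = w_cal == w_cal.max()
    assert cal_keep.any(), "calibration cannot be entirely discarded"
    if not src_keep.any() and cal_keep.sum() == 0:
        raise ValueError("empty training set after discarding")

    X_round = np.concatenate([Xs_std[src_keep], Xc_std[cal_keep]])
    y_round = np.concatenate([ys[src_keep], yc[cal_keep]])
    w_round = np.concatenate([w_src[src_keep], w_cal[cal_keep]])
    sample_weight = (
        w_round / w_round.mean() if config.round_weighted else None
    )
    svc = _fit_svc(X_round, y_round, config.C, sample_weight)

    miss_src = svc.predict(Xs_std) != ys
    miss_cal = svc.predict(Xc_std) != yc
    eps = float(w_cal[miss_cal].sum() / w_cal.sum())
    eps = float(np.clip(eps, config.eps_clip[0], config.eps_clip[1]))
    beta_t = eps / (1.0 - eps)

    new_src = w_src.copy()
    new_cal = w_cal.copy()
    new_src[miss_src] *= beta
    new_cal[miss_cal] /= beta_t
    total = new_src.sum() + new_cal.sum()
    new_src /= total
    new_cal /= total

    record = TradaboostRound(
        svc=svc, eps=eps, source_kept=src_keep, calibration_kept=cal_keep,
        calibration_kept_count=int(cal_keep.sum()),
        calibration_kept_weight=float(w_cal[cal_keep].sum()),
    )
    return new_src, new_cal, record


def tradaboost_run(
    Xs_std: np.ndarray,
    ys: np.ndarray,
    Xc_std: np.ndarray,
    yc: np.ndarray,
    config: AdaptationConfig = AdaptationConfig(),
) -> tuple[list[TradaboostRound], int]:
    """Run all boosting rounds and pick the final round.

    The chosen round comes from the last half of the rounds (for 26
    rounds, rounds 14..26): the one whose training set contained the most
    calibration samples (or the largest calibration weight when
    ``select_by_weight``), ties resolved toward the latest round.

    Returns ``(rounds, selected_index)`` with a 0-based index.
    """
    n_src, n_cal = len(ys), len(yc)
    if n_src == 0 or n_cal == 0:
        raise ValueError("source and calibration sets must be nonempty")
    beta = source_beta(n_src, config.rounds)
    w_src = np.full(n_src, 1.0 / (n_src + n_cal))
    w_cal = np.full(n_cal, 1.0 / (n_src + n_cal))
    records: list[TradaboostRound] = []
    for _ in range(config.rounds):
        w_src, w_cal, rec = tradaboost_round(
            Xs_std, ys, Xc_std, yc, w_src, w_cal, beta, config
        )
        records.append(rec)
    first_eligible = -(-config.rounds // 2)  # ceil(n/2): 0-based index of round ceil(n/2)+1
    key = (
        (lambda r: r.calibration_kept_weight)
        if config.select_by_weight
        else (lambda r: r.calibration_kept_count)
    )
    best = first_eligible
    for i in range(first_eligible, config.rounds):
        if key(records[i]) >= key(records[best]):
            best = i  # >= resolves ties toward the latest round
    return records, best


def tradaboost_adapt(
    X_src: np.ndarray,
    y_src: np.ndarray,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    config: AdaptationConfig = AdaptationConfig(),
    base_model: SvmModel | None = None,
) -> SvmModel:
    """T-SVM: adapt by instance-transfer boosting; return the selected model.

    ``base_model`` supplies the frozen Day-1 standardisation; when absent a
    scaler is fitted on the source set (which is the Day-1 training set).
    """
    X_src = np.asarray(X_src, dtype=float)
    X_cal = np.asarray(X_cal, dtype=float)
    y_src = np.asarray(y_src)
    y_cal = np.asarray(y_cal)
    scaler = (
        base_model.scaler if base_model is not None
        else StandardScaler().fit(X_src)
    )
    Xs_std = scaler.transform(X_src)
    Xc_std = scaler.transform(X_cal)
    records, best = tradaboost_run(Xs_std, y_src, Xc_std, y_cal, config)
    rec = records[best]
    X_round = np.concatenate([X_src[rec.source_kept], X_cal[rec.calibration_kept]])
    y_round = np.concatenate([y_src[rec.source_kept], y_cal[rec.calibration_kept]])
    sup = rec.svc.support_
    return SvmModel(
        svc=rec.svc, scaler=scaler, support_X=X_round[sup].copy(),
        support_y=y_round[sup].copy(),
        classes=np.unique(np.concatenate([y_src, y_cal])),
        history=["base", f"tradaboost:round{best + 1}/{config.rounds}"],
    )


def ti_svm_adapt(
    X_src: np.ndarray,
    y_src: np.ndarray,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    config: AdaptationConfig = AdaptationConfig(),
    base_model: SvmModel | None = None,
) -> SvmModel:
    """TI-SVM: TrAdaBoost set construction, then incremental adaptation.

    The boosting stage rebuilds the training set around the target-day
    distribution; the selected round's model is then incrementally adapted
    with the *full* calibration set in batches of ``batch_size``.
    """
    t_model = tradaboost_adapt(
        X_src, y_src, X_cal, y_cal, config, base_model=base_model
    )
    model = incremental_adapt(t_model, X_cal, y_cal, config)
    model.history = t_model.history + [model.history[-1]]
    return model


def predict(
    model: SvmModel, X: np.ndarray, return_time: bool = False
):
    """Classify feature vectors; optionally report the wall-clock response time."""
    X_std = model.decision_input(X)
    t0 = time.perf_counter()
    labels = model.svc.predict(X_std)
    elapsed = time.perf_counter() - t0
    if return_time:
        return labels, elapsed
    return labels
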
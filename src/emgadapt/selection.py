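"""Feature selection: J3 separability scoring, greedy SFS, and PSO.

All three selectors operate on Day-1 feature matrices only; the chosen
dimension set is then reused unchanged on later days.  SFS works at the
granularity of the 14 named feature groups (each group = one feature across
all channels) and maximises the Fisher-type criterion

    J3 = trace(Sw^-1 Sm),

where Sw and Sm are the within-class and mixture scatter matrices.  PSO
searches individual dimensions, scoring candidate masks by the validation
accuracy of a linear SVM on a fixed stratified split of the Day-1 data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg as _linalg
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES, FeatureLayout


@dataclass(frozen=True)
class ScatterMatrices:
    """Within-class (Sw), between-class (Sb) and mixture (Sm) scatter.

    Classes are weighted uniformly (1/M each) regardless of size; the
    within-class expectation uses the per-class sample average.  By
    construction ``Sm = Sb + Sw``.
    """

    sw: np.ndarray
    sb: np.ndarray
    sm: np.ndarray
    class_means: np.ndarray  # (M, D)
    global_mean: np.ndarray  # (D,)
    classes: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def scatter_matrices(X: np.ndarray, y: np.ndarray) -> ScatterMatrices:
    """Compute class-uniform scatter matrices of a labelled feature matrix.

    A class with a single sample is allowed (it contributes zero
    within-class scatter).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    classes = np.unique(y)
    M = len(classes)
    if M < 2:
        raise ValueError("need at least 2 classes")
    if X.shape[0] < M:
        raise ValueError("need at least one sample per class")
    D = X.shape[1]
    u0 = X.mean(axis=0)
    sw = np.zeros((D, D))
    sb = np.zeros((D, D))
    means = np.empty((M, D))
    for i, cls in enumerate(classes):
        Xi = X[y == cls]
        ui = Xi.mean(axis=0)
        means[i] = ui
        dev = Xi - ui
        sw += (dev.T @ dev) / Xi.shape[0] / M
        dm = (ui - u0)[:, None]
        sb += (dm @ dm.T) / M
    return ScatterMatrices(
        sw=sw, sb=sb, sm=sb + sw, class_means=means, global_mean=u0,
        classes=classes,
    )


def j3_score(S: ScatterMatrices, ridge: float = 1e-8) -> float:
    """J3 = trace(Sw^-1 Sm), with a small ridge on Sw for conditioning.

    The ridge is ``ridge * trace(Sw)/D`` added to the diagonal; high-dim Sw
    estimated from limited samples is frequently near-singular.  J3 >= D
    always, with equality when the class means coincide.
    """
    D = S.sw.shape[0]
    eps = ridge * np.trace(S.sw) / D
    if eps <= 0:
        eps = ridge
    sw_reg = S.sw + eps * np.eye(D)
    try:
        sol = _linalg.solve(sw_reg, S.sm, assume_a="pos")
    except _linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "within-class scatter is singular even after ridge "
            "regularisation; reduce the feature dimension"
        ) from exc
    return float(np.trace(sol))


def j3_of(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8) -> float:
    """Convenience: J3 of a feature submatrix."""
    return j3_score(scatter_matrices(X, y), ridge)


@dataclass
class SelectionResult:
    """Outcome of a feature-selection run.

    ``dims`` are 0-based column indices into the full feature matrix, in
    selection order for SFS and ascending order for NFS/PSO.
    """

    method: str
    dims: np.ndarray
    groups: list[str] | None = None
    score: float | None = None
    trajectory: list[float] = field(default_factory=list)

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    def mask(self, total: int) -> np.ndarray:
        m = np.zeros(total, dtype=bool)
        m[self.dims] = True
        return m

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "dims": [int(d) for d in self.dims],
            "groups": self.groups,
            "score": self.score,
            "trajectory": [float(t) for t in self.trajectory],
        }


def nfs_select(n_dims: int) -> SelectionResult:
    """No feature selection: the identity mask over all dimensions."""
    return SelectionResult(method="NFS", dims=np.arange(n_dims))


def feature_groups(layout: FeatureLayout) -> dict[str, np.ndarray]:
    """The 14 named column-index blocks (one feature across all channels)."""
    return {name: layout.group_indices(name) for name in FEATURE_NAMES}


def sfs_select(
    X: np.ndarray,
    y: np.ndarray,
    groups: dict[str, np.ndarray] | None = None,
    layout: FeatureLayout | None = None,
    tol: float = 1e-9,
    ridge: float = 1e-8,
) -> SelectionResult:
    """Greedy forward selection over feature groups by J3.

    Set A starts with the single group of highest J3; each iteration moves
    over the group whose union with Set A gives the highest J3, stopping
    when no remaining group strictly increases J3 (tolerance ``tol``).
    Ties break deterministically by canonical group order (MAV first).
    """
    X = np.asarray(X, dtype=float)
    if groups is None:
        if layout is None:
            layout = FeatureLayout(X.shape[1] // 42)
        groups = feature_groups(layout)
    names = list(groups)
    selected: list[str] = []
    selected_idx = np.empty(0, dtype=int)
    trajectory: list[float] = []
    current = -np.inf
    for _ in range(len(names)):
        remaining = [g for g in names if g not in selected]
        if not remaining:
            break
        best_name, best_j3 = None, -np.inf
        for g in remaining:  # canonical order => deterministic tie-break
            idx = np.concatenate([selected_idx, groups[g]])
            j3 = j3_of(X[:, idx], y, ridge)
            if j3 > best_j3:
                best_name, best_j3 = g, j3
        if selected and best_j3 <= current + tol:
            break
        selected.append(best_name)
        selected_idx = np.concatenate([selected_idx, groups[best_name]])
        trajectory.append(best_j3)
        current = best_j3
    return SelectionResult(
        method="SFS", dims=selected_idx.astype(int), groups=selected,
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# PSO
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsoConfig:
    """Particle-swarm parameters.

    Positions are continuous in [0,1]^D; a dimension is included when its
    position exceeds ``threshold``.  ``w`` is the constriction (inertia)
    factor, ``c1``/``c2`` the cognitive/social learning factors.
    """

    n_particles: int = 80
    max_iterations: int = 50
    w: float = 0.7
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 0.5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not 0 < self.w < 1:
            raise ValueError("w must lie in (0, 1)")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


def make_day1_fitness(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    C: float = 1.0,
    val_fraction: float = 0.2,
) -> Callable[[np.ndarray], float]:
    """Mask-fitness closure: linear-SVM validation accuracy on a fixed split.

    The stratified 4/5 - 1/5 split of the Day-1 vectors is drawn once so
    that fitness values are comparable across particles and iterations;
    standardisation is fitted on the training split only.  An empty mask
    scores 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Xtr, Xva, ytr, yva = train_test_split(
        X, y, test_size=val_fraction, stratify=y, random_state=seed
    )
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return 0.0
        key = np.packbits(mask).tobytes()
        if key in cache:
            return cache[key]
        scaler = StandardScaler().fit(Xtr[:, mask])
        clf = SVC(kernel="linear", C=C)
        clf.fit(scaler.transform(Xtr[:, mask]), ytr)
        acc = float(clf.score(scaler.transform(Xva[:, mask]), yva))
        cache[key] = acc
        return acc

    return fitness


def pso_select(
    X: np.ndarray,
    y: np.ndarray,
    config: PsoConfig,
    fitness: Callable[[np.ndarray], float] | None = None,
) -> SelectionResult:
    """Particle-swarm search over feature-dimension masks.

    Each of ``n_particles`` particles holds a continuous position in
    [0,1]^D decoded to a mask by thresholding.  Velocities follow the
    canonical update ``v <- w v + c1 r1 (pbest-x) + c2 r2 (gbest-x)`` with
    fresh uniform r1, r2 per dimension per step, clamped to ``±v_max``;
    positions are clipped back into [0,1].  Returns the global-best mask.
    """
    X = np.asarray(X, dtype=float)
    D = X.shape[1]
    if D < 1:
        raise ValueError("need at least one feature dimension")
    if fitness is None:
        fitness = make_day1_fitness(X, y, seed=config.seed)
    rng = np.random.default_rng(config.seed)

    pos = rng.uniform(0.0, 1.0, size=(config.n_particles, D))
    vel = np.zeros((config.n_particles, D))
    pbest_pos = pos.copy()
    pbest_fit = np.array([fitness(p > config.threshold) for p in pos])
    g = int(np.argmax(pbest_fit))
    gbest_pos, gbest_fit = pbest_pos[g].copy(), float(pbest_fit[g])
    trajectory = [gbest_fit]

    for _ in range(config.max_iterations):
        r1 = rng.uniform(size=(config.n_particles, D))
        r2 = rng.uniform(size=(config.n_particles, D))
        vel = (
            config.w * vel
            + config.c1 * r1 * (pbest_pos - pos)
            + config.c2 * r2 * (gbest_pos[None, :] - pos)
        )
        np.clip(vel, -config.v_max, config.v_max, out=vel)
        pos = np.clip(pos + vel, 0.0, 1.0)
        for j in range(config.n_particles):
            fit = fitness(pos[j] > config.threshold)
            if fit > pbest_fit[j]:
                pbest_fit[j] = fit
                pbest_pos[j] = pos[j]
                if fit > gbest_fit:
                    gbest_fit = float(fit)
                    gbest_pos = pos[j].copy()
        trajectory.append(gbest_fit)

    dims = np.flatnonzero(gbest_pos > config.threshold)
    return SelectionResult(
        method="PSO", dims=dims, score=gbest_fit, trajectory=trajectory
    )


def validate_selection(
    dims: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    C: float = 1.0,
) -> float:
    """Validation accuracy of a dimension set on Day-1 data.

    Stratified 4/5 train - 1/5 validation split; linear SVM on standardised
    features.  Deterministic for a given seed.
    """
    dims = np.asarray(dims, dtype=int)
    if dims.size == 0:
        raise ValueError("empty dimension set")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("validation split needs at least two classes")
    fitness = make_day1_fitness(X, y, seed=seed, C=C)
    mask = np.zeros(X.shape[1], dtype=bool)
    mask[dims] = True
    return fitness(mask)
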
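"""Semi-supervised max-margin polytope clustering of cases against controls.

The model fits K linear max-margin classifiers that each separate one cluster
of cases from the full control group; the classifier hyperplanes form the
faces of a convex polytope around the controls, and each case belongs to the
face that separates it best. Fitting alternates between (a) training the K
hinge-loss classifiers given the current hard case assignments (controls are
labelled -1 for every classifier) and (b) reassigning each case to the
classifier giving it the largest signed score. Clusters therefore capture the
directions in marker space along which subsets of cases deviate from
controls, not population-wide variance.

Model selection and stability use a hold-out scheme: the clustering is
repeated on stratified subsamples (default 100 draws of 80% of the cohort
with case/control proportions preserved), stability per K is the mean
Adjusted Rand Index over all pairs of subsample solutions restricted to their
shared cases, and a consensus partition is extracted from the case-by-case
co-clustering frequency matrix by spectral clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.cluster import SpectralClustering
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .preprocess import residualise_covariates

__all__ = [
    "HydraConfig",
    "Polytope",
    "AssignmentMatrix",
    "ConsensusResult",
    "fit_polytope",
    "adjusted_rand_index",
    "stability_analysis",
    "consensus_labels",
]


@dataclass
class HydraConfig:
    k_min: int = 2
    k_max: int = 5
    n_subsamples: int = 100
    subsample_fraction: float = 0.8
    margin_penalty: float = 1.0
    n_restarts: int = 10
    max_iter: int = 50
    tol: int = 0  # assignment changes tolerated at convergence
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if not 0.0 < self.subsample_fraction < 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if self.margin_penalty <= 0:
            raise ValueError("margin_penalty must be positive")
        if self.n_restarts < 1 or self.max_iter < 1 or self.n_subsamples < 1:
            raise ValueError("counts must be positive")


@dataclass
class Polytope:
    """K hyperplanes (w_j, b_j) over the marker space."""

    weights: np.ndarray  # (K, d)
    offsets: np.ndarray  # (K,)

    @property
    def k(self) -> int:
        return len(self.offsets)

    def scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights.T + self.offsets

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "offsets": self.offsets.tolist()}


@dataclass
class AssignmentMatrix:
    """Case-to-cluster weights; rows sum to one (hard one-hot here)."""

    S: np.ndarray  # (n_cases, K)

    def __post_init__(self) -> None:
        if np.any(self.S < 0) or not np.allclose(self.S.sum(axis=1), 1.0):
            raise ValueError("assignment rows must be nonnegative and sum to 1")

    @property
    def hard(self) -> np.ndarray:
        """Hard labels in {1..K} (argmax per row, ties to lower index)."""
        return self.S.argmax(axis=1) + 1


@dataclass
class PerKStability:
    mean_ari: float
    sd_ari: float
    consensus: np.ndarray  # labels in {1..K} over all cases


@dataclass
class ConsensusResult:
    per_k: dict[int, PerKStability]
    case_ids: list = field(default_factory=list)

    @property
    def selected_k(self) -> int:
        return max(self.per_k, key=lambda k: self.per_k[k].mean_ari)

    def stability_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": list(self.per_k),
                "mean_ARI": [r.mean_ari for r in self.per_k.values()],
                "sd_ARI": [r.sd_ari for r in self.per_k.values()],
            }
        )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand index via the closed-form contingency formula.

    Returns 1.0 for the degenerate cases where the expected index equals the
    maximum index (e.g. both partitions trivial and identical).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)
    sum_ij = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _fit_margin_classifier(X, y, C):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LinearSVC(
            C=C, loss="hinge", dual=True, tol=1e-5, max_iter=20000, random_state=0
        ).fit(X, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def _objective(X_controls, X_cases, assign, W, b, C, fitted) -> float:
    """0.5 (||w_j||^2 + b_j^2) + C * weighted hinge losses, summed over the
    fitted classifiers (the intercept is regularised by the solver, so it is
    included here for consistency)."""
    obj = 0.0
    for j in np.flatnonzero(fitted):
        margin_controls = -(X_controls @ W[j] + b[j])
        members = assign == j
        margin_cases = X_cases[members] @ W[j] + b[j]
        hinge = np.maximum(0.0, 1.0 - margin_controls).sum()
        hinge += np.maximum(0.0, 1.0 - margin_cases).sum()
        obj += 0.5 * (W[j] @ W[j] + b[j] ** 2) + C * hinge
    return float(obj)


def fit_polytope(
    X: np.ndarray,
    case_mask,
    K: int,
    config: HydraConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Polytope, AssignmentMatrix, list[float]]:
    """Alternating fit of the K-face max-margin polytope.

    Returns the best-of-``n_restarts`` polytope, the case assignment matrix
    and the objective trace of the winning restart (non-increasing across
    iterations up to solver tolerance).
    """
    config = config or HydraConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    X_cases = X[case_mask]
    X_controls = X[~case_mask]
    n_cases = len(X_cases)
    if K > n_cases:
        raise ValueError(f"K={K} exceeds the number of cases ({n_cases})")
    C = config.margin_penalty
    d = X.shape[1]

    best = None
    for _ in range(config.n_restarts):
        assign = rng.integers(0, K, size=n_cases)
        # guarantee non-empty clusters at initialisation
        for j in range(K):
            if not np.any(assign == j):
                assign[rng.integers(n_cases)] = j
        W = np.zeros((K, d))
        b = np.zeros(K)
        fitted = np.zeros(K, dtype=bool)
        trace: list[float] = []
        for _it in range(config.max_iter):
            for j in range(K):
                members = np.flatnonzero(assign == j)
                if len(members) == 0:
                    continue  # keep the previous face for an emptied cluster
                Xj = np.vstack([X_controls, X_cases[members]])
                yj = np.concatenate(
                    [-np.ones(len(X_controls)), np.ones(len(members))]
                )
                W[j], b[j] = _fit_margin_classifier(Xj, yj, C)
                fitted[j] = True
            trace.append(_objective(X_controls, X_cases, assign, W, b, C, fitted))
            scores = X_cases @ W[fitted].T + b[fitted]
            new = np.flatnonzero(fitted)[scores.argmax(axis=1)]
            if np.sum(new != assign) <= config.tol:
                assign = new
                break
            assign = new
        final = _objective(X_controls, X_cases, assign, W, b, C, fitted)
        if best is None or final < best[0]:
            best = (final, W.copy(), b.copy(), assign.copy(), trace)

    _, W, b, assign, trace = best
    S = np.zeros((n_cases, K))
    S[np.arange(n_cases), assign] = 1.0
    return Polytope(W, b), AssignmentMatrix(S), trace


def consensus_labels(
    subsample_solutions: list[tuple[np.ndarray, np.ndarray]],
    K: int,
    n_cases: int,
    seed: int = 0,
) -> np.ndarray:
    """Consensus partition from subsample solutions.

    Each solution is ``(case_indices, labels)`` over a subsample of the
    cases. The case-by-case co-clustering frequency matrix (fraction of
    shared subsamples in which two cases land in the same cluster) is
    partitioned into K groups by spectral clustering; labels are returned in
    {1..K} with cluster 1 the largest group.
    """
    if K == 1:
        return np.ones(n_cases, dtype=int)
    co = np.zeros((n_cases, n_cases))
    shared = np.zeros((n_cases, n_cases))
    for idx, lab in subsample_solutions:
        idx = np.asarray(idx)
        lab = np.asarray(lab)
        present = np.zeros(n_cases, dtype=bool)
        present[idx] = True
        shared += np.outer(present, present)
        same = lab[:, None] == lab[None, :]
        co[np.ix_(idx, idx)] += same
    if np.any(np.diag(shared) == 0):
        missing = np.flatnonzero(np.diag(shared) == 0)
        raise ValueError(f"cases never subsampled cannot be labelled: {missing}")
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(shared > 0, co / np.maximum(shared, 1), 0.0)
    np.fill_diagonal(freq, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        sc = SpectralClustering(
            n_clusters=K, affinity="precomputed", random_state=seed,
            assign_labels="kmeans", n_init=10,
        )
        raw = sc.fit_predict(freq)
    # canonical order: cluster 1 = largest group, ties by first occurrence
    sizes = pd.Series(raw).value_counts()
    order = {old: new + 1 for new, old in enumerate(sizes.index)}
    return np.array([order[r] for r in raw], dtype=int)


def _relabel_by_marker_level(labels: np.ndarray, X_cases: np.ndarray) -> np.ndarray:
    """Order clusters by mean marker level, cluster 1 lowest."""
    ks = np.unique(labels)
    means = {k: X_cases[labels == k].mean() for k in ks}
    order = {k: rank + 1 for rank, k in enumerate(sorted(ks, key=lambda k: means[k]))}
    return np.array([order[l] for l in labels], dtype=int)


def stability_analysis(
    X: np.ndarray,
    case_mask,
    covariates: pd.DataFrame | None = None,
    config: HydraConfig | None = None,
    case_ids: list | None = None,
    compute_consensus: bool = True,
) -> ConsensusResult:
    """Hold-out stability analysis over K = k_min..k_max.

    For each K, the polytope is refit on ``n_subsamples`` stratified
    subsamples (``subsample_fraction`` of cases and of controls each); the
    stability of the solution is the mean ARI over all pairs of subsample
    solutions restricted to their shared cases. Consensus labels come from
    spectral clustering of the co-clustering frequency matrix and are
    renumbered so cluster 1 has the lower mean marker level. If covariates
    are supplied, they are residualised (controls-only fit) before
    clustering.
    """
    config = config or HydraConfig()
    X = np.asarray(X, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    if covariates is not None:
        Xdf = pd.DataFrame(X)
        X = residualise_covariates(Xdf, covariates.reset_index(drop=True),
                                   ~case_mask).to_numpy()
    case_idx = np.flatnonzero(case_mask)
    control_idx = np.flatnonzero(~case_mask)
    n_cases = len(case_idx)
    n_sub_cases = int(round(config.subsample_fraction * n_cases))
    n_sub_controls = int(round(config.subsample_fraction * len(control_idx)))
    if n_sub_cases < config.k_max:
        raise ValueError("subsamples contain fewer cases than k_max clusters")

    root = np.random.SeedSequence(config.seed)
    per_k: dict[int, PerKStability] = {}
    for K in range(config.k_min, config.k_max + 1):
        k_seed = np.random.SeedSequence(entropy=root.entropy, spawn_key=(K,))
        solutions: list[tuple[np.ndarray, np.ndarray]] = []
        for s in range(config.n_subsamples):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy, spawn_key=(K, s))
            )
            sub_cases = rng.choice(n_cases, size=n_sub_cases, replace=False)
            sub_controls = rng.choice(
                len(control_idx), size=n_sub_controls, replace=False
            )
            rows = np.concatenate(
                [case_idx[sub_cases], control_idx[sub_controls]]
            )
            sub_mask = np.concatenate(
                [np.ones(n_sub_cases, bool), np.zeros(n_sub_controls, bool)]
            )
            _, assignment, _ = fit_polytope(X[rows], sub_mask, K, config, rng)
            order = np.argsort(sub_cases)
            solutions.append((sub_cases[order], assignment.hard[order]))

        aris = _pairwise_subsample_aris(solutions, n_cases)
        if compute_consensus:
            consensus = consensus_labels(
                solutions, K, n_cases,
                seed=int(np.random.default_rng(k_seed).integers(2**31)),
            )
            consensus = _relabel_by_marker_level(consensus, X[case_idx])
        else:
            consensus = np.zeros(n_cases, dtype=int)
        per_k[K] = PerKStability(
            mean_ari=float(np.mean(aris)),
            sd_ari=float(np.std(aris, ddof=1)) if len(aris) > 1 else 0.0,
            consensus=consensus,
        )
    return ConsensusResult(per_k=per_k, case_ids=list(case_ids or range(n_cases)))


def _pairwise_subsample_aris(solutions, n_cases) -> np.ndarray:
    """ARI between every pair of subsample solutions on their shared cases."""
    full = []
    masks = []
    for idx, lab in solutions:
        arr = np.full(n_cases, -1)
        arr[idx] = lab
        full.append(arr)
        masks.append(arr >= 0)
    aris = []
    for i in range(len(full)):
        for j in range(i + 1, len(full)):
            both = masks[i] & masks[j]
            if both.sum() < 2:
                continue
            aris.append(adjusted_rand_index(full[i][both], full[j][both]))
    return np.asarray(aris)
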
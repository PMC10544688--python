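"""Pairwise and generalization LDA decoding with permutation nulls.

Within each time bin, trials are split 1000 times into balanced train/test
halves; each split is reduced to the top 40 SVD components of the training
data and classified with a shared-covariance linear discriminant.  A null
distribution built identically on label-shuffled data provides chance-level
performance, and significance is tiered by the most stringent of the
{95, 97.5, 99}% percentile confidence intervals that do not overlap
between the real and null accuracy distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import SessionBundle

TIER_LEVELS = ((0.99, "***"), (0.975, "**"), (0.95, "*"))


# ------------------------------------------------------------------ splits
def split_balanced(labels: np.ndarray, rng: np.random.Generator):
    """One balanced train/test partition: each class contributes exactly
    half of its trials (floored; the odd remainder is dropped) to each
    side.  Run and session membership are ignored."""
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 trials")
        half = idx.size // 2
        perm = rng.permutation(idx)
        train_idx.append(perm[:half])
        test_idx.append(perm[half:2 * half])
    return np.concatenate(train_idx), np.concatenate(test_idx)


# --------------------------------------------------------------------- SVD
@dataclass
class SvdProjection:
    """Linear map onto the top-k variance directions of the training data."""

    mean: np.ndarray
    components: np.ndarray   # (k_eff, n_features)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean) @ self.components.T


def fit_svd_projection(train_matrix: np.ndarray, k: int) -> SvdProjection:
    """Fit an SVD projection (train-mean centered) keeping the top
    ``min(k, rank)`` left-singular directions."""
    X = np.asarray(train_matrix, dtype=float)
    if X.size == 0:
        raise ValueError("empty training matrix")
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    k_eff = max(min(k, rank), 1)
    return SvdProjection(mean=mean, components=vt[:k_eff])


# --------------------------------------------------------------------- LDA
def lda_accuracy(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    shrinkage: float = 1e-6,
) -> float:
    """Two-class linear discriminant accuracy on held-out data.

    Pooled within-class covariance with shrinkage toward a scaled identity
    (raised automatically by decades if the solve is singular).  The
    discriminant score is ``w.(x - (mu_a+mu_b)/2)`` with
    ``w = S^-1 (mu_a - mu_b)``; a score of exactly zero is assigned to the
    first class in sorted label order (deterministic tie-break).
    """
    train_X = np.asarray(train_X, float)
    test_X = np.asarray(test_X, float)
    classes = np.unique(train_y)
    if len(classes) != 2:
        raise ValueError("lda_accuracy is strictly two-class")
    a, b = classes
    Xa, Xb = train_X[train_y == a], train_X[train_y == b]
    mu_a, mu_b = Xa.mean(axis=0), Xb.mean(axis=0)
    n_a, n_b = len(Xa), len(Xb)
    p = train_X.shape[1]
    dof = max(n_a + n_b - 2, 1)
    S = ((Xa - mu_a).T @ (Xa - mu_a) + (Xb - mu_b).T @ (Xb - mu_b)) / dof
    scale = np.trace(S) / p if np.trace(S) > 0 else 1.0
    lam = shrinkage
    while True:
        try:
            w = np.linalg.solve(S + lam * scale * np.eye(p), mu_a - mu_b)
            break
        except np.linalg.LinAlgError:
            lam = max(lam * 10.0, 1e-8)
            if lam > 1.0:
                w = np.linalg.pinv(S) @ (mu_a - mu_b)
                break
    scores = (test_X - (mu_a + mu_b) / 2.0) @ w
    pred = np.where(scores >= 0, a, b)
    return float(np.mean(pred == np.asarray(test_y)))


# ----------------------------------------------------------------- results
@dataclass
class DecodeResult:
    """Accuracy distribution over resampling splits with its matched null."""

    accuracies: np.ndarray
    null_accuracies: np.ndarray
    class_a: str = ""
    class_b: str = ""
    bin_center: float = np.nan

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        q = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.accuracies, [q, 1.0 - q])
        return float(lo), float(hi)

    @property
    def tier(self) -> str:
        return significance_tier(self.accuracies, self.null_accuracies)


def significance_tier(result: np.ndarray, null: np.ndarray) -> str:
    """Most stringent of the {99, 97.5, 95}% percentile-CI levels at which
    the result and null distributions do not overlap: '***', '**', '*',
    else 'ns'."""
    result = np.asarray(result, float)
    null = np.asarray(null, float)
    if result.size == 0 or null.size == 0:
        raise ValueError("both distributions must be non-empty")
    for level, label in TIER_LEVELS:
        q = (1.0 - level) / 2.0
        r_lo, r_hi = np.quantile(result, [q, 1.0 - q])
        n_lo, n_hi = np.quantile(null, [q, 1.0 - q])
        if r_lo > n_hi or r_hi < n_lo:
            return label
    return "ns"


# ------------------------------------------------------------- decode core
def _decode_bin(
    X: np.ndarray,
    y: np.ndarray,
    n_splits: int,
    n_dims: int,
    rng: np.random.Generator,
    shuffle: bool,
) -> np.ndarray:
    """Accuracies over ``n_splits`` split->SVD->LDA iterations on one bin.

    With ``shuffle=True`` the labels are permuted once per iteration
    before splitting (the permutation-null convention)."""
    accs = np.empty(n_splits)
    for i in range(n_splits):
        yi = rng.permutation(y) if shuffle else y
        tr, te = split_balanced(yi, rng)
        proj = fit_svd_projection(X[tr], n_dims)
        accs[i] = lda_accuracy(
            proj.transform(X[tr]), yi[tr], proj.transform(X[te]), yi[te]
        )
    return accs


def decode_pair(
    X: np.ndarray,
    y: np.ndarray,
    n_splits: int = 1000,
    n_dims: int = 40,
    seed: int | np.random.Generator = 0,
) -> DecodeResult:
    """Decode two classes from a (trials, channels) matrix with matched
    label-shuffled null."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accs = _decode_bin(X, y, n_splits, n_dims, rng, shuffle=False)
    nulls = _decode_bin(X, y, n_splits, n_dims, rng, shuffle=True)
    classes = np.unique(y)
    return DecodeResult(accuracies=accs, null_accuracies=nulls,
                        class_a=str(classes[0]), class_b=str(classes[1]))


def run_pairwise(
    bundle: SessionBundle,
    pairs=None,
    window: tuple[float, float] | None = None,
    n_splits: int = 1000,
    n_dims: int = 40,
    seed: int = 0,
) -> list[DecodeResult]:
    """Pairwise condition decoding for every time bin of the bundle.

    The bundle should already be normalized, catch-free and rebinned to
    the decoding bin width (0.5 s or 0.1 s).  ``pairs`` defaults to all
    condition pairs; ``window`` restricts the bins analyzed.
    """
    conds = bundle.conditions
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1:]]
    for a, b in pairs:
        for c in (a, b):
            if c not in conds:
                raise KeyError(f"unknown condition code: {c!r}")
    sl = bundle.bin_slice(window) if window is not None else slice(0, bundle.n_bins)
    centers = bundle.bin_centers[sl]
    ss = np.random.SeedSequence(seed)
    results = []
    for (a, b), child in zip(pairs, ss.spawn(len(pairs))):
        sub = bundle.select_conditions([a, b])
        y = sub.labels
        rng = np.random.default_rng(child)
        for j, center in zip(range(sl.start, sl.stop), centers):
            X = sub.rates[:, :, j].T          # (trials, channels)
            res = decode_pair(X, y, n_splits=n_splits, n_dims=n_dims, seed=rng)
            res.class_a, res.class_b, res.bin_center = a, b, float(center)
            results.append(res)
    return results


def run_generalization(
    bundle: SessionBundle,
    train_classes: tuple[list, list],
    test_classes: tuple[list, list],
    window: tuple[float, float] | None = None,
    n_splits: int = 1000,
    n_dims: int = 40,
    seed: int = 0,
) -> list[DecodeResult]:
    """Cross-condition generalization decoding per time bin.

    The two classes are defined by condition lists, separately for the
    training set and the test set — e.g. train arm-vs-finger on observed
    third-person touches (``(["TPa"], ["TPf"])``) and test on seen
    physical touches (``(["FPa"], ["FPf"])``).  When the train and test
    selectors coincide, held-out halves are used (matching the pairwise
    decoder); when they are disjoint, each iteration trains on a balanced
    random half of the training trials and tests on all test trials.
    """
    (tr_a, tr_b), (te_a, te_b) = train_classes, test_classes
    for sel in (tr_a, tr_b, te_a, te_b):
        if not sel:
            raise ValueError("empty condition selector")
    lab = bundle.labels
    idx_tr_a = np.flatnonzero(np.isin(lab, tr_a))
    idx_tr_b = np.flatnonzero(np.isin(lab, tr_b))
    idx_te_a = np.flatnonzero(np.isin(lab, te_a))
    idx_te_b = np.flatnonzero(np.isin(lab, te_b))
    same = (set(idx_tr_a) == set(idx_te_a)) and (set(idx_tr_b) == set(idx_te_b))
    overlap = (set(idx_tr_a) | set(idx_tr_b)) & (set(idx_te_a) | set(idx_te_b))
    if not same and overlap:
        raise ValueError("train and test selectors must be identical or disjoint")

    sl = bundle.bin_slice(window) if window is not None else slice(0, bundle.n_bins)
    centers = bundle.bin_centers[sl]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    results = []
    for j, center in zip(range(sl.start, sl.stop), centers):
        Xall = bundle.rates[:, :, j].T
        accs = np.empty(n_splits)
        nulls = np.empty(n_splits)
        for shuffle, out in ((False, accs), (True, nulls)):
            for i in range(n_splits):
                ia, ib = idx_tr_a, idx_tr_b
                ja, jb = idx_te_a, idx_te_b
                if shuffle:
                    pool_tr = np.concatenate([ia, ib])
                    perm = rng.permutation(pool_tr)
                    ia, ib = perm[: len(ia)], perm[len(ia):]
                    if not same:
                        pool_te = np.concatenate([ja, jb])
                        perm = rng.permutation(pool_te)
                        ja, jb = perm[: len(ja)], perm[len(ja):]
                half = min(len(ia), len(ib)) // 2
                pa, pb = rng.permutation(ia), rng.permutation(ib)
                tr_idx = np.concatenate([pa[:half], pb[:half]])
                tr_y = np.array([0] * half + [1] * half)
                if same:
                    te_idx = np.concatenate([pa[half:2 * half], pb[half:2 * half]])
                    te_y = np.array([0] * half + [1] * half)
                else:
                    if shuffle:
                        te_idx = np.concatenate([ja, jb])
                        te_y = np.array([0] * len(ja) + [1] * len(jb))
                    else:
                        te_idx = np.concatenate([idx_te_a, idx_te_b])
                        te_y = np.array([0] * len(idx_te_a) + [1] * len(idx_te_b))
                proj = fit_svd_projection(Xall[tr_idx], n_dims)
                out[i] = lda_accuracy(
                    proj.transform(Xall[tr_idx]), tr_y,
                    proj.transform(Xall[te_idx]), te_y,
                )
        res = DecodeResult(
            accuracies=accs, null_accuracies=nulls,
            class_a="+".join(map(str, te_a)), class_b="+".join(map(str, te_b)),
            bin_center=float(center),
        )
        results.append(res)
    return results


def results_to_frame(results: list[DecodeResult]) -> pd.DataFrame:
    """Tabulate decode results: pair, bin, mean accuracy, 95% CI, null mean
    and significance tier."""
    rows = []
    for r in results:
        lo, hi = r.ci(0.95)
        rows.append({
            "class_a": r.class_a, "class_b": r.class_b,
            "bin_center": r.bin_center,
            "mean_acc": r.mean_accuracy, "ci_lo": lo, "ci_hi": hi,
            "null_mean": float(np.mean(r.null_accuracies)),
            "tier": r.tier,
        })
    return pd.DataFrame(rows)
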
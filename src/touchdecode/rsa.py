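"""Crossnobis RDMs with multivariate noise normalization, and metric MDS.

The dissimilarity between two conditions is the cross-validated squared
Mahalanobis ("crossnobis") distance: fold-wise pattern differences are
whitened by a shrinkage-regularized noise covariance and multiplied across
independent folds, giving an unbiased estimator with a meaningful zero
(indistinguishable patterns average to distance 0, and estimates may go
slightly negative).  Folds follow the 10-trial runs (7 per condition).
RDM time courses are compared by Pearson correlation of their lower
triangles, and visualized with metric-stress multidimensional scaling
aligned across time bins by orthogonal Procrustes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from sklearn.manifold import MDS

from .bundle import SessionBundle


def runwise_folds(bundle: SessionBundle) -> np.ndarray:
    """Cross-validation fold per trial: the rank of its run within its
    condition (runs are condition-homogeneous, so fold m pools the m-th
    run of every condition)."""
    labels = bundle.labels
    runs = bundle.run_id
    folds = np.empty(len(labels), dtype=int)
    for cond in np.unique(labels):
        m = labels == cond
        uniq = np.unique(runs[m])
        rank = {r: i for i, r in enumerate(uniq)}
        folds[m] = [rank[r] for r in runs[m]]
    return folds


# -------------------------------------------------------------- noise model
@dataclass
class NoiseModel:
    """Shrinkage-regularized channel noise covariance and its inverse."""

    covariance: np.ndarray
    shrinkage: float
    inverse: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.covariance.shape[0]


def shrink_covariance(residuals: np.ndarray, floor: float = 0.01) -> tuple[np.ndarray, float]:
    """Covariance of residual rows shrunk toward its diagonal.

    The shrinkage intensity follows the analytic optimal rule (ratio of
    the summed sampling variances of the off-diagonal entries to their
    summed squares), clipped to ``[floor, 1]``.  Guarantees an invertible
    estimate even with fewer rows than channels.
    """
    X = np.asarray(residuals, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 residual rows")
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / (n - 1)
    # sampling variance of each entry of S
    W = Xc[:, :, None] * Xc[:, None, :]           # (n, p, p)
    var_S = W.var(axis=0, ddof=1) * n / (n - 1) ** 2
    off = ~np.eye(p, dtype=bool)
    denom = np.sum(S[off] ** 2)
    lam = float(np.sum(var_S[off]) / denom) if denom > 0 else 1.0
    lam = float(np.clip(lam, floor, 1.0))
    S_shrunk = (1.0 - lam) * S + lam * np.diag(np.diag(S))
    return S_shrunk, lam


def estimate_noise(
    bundle: SessionBundle,
    bin_index: int,
    folds: np.ndarray | None = None,
    shrinkage: float | None = None,
    floor: float = 0.01,
) -> NoiseModel:
    """Noise covariance at one time bin from within-condition residuals.

    Residuals are each trial minus its condition x fold mean (fold-wise,
    so the means entering the crossnobis distances are not reused),
    pooled over conditions and folds.  ``shrinkage`` fixes the intensity;
    by default it is chosen analytically with a floor.  ``shrinkage=1``
    yields an exactly diagonal model.
    """
    X = bundle.rates[:, :, bin_index].T              # (trials, channels)
    labels = bundle.labels
    folds = runwise_folds(bundle) if folds is None else np.asarray(folds)
    resid = np.empty_like(X)
    for cond in np.unique(labels):
        for f in np.unique(folds):
            m = (labels == cond) & (folds == f)
            if m.sum() < 2:
                raise ValueError("need >= 2 trials per condition per fold")
            resid[m] = X[m] - X[m].mean(axis=0)
    if shrinkage is None:
        cov, lam = shrink_covariance(resid, floor=floor)
    else:
        lam = float(np.clip(shrinkage, 0.0, 1.0))
        n = resid.shape[0]
        Xc = resid - resid.mean(axis=0)
        S = (Xc.T @ Xc) / (n - 1)
        cov = (1.0 - lam) * S + lam * np.diag(np.diag(S))
    return NoiseModel(covariance=cov, shrinkage=lam, inverse=np.linalg.inv(cov))


# ----------------------------------------------------------------- crossnobis
def crossnobis_rdm(
    bundle: SessionBundle,
    bin_index: int,
    noise: NoiseModel | None = None,
    folds: np.ndarray | None = None,
) -> np.ndarray:
    """Cross-validated Mahalanobis RDM at one time bin.

    ``d(a,b)`` is the average over ordered fold pairs (m != n) of
    ``(xbar_a(m) - xbar_b(m))^T Sigma^-1 (xbar_a(n) - xbar_b(n)) / P``
    with P the channel count (so values are comparable across population
    sizes).  The matrix is symmetric with NaN on the (meaningless)
    diagonal; off-diagonal entries may be negative.
    """
    X = bundle.rates[:, :, bin_index].T
    labels = bundle.labels
    folds = runwise_folds(bundle) if folds is None else np.asarray(folds)
    if noise is None:
        noise = estimate_noise(bundle, bin_index, folds=folds)
    conds = bundle.conditions
    fold_ids = np.unique(folds)
    M = len(fold_ids)
    if M < 2:
        raise ValueError("crossnobis needs at least 2 folds")
    P = X.shape[1]
    means = np.empty((len(conds), M, P))
    for i, cond in enumerate(conds):
        for m, f in enumerate(fold_ids):
            mask = (labels == cond) & (folds == f)
            if not mask.any():
                raise ValueError(f"condition {cond!r} missing from fold {f!r}")
            means[i, m] = X[mask].mean(axis=0)
    rdm = np.full((len(conds), len(conds)), np.nan)
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            delta = means[i] - means[j]               # (M, P)
            G = delta @ noise.inverse @ delta.T        # (M, M)
            d = (G.sum() - np.trace(G)) / (M * (M - 1)) / P
            rdm[i, j] = rdm[j, i] = d
    return rdm


def crossnobis_rdm_series(
    bundle: SessionBundle,
    noise: NoiseModel | None = None,
    folds: np.ndarray | None = None,
) -> "RDMSeries":
    """Per-time-bin crossnobis RDMs over run-wise folds.

    The bundle should already be rebinned to the RDM bin width (0.5 s).
    The noise model is estimated per bin unless one is supplied.
    """
    rdms = []
    for j in range(bundle.n_bins):
        nm = noise if noise is not None else estimate_noise(bundle, j, folds=folds)
        rdms.append(crossnobis_rdm(bundle, j, noise=nm, folds=folds))
    return RDMSeries(
        rdms=np.array(rdms),
        bin_centers=bundle.bin_centers.copy(),
        conditions=list(bundle.conditions),
    )


@dataclass
class RDMSeries:
    """Per-time-bin condition dissimilarity matrices (diagonal undefined)."""

    rdms: np.ndarray          # (n_bins, C, C), NaN diagonal
    bin_centers: np.ndarray
    conditions: list

    def at(self, time: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.bin_centers - time)))
        return self.rdms[j]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        C = len(self.conditions)
        for t, rdm in zip(self.bin_centers, self.rdms):
            for i in range(C):
                for j in range(i + 1, C):
                    rows.append({
                        "bin_center": float(t),
                        "cond_a": self.conditions[i],
                        "cond_b": self.conditions[j],
                        "distance": float(rdm[i, j]),
                    })
        return pd.DataFrame(rows)


# ------------------------------------------------------------- correlations
def rdm_correlation(
    rdm_a: np.ndarray,
    rdm_b: np.ndarray,
    n_comparisons: int = 1,
) -> tuple[float, float]:
    """Pearson correlation of two RDMs over the lower off-diagonal
    triangle, with Bonferroni-multiplied p (capped at 1).

    Returns ``(nan, nan)`` when either triangle is constant (undefined r).
    """
    a = np.asarray(rdm_a, float)
    b = np.asarray(rdm_b, float)
    if a.shape != b.shape:
        raise ValueError("RDMs must share the condition set and ordering")
    iu = np.tril_indices(a.shape[0], k=-1)
    va, vb = a[iu], b[iu]
    if np.std(va) == 0 or np.std(vb) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(va, vb)
    return float(r), float(min(p * n_comparisons, 1.0))


# --------------------------------------------------------------------- MDS
@dataclass
class MDSEmbedding:
    """2-D metric-stress embedding of one RDM."""

    coords: np.ndarray          # (C, dims)
    stress: float               # normalized stress-1
    residuals: np.ndarray       # (C, C) |embedded - target| per pair
    conditions: list


def mds_embed(
    rdm: np.ndarray,
    dims: int = 2,
    seed: int = 0,
    conditions: list | None = None,
    align_to: np.ndarray | None = None,
    n_init: int = 8,
) -> MDSEmbedding:
    """Metric-stress MDS of one RDM (negative crossnobis values clipped to
    zero, diagonal zeroed).

    ``align_to`` applies an orthogonal Procrustes rotation toward a
    previous embedding so successive time bins share axes.  The reported
    stress is normalized (stress-1); residuals are absolute per-pair
    distortions underlying "rubber band" visualizations.
    """
    D = np.asarray(rdm, float).copy()
    if D.shape[0] != D.shape[1]:
        raise ValueError("RDM must be square")
    if not np.allclose(np.nan_to_num(D), np.nan_to_num(D.T)):
        raise ValueError("RDM must be symmetric")
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    if not D.any():
        # fully degenerate: all conditions indistinguishable
        coords = np.zeros((D.shape[0], dims))
        return MDSEmbedding(
            coords=coords, stress=0.0, residuals=np.zeros_like(D),
            conditions=list(conditions) if conditions is not None else
            list(range(D.shape[0])),
        )
    mds = MDS(
        n_components=dims, metric_mds=True, metric="precomputed",
        n_init=n_init, init="random", random_state=seed,
        normalized_stress=False,
    )
    coords = mds.fit_transform(D)
    denom = np.sum(D**2) / 2.0
    stress1 = float(np.sqrt(mds.stress_ / denom)) if denom > 0 else 0.0
    coords = coords - coords.mean(axis=0)
    if align_to is not None:
        ref = np.asarray(align_to, float) - np.asarray(align_to, float).mean(axis=0)
        R, _ = orthogonal_procrustes(coords, ref)
        coords = coords @ R
    emb_d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    residuals = np.abs(emb_d - D)
    np.fill_diagonal(residuals, 0.0)
    return MDSEmbedding(
        coords=coords, stress=stress1, residuals=residuals,
        conditions=list(conditions) if conditions is not None else
        list(range(D.shape[0])),
    )


def mds_series(series: RDMSeries, dims: int = 2, seed: int = 0) -> list[MDSEmbedding]:
    """Embed every bin of an RDM series, Procrustes-aligned bin to bin."""
    out: list[MDSEmbedding] = []
    prev = None
    for k in range(series.rdms.shape[0]):
        emb = mds_embed(
            series.rdms[k], dims=dims, seed=seed,
            conditions=series.conditions, align_to=prev,
        )
        out.append(emb)
        prev = emb.coords
    return out
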
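"""Spatial gradients of time-series features and group inference on maps.

Regions are treated as observations and normalized features as variables;
PCA region scores are the spatial gradient maps. Individuals are aligned
to a control-defined reference by orthogonal Procrustes (rotation and
reflection only), group differences are localized with covariate-adjusted
Freedman-Lane permutation tests under per-hemisphere max-|t| family-wise
error control, aggregated over seven functional communities with
Bonferroni correction, and attributed back to the contributing features
by spatial correlation.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from sklearn.decomposition import PCA

from .io import Parcellation


@dataclasses.dataclass
class GradientSet:
    """regions x k spatial component maps with loadings and explained variance."""

    components: np.ndarray          # regions x k region scores
    explained_variance: np.ndarray  # k fractions, non-increasing
    loadings: np.ndarray            # features x k
    is_reference: bool = False

    @property
    def k(self) -> int:
        return self.components.shape[1]

    @property
    def n_regions(self) -> int:
        return self.components.shape[0]


def _fix_signs(components: np.ndarray, loadings: np.ndarray,
               reference_axis: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so it correlates nonnegatively with a fixed axis.

    The default axis is the region index (a deterministic stand-in when no
    anterior-posterior centroid coordinate is supplied).
    """
    n = components.shape[0]
    axis = np.arange(n, dtype=float) if reference_axis is None else np.asarray(
        reference_axis, dtype=float)
    axis = axis - axis.mean()
    comps = components.copy()
    loads = loadings.copy()
    for j in range(comps.shape[1]):
        c = comps[:, j] - comps[:, j].mean()
        if float(c @ axis) < 0:
            comps[:, j] *= -1
            loads[:, j] *= -1
    return comps, loads


def compute_gradients(values: np.ndarray, k: int,
                      reference_axis: np.ndarray | None = None,
                      is_reference: bool = False) -> GradientSet:
    """PCA gradients of a normalized features x regions matrix.

    Feature-wise centering (regions as observations); ``reference_axis``
    (e.g. the anterior-posterior centroid coordinate) fixes component signs.
    """
    values = np.asarray(values, dtype=float)
    if hasattr(values, "values"):
        values = values.values
    n_features, n_regions = values.shape
    if k > min(n_features, n_regions) - 1:
        raise ValueError("k exceeds min(features, regions) - 1")
    X = values.T  # regions x features; PCA centers each feature
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < k:
        raise ValueError(f"degenerate covariance: rank {rank} < k={k}")
    comps, loads = _fix_signs(scores, pca.components_.T, reference_axis)
    return GradientSet(comps, pca.explained_variance_ratio_.copy(), loads,
                       is_reference=is_reference)


def procrustes_align(individual: GradientSet, reference: GradientSet
                     ) -> tuple[GradientSet, float]:
    """Orthogonal Procrustes alignment of individual gradients to a reference.

    Rotation/reflection only — no scaling, no translation beyond column
    centering. Returns the aligned set and the disparity (residual sum of
    squares against the centered reference).
    """
    if individual.k != reference.k or individual.n_regions != reference.n_regions:
        raise ValueError("gradient sets must share region count and k")
    A = individual.components - individual.components.mean(axis=0)
    B = reference.components - reference.components.mean(axis=0)
    R, _ = orthogonal_procrustes(A, B)
    aligned = A @ R
    disparity = float(((aligned - B) ** 2).sum())
    return (
        GradientSet(aligned, individual.explained_variance.copy(),
                    individual.loadings @ R, is_reference=False),
        disparity,
    )


def _t_statistics(y: np.ndarray, g: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Per-region t statistic of the group regressor with nuisance Z partialled out."""
    Rz = np.eye(len(g)) - Z @ np.linalg.pinv(Z)
    gr = Rz @ g
    yr = Rz @ y
    gg = float(gr @ gr)
    beta = (gr @ yr) / gg
    resid = yr - np.outer(gr, beta)
    dof = len(g) - Z.shape[1] - 1
    s2 = (resid**2).sum(axis=0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / np.sqrt(s2 / gg)
    return np.where(np.isfinite(t), t, 0.0)


def group_difference_map(
    maps: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None,
    hemispheres: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Covariate-adjusted two-sample permutation test per region, FWE-corrected.

    ``maps`` is subjects x regions (one aligned component), ``groups`` a
    binary label vector (1 = patients), ``covariates`` subjects x p (e.g.
    age and sex; regressed out by Freedman-Lane residual permutation).
    Family-wise error is controlled by the max-|t| null computed separately
    within each hemisphere. Returns t map, corrected p map, and mask.
    """
    maps = np.asarray(maps, dtype=float)
    groups = np.asarray(groups)
    n_sub, n_regions = maps.shape
    if len(np.unique(groups)) != 2:
        raise ValueError("need exactly two groups")
    g = (groups == np.unique(groups)[1]).astype(float)
    if min(g.sum(), (1 - g).sum()) < 2:
        raise ValueError("need at least 2 subjects per group")
    Z = np.ones((n_sub, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if not np.all(np.isfinite(cov)):
            raise ValueError("covariates must be complete")
        Z = np.column_stack([Z, cov])
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is small; p-values are coarse", stacklevel=2)

    zero_var = maps.std(axis=0) == 0
    t_obs = _t_statistics(maps, g, Z)
    t_obs[zero_var] = 0.0

    # Freedman-Lane: permute reduced-model residuals, add fitted part back
    Hz = Z @ np.linalg.pinv(Z)
    fitted = Hz @ maps
    resid = maps - fitted
    hemis = np.asarray(hemispheres)
    sides = np.unique(hemis)
    rng = np.random.default_rng(seed)
    max_null = {s: np.empty(n_perm) for s in sides}
    for p in range(n_perm):
        perm = rng.permutation(n_sub)
        t_star = _t_statistics(fitted + resid[perm], g, Z)
        for s in sides:
            max_null[s][p] = np.abs(t_star[hemis == s]).max()
    p_fwe = np.ones(n_regions)
    for s in sides:
        sel = hemis == s
        null = max_null[s]
        p_fwe[sel] = (1 + (null[None, :] >= np.abs(t_obs[sel])[:, None]).sum(axis=1)) / (
            n_perm + 1
        )
    return {
        "t": t_obs,
        "p_fwe": p_fwe,
        "significant": (p_fwe < alpha) & ~zero_var,
        "zero_variance": zero_var,
    }


def networkwise_compare(
    maps: np.ndarray,
    parcellation: Parcellation,
    groups: np.ndarray,
    alpha: float = 0.05,
    m: int = 7,
) -> pd.DataFrame:
    """Subject-level network means compared between groups, Bonferroni alpha/m."""
    maps = np.asarray(maps, dtype=float)
    groups = np.asarray(groups)
    labels = [n for n in dict.fromkeys(parcellation.network) if n != "unassigned"]
    ga, gb = np.unique(groups)
    rows = []
    for net in labels:
        idx = parcellation.network_regions(net)
        if len(idx) == 0:
            raise ValueError(f"empty network {net!r}")
        means = maps[:, idx].mean(axis=1)
        a, b = means[groups == gb], means[groups == ga]
        t, p = stats.ttest_ind(a, b)
        rows.append(
            {"network": net, "mean_difference": float(a.mean() - b.mean()),
             "t": float(t), "p": float(p), "significant": bool(p < alpha / m)}
        )
    return pd.DataFrame(rows)


def rank_contributing_features(
    feature_rows: np.ndarray, feature_names: list[str], t_map: np.ndarray
) -> pd.DataFrame:
    """Features ranked by |Pearson r| against a group-difference t map."""
    feature_rows = np.asarray(feature_rows, dtype=float)
    t_map = np.asarray(t_map, dtype=float)
    if t_map.std() == 0:
        raise ValueError("zero-variance difference map")
    rows = []
    for vals, name in zip(feature_rows, feature_names):
        if vals.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(vals, t_map)[0, 1])
        rows.append({"feature": name, "r": r, "sign": int(np.sign(r))})
    table = pd.DataFrame(rows)
    table["abs_r"] = table["r"].abs()
    table = table.sort_values(["abs_r", "feature"], ascending=[False, True],
                              kind="stable").drop(columns="abs_r")
    return table.reset_index(drop=True)


def compute_fc_gradient(fc: np.ndarray, sparsity: float = 0.9,
                        reference_axis: np.ndarray | None = None) -> np.ndarray:
    """Principal functional-connectivity gradient by diffusion-map embedding.

    FC rows are sparsified to their top decile, a cosine affinity is built
    between the sparsified connectivity profiles, and the first nontrivial
    component of the anisotropic (alpha = 0.5) diffusion operator is
    returned z-scored, with the sign convention of ``compute_gradients``.
    """
    fc = np.asarray(fc, dtype=float)
    n = fc.shape[0]
    if fc.shape != (n, n) or not np.allclose(fc, fc.T, atol=1e-10):
        raise ValueError("FC must be square and symmetric")
    if not np.allclose(np.diag(fc), 1.0):
        raise ValueError("FC must have unit diagonal")
    # per-row top-decile sparsification
    thresh = np.quantile(fc, sparsity, axis=1, keepdims=True)
    prof = np.where(fc >= thresh, fc, 0.0)
    norms = np.linalg.norm(prof, axis=1)
    if np.any(norms == 0):
        raise ValueError("a region has an empty sparsified profile")
    cosine = (prof @ prof.T) / np.outer(norms, norms)
    affinity = np.clip(cosine, 0.0, None)
    np.fill_diagonal(affinity, 1.0)
    deg = affinity.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("disconnected affinity graph")
    # anisotropic normalization, alpha = 0.5
    W = affinity / np.sqrt(np.outer(deg, deg))
    d2 = W.sum(axis=1)
    # symmetric conjugate of the Markov operator for a stable eigenproblem
    M = W / np.sqrt(np.outer(d2, d2))
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # right eigenvectors of the Markov operator via the degree conversion
    psi = vecs / np.sqrt(d2)[:, None]
    lam = np.clip(vals[1], None, 1 - 1e-12)
    grad = psi[:, 1] * (lam / (1 - lam))  # automatic diffusion time
    if grad.std() == 0:
        raise ValueError("degenerate first component")
    grad = (grad - grad.mean()) / grad.std()
    comps, _ = _fix_signs(grad[:, None], np.zeros((1, 1)), reference_axis)
    return comps[:, 0]
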
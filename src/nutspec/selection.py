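"""Spectral sample selection: PCA, standardized Mahalanobis H, NH grouping.

The selection works in the score space of a mean-centered PCA retaining the
smallest number of components explaining a target fraction (default 99 %) of
the spectral variance. Distances are reported in the "global H" convention:

    H(x)     = (1/k) * sum_j (t_j / sd_j)^2
    NH(x, z) = (1/k) * sum_j ((t_j - u_j) / sd_j)^2

i.e. squared Mahalanobis distance in score space divided by the number of
components k, so that the training-set mean of H is (N-1)/N ~ 1. With this
normalization the customary thresholds are meaningful: H > 3 flags a sample
as a spectral outlier, and NH < 0.9 defines spectral equivalence between two
samples.

Grouping is greedy: the unassigned sample with the most unassigned
NH-neighbours becomes a group seed (ties broken by lowest index) and absorbs
them, until every sample is assigned. One sample per group (the seed) forms
the calibration set; the member closest to the seed (when the group has one)
forms the validation set; the rest are left unselected but can be predicted
later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PCAModel:
    k: int
    loadings: np.ndarray          # (bands, k), orthonormal columns
    score_sds: np.ndarray         # (k,), sd of training scores (ddof=1)
    center: np.ndarray            # (bands,)
    explained_fraction: float     # cumulative fraction at k
    explained_by_component: np.ndarray = field(default=None, repr=False)

    def scores(self, spectra: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
        return (X - self.center) @ self.loadings


def fit_pca(spectra: np.ndarray, var_target: float = 0.99) -> PCAModel:
    """Mean-centered PCA keeping the fewest components reaching ``var_target``."""
    if not 0.0 < var_target <= 1.0:
        raise ValueError("var_target must lie in (0, 1]")
    X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for PCA selection")
    center = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - center, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("spectra have zero variance")
    frac = np.cumsum(var) / total
    k = int(np.searchsorted(frac, var_target - 1e-12) + 1)
    k = min(k, int((s > s[0] * 1e-12).sum()))  # drop numerically null directions
    sds = s[:k] / np.sqrt(n - 1)
    return PCAModel(k, vt[:k].T.copy(), sds, center, float(frac[k - 1]), var / total)


def global_h(model: PCAModel, spectra: np.ndarray) -> np.ndarray:
    """Standardized squared Mahalanobis distance to the spectral center."""
    t = model.scores(spectra)
    return ((t / model.score_sds) ** 2).sum(axis=1) / model.k


def flag_outliers(h_values: np.ndarray, threshold: float = 3.0) -> np.ndarray:
    """Indices of samples with H strictly above the threshold."""
    return np.nonzero(np.asarray(h_values) > threshold)[0]


def nh_matrix(model: PCAModel, spectra: np.ndarray) -> np.ndarray:
    """Pairwise standardized neighbourhood distances NH(i, j)."""
    u = model.scores(spectra) / model.score_sds
    sq = (u**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (u @ u.T)
    np.maximum(d2, 0.0, out=d2)
    return d2 / model.k


@dataclass
class Group:
    seed: int                 # index of the seed sample
    members: list[int]        # all member indices, seed included


def neighborhood_groups(
    model: PCAModel, spectra: np.ndarray, nh_threshold: float = 0.9
) -> list[Group]:
    """Greedy max-degree grouping of samples at NH < ``nh_threshold``."""
    nh = nh_matrix(model, spectra)
    n = nh.shape[0]
    neighbors = nh < nh_threshold
    np.fill_diagonal(neighbors, False)
    unassigned = np.ones(n, dtype=bool)
    groups: list[Group] = []
    while unassigned.any():
        counts = (neighbors & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = [seed] + [int(j) for j in np.nonzero(neighbors[seed] & unassigned)[0] if j != seed]
        for m in members:
            unassigned[m] = False
        groups.append(Group(seed, members))
    return groups


def allocate_sets(
    groups: list[Group], nh: np.ndarray
) -> tuple[list[int], list[int], list[int]]:
    """One calibration sample (the seed) per group; nearest member validates."""
    if not groups:
        raise ValueError("no groups to allocate")
    cal, val, nonsel = [], [], []
    for grp in groups:
        cal.append(grp.seed)
        others = [m for m in grp.members if m != grp.seed]
        if others:
            closest = min(others, key=lambda m: (nh[grp.seed, m], m))
            val.append(closest)
            nonsel.extend(m for m in others if m != closest)
    return cal, val, nonsel


@dataclass
class SelectionResult:
    h_values: np.ndarray
    outlier_ids: list[int]
    groups: list[Group]
    calibration_ids: list[int]
    validation_ids: list[int]
    non_selected_ids: list[int]
    pca: PCAModel

    def set_labels(self, n: int) -> list[str]:
        labels = ["NONSEL"] * n
        for i in self.outlier_ids:
            labels[i] = "OUTLIER"
        for i in self.calibration_ids:
            labels[i] = "CAL"
        for i in self.validation_ids:
            labels[i] = "VAL"
        return labels


def select_samples(
    spectra: np.ndarray,
    var_target: float = 0.99,
    h_threshold: float = 3.0,
    nh_threshold: float = 0.9,
) -> SelectionResult:
    """Full selection chain on (already pretreated) spectra.

    Indices in the result refer to rows of ``spectra``; outliers are removed
    before grouping, and the calibration/validation/non-selected sets
    partition the non-outlier samples.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    model = fit_pca(X, var_target)
    h = global_h(model, X)
    outliers = flag_outliers(h, h_threshold).tolist()
    keep = np.asarray([i for i in range(X.shape[0]) if i not in set(outliers)])
    groups_local = neighborhood_groups(model, X[keep], nh_threshold)
    nh_local = nh_matrix(model, X[keep])
    cal_l, val_l, non_l = allocate_sets(groups_local, nh_local)
    to_global = lambda idx: [int(keep[i]) for i in idx]
    groups = [Group(int(keep[g.seed]), to_global(g.members)) for g in groups_local]
    return SelectionResult(
        h_values=h,
        outlier_ids=outliers,
        groups=groups,
        calibration_ids=to_global(cal_l),
        validation_ids=to_global(val_l),
        non_selected_ids=to_global(non_l),
        pca=model,
    )
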
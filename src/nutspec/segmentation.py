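"""Pixel segmentation by stepwise LDA, ROI extraction, per-kernel spectra.

A stepwise linear discriminant classifier separates kernel from background
pixels using a handful of discriminating wavelengths: forward selection
minimizes Wilks' lambda, a band enters when its partial F reaches
``f_enter`` (default 3.84) and leaves when it drops below ``f_remove``
(default 2.71), and a Fisher discriminant with equal priors is fit on the
selected bands with the decision threshold at the midpoint of the projected
class means.

Kernel regions are 4-connected components of the classified mask (speckle
below ``min_area`` dropped), ids assigned in reading order of centroids.
Per-kernel spectra are arithmetic means over ROI pixels; the two rotated
acquisitions of a tray are merged by averaging paired kernels' spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage import measure

from .cube import HyperCube


@dataclass
class LDAModel:
    selected_band_indices: list[int]
    selected_wavelengths: np.ndarray
    weights: np.ndarray          # coefficient vector on the selected bands
    intercept: float             # decision rule: w . x > intercept -> kernel
    class_means: tuple[np.ndarray, np.ndarray]  # (background, kernel)
    training_summary: list[dict] = field(default_factory=list)  # per-step Wilks/F

    def decision(self, spectra_selected: np.ndarray) -> np.ndarray:
        return spectra_selected @ self.weights - self.intercept


def _scatter_matrices(X: np.ndarray, labels: np.ndarray):
    grand = X.mean(axis=0)
    Xc = X - grand
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for cls in (0, 1):
        sub = X[labels == cls]
        sc = sub - sub.mean(axis=0)
        W += sc.T @ sc
    return T, W


def _partial_f_enter(T, W, selected, candidates, n):
    """Partial F-to-enter for every candidate, via Schur-complement residuals."""
    p = len(selected)
    if p == 0:
        r_t = np.diag(T)[candidates]
        r_w = np.diag(W)[candidates]
    else:
        S = list(selected)
        r_t = np.diag(T)[candidates] - np.einsum(
            "ij,ij->j", T[np.ix_(S, candidates)], np.linalg.solve(T[np.ix_(S, S)], T[np.ix_(S, candidates)])
        )
        r_w = np.diag(W)[candidates] - np.einsum(
            "ij,ij->j", W[np.ix_(S, candidates)], np.linalg.solve(W[np.ix_(S, S)], W[np.ix_(S, candidates)])
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (n - 2 - p) * (r_t / r_w - 1.0)
    # collinear or numerically null candidates are ineligible
    bad = (r_t <= 1e-10 * np.diag(T)[candidates]) | ~np.isfinite(f) | (r_w <= 0)
    f = np.where(bad, -np.inf, f)
    return f


def _partial_f_remove(T, W, selected, n):
    S = list(selected)
    p = len(S)
    w_inv = np.linalg.inv(W[np.ix_(S, S)])
    t_inv = np.linalg.inv(T[np.ix_(S, S)])
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (n - 1 - p) * (np.diag(w_inv) / np.diag(t_inv) - 1.0)
    return f


def train_stepwise_lda(
    pixels: np.ndarray,
    labels: np.ndarray,
    wavelengths: np.ndarray | None = None,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    max_vars: int = 30,
) -> LDAModel:
    """Forward-stepwise Wilks'-lambda band selection + Fisher discriminant.

    ``labels`` are 1 for kernel pixels, 0 for background. Constant bands are
    skipped with a warning.
    """
    X = np.atleast_2d(np.asarray(pixels, dtype=np.float64))
    y = np.asarray(labels).astype(int).ravel()
    n, b = X.shape
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if n <= max_vars:
        raise ValueError("need more training pixels than max_vars")
    if wavelengths is None:
        wavelengths = np.arange(b, dtype=np.float64)
    wavelengths = np.asarray(wavelengths, dtype=np.float64)

    T, W = _scatter_matrices(X, y)
    variances = np.diag(T)
    constant = variances <= 0
    if constant.any():
        warnings.warn(f"skipping {int(constant.sum())} constant band(s)")

    selected: list[int] = []
    summary: list[dict] = []
    seen: set[tuple[int, ...]] = set()
    while len(selected) < max_vars:
        candidates = np.asarray([j for j in range(b) if j not in selected and not constant[j]])
        if candidates.size == 0:
            break
        f_vals = _partial_f_enter(T, W, selected, candidates, n)
        best = int(np.argmax(f_vals))
        if f_vals[best] < f_enter:
            break
        entered = int(candidates[best])
        selected.append(entered)
        lam = float(
            np.linalg.det(W[np.ix_(selected, selected)])
            / np.linalg.det(T[np.ix_(selected, selected)])
        )
        summary.append({"step": len(summary) + 1, "action": "enter",
                        "band": entered, "wavelength": float(wavelengths[entered]),
                        "partial_f": float(f_vals[best]), "wilks_lambda": lam})
        # backward sweep
        while len(selected) > 1:
            f_rem = _partial_f_remove(T, W, selected, n)
            order = np.argsort(f_rem, kind="stable")
            worst = int(order[0])
            if selected[worst] == entered or f_rem[worst] >= f_remove:
                break
            removed = selected.pop(worst)
            summary.append({"step": len(summary) + 1, "action": "remove",
                            "band": removed, "wavelength": float(wavelengths[removed]),
                            "partial_f": float(f_rem[worst]), "wilks_lambda": float("nan")})
        key = tuple(sorted(selected))
        if key in seen:  # cycling guard
            break
        seen.add(key)
    if not selected:
        raise ValueError("no band reached the F-to-enter threshold")

    sub = X[:, selected]
    m0 = sub[y == 0].mean(axis=0)
    m1 = sub[y == 1].mean(axis=0)
    sw = W[np.ix_(selected, selected)] / (n - 2)
    weights = np.linalg.solve(sw, m1 - m0)
    intercept = float(weights @ (m0 + m1) / 2.0)
    return LDAModel(
        selected_band_indices=list(selected),
        selected_wavelengths=wavelengths[selected].copy(),
        weights=weights,
        intercept=intercept,
        class_means=(m0, m1),
        training_summary=summary,
    )


def _band_indices_for(model: LDAModel, wavelengths: np.ndarray) -> np.ndarray:
    idx = []
    for wl in model.selected_wavelengths:
        matches = np.nonzero(np.isclose(wavelengths, wl, atol=1e-6))[0]
        if matches.size == 0:
            raise ValueError(f"cube lacks the model band at {wl} nm")
        idx.append(int(matches[0]))
    return np.asarray(idx)


def classify_pixels(model: LDAModel, cube: HyperCube) -> np.ndarray:
    """Per-pixel kernel (1) / background (0) mask for an absorbance cube."""
    if cube.stage != "absorbance":
        raise ValueError(f"expected an absorbance cube, got stage {cube.stage!r}")
    idx = _band_indices_for(model, cube.wavelengths)
    scores = cube.data[:, :, idx] @ model.weights - model.intercept
    return (scores > 0).astype(np.uint8)


@dataclass
class KernelROI:
    kernel_id: int
    pixel_set: np.ndarray   # (n, 2) array of (line, pixel) coordinates
    area: int
    centroid: tuple[float, float]


def extract_objects(mask: np.ndarray, min_area: int = 50) -> list[KernelROI]:
    """4-connected components of the kernel mask, small speckle dropped."""
    labeled = measure.label(np.asarray(mask) > 0, connectivity=1)
    rois = []
    for region in measure.regionprops(labeled):
        if region.area < min_area:
            continue
        rois.append((region.centroid, region.coords, int(region.area)))
    rois.sort(key=lambda r: (r[0][0], r[0][1]))
    return [
        KernelROI(kernel_id=i + 1, pixel_set=coords, area=area, centroid=tuple(centroid))
        for i, (centroid, coords, area) in enumerate(rois)
    ]


def mean_spectrum(cube: HyperCube, roi: KernelROI) -> np.ndarray:
    """Arithmetic mean spectrum over an ROI's pixels."""
    return cube.data[roi.pixel_set[:, 0], roi.pixel_set[:, 1], :].mean(axis=0)


def merge_acquisitions(
    spectra_a: dict[int, np.ndarray],
    spectra_b: dict[int, np.ndarray],
    pairing: dict[int, int],
) -> dict[int, np.ndarray]:
    """Average paired kernels' spectra from the two rotated acquisitions."""
    unpaired = sorted(set(spectra_a) - set(pairing))
    missing = sorted({pairing[k] for k in spectra_a if k in pairing} - set(spectra_b))
    if unpaired or missing:
        raise ValueError(
            f"unpaired kernels: A-side {unpaired}, missing B-side {missing}"
        )
    return {ka: (spectra_a[ka] + spectra_b[pairing[ka]]) / 2.0 for ka in spectra_a}


def pair_rois_by_rotation(
    rois_a: list[KernelROI], rois_b: list[KernelROI], shape: tuple[int, int]
) -> dict[int, int]:
    """Pair kernels across a 180 deg rotation by centroid nearest-neighbour.

    Rotates B centroids back onto A's frame and solves the optimal
    assignment, so the pairing is a bijection even with position jitter.
    """
    if len(rois_a) != len(rois_b):
        raise ValueError("acquisitions hold different kernel counts")
    ca = np.asarray([r.centroid for r in rois_a])
    cb = np.asarray(
        [(shape[0] - 1 - r.centroid[0], shape[1] - 1 - r.centroid[1]) for r in rois_b]
    )
    cost = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return {rois_a[i].kernel_id: rois_b[j].kernel_id for i, j in zip(rows, cols)}


def match_rois_to_truth(rois: list[KernelROI], truth_mask: np.ndarray) -> dict[int, int]:
    """Map extracted ROI ids to ground-truth kernel ids by majority overlap."""
    out = {}
    for roi in rois:
        overlap = truth_mask[roi.pixel_set[:, 0], roi.pixel_set[:, 1]]
        values, counts = np.unique(overlap[overlap > 0], return_counts=True)
        if values.size == 0:
            raise ValueError(f"ROI {roi.kernel_id} overlaps no true kernel")
        out[roi.kernel_id] = int(values[np.argmax(counts)])
    return out
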
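"""Modified partial least squares (MPLS) regression for single analytes.

MPLS is the Shenk & Westerhaus variant of PLS1 used throughout NIR
calibration practice: after each latent factor is extracted and deflated,
every spectral residual column and the chemistry residual are divided by
their standard deviations, so later factors work on standardized residuals.
With all residual scalings forced to one, the algorithm reduces exactly to
standard single-response PLS.

The full calibration procedure is:

1. apply the pretreatment code to the calibration spectra (fit mode),
2. cross-validate (shuffled contiguous folds) to pick the factor count
   minimizing SECV,
3. remove chemistry outliers with T = |y - y_cv| / SECV > 2.5 and refit,
   for up to ``max_passes`` elimination passes,
4. refit at the chosen factor count on the retained samples.

Prediction replays the stored pretreatment (transform mode), the centering,
and the per-factor weights, loadings and residual scalings; a model is fully
reconstructible from its JSON serialization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pretreat import FittedPretreatment, parse_code


@dataclass
class FactorStack:
    """Per-factor state of an (M)PLS decomposition."""

    weights: np.ndarray      # (F, B) unit-norm weight vectors
    x_loadings: np.ndarray   # (F, B)
    y_loadings: np.ndarray   # (F,)
    x_scales: np.ndarray     # (F, B) residual sds applied after each factor
    y_scales: np.ndarray     # (F,)

    @property
    def n_max(self) -> int:
        return self.weights.shape[0]


def fit_factors(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    scale_residuals: bool = True,
) -> tuple[FactorStack, np.ndarray, float]:
    """Extract ``n_factors`` (M)PLS factors from pretreated spectra.

    Returns the factor stack plus the column centers of X and the center of
    y. ``scale_residuals=False`` disables the modification and yields
    standard PLS1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    n, b = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if y.std() == 0:
        raise ValueError("reference values have zero variance")
    if n <= n_factors + 1:
        raise ValueError(f"need more than {n_factors + 1} samples for {n_factors} factors")

    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    Xr = X - x_center
    yr = y - y_center

    W = np.zeros((n_factors, b))
    P = np.zeros((n_factors, b))
    Q = np.zeros(n_factors)
    Sx = np.ones((n_factors, b))
    Sy = np.ones(n_factors)
    eps = 1e-12
    used = n_factors
    for f in range(n_factors):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < eps:
            warnings.warn(f"rank exhausted after {f} factors; truncating")
            used = f
            break
        w /= norm
        t = Xr @ w
        tt = float(t @ t)
        if tt < eps:
            warnings.warn(f"degenerate scores at factor {f + 1}; truncating")
            used = f
            break
        p = Xr.T @ t / tt
        q = float(yr @ t / tt)
        Xr = Xr - np.outer(t, p)
        yr = yr - t * q
        W[f], P[f], Q[f] = w, p, q
        if scale_residuals:
            sx = Xr.std(axis=0, ddof=1)
            sx[sx < eps] = 1.0
            sy = float(yr.std(ddof=1))
            if sy < eps:
                sy = 1.0
            Xr = Xr / sx
            yr = yr / sy
            Sx[f], Sy[f] = sx, sy
    stack = FactorStack(W[:used], P[:used], Q[:used], Sx[:used], Sy[:used])
    return stack, x_center, y_center


def predict_factors(
    stack: FactorStack,
    x_center: np.ndarray,
    y_center: float,
    X: np.ndarray,
    n_factors: int | None = None,
) -> np.ndarray:
    """Predict from a factor stack; optionally truncate to ``n_factors``."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    nf = stack.n_max if n_factors is None else min(n_factors, stack.n_max)
    r = X - x_center
    yhat = np.full(X.shape[0], y_center)
    acc = 1.0
    for f in range(nf):
        t = r @ stack.weights[f]
        yhat = yhat + acc * t * stack.y_loadings[f]
        r = (r - np.outer(t, stack.x_loadings[f])) / stack.x_scales[f]
        acc *= stack.y_scales[f]
    return yhat


def _prediction_path(stack, x_center, y_center, X, f_max):
    """Predictions at every factor count 1..f_max, shape (n, f_max)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    out = np.zeros((X.shape[0], f_max))
    r = X - x_center
    yhat = np.full(X.shape[0], y_center)
    acc = 1.0
    nf = min(f_max, stack.n_max)
    for f in range(nf):
        t = r @ stack.weights[f]
        yhat = yhat + acc * t * stack.y_loadings[f]
        r = (r - np.outer(t, stack.x_loadings[f])) / stack.x_scales[f]
        acc *= stack.y_scales[f]
        out[:, f] = yhat
    for f in range(nf, f_max):  # rank exhausted: constant continuation
        out[:, f] = yhat
    return out


@dataclass
class CVResult:
    secv_by_factor: np.ndarray
    chosen_factors: int
    fold_assignment: np.ndarray
    cv_predictions: np.ndarray  # (n,) at chosen_factors

    @property
    def secv(self) -> float:
        return float(self.secv_by_factor[self.chosen_factors - 1])


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    f_max: int,
    n_folds: int = 6,
    seed: int = 0,
    scale_residuals: bool = True,
) -> CVResult:
    """K-fold cross-validation over factor counts 1..f_max.

    Folds are contiguous blocks of a seeded shuffle. SECV(f) is the root
    mean square of the held-out residuals; the chosen factor count is the
    global argmin.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n < 2 * n_folds:
        raise ValueError("need at least 2 samples per fold")
    f_max = min(f_max, n - n // n_folds - 2)
    if f_max < 1:
        raise ValueError("not enough samples for even one factor")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.zeros(n, dtype=int)
    for k, block in enumerate(np.array_split(perm, n_folds)):
        folds[block] = k
    preds = np.zeros((n, f_max))
    for k in range(n_folds):
        test = folds == k
        stack, xc, yc = fit_factors(X[~test], y[~test], f_max, scale_residuals)
        preds[test] = _prediction_path(stack, xc, yc, X[test], f_max)
    secv = np.sqrt(((y[:, None] - preds) ** 2).mean(axis=0))
    chosen = int(np.argmin(secv)) + 1
    return CVResult(secv, chosen, folds, preds[:, chosen - 1])


def remove_t_outliers(
    y: np.ndarray,
    y_cv: np.ndarray,
    secv: float,
    threshold: float = 2.5,
) -> tuple[np.ndarray, list[dict]]:
    """Single elimination pass of the chemistry T-statistic.

    T_i = |y_i - y_cv,i| / SECV; samples with T strictly above the threshold
    are dropped. Returns kept indices and a ledger of removals.
    """
    if secv <= 0:
        raise ValueError("SECV must be positive")
    y = np.asarray(y, dtype=np.float64).ravel()
    t = np.abs(y - np.asarray(y_cv).ravel()) / secv
    removed = np.nonzero(t > threshold)[0]
    ledger = [{"index": int(i), "t": float(t[i])} for i in removed]
    kept = np.asarray([i for i in range(y.size) if t[i] <= threshold])
    return kept, ledger


@dataclass
class MPLSModel:
    """A fitted MPLS calibration: pretreatment + centering + factor stack."""

    pretreatment: FittedPretreatment
    stack: FactorStack
    x_center: np.ndarray
    y_center: float
    n_factors: int
    removed_outliers: list[dict] = field(default_factory=list)
    sec: float = float("nan")
    rsq: float = float("nan")
    secv: float = float("nan")
    secv_by_factor: np.ndarray | None = None
    n_train: int = 0
    kept_indices: list[int] = field(default_factory=list)
    analyte: str = ""

    def predict(self, spectra: np.ndarray, wavelengths: np.ndarray | None = None) -> np.ndarray:
        """Predict the analyte for raw (un-pretreated) spectra."""
        Xp = self.pretreatment.transform(spectra, wavelengths)
        return predict_factors(self.stack, self.x_center, self.y_center, Xp, self.n_factors)

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "pretreatment": self.pretreatment.to_dict(),
            "weights": self.stack.weights.tolist(),
            "x_loadings": self.stack.x_loadings.tolist(),
            "y_loadings": self.stack.y_loadings.tolist(),
            "x_scales": self.stack.x_scales.tolist(),
            "y_scales": self.stack.y_scales.tolist(),
            "x_center": self.x_center.tolist(),
            "y_center": self.y_center,
            "n_factors": self.n_factors,
            "removed_outliers": self.removed_outliers,
            "sec": self.sec,
            "rsq": self.rsq,
            "secv": self.secv,
            "secv_by_factor": None if self.secv_by_factor is None else self.secv_by_factor.tolist(),
            "n_train": self.n_train,
            "kept_indices": self.kept_indices,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MPLSModel":
        stack = FactorStack(
            np.asarray(payload["weights"], dtype=np.float64),
            np.asarray(payload["x_loadings"], dtype=np.float64),
            np.asarray(payload["y_loadings"], dtype=np.float64),
            np.asarray(payload["x_scales"], dtype=np.float64),
            np.asarray(payload["y_scales"], dtype=np.float64),
        )
        return cls(
            pretreatment=FittedPretreatment.from_dict(payload["pretreatment"]),
            stack=stack,
            x_center=np.asarray(payload["x_center"], dtype=np.float64),
            y_center=float(payload["y_center"]),
            n_factors=int(payload["n_factors"]),
            removed_outliers=payload.get("removed_outliers", []),
            sec=payload.get("sec", float("nan")),
            rsq=payload.get("rsq", float("nan")),
            secv=payload.get("secv", float("nan")),
            secv_by_factor=None
            if payload.get("secv_by_factor") is None
            else np.asarray(payload["secv_by_factor"], dtype=np.float64),
            n_train=payload.get("n_train", 0),
            kept_indices=payload.get("kept_indices", []),
            analyte=payload.get("analyte", ""),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "MPLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    y: np.ndarray,
    code: str = "SNV 2,5,5,1",
    f_max: int | None = None,
    n_folds: int = 6,
    t_threshold: float = 2.5,
    max_passes: int = 2,
    seed: int = 0,
    min_samples: int = 10,
    analyte: str = "",
) -> MPLSModel:
    """Full MPLS calibration: pretreat, cross-validate, eliminate T outliers.

    ``f_max`` defaults to min(15, N // 3), a cap that keeps factor counts in
    the 1-7 range typical of NIR work and guards against overfitting small
    calibration sets.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    fp = FittedPretreatment(parse_code(code))
    Xp, _ = fp.fit(spectra, wavelengths)
    n = Xp.shape[0]
    if f_max is None:
        f_max = min(15, max(1, n // 3))

    kept = np.arange(n)
    ledger: list[dict] = []

    def _cv(idx):
        folds = max(2, min(n_folds, idx.size // 2))  # adapt to small sets
        return cross_validate(Xp[idx], y[idx], f_max, folds, seed)

    cv = _cv(kept)
    for _ in range(max_passes):
        kept_local, removals = remove_t_outliers(y[kept], cv.cv_predictions, cv.secv, t_threshold)
        if not removals:
            break
        if kept_local.size < min_samples:
            warnings.warn(
                f"T-outlier removal would leave {kept_local.size} < {min_samples} "
                "samples; stopping elimination"
            )
            break
        ledger.extend({"index": int(kept[r["index"]]), "t": r["t"]} for r in removals)
        kept = kept[kept_local]
        cv = _cv(kept)

    stack, xc, yc = fit_factors(Xp[kept], y[kept], cv.chosen_factors)
    yhat = predict_factors(stack, xc, yc, Xp[kept])
    resid = y[kept] - yhat
    dof = max(kept.size - cv.chosen_factors - 1, 1)
    sec = float(np.sqrt((resid**2).sum() / dof))
    sst = float(((y[kept] - y[kept].mean()) ** 2).sum())
    rsq = float(1.0 - (resid**2).sum() / sst) if sst > 0 else float("nan")

    return MPLSModel(
        pretreatment=fp,
        stack=stack,
        x_center=xc,
        y_center=yc,
        n_factors=cv.chosen_factors,
        removed_outliers=ledger,
        sec=sec,
        rsq=rsq,
        secv=cv.secv,
        secv_by_factor=cv.secv_by_factor,
        n_train=int(kept.size),
        kept_indices=[int(i) for i in kept],
        analyte=analyte,
    )
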
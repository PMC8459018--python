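"""WinISI-style spectral pretreatments: scatter correction and gap-segment derivatives.

A pretreatment is written exactly as it is reported in NIR calibration work,
e.g. ``"SNV+detrend 2,5,5,1"`` or ``"MSC 1,5,5,1"``: a scatter-correction
token followed by four numbers ``d,g,s1,s2`` — the derivative order, the gap
(in bands) over which the derivative is taken, and the widths of a first and
second running-mean smoothing. ``"None 0,0,1,1"`` is the identity.

Scatter corrections:

* **SNV** — per-spectrum standardization (x - mean) / sd, sd with n-1.
* **Detrend** — subtract the per-spectrum least-squares polynomial (degree 2)
  in wavelength.
* **MSC** — regress each spectrum on a reference (the calibration-set mean),
  x ~ a + b*ref, and correct to (x - a) / b. The reference is learned at fit
  time and reused verbatim at prediction time.

The gap-segment derivative runs: smooth (width ``s1``) -> derivative
(order ``d`` over gap ``g``; central stencil) -> smooth (width ``s2``).
Bands without full stencil support are dropped, never padded, so the
surviving wavelength grid is returned alongside the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_SCATTER_TOKENS = {
    "none": (),
    "snv": ("snv",),
    "msc": ("msc",),
    "detrend": ("detrend",),
    "snv+detrend": ("snv", "detrend"),
    "detrend+snv": ("detrend", "snv"),
}
_CANONICAL = {(): "None", ("snv",): "SNV", ("msc",): "MSC", ("detrend",): "Detrend",
              ("snv", "detrend"): "SNV+detrend", ("detrend", "snv"): "Detrend+SNV"}


@dataclass(frozen=True)
class PretreatmentCode:
    """Parsed form of a pretreatment string such as ``"SNV+detrend 2,5,5,1"``."""

    scatter_ops: tuple[str, ...] = ()
    d: int = 0
    g: int = 0
    s1: int = 1
    s2: int = 1

    def __post_init__(self) -> None:
        if any(op not in ("snv", "msc", "detrend") for op in self.scatter_ops):
            raise ValueError(f"unknown scatter ops {self.scatter_ops}")
        if self.d not in (0, 1, 2):
            raise ValueError(f"derivative order must be 0, 1 or 2, got {self.d}")
        if self.d >= 1 and self.g < 1:
            raise ValueError("gap g must be >= 1 when a derivative is requested")
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("smoothing widths must be >= 0")

    def serialize(self) -> str:
        name = _CANONICAL.get(self.scatter_ops)
        if name is None:
            name = "+".join(self.scatter_ops)
        return f"{name} {self.d},{self.g},{self.s1},{self.s2}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


def parse_code(text: str | PretreatmentCode) -> PretreatmentCode:
    """Parse ``"<scatter> d,g,s1,s2"`` (case-insensitive) into a code object."""
    if isinstance(text, PretreatmentCode):
        return text
    parts = text.strip().split()
    if len(parts) == 1:
        scatter, numbers = parts[0], "0,0,1,1"
    elif len(parts) == 2:
        scatter, numbers = parts
    else:
        raise ValueError(f"cannot parse pretreatment code {text!r}")
    key = scatter.lower()
    if key not in _SCATTER_TOKENS:
        raise ValueError(f"unknown scatter correction {scatter!r} in {text!r}")
    nums = [s for s in numbers.split(",") if s]
    if len(nums) != 4:
        raise ValueError(f"expected 4 numbers d,g,s1,s2 in {text!r}")
    d, g, s1, s2 = (int(n) for n in nums)
    return PretreatmentCode(_SCATTER_TOKENS[key], d, g, s1, s2)


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and unit-scale each spectrum (sd, n-1)."""
    X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    sd = X.std(axis=1, ddof=1)
    dead = np.nonzero(sd <= 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance spectrum at row(s) {dead.tolist()}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def detrend(spectra: np.ndarray, wavelengths: np.ndarray, degree: int = 2) -> np.ndarray:
    """Remove each spectrum's least-squares polynomial of ``degree`` in wavelength."""
    X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    wl = np.asarray(wavelengths, dtype=np.float64)
    if wl.size != X.shape[1]:
        raise ValueError("wavelength grid does not match spectra")
    if wl.size < degree + 1:
        raise ValueError("need at least degree+1 bands to detrend")
    if np.ptp(wl) <= 0:
        raise ValueError("degenerate wavelength grid")
    # scale to [-1, 1] for conditioning; the fitted subspace is unchanged
    u = 2.0 * (wl - wl.min()) / np.ptp(wl) - 1.0
    V = np.vander(u, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, X.T, rcond=None)
    return X - (V @ coef).T


def msc(spectra: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a stored reference spectrum."""
    X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    ref = np.asarray(reference, dtype=np.float64)
    if ref.size != X.shape[1]:
        raise ValueError("MSC reference does not match spectra band count")
    refc = ref - ref.mean()
    denom = refc @ refc
    if denom <= 0:
        raise ValueError("MSC reference has zero variance")
    b = (X - X.mean(axis=1, keepdims=True)) @ refc / denom
    small = np.nonzero(np.abs(b) < 1e-8)[0]
    if small.size:
        raise ValueError(f"MSC slope ~ 0 for spectrum row(s) {small.tolist()}")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def _running_mean(X: np.ndarray, wl: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    if width <= 1:
        return X, wl
    if width % 2 == 0:
        warnings.warn(f"even smoothing width {width} rounded up to {width + 1}")
        width += 1
    if X.shape[1] < width:
        raise ValueError(f"smoothing width {width} exceeds {X.shape[1]} bands")
    c = np.cumsum(X, axis=1, dtype=np.float64)
    out = (c[:, width - 1 :] - np.concatenate([np.zeros((X.shape[0], 1)), c[:, :-width]], axis=1)) / width
    half = (width - 1) // 2
    return out, wl[half : wl.size - half]


def gap_segment_derivative(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    d: int,
    g: int,
    s1: int = 1,
    s2: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Gap-segment derivative ``d,g,s1,s2``; returns (matrix, surviving grid).

    d=0 applies the two smoothings only. d=1 uses the central difference
    D(i) = s(i+g) - s(i-g); d=2 uses s(i-g) - 2 s(i) + s(i+g).
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    wl = np.asarray(wavelengths, dtype=np.float64)
    if wl.size != X.shape[1]:
        raise ValueError("wavelength grid does not match spectra")
    X, wl = _running_mean(X, wl, s1)
    if d >= 1:
        if X.shape[1] <= 2 * g:
            raise ValueError("band support exhausted by derivative gap")
        if d == 1:
            X = X[:, 2 * g :] - X[:, : -2 * g]
        else:
            X = X[:, : -2 * g] - 2.0 * X[:, g : -g] + X[:, 2 * g :]
        wl = wl[g : wl.size - g]
    X, wl = _running_mean(X, wl, s2)
    if X.shape[1] < 1:
        raise ValueError("band support exhausted")
    return X, wl


@dataclass
class FittedPretreatment:
    """A pretreatment code bound to fit-time state (MSC reference, band grids).

    ``fit`` learns any data-dependent state on the calibration spectra and
    returns the transformed matrix; ``transform`` replays the identical chain
    on new spectra.
    """

    code: PretreatmentCode
    derivative_first: bool = False
    msc_reference: np.ndarray | None = None
    input_wavelengths: np.ndarray | None = None
    output_wavelengths: np.ndarray | None = None
    _fitted: bool = field(default=False, repr=False)

    def _scatter(self, X: np.ndarray, wl: np.ndarray, fit: bool) -> np.ndarray:
        for op in self.code.scatter_ops:
            if op == "snv":
                X = snv(X)
            elif op == "detrend":
                X = detrend(X, wl)
            elif op == "msc":
                if fit:
                    self.msc_reference = X.mean(axis=0)
                elif self.msc_reference is None:
                    raise ValueError("MSC transform requested before fit")
                ref = self.msc_reference
                if ref.size != X.shape[1]:
                    raise ValueError("MSC reference/band mismatch")
                X = msc(X, ref)
        return X

    def _apply(self, spectra: np.ndarray, wavelengths: np.ndarray, fit: bool) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
        wl = np.asarray(wavelengths, dtype=np.float64)
        c = self.code
        if self.derivative_first:
            X, wl = gap_segment_derivative(X, wl, c.d, c.g, c.s1, c.s2)
            X = self._scatter(X, wl, fit)
        else:
            X = self._scatter(X, wl, fit)
            X, wl = gap_segment_derivative(X, wl, c.d, c.g, c.s1, c.s2)
        return X, wl

    def fit(self, spectra: np.ndarray, wavelengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        self.input_wavelengths = np.asarray(wavelengths, dtype=np.float64).copy()
        X, wl = self._apply(spectra, wavelengths, fit=True)
        self.output_wavelengths = wl.copy()
        self._fitted = True
        return X, wl

    def transform(self, spectra: np.ndarray, wavelengths: np.ndarray | None = None) -> np.ndarray:
        if not self._fitted:
            raise ValueError("pretreatment not fitted")
        if wavelengths is None:
            wavelengths = self.input_wavelengths
        wavelengths = np.asarray(wavelengths, dtype=np.float64)
        if not np.allclose(wavelengths, self.input_wavelengths):
            raise ValueError("new spectra are not on the fitted wavelength grid")
        X, _ = self._apply(spectra, wavelengths, fit=False)
        return X

    def to_dict(self) -> dict:
        return {
            "code": self.code.serialize(),
            "derivative_first": self.derivative_first,
            "msc_reference": None if self.msc_reference is None else self.msc_reference.tolist(),
            "input_wavelengths": None if self.input_wavelengths is None else self.input_wavelengths.tolist(),
            "output_wavelengths": None if self.output_wavelengths is None else self.output_wavelengths.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FittedPretreatment":
        obj = cls(parse_code(payload["code"]), payload.get("derivative_first", False))
        for key in ("msc_reference", "input_wavelengths", "output_wavelengths"):
            val = payload.get(key)
            setattr(obj, key, None if val is None else np.asarray(val, dtype=np.float64))
        obj._fitted = obj.input_wavelengths is not None
        return obj


def apply_code(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    code: str | PretreatmentCode,
    fit_mode: str = "fit",
    fitted: FittedPretreatment | None = None,
    derivative_first: bool = False,
) -> tuple[np.ndarray, np.ndarray, FittedPretreatment]:
    """Functional one-shot interface over :class:`FittedPretreatment`.

    In ``fit`` mode a new fitted object is created and returned; in
    ``transform`` mode a previously fitted object must be supplied.
    """
    if fit_mode == "fit":
        fp = FittedPretreatment(parse_code(code), derivative_first)
        X, wl = fp.fit(spectra, wavelengths)
        return X, wl, fp
    if fit_mode == "transform":
        if fitted is None:
            raise ValueError("transform mode requires a fitted pretreatment")
        X = fitted.transform(spectra, wavelengths)
        return X, fitted.output_wavelengths, fitted
    raise ValueError(f"fit_mode must be 'fit' or 'transform', got {fit_mode!r}")
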
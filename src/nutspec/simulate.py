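"""Synthetic hyperspectral scenes and reference-chemistry panels.

The real walnut dataset behind this workflow is not publicly deposited, so
every downstream stage is exercised on synthetic data with the same
statistical structure:

* **Reference panels** draw per-sample chemistry around published
  per-variety means, with spread sqrt(n) * SE so that a sample of size n
  reproduces the published standard errors. Negative draws are truncated at
  zero and the 16 acids are renormalized to sum exactly 100 (relative %).
* **Spectra** follow a Beer-Lambert encoding: each compositional component
  carries an absorptivity signature (a sum of Gaussian bands in the
  1,150-1,500 nm first-overtone region) and a kernel pixel's absorbance is
  the concentration-weighted sum, times a per-kernel multiplicative scatter
  and per-pixel path-length jitter, plus a per-kernel additive baseline and
  sensor noise. Reflectance is R = 10^(-A), and the raw sensor cube is
  encoded as raw = dark + R * (white - dark) so that two-point calibration
  inverts the encoding exactly when noise is off.
* **Scenes** place up to 10 kernels (irregular ellipses, 300-900 px on a
  256 x 320 frame) on a spectrally flat background; each group is rendered
  twice, the second acquisition at 180 deg-rotated positions with fresh
  scatter and noise, with the kernel pairing recorded.

All randomness flows from one integer seed; layout, chemistry and noise use
independent substreams so one can be held fixed while another varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cube import CalibrationFrames, HyperCube
from .composition import family_sums
from .varieties import ALL_ACIDS, VarietyProfile

#: analytes the calibration targets (concentrations read off the panel)
ANALYTE_COMPONENTS = ("total_fat", "SFA", "MUFA", "PUFA")
#: nuisance constituents varying kernel-to-kernel, never calibrated here
NUISANCE_COMPONENTS = ("moisture", "protein", "carbohydrate", "fiber")
#: all components carrying spectral signatures
COMPONENTS = ANALYTE_COMPONENTS + NUISANCE_COMPONENTS


def default_band_grid(min_nm: float = 950.0, max_nm: float = 1650.0, step: float = 3.25) -> np.ndarray:
    """Instrument-like wavelength grid (inclusive start, 3.25 nm pitch)."""
    n = int(np.floor((max_nm - min_nm) / step)) + 1
    return min_nm + step * np.arange(n)


@dataclass(frozen=True)
class SignatureSet:
    """Absorptivity signatures (absorbance per unit concentration) per component."""

    band_grid: np.ndarray
    signatures: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, sig in self.signatures.items():
            if sig.shape != self.band_grid.shape:
                raise ValueError(f"signature {name!r} does not match the band grid")
            if np.any(sig < 0):
                raise ValueError(f"signature {name!r} has negative absorptivity")

    def matrix(self, components: tuple[str, ...] = COMPONENTS) -> np.ndarray:
        missing = [c for c in components if c not in self.signatures]
        if missing:
            raise ValueError(f"no signature for component(s) {missing}")
        return np.stack([self.signatures[c] for c in components])


def _gaussians(wl: np.ndarray, bands: list[tuple[float, float, float]]) -> np.ndarray:
    sig = np.zeros_like(wl)
    for center, width, height in bands:
        sig += height * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return sig


def default_signatures(band_grid: np.ndarray | None = None) -> SignatureSet:
    """Five-component library in the NIR first-overtone region.

    The broad band on the total-fat signature stands in for the bulk
    organic matrix, keeping kernel absorbance in roughly [0.1, 1.2] over the
    kept subrange; the family signatures differ in at least one band center
    so composition is spectrally identifiable.
    """
    wl = default_band_grid() if band_grid is None else np.asarray(band_grid, dtype=np.float64)
    sigs = {
        "total_fat": _gaussians(wl, [(1210.0, 28.0, 0.50), (1390.0, 30.0, 0.40), (1320.0, 200.0, 0.35)]),
        "SFA": _gaussians(wl, [(1190.0, 18.0, 1.60), (1360.0, 22.0, 1.10)]),
        "MUFA": _gaussians(wl, [(1225.0, 16.0, 1.40), (1410.0, 20.0, 1.20), (1300.0, 25.0, 0.70)]),
        "PUFA": _gaussians(wl, [(1160.0, 20.0, 0.50), (1260.0, 30.0, 0.55), (1470.0, 25.0, 0.45)]),
        "moisture": _gaussians(wl, [(1450.0, 40.0, 2.20), (1190.0, 35.0, 0.80)]),
        "protein": _gaussians(wl, [(1180.0, 12.0, 1.00), (1510.0, 14.0, 0.90)]),
        "carbohydrate": _gaussians(wl, [(1205.0, 10.0, 0.80), (1585.0, 14.0, 0.70)]),
        "fiber": _gaussians(wl, [(1240.0, 9.0, 0.80), (1545.0, 12.0, 0.60)]),
    }
    return SignatureSet(wl, sigs)


@dataclass(frozen=True)
class NoiseConfig:
    """Noise levels of the synthetic acquisition and reference chemistry.

    Units: absorbance for sensor/baseline noise, dimensionless for the
    multiplicative terms, analyte units for the assay SDs.
    """

    sensor_sd: float = 0.005          # additive per-pixel, per-band (absorbance)
    scatter_sd: float = 0.05          # per-kernel multiplicative scatter
    baseline_sd: float = 0.02         # per-kernel additive offset (absorbance)
    pixel_jitter_sd: float = 0.02     # per-pixel path-length jitter
    structure_sd: float = 0.006       # per-kernel smooth spectral microstructure
    structure_dof: int = 12           # smooth basis functions for the above
    structure_range: tuple = (1490.0, 1650.0)  # nm window carrying the microstructure
    #: nuisance constituent concentrations: name -> (mean, sd), fractions
    nuisance: dict = field(
        default_factory=lambda: {
            "moisture": (0.040, 0.006),
            "protein": (0.150, 0.015),
            "carbohydrate": (0.140, 0.015),
            "fiber": (0.065, 0.010),
        }
    )
    assay_sd: dict = field(
        default_factory=lambda: {"total_fat": 0.5, "SFA": 0.15, "MUFA": 0.25, "PUFA": 0.30}
    )

    def __post_init__(self) -> None:
        # normalize container types so configs round-trip through YAML
        object.__setattr__(self, "structure_range", tuple(float(v) for v in self.structure_range))
        object.__setattr__(
            self, "nuisance",
            {k: (float(m), float(s)) for k, (m, s) in self.nuisance.items()},
        )
        object.__setattr__(
            self, "assay_sd", {k: float(v) for k, v in self.assay_sd.items()}
        )

    def silent(self) -> "NoiseConfig":
        """Copy with every stochastic term switched off (nuisance means kept)."""
        return replace(
            self, sensor_sd=0.0, scatter_sd=0.0, baseline_sd=0.0,
            pixel_jitter_sd=0.0, structure_sd=0.0, assay_sd={},
            nuisance={k: (m, 0.0) for k, (m, _) in self.nuisance.items()},
        )


def generate_reference_panel(
    profiles: list[VarietyProfile] | tuple[VarietyProfile, ...],
    n_per_variety: int | dict[str, int],
    seed: int,
) -> pd.DataFrame:
    """Draw a per-sample chemistry panel around per-variety means.

    Each acid is drawn independently as N(mean, n * SE^2) — so the standard
    error of a size-n variety sample targets the published SE — truncated at
    zero, then the 16 acids are renormalized to sum exactly 100. Total fat
    is drawn independently (same spread convention, no renormalization) and
    family totals are recomputed as sums of member acids. Renormalization
    induces the compositional negative correlation between acids; it also
    shrinks the realized spread of dominant acids somewhat (closure effect).
    """
    if not profiles:
        raise ValueError("no variety profiles supplied")
    rng = np.random.default_rng([int(seed), 101])
    rows = []
    sample_no = 0
    for prof in profiles:
        n = n_per_variety[prof.name] if isinstance(n_per_variety, dict) else int(n_per_variety)
        if n < 1:
            raise ValueError(f"n_per_variety must be >= 1, got {n} for {prof.name}")
        scale = np.sqrt(n)
        acid_means = np.asarray([prof.fa_means[a] for a in ALL_ACIDS])
        acid_sds = scale * np.asarray([prof.fa_ses[a] for a in ALL_ACIDS])
        acids = rng.normal(acid_means, acid_sds, size=(n, len(ALL_ACIDS)))
        np.clip(acids, 0.0, None, out=acids)
        acids *= 100.0 / acids.sum(axis=1, keepdims=True)
        fat = np.clip(rng.normal(prof.mean_total_fat, scale * prof.se_total_fat, size=n), 0.0, None)
        for i in range(n):
            row = {"sample_id": f"S{sample_no:04d}", "variety": prof.name, "total_fat": fat[i]}
            row.update({a: acids[i, j] for j, a in enumerate(ALL_ACIDS)})
            rows.append(row)
            sample_no += 1
    return family_sums(pd.DataFrame(rows))


def assay_panel(panel: pd.DataFrame, noise: NoiseConfig, seed: int) -> pd.DataFrame:
    """Overlay reference-assay measurement noise on a true-composition panel."""
    rng = np.random.default_rng([int(seed), 202])
    out = panel.copy()
    for analyte, sd in noise.assay_sd.items():
        if analyte in out.columns and sd > 0:
            out[analyte] = out[analyte] + rng.normal(0.0, sd, size=len(out))
    return out


def composition_vectors(panel: pd.DataFrame, nuisance: np.ndarray) -> np.ndarray:
    """Per-sample concentration vectors over COMPONENTS (fractions, not %)."""
    analytes = np.column_stack([panel[c].to_numpy() / 100.0 for c in ANALYTE_COMPONENTS])
    return np.column_stack([analytes, np.asarray(nuisance)])


def _draw_nuisance(rng: np.random.Generator, n: int, noise: NoiseConfig) -> np.ndarray:
    """Per-kernel nuisance constituent concentrations, truncated at zero."""
    cols = [
        np.clip(rng.normal(*noise.nuisance[name], size=n), 0.0, None)
        for name in NUISANCE_COMPONENTS
    ]
    return np.column_stack(cols)


def _structure_basis(wl: np.ndarray, dof: int, lo: float, hi: float) -> np.ndarray:
    """Smooth Gaussian-bump basis for per-kernel spectral microstructure."""
    lo = max(lo, float(wl.min()))
    hi = min(hi, float(wl.max()))
    centers = np.linspace(lo, hi, dof)
    width = (hi - lo) / dof
    return np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / width) ** 2)


def _draw_structure(rng: np.random.Generator, n: int, wl: np.ndarray, noise: NoiseConfig) -> np.ndarray:
    """Per-kernel smooth absorbance perturbations (surface/microstructure).

    These stand in for kernel-to-kernel spectral variability not explained
    by bulk composition — surface texture and internal scattering riding on
    the steep long-wavelength water/OH shoulder — and are what gives real
    spectra their high effective rank. They live in ``structure_range`` so
    the first-overtone composition bands stay quantitatively informative.
    """
    if noise.structure_sd <= 0:
        return np.zeros((n, wl.size))
    coefs = rng.normal(0.0, noise.structure_sd, size=(n, noise.structure_dof))
    return coefs @ _structure_basis(wl, noise.structure_dof, *noise.structure_range)


def generate_spectra(
    panel: pd.DataFrame,
    signatures: SignatureSet | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    n_pixels: int = 400,
    n_acquisitions: int = 2,
) -> pd.DataFrame:
    """Per-kernel mean absorbance spectra, bypassing the imaging stage.

    Emulates what segmentation + ROI averaging would deliver: for each
    sample and acquisition, the mean over ``n_pixels`` kernel pixels of the
    pixel-level absorbance model, averaged over acquisitions. Pixel-level
    jitter and sensor noise enter through their sqrt(n_pixels)-reduced
    means, so the returned table is statistically identical to averaging a
    rendered ROI of the same size.
    """
    signatures = signatures or default_signatures()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng([int(seed), 303])
    S = signatures.matrix()  # (5, B)
    nuisance = _draw_nuisance(rng, len(panel), noise)
    comp = composition_vectors(panel, nuisance)
    base = comp @ S  # (N, B) noiseless kernel absorbance
    n, b = base.shape
    structure = _draw_structure(rng, n, signatures.band_grid, noise)  # kernel property
    acc = np.zeros((n, b))
    for _ in range(n_acquisitions):
        scatter = 1.0 + rng.normal(0.0, noise.scatter_sd, size=(n, 1))
        baseline = rng.normal(0.0, noise.baseline_sd, size=(n, 1))
        jitter_mean = rng.normal(0.0, noise.pixel_jitter_sd / np.sqrt(n_pixels), size=(n, 1))
        sensor_mean = rng.normal(0.0, noise.sensor_sd / np.sqrt(n_pixels), size=(n, b))
        acc += base * (1.0 + jitter_mean) * scatter + structure + baseline + sensor_mean
    acc /= n_acquisitions
    out = pd.DataFrame(acc, columns=[f"{w:.2f}" for w in signatures.band_grid])
    out.insert(0, "variety", panel["variety"].to_numpy())
    out.insert(0, "sample_id", panel["sample_id"].to_numpy())
    return out


def spectra_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a spectrum table into (matrix, wavelength grid)."""
    band_cols = [c for c in table.columns if c not in ("sample_id", "variety", "area")]
    wl = np.asarray([float(c) for c in band_cols])
    return table[band_cols].to_numpy(dtype=np.float64), wl


# ---------------------------------------------------------------------------
# full scene rendering


@dataclass
class SceneTruth:
    """Ground truth of one rendered acquisition."""

    mask: np.ndarray                      # (lines, pixels) int; 0 = background
    sample_ids: dict[int, str]            # kernel id -> panel sample id
    compositions: dict[int, np.ndarray]   # kernel id -> component concentrations
    pairing: dict[int, int] | None = None  # id here -> id in the sister acquisition


@dataclass
class Acquisition:
    raw: HyperCube
    frames: CalibrationFrames
    truth: SceneTruth
    reflectance_truth: np.ndarray | None = None  # noiseless-encoded R (lines, px, B)


@dataclass
class ScenePair:
    a: Acquisition
    b: Acquisition
    pairing: dict[int, int]  # kernel id in A -> kernel id in B


def _kernel_footprint(rng, shape, center, area):
    """Pixel coordinates of one irregular-ellipse kernel."""
    ratio = rng.uniform(0.75, 1.3)
    r0 = np.sqrt(area / (np.pi * ratio))
    ra, rb = r0 * ratio, r0
    angle = rng.uniform(0.0, np.pi)
    phase3, phase5 = rng.uniform(0.0, 2 * np.pi, size=2)
    amp3, amp5 = rng.uniform(0.02, 0.08), rng.uniform(0.01, 0.05)
    rmax = int(np.ceil(max(ra, rb) * 1.3)) + 2
    cy, cx = center
    yy, xx = np.mgrid[
        max(0, cy - rmax) : min(shape[0], cy + rmax + 1),
        max(0, cx - rmax) : min(shape[1], cx + rmax + 1),
    ]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / ra
    v = (-sa * dx + ca * dy) / rb
    theta = np.arctan2(v, u)
    bound = 1.0 + amp3 * np.sin(3 * theta + phase3) + amp5 * np.sin(5 * theta + phase5)
    inside = u**2 + v**2 <= bound**2
    return yy[inside], xx[inside]


def _layout(rng, shape, n_kernels, area_range):
    """Centers and footprints for up to 10 kernels in a 5 x 2 tray layout."""
    lines, pixels = shape
    cells = [(r, c) for r in range(2) for c in range(5)][:n_kernels]
    cell_h, cell_w = lines // 2, pixels // 5
    placements = []
    for r, c in cells:
        area = rng.uniform(*area_range)
        cy = int(r * cell_h + cell_h / 2 + rng.uniform(-0.12, 0.12) * cell_h)
        cx = int(c * cell_w + cell_w / 2 + rng.uniform(-0.12, 0.12) * cell_w)
        placements.append(((cy, cx), area))
    return placements


def _background_absorbance(wl: np.ndarray) -> np.ndarray:
    """Flat, spectrally distinct polyethylene-tray background."""
    r_bg = 0.50 + 0.08 * (wl - wl.mean()) / np.ptp(wl)
    return -np.log10(r_bg)


def _lamp_white(wl: np.ndarray, pixels: int) -> np.ndarray:
    """White-reference counts: smooth lamp spectrum with mild vignetting."""
    lamp = 3500.0 * (1.0 - 0.25 * ((wl - 1300.0) / 500.0) ** 2)
    vignette = 1.0 - 0.05 * (np.linspace(-1, 1, pixels) ** 2)
    return vignette[:, None] * lamp[None, :]


def _render_acquisition(
    footprints, panel, comp, signatures, noise, rng, shape, structure=None
) -> Acquisition:
    """Render one acquisition from fixed kernel footprints + fresh noise.

    ``footprints`` is a list of (ys, xs) pixel coordinate arrays, one per
    panel row. Kernel ids are assigned in reading order of the centroids.
    """
    wl = signatures.band_grid
    b = wl.size
    lines, pixels = shape
    # noiseless scenes render in double precision so two-point calibration
    # inverts the encoding to 1e-10; noisy scenes use single precision (the
    # sensor noise floor dwarfs float32 rounding) for speed
    noisy = any((noise.sensor_sd, noise.scatter_sd, noise.baseline_sd, noise.pixel_jitter_sd))
    dtype = np.float32 if noisy else np.float64
    mask = np.zeros(shape, dtype=np.int32)
    S = signatures.matrix()
    a_bg = _background_absorbance(wl).astype(dtype)
    absorb = np.empty((lines, pixels, b), dtype=dtype)
    absorb[:] = a_bg
    centroids = [(ys.mean(), xs.mean()) for ys, xs in footprints]
    order = np.argsort([cy * pixels + cx for cy, cx in centroids], kind="stable")
    sample_ids, comps = {}, {}
    for rank, idx in enumerate(order, start=1):
        ys, xs = footprints[idx]
        base = comp[idx] @ S
        if structure is not None:
            base = base + structure[idx]
        scatter = 1.0 + (rng.normal(0.0, noise.scatter_sd) if noise.scatter_sd else 0.0)
        baseline = rng.normal(0.0, noise.baseline_sd) if noise.baseline_sd else 0.0
        jitter = (
            rng.normal(0.0, noise.pixel_jitter_sd, size=ys.size)
            if noise.pixel_jitter_sd
            else np.zeros(ys.size)
        )
        absorb[ys, xs, :] = base[None, :] * (1.0 + jitter)[:, None] * scatter + baseline
        mask[ys, xs] = rank
        sample_ids[rank] = str(panel["sample_id"].iloc[idx])
        comps[rank] = comp[idx]
    if noise.sensor_sd:
        sensor = rng.standard_normal(absorb.shape, dtype=dtype)
        sensor *= noise.sensor_sd
        absorb += sensor
    refl = np.exp(absorb * dtype(-np.log(10.0)))
    np.clip(refl, 1e-4, 1.5, out=refl)

    span = _lamp_white(wl, pixels).astype(dtype)  # (pixels, bands) lamp counts
    dark = np.broadcast_to(np.asarray(80.0, dtype=dtype), (lines, pixels, b))
    white = np.broadcast_to(span + dtype(80.0), (lines, pixels, b))
    raw = refl.copy()
    raw *= span[None, :, :]
    raw += dtype(80.0)
    return Acquisition(
        raw=HyperCube(raw, wl, "raw"),
        frames=CalibrationFrames(dark, white),
        truth=SceneTruth(mask, sample_ids, comps),
        reflectance_truth=refl,
    )


def generate_scene(
    panel_rows: pd.DataFrame,
    signatures: SignatureSet | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (256, 320),
    area_range: tuple[float, float] = (300.0, 900.0),
) -> ScenePair:
    """Render one tray of up to 10 kernels as two rotated acquisitions.

    The second acquisition re-renders the same kernels at 180 deg-rotated
    positions with fresh scatter, jitter and noise; the id pairing between
    the two acquisitions is returned alongside both ground-truth masks.
    """
    signatures = signatures or default_signatures()
    noise = noise or NoiseConfig()
    n = len(panel_rows)
    if n < 1 or n > 10:
        raise ValueError(f"a scene holds 1-10 kernels, got {n}")
    layout_rng = np.random.default_rng([int(seed), 11])
    noise_rng_a = np.random.default_rng([int(seed), 12])
    noise_rng_b = np.random.default_rng([int(seed), 13])
    chem_rng = np.random.default_rng([int(seed), 14])

    if set(COMPONENTS) - set(signatures.signatures):
        raise ValueError("signature set lacks a component signature")
    nuisance = _draw_nuisance(chem_rng, n, noise)
    comp = composition_vectors(panel_rows, nuisance)
    structure = _draw_structure(chem_rng, n, signatures.band_grid, noise)
    placements = _layout(layout_rng, shape, n, area_range)
    footprints_a = [
        _kernel_footprint(layout_rng, shape, center, area) for center, area in placements
    ]
    footprints_b = [
        (shape[0] - 1 - ys, shape[1] - 1 - xs) for ys, xs in footprints_a
    ]
    acq_a = _render_acquisition(footprints_a, panel_rows, comp, signatures, noise, noise_rng_a, shape, structure)
    acq_b = _render_acquisition(footprints_b, panel_rows, comp, signatures, noise, noise_rng_b, shape, structure)
    by_sample_b = {v: k for k, v in acq_b.truth.sample_ids.items()}
    pairing = {ka: by_sample_b[sid] for ka, sid in acq_a.truth.sample_ids.items()}
    acq_a.truth.pairing = pairing
    acq_b.truth.pairing = {v: k for k, v in pairing.items()}
    return ScenePair(acq_a, acq_b, pairing)


def scene_batches(panel: pd.DataFrame, group_size: int = 10):
    """Split a panel into consecutive tray groups of at most ``group_size``."""
    for start in range(0, len(panel), group_size):
        yield panel.iloc[start : start + group_size]


# ---------------------------------------------------------------------------
# on-disk scene exchange (ENVI dialect + JSON truth)


def write_scene(pair: ScenePair, directory, stem: str, dtype: str = "float32") -> None:
    """Persist both acquisitions of a scene: raw/dark/white cubes + truth."""
    import json
    from pathlib import Path

    from .cube import write_cube

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tag, acq in (("a", pair.a), ("b", pair.b)):
        wl = acq.raw.wavelengths
        write_cube(acq.raw, directory / f"{stem}_{tag}_raw.hdr", dtype=dtype)
        # frames are per-pixel-column references; one line suffices on disk
        write_cube(HyperCube(acq.frames.dark[:1].copy(), wl, "raw"),
                   directory / f"{stem}_{tag}_dark.hdr", dtype=dtype)
        write_cube(HyperCube(acq.frames.white[:1].copy(), wl, "raw"),
                   directory / f"{stem}_{tag}_white.hdr", dtype=dtype)
        write_cube(HyperCube(acq.truth.mask[:, :, None].astype(float), np.asarray([0.0]), "raw"),
                   directory / f"{stem}_{tag}_truthmask.hdr", dtype="int32")
        payload = {
            "sample_ids": {str(k): v for k, v in acq.truth.sample_ids.items()},
            "compositions": {str(k): v.tolist() for k, v in acq.truth.compositions.items()},
            "pairing": {str(k): v for k, v in (acq.truth.pairing or {}).items()},
        }
        (directory / f"{stem}_{tag}_truth.json").write_text(json.dumps(payload))


def read_acquisition(directory, stem: str, tag: str) -> Acquisition:
    """Load one persisted acquisition (raw cube, frames, truth)."""
    import json
    from pathlib import Path

    from .cube import read_cube

    directory = Path(directory)
    raw = read_cube(directory / f"{stem}_{tag}_raw.hdr")
    dark = read_cube(directory / f"{stem}_{tag}_dark.hdr")
    white = read_cube(directory / f"{stem}_{tag}_white.hdr")
    mask = read_cube(directory / f"{stem}_{tag}_truthmask.hdr").data[:, :, 0].astype(np.int32)
    payload = json.loads((directory / f"{stem}_{tag}_truth.json").read_text())
    truth = SceneTruth(
        mask=mask,
        sample_ids={int(k): v for k, v in payload["sample_ids"].items()},
        compositions={int(k): np.asarray(v) for k, v in payload["compositions"].items()},
        pairing={int(k): v for k, v in payload["pairing"].items()} or None,
    )
    return Acquisition(raw=raw, frames=CalibrationFrames(dark.data, white.data), truth=truth)
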
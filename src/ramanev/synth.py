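"""Synthetic single-EV spectra and hyperspectral cell phantoms.

Every downstream stage of the pipeline is tested against phantoms generated
here, with complete ground truth. A phantom cell image is a linear mixture of
Gaussian-peak component signatures (nuclei, nucleoli, lipids, proteins,
whole-cell C–H, deuterium) placed on geometric subcellular masks, plus a
slowly varying autofluorescence baseline, a system background common to every
pixel (substrate/buffer bands that survive baseline filtering), planted
sub-resolution deuterium-positive EV pixels, and optional Gaussian noise.

EVs (~120 nm) are far below the 500 nm pixel size, so each planted EV cluster
is a single-pixel point source; clusters are built from adjacent pixels. All
randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectral import HyperCube, SpectralAxis, Spectrum

__all__ = [
    "BasisComponent",
    "BaselineParams",
    "EvPixel",
    "CellPhantomSpec",
    "PhantomTruth",
    "TrapSimParams",
    "default_components",
    "gaussian_peak",
    "component_signature",
    "simulate_ev_spectrum",
    "simulate_cell_cube",
    "make_uptake_phantom_spec",
    "UPTAKE_COHORTS",
]

SILENT_REGION = (1800.0, 2800.0)

#: univariate band windows (cm⁻¹) used for component assignment checks
COMPONENT_WINDOWS = {
    "nuclei": (775.0, 805.0),
    "nucleoli": (985.0, 1015.0),
    "lipids": (1425.0, 1485.0),
    "proteins": (1635.0, 1685.0),
    "whole_cell": (2800.0, 3000.0),
    "deuterium": (2025.0, 2275.0),
}


def gaussian_peak(axis: SpectralAxis, center: float, sigma: float, amplitude: float) -> np.ndarray:
    """Gaussian line shape in wavenumber (analytically integrable: area =
    amplitude * sigma * sqrt(2*pi))."""
    x = axis.values
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


@dataclass(frozen=True)
class BasisComponent:
    """Named subcellular spectral signature: a sum of Gaussian peaks.

    ``peaks`` is a sequence of (center cm⁻¹, sigma cm⁻¹, relative amplitude).
    A named component must place at least one peak inside its band window;
    deuterium peaks must lie in the Raman silent region (1800–2800 cm⁻¹)
    where endogenous biomolecules are dark.
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"component {self.name!r} has no peaks")
        for center, sigma, amp in self.peaks:
            if sigma <= 0 or amp < 0:
                raise ValueError(
                    f"component {self.name!r}: sigma must be > 0 and amplitude >= 0"
                )
        if self.name in COMPONENT_WINDOWS:
            lo, hi = COMPONENT_WINDOWS[self.name]
            if not any(lo <= c <= hi for c, _, _ in self.peaks):
                raise ValueError(
                    f"component {self.name!r} has no peak inside its band "
                    f"window [{lo}, {hi}] cm-1"
                )
        if self.name == "deuterium":
            lo, hi = SILENT_REGION
            for center, _, _ in self.peaks:
                if not lo <= center <= hi:
                    raise ValueError(
                        "deuterium peaks must lie in the silent region "
                        f"[{lo}, {hi}] cm-1, got {center}"
                    )


def component_signature(component: BasisComponent, axis: SpectralAxis) -> np.ndarray:
    sig = np.zeros(axis.n_bins)
    for center, sigma, amp in component.peaks:
        sig += gaussian_peak(axis, center, sigma, amp)
    return sig


def default_components() -> dict[str, BasisComponent]:
    """Default six-component basis.

    Fingerprint peaks sit inside the standard band windows (DNA phosphodiester
    ~790, phenylalanine ~1000, CH2 bend ~1455, amide I ~1660); lipids and
    proteins additionally contribute to the 2800–3000 cm⁻¹ C–H stretch, and a
    broad whole-cell C–H signature covers the full cell footprint. The
    deuterium (C–D) signature is a single band at 2140 cm⁻¹ in the silent
    region.
    """
    return {
        "nuclei": BasisComponent("nuclei", ((790.0, 12.0, 1.0), (1090.0, 16.0, 0.35))),
        "nucleoli": BasisComponent("nucleoli", ((1000.0, 10.0, 1.2), (1030.0, 12.0, 0.3))),
        "lipids": BasisComponent(
            "lipids", ((1455.0, 16.0, 1.0), (2850.0, 28.0, 0.9), (2885.0, 24.0, 0.5))
        ),
        "proteins": BasisComponent(
            "proteins", ((1660.0, 18.0, 1.0), (1450.0, 14.0, 0.3), (2930.0, 32.0, 0.6))
        ),
        "whole_cell": BasisComponent("whole_cell", ((2900.0, 45.0, 1.0), (1445.0, 20.0, 0.2))),
        "deuterium": BasisComponent("deuterium", ((2140.0, 25.0, 1.0),)),
    }


@dataclass(frozen=True)
class BaselineParams:
    """Slow additive autofluorescence background.

    Cubic polynomial in the scaled coordinate u = (nu - nu_min)/(nu_max -
    nu_min), plus an optional broad Gaussian hump. Magnitudes are free
    parameters of the phantom; defaults put the background on the same order
    as the Raman bands but vary it over hundreds of cm⁻¹, which is what the
    morphological 'shape' filter is built to remove.
    """

    poly_coeffs: tuple[float, ...] = (2.0, 1.5, 0.8, -0.6)  # c0 + c1 u + c2 u^2 + c3 u^3
    hump_amplitude: float = 0.3
    hump_center: float = 1400.0
    hump_sigma: float = 800.0

    def evaluate(self, axis: SpectralAxis) -> np.ndarray:
        x = axis.values
        u = (x - x[0]) / (x[-1] - x[0])
        baseline = np.zeros_like(x)
        for power, coeff in enumerate(self.poly_coeffs):
            baseline += coeff * u**power
        if self.hump_amplitude:
            baseline += gaussian_peak(axis, self.hump_center, self.hump_sigma, self.hump_amplitude)
        return baseline


#: system (substrate/buffer) background peaks that survive baseline filtering:
#: (center, sigma, amplitude)
DEFAULT_SYSTEM_PEAKS: tuple[tuple[float, float, float], ...] = (
    (490.0, 18.0, 1.2),
    (1050.0, 22.0, 0.8),
    (3250.0, 60.0, 0.8),
)

PLACEMENTS = ("inside", "membrane", "outside")


@dataclass(frozen=True)
class EvPixel:
    """One planted sub-resolution deuterium-positive pixel."""

    row: int
    col: int
    amplitude: float
    placement: str  # inside | membrane | outside

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown EV placement {self.placement!r}")
        if self.amplitude < 0:
            raise ValueError("EV amplitude must be >= 0")


@dataclass
class CellPhantomSpec:
    """Geometry and signal model of one synthetic cell image."""

    shape: tuple[int, int] = (48, 48)
    pixel_size_um: float = 0.5
    cell_center: tuple[float, float] | None = None
    cell_radii: tuple[float, float] | None = None
    nucleus_offset: tuple[float, float] = (-2.0, 1.0)
    nucleus_radius_frac: float = 0.45
    component_amplitudes: dict[str, float] = field(
        default_factory=lambda: {
            "nuclei": 1.6,
            "nucleoli": 1.8,
            "lipids": 1.5,
            "proteins": 1.4,
            "whole_cell": 2.0,
        }
    )
    components: dict[str, BasisComponent] = field(default_factory=default_components)
    baseline: BaselineParams = field(default_factory=BaselineParams)
    system_peaks: tuple[tuple[float, float, float], ...] = DEFAULT_SYSTEM_PEAKS
    system_offset: float = 0.5  # flat part of the system background
    ev_pixels: tuple[EvPixel, ...] = ()
    deuterium_sigma: float = 25.0  # width of the planted C-D band
    #: cell-signature attenuation on boundary pixels, which straddle the cell
    #: edge (partial-volume effect of the confocal voxel)
    membrane_attenuation: float = 0.5
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 32 or w < 32:
            raise ValueError("phantom image must be at least 32 x 32 pixels")


@dataclass
class PhantomTruth:
    """Complete ground truth for one simulated cube."""

    cell_mask: np.ndarray
    component_masks: dict[str, np.ndarray]
    ev_pixels: tuple[EvPixel, ...]
    baseline_params: BaselineParams
    noise_sd: float
    seed: int
    clean_signal: np.ndarray  # noise-free component+EV mixture, no background
    background: np.ndarray  # baseline + system spectrum added to every pixel

    @property
    def membrane_mask(self) -> np.ndarray:
        from scipy.ndimage import binary_erosion

        eroded = binary_erosion(self.cell_mask, structure=np.ones((3, 3)))
        return self.cell_mask & ~eroded

    def ev_table(self):
        """Truth table as a DataFrame (row, col, amplitude, placement)."""
        import pandas as pd

        return pd.DataFrame(
            [(p.row, p.col, p.amplitude, p.placement) for p in self.ev_pixels],
            columns=["row", "col", "amplitude", "placement"],
        )


@dataclass(frozen=True)
class TrapSimParams:
    """Parameters for simulated optically trapped single-EV spectra."""

    cd_to_ch_ratio: float = 0.5
    n_spectra: int = 1
    noise_sd: float = 0.0
    seed: int = 0
    ch_sigma: float = 18.0
    cd_sigma: float = 20.0

    def __post_init__(self) -> None:
        if self.cd_to_ch_ratio < 0:
            raise ValueError("cd_to_ch_ratio must be >= 0 (0 means unlabelled)")
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


CH_POSITION = 1440.0
CD_POSITION = 2140.0


def simulate_ev_spectrum(params: TrapSimParams, axis: SpectralAxis) -> list[Spectrum]:
    """Simulate trapped single-EV spectra with a programmed C–D/C–H ratio.

    The noise-free intensity at the bin nearest 2140 cm⁻¹ divided by the
    intensity at the bin nearest 1440 cm⁻¹ equals ``cd_to_ch_ratio`` exactly.
    Deterministic given ``params.seed``.
    """
    for pos in (CH_POSITION, CD_POSITION):
        if not axis.covers(pos):
            raise ValueError(f"axis does not cover the {pos} cm-1 peak")

    # EV body: lipid-rich C-H profile plus minor protein band
    base = (
        gaussian_peak(axis, CH_POSITION, params.ch_sigma, 1.0)
        + gaussian_peak(axis, 2930.0, 40.0, 0.8)
        + gaussian_peak(axis, 1660.0, 20.0, 0.3)
    )
    ch_bin = axis.nearest_bin(CH_POSITION)
    cd_bin = axis.nearest_bin(CD_POSITION)
    cd_unit = gaussian_peak(axis, CD_POSITION, params.cd_sigma, 1.0)
    if params.cd_to_ch_ratio > 0:
        # scale the C-D band so the nearest-bin intensity ratio is exact
        target = params.cd_to_ch_ratio * base[ch_bin]
        cd = cd_unit * ((target - base[cd_bin]) / cd_unit[cd_bin])
        clean = base + cd
    else:
        clean = base

    rng = np.random.default_rng(params.seed)
    spectra = []
    for _ in range(params.n_spectra):
        noisy = clean + rng.normal(0.0, params.noise_sd, axis.n_bins) if params.noise_sd else clean.copy()
        spectra.append(Spectrum(axis, noisy))
    return spectra


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], radii: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _build_masks(spec: CellPhantomSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    h, w = spec.shape
    center = spec.cell_center if spec.cell_center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    radii = spec.cell_radii if spec.cell_radii is not None else (0.38 * h, 0.40 * w)
    cell = _ellipse_mask(spec.shape, center, radii)

    nuc_center = (center[0] + spec.nucleus_offset[0], center[1] + spec.nucleus_offset[1])
    nuc_radii = (radii[0] * spec.nucleus_radius_frac, radii[1] * spec.nucleus_radius_frac)
    nucleus = _ellipse_mask(spec.shape, nuc_center, nuc_radii) & cell

    r_nucleolus = max(1.5, 0.25 * min(nuc_radii))
    nucleoli = (
        _disk_mask(spec.shape, (nuc_center[0] - 0.4 * nuc_radii[0], nuc_center[1]), r_nucleolus)
        | _disk_mask(spec.shape, (nuc_center[0] + 0.4 * nuc_radii[0], nuc_center[1] + 0.3 * nuc_radii[1]), r_nucleolus)
    ) & nucleus

    cytoplasm = cell & ~nucleus
    r_droplet = max(1.5, 0.12 * min(radii))
    lipids = (
        _disk_mask(spec.shape, (center[0], center[1] + 0.65 * radii[1]), r_droplet)
        | _disk_mask(spec.shape, (center[0] + 0.55 * radii[0], center[1] - 0.35 * radii[1]), r_droplet)
        | _disk_mask(spec.shape, (center[0] - 0.55 * radii[0], center[1] - 0.45 * radii[1]), r_droplet)
    ) & cytoplasm

    masks = {
        "nuclei": nucleus,
        "nucleoli": nucleoli,
        "lipids": lipids,
        "proteins": cytoplasm,
        "whole_cell": cell,
    }
    return cell, masks


def _validate_ev_placements(ev_pixels, cell_mask: np.ndarray, membrane: np.ndarray) -> None:
    h, w = cell_mask.shape
    interior = cell_mask & ~membrane
    for p in ev_pixels:
        if not (0 <= p.row < h and 0 <= p.col < w):
            raise ValueError(f"EV pixel ({p.row}, {p.col}) outside the image frame")
        if p.placement == "inside" and not interior[p.row, p.col]:
            raise ValueError(
                f"EV pixel ({p.row}, {p.col}) declared inside but not strictly "
                "within the cell mask"
            )
        if p.placement == "membrane" and not membrane[p.row, p.col]:
            raise ValueError(
                f"EV pixel ({p.row}, {p.col}) declared on the membrane but not "
                "on the mask boundary"
            )
        if p.placement == "outside" and cell_mask[p.row, p.col]:
            raise ValueError(
                f"EV pixel ({p.row}, {p.col}) declared outside but lies on the "
                "cell mask"
            )


def simulate_cell_cube(
    spec: CellPhantomSpec, axis: SpectralAxis, seed: int = 0
) -> tuple[HyperCube, PhantomTruth]:
    """Render one phantom cell image cube with full ground truth.

    Each pixel spectrum is the mask-weighted sum of component signatures, plus
    the shared autofluorescence baseline and system background, plus planted
    EV deuterium signatures, plus i.i.d. Gaussian noise. Bit-identical for a
    given (spec, axis, seed).
    """
    cell_mask, masks = _build_masks(spec)
    from scipy.ndimage import binary_erosion

    membrane = cell_mask & ~binary_erosion(cell_mask, structure=np.ones((3, 3)))
    _validate_ev_placements(spec.ev_pixels, cell_mask, membrane)

    h, w = spec.shape
    nb = axis.n_bins
    clean = np.zeros((h, w, nb))
    for name, mask in masks.items():
        amp = spec.component_amplitudes.get(name, 0.0)
        if amp == 0.0 or not mask.any():
            continue
        sig = component_signature(spec.components[name], axis)
        clean[mask] += amp * sig
    if spec.membrane_attenuation != 1.0:
        clean[membrane] *= spec.membrane_attenuation

    cd_sig = gaussian_peak(axis, CD_POSITION, spec.deuterium_sigma, 1.0)
    for p in spec.ev_pixels:
        clean[p.row, p.col] += p.amplitude * cd_sig

    background = spec.baseline.evaluate(axis) + spec.system_offset
    for center, sigma, amp in spec.system_peaks:
        background += gaussian_peak(axis, center, sigma, amp)

    data = clean + background
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, spec.noise_sd, data.shape)

    cube = HyperCube(axis, data, spec.pixel_size_um)
    truth = PhantomTruth(
        cell_mask=cell_mask,
        component_masks=masks,
        ev_pixels=tuple(spec.ev_pixels),
        baseline_params=spec.baseline,
        noise_sd=spec.noise_sd,
        seed=seed,
        clean_signal=clean,
        background=background,
    )
    return cube, truth


# ---------------------------------------------------------------------------
# uptake cohort phantoms (internalised vs surface-bound vs low-uptake)
# ---------------------------------------------------------------------------

#: planted uptake conditions per cohort: number of EV cluster sites per
#: placement, their per-pixel deuterium amplitudes, and the minimum interior
#: depth (pixels from the membrane) for "inside" sites
UPTAKE_COHORTS = {
    "internalised": dict(n_inside=6, n_membrane=0, n_outside=1, amp_inside=2.0, amp_other=1.0, min_depth=4),
    "surface_bound": dict(n_inside=2, n_membrane=3, n_outside=3, amp_inside=1.5, amp_other=1.5, min_depth=1),
    "low_uptake": dict(n_inside=1, n_membrane=1, n_outside=5, amp_inside=1.0, amp_other=1.5, min_depth=1),
}


class _ClusterSampler:
    """Sample 2-pixel EV cluster sites (adjacent pixel pairs) from candidate
    masks, without overlap between sites.

    Detected deuterium signal in real images corresponds to clusters of EVs
    spanning more than one pixel, so planted sites are adjacent pairs; this
    also lets isolated-pixel pruning separate planted signal from noise.
    """

    def __init__(self, rng: np.random.Generator, shape: tuple[int, int]):
        self.rng = rng
        self.used = np.zeros(shape, dtype=bool)

    def sample(
        self,
        ev_pixels: list[EvPixel],
        first_mask: np.ndarray,
        second_mask: np.ndarray,
        n_sites: int,
        amplitude: float,
        placement: str,
    ) -> None:
        for _ in range(n_sites):
            # pairs: (r, c) in first_mask with an 8-neighbour in second_mask
            placed = False
            candidates = np.argwhere(first_mask & ~self.used)
            order = self.rng.permutation(len(candidates))
            for idx in order:
                r, c = map(int, candidates[idx])
                neigh = [
                    (r + dr, c + dc)
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if (dr, dc) != (0, 0)
                ]
                self.rng.shuffle(neigh)
                for r2, c2 in neigh:
                    if (
                        0 <= r2 < second_mask.shape[0]
                        and 0 <= c2 < second_mask.shape[1]
                        and second_mask[r2, c2]
                        and not self.used[r2, c2]
                    ):
                        for rr, cc in ((r, c), (r2, c2)):
                            ev_pixels.append(EvPixel(rr, cc, amplitude, placement))
                            self.used[rr, cc] = True
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                raise ValueError(f"not enough candidate pixel pairs for placement {placement!r}")


def make_uptake_phantom_spec(
    cohort: str,
    seed: int = 0,
    shape: tuple[int, int] = (48, 48),
    noise_sd: float = 0.1,
) -> CellPhantomSpec:
    """Phantom spec for one uptake cohort, with 2-pixel EV cluster sites
    sampled at the planted depths/placements for that cohort.

    ``internalised`` plants most deuterium amplitude deep inside the cell
    (EV uptake at 37 °C), ``surface_bound`` concentrates it on and just
    outside the membrane (uptake blocked at 4 °C), and ``low_uptake`` plants
    little amplitude, mostly outside (poorly interacting recipient cells).
    """
    if cohort not in UPTAKE_COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}; expected one of {sorted(UPTAKE_COHORTS)}")
    cfg = UPTAKE_COHORTS[cohort]
    base = CellPhantomSpec(shape=shape, noise_sd=noise_sd)
    cell_mask, _ = _build_masks(base)
    from scipy.ndimage import binary_erosion, distance_transform_edt

    membrane = cell_mask & ~binary_erosion(cell_mask, structure=np.ones((3, 3)))
    depth = distance_transform_edt(cell_mask & ~membrane)
    outside_dist = distance_transform_edt(~cell_mask)

    rng = np.random.default_rng(seed)
    ev_pixels: list[EvPixel] = []
    sampler = _ClusterSampler(rng, base.shape)

    deep = depth >= cfg["min_depth"]
    sampler.sample(ev_pixels, deep, deep, cfg["n_inside"], cfg["amp_inside"], "inside")
    if cfg["n_membrane"]:
        sampler.sample(ev_pixels, membrane, membrane, cfg["n_membrane"], cfg["amp_other"], "membrane")
    # outside sites near (but clear of) the cell, as surface-shed signal
    ring = (outside_dist >= 2) & (outside_dist <= 6)
    sampler.sample(ev_pixels, ring, ring, cfg["n_outside"], cfg["amp_other"], "outside")

    return replace(base, ev_pixels=tuple(ev_pixels))


#: default mixing weights (cell background, EV signature) per uptake cohort:
#: internalised pixels carry strong surrounding-cell protein/lipid signal,
#: surface-bound pixels are deuterium-dominant with little cell background
UPTAKE_SPECTRA_MIXING = {
    "internalised": (1.0, 0.6),
    "surface_bound": (0.25, 1.0),
}


def simulate_uptake_cohort_spectra(
    axis: SpectralAxis,
    n_per_cohort: int = 40,
    noise_sd: float = 0.02,
    seed: int = 0,
    mixing: dict[str, tuple[float, float]] | None = None,
):
    """Synthetic deuterium-positive pixel spectra for uptake cohorts.

    Each spectrum is ``cell_w * a * cell_background + ev_w * b * ev_signature
    + noise`` with per-spectrum lognormal weight jitter (a, b), followed by
    area normalization — the input expected by the PCA separation analysis.
    Returns (spectra array, cohort labels).
    """
    from .preprocess import auc_normalize

    mixing = mixing or UPTAKE_SPECTRA_MIXING
    comps = default_components()
    cell_bg = (
        1.4 * component_signature(comps["proteins"], axis)
        + 1.5 * component_signature(comps["lipids"], axis)
        + 2.0 * component_signature(comps["whole_cell"], axis)
    )
    ev_sig = (
        gaussian_peak(axis, CD_POSITION, 25.0, 1.0)
        + gaussian_peak(axis, 2930.0, 40.0, 0.4)
        + gaussian_peak(axis, CH_POSITION, 18.0, 0.3)
    )
    rng = np.random.default_rng(seed)
    spectra, labels = [], []
    for cohort, (cell_w, ev_w) in mixing.items():
        for _ in range(n_per_cohort):
            a, b = rng.lognormal(0.0, 0.15, 2)
            y = cell_w * a * cell_bg + ev_w * b * ev_sig
            if noise_sd:
                y = y + rng.normal(0.0, noise_sd, axis.n_bins)
            spectra.append(auc_normalize(Spectrum(axis, y)).intensities)
            labels.append(cohort)
    return np.array(spectra), np.array(labels)


def make_partition_phantom_spec(
    n_inside_sites: int,
    n_outside_sites: int,
    seed: int = 0,
    amplitude: float = 2.0,
    shape: tuple[int, int] = (48, 48),
    noise_sd: float = 0.0,
) -> CellPhantomSpec:
    """Phantom with a programmed inside-amplitude fraction.

    All EV cluster sites carry the same per-pixel amplitude, so the planted
    inside fraction is n_inside_sites / (n_inside_sites + n_outside_sites).
    """
    base = CellPhantomSpec(shape=shape, noise_sd=noise_sd)
    cell_mask, _ = _build_masks(base)
    from scipy.ndimage import binary_erosion, distance_transform_edt

    membrane = cell_mask & ~binary_erosion(cell_mask, structure=np.ones((3, 3)))
    depth = distance_transform_edt(cell_mask & ~membrane)
    outside_dist = distance_transform_edt(~cell_mask)

    rng = np.random.default_rng(seed)
    ev_pixels: list[EvPixel] = []
    sampler = _ClusterSampler(rng, base.shape)
    deep = depth >= 3
    if n_inside_sites:
        sampler.sample(ev_pixels, deep, deep, n_inside_sites, amplitude, "inside")
    ring = (outside_dist >= 2) & (outside_dist <= 6)
    if n_outside_sites:
        sampler.sample(ev_pixels, ring, ring, n_outside_sites, amplitude, "outside")
    return replace(base, ev_pixels=tuple(ev_pixels))
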
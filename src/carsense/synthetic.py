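"""Synthetic phantom cells and hyperspectral cubes with known composition.

Real multiplex CARS measurements of primary cells are not redistributable, so
every downstream stage is exercised against phantoms: circular cells with
cytoplasm / nucleoplasm / nucleolus regions whose amide-region spectra are
mixtures of the three Gaussian band components (purine 1570, alpha-helix 1650,
beta-sheet 1667 cm^-1) plus an aliphatic CH band near 2933 cm^-1 and an
optional water band at 1640 cm^-1.  "Senescent" cells are binucleate with
enlarged, beta-sheet-rich nucleoli so that their amide I peak sits above
1660 cm^-1, the spectroscopic signature of amyloid-like aggregates, while
control cytoplasm peaks at the canonical 1653 cm^-1.

Cubes can be produced directly in the Im[chi3] domain (``im_domain``) or as
raw CARS intensity |chi_NR + sum_j A_j/(Omega_j - nu - i Gamma_j)|^2
(``chi3_domain``) to exercise phase retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from carsense.amide import (
    DEFAULT_BAND_MODEL,
    BandModel,
    amplitude_for_area,
    gaussian_band,
)
from carsense.cube import HyperspectralCube

BACKGROUND, CYTOPLASM, NUCLEOPLASM, NUCLEOLUS = 0, 1, 2, 3
REGION_NAMES = {1: "cytoplasm", 2: "nucleoplasm", 3: "nucleolus"}

#: CH-stretch band anchor used for segmentation-style intensity images.
CH_CENTER = 2933.0
CH_FWHM = 60.0
WATER_CENTER = 1640.0
WATER_FWHM = 90.0

DEFAULT_AXIS = np.arange(1500.0, 1801.0, 2.5)


@dataclass(frozen=True)
class SpectralComposition:
    """Non-negative area weights for the three amide components plus extras.

    ``weights`` orders the components as (0) purine, (1) alpha-helix/lipid,
    (2) beta-sheet; values are integrated band areas in arbitrary units.
    """

    weights: tuple[float, float, float]
    ch_weight: float = 0.0
    water_weight: float = 0.0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights) or self.ch_weight < 0 or self.water_weight < 0:
            raise ValueError("composition weights must be >= 0")

    @property
    def beta_fraction(self) -> float:
        """True beta ratio w2 / (w1 + w2); nan if both protein weights are 0."""
        denom = self.weights[1] + self.weights[2]
        return self.weights[2] / denom if denom > 0 else float("nan")

    def scaled(self, k: float) -> "SpectralComposition":
        return replace(
            self,
            weights=tuple(k * w for w in self.weights),
            ch_weight=k * self.ch_weight,
            water_weight=k * self.water_weight,
        )


# Default compositions, tuned on a dense-grid (0.01 cm^-1) argmax oracle:
# control cytoplasm peaks at 1653.0 cm^-1, control nucleolus at 1657.2
# (below the 1660 amyloid threshold), senescent nucleolus (beta fraction
# 0.60) at 1665.0.  CH weights grade background < cytoplasm < nucleoplasm
# < nucleolus so the 2933 cm^-1 image separates the regions.
DEFAULT_COMPOSITIONS: dict[tuple[str, str], SpectralComposition] = {
    ("control", "cytoplasm"): SpectralComposition((0.30, 1.00, 0.25), ch_weight=1.0),
    ("control", "nucleoplasm"): SpectralComposition((0.35, 0.75, 0.25), ch_weight=1.6),
    ("control", "nucleolus"): SpectralComposition((0.40, 0.70, 0.30), ch_weight=2.4),
    ("senescent", "cytoplasm"): SpectralComposition((0.30, 1.00, 0.25), ch_weight=1.0),
    ("senescent", "nucleoplasm"): SpectralComposition((0.35, 0.60, 0.40), ch_weight=1.6),
    ("senescent", "nucleolus"): SpectralComposition((0.40, 0.40, 0.60), ch_weight=3.2),
}


@dataclass(frozen=True)
class PhantomLayout:
    """Geometry of the phantom field: image size and per-phenotype cell counts.

    Radii are in pixels.  Senescent cells are binucleate with enlarged
    nucleoli; control cells are mononuclear with a nucleus well under the
    118 um^2 polyploidy threshold at the default 0.5 um/pixel sampling.
    """

    shape: tuple[int, int] = (96, 96)
    n_control: int = 6
    n_senescent: int = 6
    pixel_size_um: float = 0.5
    cell_radius: float = 10.0
    nucleus_radius_control: float = 5.0
    nucleus_radius_senescent: float = 4.5
    nucleolus_radius_control: float = 2.0
    nucleolus_radius_senescent: float = 2.8
    nucleoli_per_nucleus: int = 1
    margin: int = 2

    def __post_init__(self) -> None:
        if self.shape[0] < 64 or self.shape[1] < 64:
            raise ValueError("phantom image must be at least 64 x 64")
        if self.n_control + self.n_senescent < 1:
            raise ValueError("at least one cell is required")
        for r_ncl, r_nuc in (
            (self.nucleolus_radius_control, self.nucleus_radius_control),
            (self.nucleolus_radius_senescent, self.nucleus_radius_senescent),
        ):
            if not (r_ncl < r_nuc < self.cell_radius):
                raise ValueError("need nucleolus radius < nucleus radius < cell radius")


@dataclass
class LabeledPhantom:
    """Region-labelled phantom: label image, cell map, and composition truth."""

    label_image: np.ndarray
    cell_ids: np.ndarray
    phenotype: dict[int, str]
    nuclei_per_cell: dict[int, int]
    pixel_size_um: float
    truth_table: dict[tuple[str, str], SpectralComposition]

    @property
    def n_cells(self) -> int:
        return len(self.phenotype)

    def region_mask(self, label: int) -> np.ndarray:
        return self.label_image == label

    def outside_mask(self) -> np.ndarray:
        return self.label_image == BACKGROUND


@dataclass
class GroundTruth:
    """Exact per-pixel g areas and per-cell truth for round-trip testing."""

    g: np.ndarray  # (ny, nx, 3) true integrated intensities
    beta_fraction: pd.DataFrame  # columns: cell_id, region, beta_fraction
    phenotype: dict[int, str]

    def to_csv(self, path) -> None:
        self.beta_fraction.to_csv(path, index=False)


def _disk(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def make_phantom(
    layout: PhantomLayout = PhantomLayout(),
    seed: int = 0,
    compositions: dict[tuple[str, str], SpectralComposition] | None = None,
    phenotypes: list[str] | None = None,
) -> LabeledPhantom:
    """Place circular cells on a jittered grid and label their regions.

    Cells are laid out on a regular grid with small random jitter so that a
    fixed seed reproduces the field bit-exactly.  ``phenotypes`` overrides
    the default control/senescent assignment with an arbitrary per-cell
    phenotype list (each must have entries in ``compositions``).
    """
    rng = np.random.default_rng(seed)
    compositions = dict(DEFAULT_COMPOSITIONS if compositions is None else compositions)
    if phenotypes is None:
        phenotypes = ["control"] * layout.n_control + ["senescent"] * layout.n_senescent
    n = len(phenotypes)

    ny, nx = layout.shape
    slot = int(np.ceil(2 * layout.cell_radius + 2 * layout.margin))
    cols = max(1, nx // slot)
    rows = max(1, ny // slot)
    if cols * rows < n:
        raise ValueError(
            f"cannot place cell {cols * rows + 1} of {n}: grid of {rows}x{cols} slots "
            f"(slot {slot} px) does not fit in {ny}x{nx}"
        )

    label = np.zeros(layout.shape, dtype=np.int32)
    cell_ids = np.zeros(layout.shape, dtype=np.int32)
    phenotype_map: dict[int, str] = {}
    nuclei_per_cell: dict[int, int] = {}

    order = rng.permutation(cols * rows)[:n]
    for cell_idx, slot_idx in enumerate(order):
        cid = cell_idx + 1
        phen = phenotypes[cell_idx]
        gy, gx = divmod(int(slot_idx), cols)
        jitter = layout.margin - 1
        cy = gy * slot + slot // 2 + (rng.integers(-jitter, jitter + 1) if jitter > 0 else 0)
        cx = gx * slot + slot // 2 + (rng.integers(-jitter, jitter + 1) if jitter > 0 else 0)
        cy = int(np.clip(cy, layout.cell_radius, ny - 1 - layout.cell_radius))
        cx = int(np.clip(cx, layout.cell_radius, nx - 1 - layout.cell_radius))

        cell = _disk(layout.shape, cy, cx, layout.cell_radius)
        label[cell] = CYTOPLASM
        cell_ids[cell] = cid

        senescent_like = phen == "senescent"
        n_nuclei = 2 if senescent_like else 1
        r_nuc = (
            layout.nucleus_radius_senescent if senescent_like else layout.nucleus_radius_control
        )
        r_ncl = (
            layout.nucleolus_radius_senescent if senescent_like else layout.nucleolus_radius_control
        )
        if n_nuclei == 1:
            centers = [(cy, cx)]
        else:
            off = min(r_nuc + 1, layout.cell_radius - r_nuc - 0.5)
            centers = [(cy, cx - off), (cy, cx + off)]
        nuclei_per_cell[cid] = n_nuclei
        phenotype_map[cid] = phen
        for ncy, ncx in centers:
            nuc = _disk(layout.shape, ncy, ncx, r_nuc) & cell
            label[nuc] = NUCLEOPLASM
            for _ in range(layout.nucleoli_per_nucleus):
                # keep the whole nucleolus strictly inside the nucleoplasm
                max_off = r_nuc - r_ncl - 1.5
                if max_off > 0:
                    theta = rng.uniform(0, 2 * np.pi)
                    rad = max_off * np.sqrt(rng.uniform())
                    dy, dx = rad * np.sin(theta), rad * np.cos(theta)
                else:
                    dy = dx = 0.0
                ncl = _disk(layout.shape, ncy + dy, ncx + dx, r_ncl) & nuc
                label[ncl] = NUCLEOLUS

    return LabeledPhantom(
        label_image=label,
        cell_ids=cell_ids,
        phenotype=phenotype_map,
        nuclei_per_cell=nuclei_per_cell,
        pixel_size_um=layout.pixel_size_um,
        truth_table=compositions,
    )


def compose_region_spectrum(
    composition: SpectralComposition,
    axis: np.ndarray,
    band_model: BandModel = DEFAULT_BAND_MODEL,
    meta: dict | None = None,
) -> np.ndarray:
    """Noiseless spectrum of a composition: weight-scaled sum of unit-area bands.

    The result is linear in the weights.  Components whose +/- 3 FWHM support
    is not covered by ``axis`` (and have nonzero weight) are flagged in
    ``meta['uncovered']`` when a metadata dict is supplied.
    """
    axis = np.asarray(axis, dtype=float)
    if np.any(np.diff(axis) <= 0):
        raise ValueError("axis must be strictly increasing")
    bands = [
        (role, c, w, wt)
        for (role, c, w), wt in zip(band_model.components, composition.weights)
    ]
    bands.append(("ch", CH_CENTER, CH_FWHM, composition.ch_weight))
    bands.append(("water", WATER_CENTER, WATER_FWHM, composition.water_weight))

    spectrum = np.zeros_like(axis)
    uncovered = []
    for role, center, fwhm, weight in bands:
        if weight == 0:
            continue
        if axis[0] > center - 3 * fwhm or axis[-1] < center + 3 * fwhm:
            uncovered.append(role)
        spectrum += gaussian_band(axis, amplitude_for_area(weight, fwhm), center, fwhm)
    if meta is not None:
        meta["uncovered"] = uncovered
    return spectrum


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian noise plus optional shot-like (intensity-scaled) term.

    ``sigma`` is the additive standard deviation in the same arbitrary units
    as the spectra; ``shot_fraction`` adds a component with standard
    deviation ``shot_fraction * sqrt(max(signal, 0))``.  ``baseline_amp``
    superimposes a slowly varying quadratic baseline common to all pixels
    (removed downstream by the outside-cell subtraction / arPLS stages).
    """

    sigma: float = 0.0
    shot_fraction: float = 0.0
    baseline_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.shot_fraction < 0:
            raise ValueError("noise levels must be >= 0")


def _smooth_baseline(axis: np.ndarray, amp: float) -> np.ndarray:
    # Gentle convex quadratic spanning the axis, peak-normalised to `amp`.
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    return amp * (0.4 + 0.6 * (t - 0.3) ** 2 / 0.49)


def _lorentzian_lines_for(
    composition: SpectralComposition,
    band_model: BandModel,
    resonant_scale: float,
) -> list[tuple[float, float, float]]:
    """Lorentzian (Omega, A, Gamma) lines area-matched to the Gaussian truth.

    Gamma = FWHM/2 so linewidths match; A is chosen so the Im[chi3] area over
    the fit window equals the (scaled) Gaussian component area, since the
    heavy Lorentzian tails would otherwise lose 5-10% of the area outside
    the window.
    """
    lo, hi = band_model.window
    lines = []
    for (role, center, fwhm), weight in zip(band_model.components, composition.weights):
        if weight == 0:
            continue
        gamma = fwhm / 2.0
        window_frac = (
            np.arctan((hi - center) / gamma) + np.arctan((center - lo) / gamma)
        )
        area = resonant_scale * weight
        lines.append((center, area / window_frac, gamma))
    return lines


def synthesize_cube(
    phantom: LabeledPhantom,
    compositions: dict[tuple[str, str], SpectralComposition] | None = None,
    noise: NoiseConfig = NoiseConfig(),
    mode: str = "im_domain",
    seed: int = 0,
    axis: np.ndarray = DEFAULT_AXIS,
    band_model: BandModel = DEFAULT_BAND_MODEL,
    chi_nr: float = 1.0,
    resonant_scale: float = 40.0,
) -> tuple[HyperspectralCube, GroundTruth]:
    """Render a hyperspectral cube from a labelled phantom.

    ``im_domain`` emits Im[chi3]-like spectra directly (composition spectrum
    plus optional baseline and noise).  ``chi3_domain`` emits raw CARS
    intensity |chi_NR + sum_j A_j/(Omega_j - nu - i Gamma_j)|^2 with the
    Lorentzian lines matched in centre and window-area to the Gaussian
    truth; ``resonant_scale`` sets the resonant-to-nonresonant contrast.
    The returned :class:`GroundTruth` carries the exact g areas (in the
    chi3 case scaled by ``resonant_scale``).
    """
    if mode not in ("im_domain", "chi3_domain"):
        raise ValueError(f"unknown cube mode {mode!r}")
    compositions = phantom.truth_table if compositions is None else compositions
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    ny, nx = phantom.label_image.shape

    zero = SpectralComposition((0.0, 0.0, 0.0))
    data = np.zeros((ny, nx, axis.size))
    g_true = np.zeros((ny, nx, 3))
    scale = 1.0 if mode == "im_domain" else resonant_scale

    # One spectrum per (phenotype, region) pair; regions are homogeneous.
    spectra_cache: dict[tuple[str, str], np.ndarray] = {}
    for cid, phen in phantom.phenotype.items():
        for region_label, region_name in REGION_NAMES.items():
            sel = (phantom.cell_ids == cid) & (phantom.label_image == region_label)
            if not sel.any():
                continue
            key = (phen, region_name)
            comp = compositions.get(key, zero)
            if key not in spectra_cache:
                if mode == "im_domain":
                    spectra_cache[key] = compose_region_spectrum(comp, axis, band_model)
                else:
                    lines = _lorentzian_lines_for(comp, band_model, resonant_scale)
                    chi = np.full(axis.size, chi_nr, dtype=complex)
                    for om, a, gm in lines:
                        chi += a / (om - axis - 1j * gm)
                    # CH band enters as extra real polarizability far from
                    # the window; add its Gaussian directly to the intensity
                    # so segmentation images keep their contrast.
                    intensity = np.abs(chi) ** 2
                    if comp.ch_weight > 0:
                        intensity = intensity + compose_region_spectrum(
                            SpectralComposition((0, 0, 0), ch_weight=comp.ch_weight),
                            axis,
                            band_model,
                        )
                    spectra_cache[key] = intensity
            data[sel] = spectra_cache[key]
            g_true[sel] = scale * np.asarray(comp.weights)

    if noise.baseline_amp > 0:
        data += _smooth_baseline(axis, noise.baseline_amp)
    if noise.sigma > 0:
        data += rng.normal(0.0, noise.sigma, size=data.shape)
    if noise.shot_fraction > 0:
        data += rng.normal(0.0, 1.0, size=data.shape) * noise.shot_fraction * np.sqrt(
            np.clip(data, 0.0, None)
        )

    rows = []
    for cid, phen in phantom.phenotype.items():
        for region_label, region_name in REGION_NAMES.items():
            comp = compositions.get((phen, region_name), zero)
            rows.append(
                {
                    "cell_id": cid,
                    "phenotype": phen,
                    "region": region_name,
                    "beta_fraction": comp.beta_fraction,
                }
            )
    truth = GroundTruth(
        g=g_true,
        beta_fraction=pd.DataFrame(rows),
        phenotype=dict(phantom.phenotype),
    )
    cube = HyperspectralCube(
        data=data,
        axis_cm1=axis,
        pixel_size_um=phantom.pixel_size_um,
        mode=mode,
        meta={"seed": seed, "noise": vars(noise) | {}, "chi_nr": chi_nr},
    )
    return cube, truth


def ch_intensity_image(
    phantom: LabeledPhantom,
    compositions: dict[tuple[str, str], SpectralComposition] | None = None,
) -> np.ndarray:
    """Noiseless CH-band (2933 cm^-1 anchor) intensity image for segmentation."""
    compositions = phantom.truth_table if compositions is None else compositions
    img = np.zeros(phantom.label_image.shape)
    for cid, phen in phantom.phenotype.items():
        for region_label, region_name in REGION_NAMES.items():
            sel = (phantom.cell_ids == cid) & (phantom.label_image == region_label)
            comp = compositions.get((phen, region_name))
            if comp is not None:
                img[sel] = comp.ch_weight
    return img


def senescent_composition(beta_fraction: float, protein_total: float = 1.0) -> SpectralComposition:
    """Nucleolar composition with a prescribed beta fraction (protein area fixed)."""
    if not 0.0 <= beta_fraction <= 1.0:
        raise ValueError("beta_fraction must be in [0, 1]")
    w2 = protein_total * beta_fraction
    w1 = protein_total - w2
    return SpectralComposition((0.40, w1, w2), ch_weight=3.0)


def make_regression_sweep(
    n_cells: int = 24,
    seed: int = 0,
    shape: tuple[int, int] = (160, 160),
    beta_range: tuple[float, float] = (0.25, 0.60),
    radius_range: tuple[float, float] = (1.8, 4.2),
    beta_noise: float = 0.03,
) -> tuple[LabeledPhantom, dict[tuple[str, str], SpectralComposition]]:
    """Mononuclear phantom sweep where nucleolus size and beta fraction co-vary.

    Emulates a naive cell population in which larger nucleoli carry a larger
    beta-sheet burden, the configuration used for the size-vs-ratio
    regression.  Each cell gets its own phenotype key with a nucleolus
    radius interpolated over ``radius_range`` and a nucleolar beta fraction
    over ``beta_range`` plus Gaussian jitter ``beta_noise``.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_cells)
    radii = radius_range[0] + t * (radius_range[1] - radius_range[0])
    betas = np.clip(
        beta_range[0] + t * (beta_range[1] - beta_range[0]) + rng.normal(0, beta_noise, n_cells),
        0.0,
        1.0,
    )
    phenotypes = [f"sweep_{i:02d}" for i in range(n_cells)]
    compositions: dict[tuple[str, str], SpectralComposition] = {}
    base = DEFAULT_COMPOSITIONS
    for phen, bf in zip(phenotypes, betas):
        compositions[(phen, "cytoplasm")] = base[("control", "cytoplasm")]
        compositions[(phen, "nucleoplasm")] = base[("control", "nucleoplasm")]
        compositions[(phen, "nucleolus")] = senescent_composition(float(bf))

    # Per-cell nucleolus radii need per-cell layouts; build incrementally by
    # rendering each cell's nucleolus radius through a per-cell layout trick:
    # place all cells with the largest radius allowed, then shrink labels.
    layout = PhantomLayout(
        shape=shape,
        n_control=n_cells,
        n_senescent=0,
        nucleolus_radius_control=radius_range[1],
    )
    phantom = make_phantom(layout, seed=seed, compositions=compositions, phenotypes=phenotypes)

    # Shrink each cell's nucleolus to its target radius (centre preserved).
    label = phantom.label_image
    for cid, r in zip(sorted(phantom.phenotype), radii):
        sel = (phantom.cell_ids == cid) & (label == NUCLEOLUS)
        if not sel.any():
            continue
        ys, xs = np.nonzero(sel)
        cy, cx = ys.mean(), xs.mean()
        keep = (ys - cy) ** 2 + (xs - cx) ** 2 <= r**2
        label[ys[~keep], xs[~keep]] = NUCLEOPLASM
    return phantom, compositions
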
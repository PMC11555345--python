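"""One-command end-to-end pipeline: simulate -> retrieve -> preprocess -> fit
-> indicator maps -> quantify -> statistics."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from carsense import amide, indicators, io, phase_retrieval, preprocessing, quantify, synthetic
from carsense.cube import HyperspectralCube

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for the end-to-end run.

    The defaults describe the demonstration field: 6 control + 6 senescent
    phantom cells on a 96 x 96 grid, 0.5 um/pixel, spectra over
    1500-1800 cm^-1, mild shot-like noise and a small common baseline.
    """

    mode: str = "im_domain"
    shape: tuple[int, int] = (96, 96)
    n_control: int = 6
    n_senescent: int = 6
    seed: int = 0
    noise_sigma: float = 0.001
    baseline_amp: float = 0.01
    pole_fraction: float = 0.45
    error_phase_order: int = 4
    arpls_lam: float = 1e5
    arpls_enabled: bool = True
    water_mode: str = "off"
    fit_mode: str = "fixed_shape"
    mask_threshold: float = indicators.RATIO_MASK_THRESHOLD
    outside_mask: str = "truth"  # "truth" or "otsu"
    resonant_scale: float = 40.0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _outside_mask_otsu(cube: HyperspectralCube) -> np.ndarray:
    """Low class of an Otsu threshold on the CH-band (2933 cm^-1) image.

    Falls back to the summed-intensity image when the axis does not reach
    the CH region.
    """
    from skimage.filters import threshold_otsu

    if cube.axis_cm1[-1] >= synthetic.CH_CENTER:
        img = cube.channel_image(synthetic.CH_CENTER)
    else:
        img = cube.data.sum(axis=2)
    return img < threshold_otsu(img)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a synthetic field and write the report directory.

    Writes ``records.csv``, indicator map TIFF/PNG images, ``summary.json``
    (group means, test p-values, regression when defined) and a stage log.
    Fully deterministic for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    chash = config.config_hash()

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed") from exc
                return False

        return _T()

    with stage("simulate"):
        layout = synthetic.PhantomLayout(
            shape=config.shape,
            n_control=config.n_control,
            n_senescent=config.n_senescent,
        )
        phantom = synthetic.make_phantom(layout, seed=config.seed)
        noise = synthetic.NoiseConfig(
            sigma=config.noise_sigma, baseline_amp=config.baseline_amp
        )
        cube, truth = synthetic.synthesize_cube(
            phantom,
            noise=noise,
            mode=config.mode,
            seed=config.seed + 1,
            resonant_scale=config.resonant_scale,
        )
        cube.meta["config_hash"] = chash
        io.write_cube(cube, outdir / "raw_cube")
        io.write_mask(phantom.label_image, outdir / "labels.tif")
        truth.to_csv(outdir / "ground_truth.csv")

    if config.mode == "chi3_domain":
        with stage("retrieve"):
            cube = phase_retrieval.retrieve_cube(
                cube,
                pole_fraction=config.pole_fraction,
                order=config.error_phase_order,
            )

    with stage("preprocess"):
        if config.outside_mask == "truth":
            outside = phantom.outside_mask()
        else:
            outside = _outside_mask_otsu(cube)
        cube = preprocessing.subtract_outside_baseline(cube, outside)
        if config.arpls_enabled:
            cube = preprocessing.arpls_cube(cube, lam=config.arpls_lam)
        if config.water_mode != "off":
            data = np.stack(
                [
                    preprocessing.remove_water_band(
                        cube.data[iy, ix], cube.axis_cm1, config.water_mode
                    )
                    for iy in range(cube.shape[0])
                    for ix in range(cube.shape[1])
                ]
            ).reshape(cube.shape)
            cube = cube.with_data(data)
        io.write_cube(cube, outdir / "corrected_cube")

    with stage("fit"):
        band_model = amide.DEFAULT_BAND_MODEL.with_mode(config.fit_mode)
        fitmaps = amide.fit_cube(cube, band_model)

    with stage("maps"):
        maps = indicators.ratio_map(fitmaps, config.mask_threshold)
        nucleus_mask = phantom.label_image >= synthetic.NUCLEOPLASM
        ring = indicators.perinuclear_ring(nucleus_mask)
        maps = indicators.subtraction_map(fitmaps, ring, maps)
        io.write_image(maps.ratio, outdir / "ratio.tif")
        io.write_image(maps.subtraction, outdir / "subtraction.tif")
        io.write_image(indicators.render_ratio(maps), outdir / "ratio_rgb.tif")
        io.write_image(indicators.render_subtraction(maps), outdir / "subtraction_rgb.tif")

    with stage("quantify"):
        records = quantify.extract_cell_records(
            phantom.label_image,
            phantom.cell_ids,
            maps,
            phantom.pixel_size_um,
            phenotype_truth=phantom.phenotype,
        )
        frame = quantify.records_to_frame(records)
        frame.to_csv(outdir / "records.csv", index=False)

    with stage("stats"):
        by_group: dict[str, np.ndarray] = {}
        for phen in sorted(set(phantom.phenotype.values())):
            vals = frame.loc[
                (frame.phenotype_truth == phen) & frame.valid,
                "largest_nucleolus_mean_ratio",
            ].to_numpy()
            by_group[phen] = vals[np.isfinite(vals)]
        summary: dict = {
            "config_hash": chash,
            "seed": config.seed,
            "mode": config.mode,
            "group_means": {k: float(v.mean()) for k, v in by_group.items() if v.size},
            "group_n": {k: int(v.size) for k, v in by_group.items()},
        }
        if len(by_group) == 2 and all(v.size >= 3 for v in by_group.values()):
            comp = quantify.group_comparison(by_group, design="ttest_scheme")
            summary["comparison"] = {
                "scheme": comp.scheme,
                "shapiro_p": comp.shapiro_p,
                "variance_test": comp.variance_test,
                "variance_p": comp.variance_p,
                "location_test": comp.location_test,
                "location_p": comp.location_p,
                "significant": comp.significant,
            }
        try:
            reg = quantify.size_ratio_regression(records)
            summary["size_ratio_regression"] = {
                "slope": reg.slope,
                "intercept": reg.intercept,
                "r_squared": reg.r_squared,
                "p_value": reg.p_value,
                "n": reg.n,
            }
        except ValueError:
            pass
        summary["non_converged_pixels"] = int((~fitmaps.converged).sum())

    summary["timings_s"] = timings
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("pipeline finished: %s", {k: v for k, v in summary.items() if k != "timings_s"})
    return summary
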
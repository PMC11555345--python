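"""Per-cell nucleolar quantification, phenotype classification and statistics.

Cells are scored by the cross-sectional average of the indicator values over
the largest nucleolus in each nucleus.  Classification follows the
morphological rules used for label-free senescence scoring: a control cell
is mononuclear with nucleus cross-section strictly below 118 um^2 (larger
mononuclear nuclei are potential polyploids), a binucleate cell is scored
senescent-like regardless of area.  Group comparisons run Shapiro-Wilk
normality per group and then either Bartlett + Dunnett-versus-control
(multi-group designs) or an F-test + two-sample Student's t (two-group
designs), with significance at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
import statsmodels.api as sm

from carsense.amide import AmideFitMaps
from carsense.indicators import IndicatorMaps
from carsense.synthetic import BACKGROUND, CYTOPLASM, NUCLEOLUS, NUCLEOPLASM

#: Mononuclear cells with nucleus cross-section at or above this (um^2) are
#: treated as potential polyploids, not controls.
CONTROL_NUCLEUS_AREA_UM2 = 118.0

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class CellRecord:
    cell_id: int
    nuclei_count: int
    largest_nucleus_area_um2: float
    largest_nucleolus_px: int
    largest_nucleolus_mean_ratio: float
    largest_nucleolus_mean_subtraction: float
    phenotype_class: str = ""
    phenotype_truth: str | None = None
    valid: bool = True


@dataclass
class GroupComparison:
    groups: list[str]
    scheme: str
    shapiro_p: dict[str, float]
    variance_test: str
    variance_p: float
    location_test: str
    location_p: dict[str, float] | float
    significant: bool
    alpha: float = 0.05


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def segment_regions(
    intensity_image: np.ndarray,
    n_classes: int = 4,
) -> np.ndarray:
    """Label regions from a CH-band (2933 cm^-1) intensity image.

    Intensity grades background < cytoplasm < nucleoplasm < nucleolus, so a
    multi-Otsu threshold into ``n_classes`` levels followed by
    connected-component cleanup recovers the region labels.  Nucleolus
    components not contained in a nucleus-level region are demoted.
    """
    from skimage.filters import threshold_multiotsu

    img = np.asarray(intensity_image, dtype=float)
    if img.ndim != 2 or np.any(img < 0):
        raise ValueError("expected a 2-D non-negative intensity image")
    if not img.any():
        return np.zeros(img.shape, dtype=np.int32)  # empty field: all background
    if np.unique(img).size < 2:
        raise ValueError("image has fewer than 2 distinct intensity levels")
    if np.unique(img).size <= n_classes:
        # Discrete, fully separable levels: map each to its rank directly.
        levels = np.unique(img)
        label = np.searchsorted(levels, img)
        return label.astype(np.int32)
    thresholds = threshold_multiotsu(img, classes=n_classes)
    label = np.digitize(img, thresholds).astype(np.int32)

    # Nucleoli must lie within nuclei: demote stray nucleolus components.
    nucleus_extent = label >= NUCLEOPLASM
    ncl_labels, n_ncl = ndimage.label(label == NUCLEOLUS, structure=FOUR_CONNECTED)
    for i in range(1, n_ncl + 1):
        comp = ncl_labels == i
        grown = ndimage.binary_dilation(comp, structure=FOUR_CONNECTED)
        if not nucleus_extent[grown & ~comp].any():
            label[comp] = CYTOPLASM
    return label


def _largest_component(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Largest 4-connected component (ties -> lowest label); (mask, size)."""
    labels, n = ndimage.label(mask, structure=FOUR_CONNECTED)
    if n == 0:
        return np.zeros_like(mask, dtype=bool), 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1  # argmax returns first max -> lowest label
    return labels == best, int(sizes[best - 1])


def extract_cell_records(
    label_image: np.ndarray,
    cell_ids: np.ndarray,
    maps: IndicatorMaps,
    pixel_size_um: float,
    phenotype_truth: dict[int, str] | None = None,
) -> list[CellRecord]:
    """Per-cell morphology and largest-nucleolus indicator averages.

    Nuclei are counted as 4-connected nucleus-extent components within each
    cell; areas are pixel count times pixel_size^2.  The largest nucleolus
    (by pixel count, ties to the lowest component label) provides the
    cross-sectional mean ratio and subtraction over its valid pixels.
    Cells without a nucleus are flagged invalid and excluded from
    statistics.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    label_image = np.asarray(label_image)
    cell_ids = np.asarray(cell_ids)
    if label_image.shape != cell_ids.shape or label_image.shape != maps.ratio.shape:
        raise ValueError("label image, cell map and indicator maps must share a shape")

    records: list[CellRecord] = []
    for cid in sorted(int(c) for c in np.unique(cell_ids) if c != 0):
        in_cell = cell_ids == cid
        nucleus_extent = in_cell & (label_image >= NUCLEOPLASM)
        nuc_labels, n_nuclei = ndimage.label(nucleus_extent, structure=FOUR_CONNECTED)
        if n_nuclei == 0:
            records.append(
                CellRecord(cid, 0, 0.0, 0, float("nan"), float("nan"), valid=False,
                           phenotype_truth=(phenotype_truth or {}).get(cid))
            )
            continue
        nuc_sizes = ndimage.sum_labels(
            np.ones_like(nuc_labels), nuc_labels, index=np.arange(1, n_nuclei + 1)
        )
        largest_nucleus_area = float(nuc_sizes.max()) * pixel_size_um**2

        ncl_mask, ncl_size = _largest_component(in_cell & (label_image == NUCLEOLUS))
        if ncl_size > 0:
            valid = ncl_mask & ~maps.ratio_invalid
            mean_ratio = float(maps.ratio[valid].mean()) if valid.any() else float("nan")
            if maps.subtraction is not None and valid.any():
                mean_sub = float(maps.subtraction[valid].mean())
            else:
                mean_sub = float("nan")
        else:
            mean_ratio = float("nan")
            mean_sub = float("nan")

        rec = CellRecord(
            cell_id=cid,
            nuclei_count=int(n_nuclei),
            largest_nucleus_area_um2=largest_nucleus_area,
            largest_nucleolus_px=ncl_size,
            largest_nucleolus_mean_ratio=mean_ratio,
            largest_nucleolus_mean_subtraction=mean_sub,
            phenotype_truth=(phenotype_truth or {}).get(cid),
        )
        rec.phenotype_class = classify_cell(rec)
        records.append(rec)
    return records


def classify_cell(record: CellRecord) -> str:
    """Morphological phenotype class from nucleus count and area.

    control: 1 nucleus with cross-section strictly below 118 um^2;
    binucleate: >= 2 nuclei; large_nucleus: mononuclear at or above the
    threshold.
    """
    if record.nuclei_count == 0:
        raise ValueError(f"cell {record.cell_id} has no nucleus; cannot classify")
    if record.nuclei_count >= 2:
        return "binucleate"
    if record.largest_nucleus_area_um2 < CONTROL_NUCLEUS_AREA_UM2:
        return "control"
    return "large_nucleus"


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def group_comparison(
    values_by_group: dict[str, np.ndarray],
    design: str = "ttest_scheme",
    control: str | None = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Shapiro-Wilk per group, then the design's variance and location tests.

    ``dunnett_scheme`` runs Bartlett's test followed by Dunnett's
    many-to-one comparison against ``control`` (default: first group);
    ``ttest_scheme`` runs a variance-ratio F-test followed by a pooled
    two-sample two-tailed Student's t (requires exactly two groups).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    names = list(groups)
    for name, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {name!r} has n={v.size} < 3")
    shapiro_p = {name: float(stats.shapiro(v).pvalue) for name, v in groups.items()}

    if design == "ttest_scheme":
        if len(groups) != 2:
            raise ValueError("ttest_scheme requires exactly two groups")
        a, b = (groups[n] for n in names)
        # Variance-ratio F test, two-tailed.
        f = np.var(a, ddof=1) / np.var(b, ddof=1)
        dfa, dfb = a.size - 1, b.size - 1
        p_one = stats.f.sf(f, dfa, dfb) if f >= 1 else stats.f.cdf(f, dfa, dfb)
        var_p = float(min(1.0, 2 * p_one))
        if np.array_equal(a, b):
            loc_p = 1.0
        else:
            loc_p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        return GroupComparison(
            groups=names,
            scheme=design,
            shapiro_p=shapiro_p,
            variance_test="f_test",
            variance_p=var_p,
            location_test="student_t",
            location_p=loc_p,
            significant=loc_p < alpha,
            alpha=alpha,
        )

    if design == "dunnett_scheme":
        if len(groups) < 2:
            raise ValueError("dunnett_scheme requires a control plus >= 1 group")
        control = names[0] if control is None else control
        others = [n for n in names if n != control]
        var_p = float(stats.bartlett(*groups.values()).pvalue)
        # Dunnett p-values come from a quasi-random multivariate-t integral;
        # fix the rng so repeated analyses are bit-identical.
        res = stats.dunnett(*(groups[n] for n in others), control=groups[control], rng=0)
        loc_p = {n: float(p) for n, p in zip(others, np.atleast_1d(res.pvalue))}
        return GroupComparison(
            groups=names,
            scheme=design,
            shapiro_p=shapiro_p,
            variance_test="bartlett",
            variance_p=var_p,
            location_test="dunnett",
            location_p=loc_p,
            significant=any(p < alpha for p in loc_p.values()),
            alpha=alpha,
        )

    raise ValueError(f"unknown design {design!r}")


def size_ratio_regression(records: list[CellRecord]) -> RegressionResult:
    """OLS of largest-nucleolus mean ratio on nucleolus size (pixel count).

    Mirrors the nucleolus-size versus beta-sheet-ratio scatter analysis:
    size in pixels on the abscissa, cross-sectional mean g2/(g1+g2) on the
    ordinate, with a two-sided p-value for the slope.
    """
    data = [
        (r.largest_nucleolus_px, r.largest_nucleolus_mean_ratio)
        for r in records
        if r.valid and r.largest_nucleolus_px > 0 and np.isfinite(r.largest_nucleolus_mean_ratio)
    ]
    if len(data) < 3:
        raise ValueError("need at least 3 records with finite nucleolus metrics")
    x = np.array([d[0] for d in data], dtype=float)
    y = np.array([d[1] for d in data], dtype=float)
    if np.var(x) == 0:
        raise ValueError("nucleolus sizes have zero variance; regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=x.size,
    )
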
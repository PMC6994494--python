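"""Fixed-cell morphometry of nuclear bodies (NBs).

Quantities reported per nucleus:

* per-object NB area (um^2), equivalent diameter ``2 sqrt(area / pi)`` and
  size class -- I: d <= 0.75 um, II: 0.75 < d <= 2 um, III: d > 2 um
  (closed upper bounds at the class boundaries);
* total NB area (sum over objects) and mean NB area;
* nucleus/cytoplasm mean-intensity ratio Fn/c, background-corrected;
* RNA intensity ratio (F_NB - F_bg) / (F_nonNB - F_bg) between the NB area
  and the non-NB nucleoplasm.

Segmentation is deliberately simple and reproducible: Otsu threshold
restricted to the nucleus (or a fixed threshold), 8-connected components,
holes filled, minimum-area filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

from .errors import err

SIZE_CLASS_I_MAX_UM = 0.75
SIZE_CLASS_II_MAX_UM = 2.0
DEFAULT_MIN_AREA_UM2 = 0.05


def size_class(eq_diameter_um: float) -> str:
    """Size class from equivalent diameter: 'I' (<= 0.75 um),
    'II' (0.75-2 um, closed above], 'III' (> 2 um)."""
    if not eq_diameter_um > 0:
        raise err("invalid_diameter", "diameter must be positive")
    if eq_diameter_um <= SIZE_CLASS_I_MAX_UM:
        return "I"
    if eq_diameter_um <= SIZE_CLASS_II_MAX_UM:
        return "II"
    return "III"


@dataclass
class NBRecord:
    """One segmented nuclear body."""

    label: int
    area_um2: float
    eq_diameter_um: float
    size_class: str
    centroid_um: tuple[float, float]  # (x, y)


@dataclass
class MorphoResult:
    """Per-nucleus morphometry summary."""

    nbs: list[NBRecord]
    total_nb_area_um2: float
    mean_nb_area_um2: float | None  # None when the nucleus has no NBs
    fn_c: float | None = None
    rna_ratio: float | None = None
    nucleus_id: str | int | None = None


def segment_nbs(
    protein_channel: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size: float,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
) -> tuple[np.ndarray, list[NBRecord]]:
    """Segment bright bodies within the nucleus.

    Returns the label image and per-object records.  A contrast-free image
    yields zero objects (not an error); an empty nucleus mask is an error.
    """
    img = np.asarray(protein_channel, dtype=np.float64)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise err("empty_nucleus")
    if pixel_size <= 0:
        raise err("invalid_config", "pixel_size must be > 0")
    if threshold_method == "fixed":
        if threshold_value is None:
            raise err("invalid_config", "fixed threshold requires threshold_value")
        thr = float(threshold_value)
    elif threshold_method == "otsu":
        vals = img[nucleus_mask]
        if np.ptp(vals) == 0:
            return np.zeros(img.shape, dtype=np.int32), []
        thr = threshold_otsu(vals)
    else:
        raise err("invalid_config", f"unknown threshold method {threshold_method!r}")

    fg = (img > thr) & nucleus_mask
    fg = ndimage.binary_fill_holes(fg)
    labels = label(fg, connectivity=2)
    px_area = pixel_size**2
    records: list[NBRecord] = []
    out = np.zeros_like(labels)
    next_label = 0
    for rp in regionprops(labels):
        area = rp.area * px_area
        if area < min_area_um2:
            continue
        next_label += 1
        out[labels == rp.label] = next_label
        d = 2.0 * np.sqrt(area / np.pi)
        cy, cx = rp.centroid
        records.append(
            NBRecord(
                label=next_label,
                area_um2=float(area),
                eq_diameter_um=float(d),
                size_class=size_class(d),
                centroid_um=((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size),
            )
        )
    return out, records


def fn_c_ratio(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    background: float = 0.0,
) -> float:
    """Nucleus/cytoplasm mean-intensity ratio, background-corrected; the
    cytoplasm is the cell area minus the (DNA-stain defined) nucleus."""
    image = np.asarray(image, dtype=np.float64)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not nucleus_mask.any():
        raise err("empty_nucleus")
    cyto = cell_mask & ~nucleus_mask
    if not cyto.any():
        raise err("degenerate_cytoplasm", "cell mask does not extend beyond the nucleus")
    mean_n = image[nucleus_mask].mean()
    mean_c = image[cyto].mean()
    if mean_c <= background:
        raise err("degenerate_cytoplasm", "cytoplasm signal not above background")
    return float((mean_n - background) / (mean_c - background))


def rna_ratio(
    rna_channel: np.ndarray,
    nb_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    background_region: np.ndarray,
) -> float:
    """(F_NB - F_background) / (F_nonNB - F_background) with means over the
    NB area, the non-NB nucleoplasm, and an extracellular background region."""
    rna = np.asarray(rna_channel, dtype=np.float64)
    nb_mask = np.asarray(nb_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    background_region = np.asarray(background_region, dtype=bool)
    if not nb_mask.any() or not background_region.any():
        raise err("empty_roi", "NB mask and background region must be non-empty")
    if (nb_mask & ~nucleus_mask).any():
        raise err("invalid_config", "NB mask must lie inside the nucleus")
    non_nb = nucleus_mask & ~nb_mask
    if not non_nb.any():
        raise err("degenerate_nucleoplasm", "no non-NB nucleoplasm area")
    f_nb = rna[nb_mask].mean()
    f_non = rna[non_nb].mean()
    f_bg = rna[background_region].mean()
    if f_non <= f_bg:
        raise err("degenerate_nucleoplasm", "nucleoplasm signal not above background")
    return float((f_nb - f_bg) / (f_non - f_bg))


def illumination_correct(image: np.ndarray, sigma: float | None = None) -> np.ndarray:
    """Flat-field correction: divide by a heavily smoothed (Gaussian,
    sigma = width/8 by default) illumination estimate, rescaled to preserve
    the global mean.  A flat image is returned unchanged."""
    img = np.asarray(image, dtype=np.float64)
    if sigma is None:
        sigma = img.shape[1] / 8.0
    field_est = gaussian(img, sigma=sigma, preserve_range=True)
    if np.all(field_est <= 0) or np.ptp(img) == 0:
        return img.copy()
    corrected = img / np.maximum(field_est, 1e-12 * field_est.max())
    scale = img.mean() / corrected.mean()
    return corrected * scale


def measure_nucleus(
    protein_channel: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size: float,
    rna_channel: np.ndarray | None = None,
    background_region: np.ndarray | None = None,
    cell_mask: np.ndarray | None = None,
    intensity_channel: np.ndarray | None = None,
    background: float = 0.0,
    nucleus_id=None,
    **segment_kwargs,
) -> MorphoResult:
    """Full per-nucleus quantitation: segmentation, sizes, and the optional
    intensity ratios (Fn/c needs a cell mask; RNA ratio needs an RNA channel
    plus an extracellular background region)."""
    labels, nbs = segment_nbs(protein_channel, nucleus_mask, pixel_size, **segment_kwargs)
    total = float(sum(nb.area_um2 for nb in nbs))
    mean_area = total / len(nbs) if nbs else None
    fnc = None
    if cell_mask is not None:
        chan = intensity_channel if intensity_channel is not None else protein_channel
        fnc = fn_c_ratio(chan, nucleus_mask, cell_mask, background)
    rr = None
    if rna_channel is not None and nbs:
        if background_region is None:
            raise err("empty_roi", "RNA ratio needs an extracellular background region")
        rr = rna_ratio(rna_channel, labels > 0, nucleus_mask, background_region)
    return MorphoResult(
        nbs=nbs,
        total_nb_area_um2=total,
        mean_nb_area_um2=mean_area,
        fn_c=fnc,
        rna_ratio=rr,
        nucleus_id=nucleus_id,
    )
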
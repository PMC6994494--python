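"""Fixed-cell image fixtures with known ground truth.

Renders a multi-channel nucleus image for exercising the morphometry
pipeline: a protein channel with bright NB discs over a dimmer
nucleoplasm, a DNA-stain (nucleus) channel, and an optional RNA channel
whose NB-area and non-NB-area means are specified independently.  The
ground-truth table lists every disc's true position, diameter and area and
the channel means, so measured morphometry can be compared to truth
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import err


@dataclass(frozen=True)
class NBSpot:
    """One ground-truth nuclear body: a disc of known size and brightness."""

    center_um: tuple[float, float]  # (x, y)
    diameter_um: float
    intensity: float  # protein-channel level inside the disc

    def __post_init__(self):
        if self.diameter_um <= 0:
            raise err("invalid_diameter", "NB diameter must be > 0")


@dataclass
class NucleusSpec:
    """Scene description for :func:`render_static_nucleus`.

    The nucleus and cell are concentric discs; intensities are mean counts
    per pixel per channel.  ``noise_sd`` adds i.i.d. Gaussian read noise
    (0 = noiseless ground-truth render).
    """

    shape: tuple[int, int] = (200, 200)
    pixel_size: float = 0.1  # um/px
    nucleus_center_um: tuple[float, float] | None = None  # default: image center
    nucleus_radius_um: float = 7.0
    cell_radius_um: float = 9.5
    nbs: list[NBSpot] = field(default_factory=list)
    nucleoplasm_level: float = 30.0
    cytoplasm_level: float = 12.0
    background_level: float = 2.0
    dapi_level: float = 100.0
    rna_nb_level: float | None = None
    rna_non_nb_level: float | None = None
    rna_background_level: float = 10.0
    noise_sd: float = 0.0


def _grid_um(shape: tuple[int, int], pixel_size: float):
    h, w = shape
    x = (np.arange(w)[None, :] + 0.5) * pixel_size
    y = (np.arange(h)[:, None] + 0.5) * pixel_size
    return x, y


def render_static_nucleus(
    spec: NucleusSpec, seed: int = 0
) -> tuple[dict[str, np.ndarray], pd.DataFrame, dict[str, np.ndarray]]:
    """Render the scene.

    Returns ``(channels, ground_truth, masks)`` where ``channels`` maps
    ``protein`` / ``dapi`` / (optionally) ``rna`` to H x W float images,
    ``ground_truth`` is a per-NB table (label, x, y, diameter, area), and
    ``masks`` holds the true ``nucleus`` / ``cell`` / ``nb`` boolean masks.
    """
    h, w = spec.shape
    cx, cy = spec.nucleus_center_um or (w * spec.pixel_size / 2, h * spec.pixel_size / 2)
    x, y = _grid_um(spec.shape, spec.pixel_size)
    r = np.hypot(x - cx, y - cy)
    nucleus = r <= spec.nucleus_radius_um
    cell = r <= spec.cell_radius_um

    nb_mask = np.zeros(spec.shape, dtype=bool)
    rows = []
    for i, nb in enumerate(spec.nbs, start=1):
        d = np.hypot(x - nb.center_um[0], y - nb.center_um[1])
        disc = d <= nb.diameter_um / 2
        if (disc & ~nucleus).any():
            raise err("nb_out_of_bounds", f"NB {i} extends outside the nucleus")
        nb_mask |= disc
        rows.append(
            {
                "label": i,
                "x_um": nb.center_um[0],
                "y_um": nb.center_um[1],
                "diameter_um": nb.diameter_um,
                "area_um2": np.pi * (nb.diameter_um / 2) ** 2,
                "intensity": nb.intensity,
            }
        )
    truth = pd.DataFrame(rows, columns=["label", "x_um", "y_um", "diameter_um", "area_um2", "intensity"])

    protein = np.full(spec.shape, spec.background_level)
    protein[cell] = spec.cytoplasm_level
    protein[nucleus] = spec.nucleoplasm_level
    for nb in spec.nbs:
        d = np.hypot(x - nb.center_um[0], y - nb.center_um[1])
        protein[d <= nb.diameter_um / 2] = nb.intensity

    dapi = np.full(spec.shape, spec.background_level)
    dapi[nucleus] = spec.dapi_level

    channels = {"protein": protein, "dapi": dapi}
    if spec.rna_nb_level is not None and spec.rna_non_nb_level is not None:
        rna = np.full(spec.shape, spec.rna_background_level)
        rna[nucleus] = spec.rna_non_nb_level
        rna[nb_mask] = spec.rna_nb_level
        channels["rna"] = rna

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        for k in channels:
            channels[k] = np.maximum(
                channels[k] + rng.normal(0, spec.noise_sd, spec.shape), 0.0
            )

    masks = {"nucleus": nucleus, "cell": cell, "nb": nb_mask}
    return channels, truth, masks
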
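"""Synthetic picrosirius-red-style section images with known collagen fraction.

The generator renders red collagen speckle on yellow myocardium with a white
background, optional white tissue gaps, and an optional thickened endocardial
collagen band along the top edge — the structures the fibrosis quantifier
must segment and (for band/gaps/background) exclude.  The collagen fraction
within the analysable area (myocardium + interstitial collagen) is imposed
exactly via a quantile threshold on a smooth random field, so the label mask
is usable as ground truth.

Label mask codes: 0 background, 1 myocardium, 2 collagen, 3 endocardium,
4 gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["HistologyGroundTruth", "generate_histology_image", "LABELS"]

LABELS = {"background": 0, "myocardium": 1, "collagen": 2, "endocardium": 3, "gap": 4}

#: base RGB colours of the rendered classes (8-bit)
CLASS_COLOURS = {
    0: (246, 246, 246),   # background: near-white
    1: (205, 175, 60),    # myocardium: picrosirius yellow
    2: (178, 34, 48),     # collagen: picrosirius red
    3: (150, 25, 40),     # endocardium: darker collagen red
    4: (246, 246, 246),   # gaps: background-coloured
}


@dataclass(frozen=True)
class HistologyGroundTruth:
    """Ground truth of one synthetic section.

    ``collagen_fraction`` is the true fibrosis fraction within the analysable
    area (0..1); ``endocardium_band_px`` the thickness of the excluded
    endocardial collagen band along the top edge; ``gap_fraction`` the
    fraction of the tissue area rendered as background-coloured gaps.
    """

    collagen_fraction: float = 0.159
    endocardium_band_px: int = 10
    gap_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.collagen_fraction <= 1.0:
            raise ValueError(
                f"collagen_fraction must lie in [0, 1], got {self.collagen_fraction}"
            )
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError("gap_fraction must lie in [0, 1]")
        if self.endocardium_band_px < 0:
            raise ValueError("endocardium_band_px must be >= 0")


def _smooth_field(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    return ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma)


def generate_histology_image(
    truth: HistologyGroundTruth,
    width_px: int = 512,
    height_px: int = 512,
    seed: int = 0,
    colour_noise_sd: float = 6.0,
    speckle_sigma_px: float = 1.5,
    gap_sigma_px: float = 8.0,
    edge_margin_px: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one section; returns ``(rgb_image, label_mask)``.

    ``rgb_image`` is uint8 of shape (H, W, 3); ``label_mask`` uint8 (H, W)
    with the codes in :data:`LABELS`.  A thin myocardium margin is kept along
    the image edges (and below the endocardial band) so interstitial collagen
    speckle never merges with border structures.  Deterministic per seed.
    """
    band = int(truth.endocardium_band_px)
    if height_px <= band + 2 * edge_margin_px + 10:
        raise ValueError(
            "image too small to contain the configured endocardial band"
        )
    rng = np.random.default_rng(seed)
    h, w = height_px, width_px
    labels = np.full((h, w), LABELS["myocardium"], dtype=np.uint8)

    if band > 0:
        labels[:band, :] = LABELS["endocardium"]

    # interior of the tissue where gaps and collagen speckle may appear
    interior = np.ones((h, w), dtype=bool)
    interior[: band + edge_margin_px, :] = False
    interior[h - edge_margin_px:, :] = False
    interior[:, :edge_margin_px] = False
    interior[:, w - edge_margin_px:] = False

    if truth.gap_fraction > 0:
        gap_field = _smooth_field((h, w), gap_sigma_px, rng)
        thr = np.quantile(gap_field[interior], 1.0 - truth.gap_fraction)
        gaps = (gap_field > thr) & interior
        labels[gaps] = LABELS["gap"]

    # collagen speckle is placeable only in the interior, but the imposed
    # fraction is taken over the full analysable area (interior + the thin
    # myocardium margins), so the ground-truth fraction is exact
    placeable = interior & (labels == LABELS["myocardium"])
    n_analysable = int(np.sum(labels == LABELS["myocardium"]))
    if truth.collagen_fraction > 0 and placeable.any():
        n_col = int(round(truth.collagen_fraction * n_analysable))
        n_placeable = int(placeable.sum())
        if n_col > n_placeable:
            raise ValueError(
                "collagen_fraction too high for the placeable interior area"
            )
        speckle = _smooth_field((h, w), speckle_sigma_px, rng)
        thr = np.quantile(speckle[placeable], 1.0 - n_col / n_placeable)
        collagen = (speckle > thr) & placeable
        labels[collagen] = LABELS["collagen"]

    img = np.zeros((h, w, 3), dtype=float)
    for code, colour in CLASS_COLOURS.items():
        img[labels == code] = colour
    if colour_noise_sd > 0:
        img += rng.normal(0.0, colour_noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), labels


def true_percent_fibrosis(labels: np.ndarray) -> float:
    """Ground-truth percent-fibrosis of a label mask: collagen / (collagen +
    myocardium) within the analysable area, as a percentage."""
    col = int(np.sum(labels == LABELS["collagen"]))
    myo = int(np.sum(labels == LABELS["myocardium"]))
    if col + myo == 0:
        return float("nan")
    return 100.0 * col / (col + myo)
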
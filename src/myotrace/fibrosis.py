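"""Percent-fibrosis quantification from picrosirius-red-stained sections.

Pixels are classified in hue/saturation/value space: red hues are collagen,
yellow hues myocardium, and low-saturation or very bright pixels are
background/gap candidates.  Non-analysable structures — background, tissue
gaps, and thick collagen bands at the tissue border (thickened endocardium or
other non-myocardial collagen) — are excluded before computing

    percent_fibrosis = 100 · collagen / (collagen + myocardium)

over the analysed area.  Per-patient values are unweighted means over
sections (protocol minimum 30 sections per patient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

__all__ = [
    "PixelClass",
    "SectionQuantification",
    "classify_pixels",
    "build_exclusion_mask",
    "percent_fibrosis",
    "quantify_section",
    "aggregate_patient",
]


class PixelClass:
    CANDIDATE_EXCLUDED = 0
    MYOCARDIUM = 1
    COLLAGEN = 2


# decision-rule defaults (degrees / unit fractions), config-exposed
COLLAGEN_HUE_DEG = (330.0, 25.0)   # wrap-around red band
MYOCARDIUM_HUE_DEG = (25.0, 90.0)  # yellow band, exclusive lower edge
MIN_SATURATION = 0.25
BACKGROUND_VALUE = 0.95
ENDO_MIN_THICKNESS_PX = 8
DEFAULT_MIN_SECTIONS = 30


@dataclass
class SectionQuantification:
    """Pixel-class areas and percent-fibrosis of one section."""

    collagen_px: int
    myocardium_px: int
    excluded_px: int
    usable: bool = True
    section_id: str = ""

    @property
    def total_px(self) -> int:
        return self.collagen_px + self.myocardium_px + self.excluded_px

    @property
    def percent_fibrosis(self) -> float:
        denom = self.collagen_px + self.myocardium_px
        if denom == 0:
            return float("nan")
        return 100.0 * self.collagen_px / denom

    def as_dict(self) -> dict:
        return {
            "section_id": self.section_id,
            "collagen_px": self.collagen_px,
            "myocardium_px": self.myocardium_px,
            "excluded_px": self.excluded_px,
            "percent_fibrosis": self.percent_fibrosis,
            "usable": self.usable,
        }


def classify_pixels(
    image: np.ndarray,
    collagen_hue_deg: tuple = COLLAGEN_HUE_DEG,
    myocardium_hue_deg: tuple = MYOCARDIUM_HUE_DEG,
    min_saturation: float = MIN_SATURATION,
    background_value: float = BACKGROUND_VALUE,
) -> np.ndarray:
    """Per-pixel class labels for an 8-bit RGB section image.

    Returns uint8 labels: 0 candidate-excluded (background/gap/other), 1
    myocardium, 2 collagen.  Deterministic; raises on non-RGB input.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an RGB image of shape (H, W, 3), got shape {image.shape}"
        )
    hsv = rgb2hsv(image)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]

    tissue = (sat >= min_saturation) & (val < background_value)
    lo, hi = collagen_hue_deg
    red = (hue >= lo) | (hue <= hi) if lo > hi else (hue >= lo) & (hue <= hi)
    mlo, mhi = myocardium_hue_deg
    yellow = (hue > mlo) & (hue <= mhi)

    labels = np.zeros(image.shape[:2], dtype=np.uint8)
    labels[tissue & red] = PixelClass.COLLAGEN
    labels[tissue & yellow] = PixelClass.MYOCARDIUM
    return labels


def build_exclusion_mask(
    label_mask: np.ndarray,
    endo_min_thickness_px: int = ENDO_MIN_THICKNESS_PX,
) -> tuple[np.ndarray, bool]:
    """Final exclusion mask: background/gaps plus border collagen bands.

    A collagen component is treated as endocardium / non-myocardial collagen
    and excluded when it touches the tissue border (the image edge or the
    outer background) and its local thickness — twice the maximum distance
    from the component to its complement — reaches ``endo_min_thickness_px``.
    Interior gaps do not define a tissue border.

    Returns ``(excluded, usable)`` where ``excluded`` is a boolean mask and
    ``usable`` is False when no analysable tissue remains.
    """
    labels = np.asarray(label_mask)
    excluded = labels == PixelClass.CANDIDATE_EXCLUDED

    # the tissue border: image edge plus outer background (components of the
    # candidate-excluded class that touch the image edge)
    border = np.zeros(labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    bg_comp, n_bg = ndimage.label(excluded)
    if n_bg:
        edge_ids = np.unique(bg_comp[border])
        edge_ids = edge_ids[edge_ids > 0]
        outer_bg = np.isin(bg_comp, edge_ids)
        border = border | ndimage.binary_dilation(outer_bg)

    collagen = labels == PixelClass.COLLAGEN
    comp, n = ndimage.label(collagen)
    if n:
        touching = np.unique(comp[border & collagen])
        touching = touching[touching > 0]
        for cid in touching:
            mask = comp == cid
            thickness = 2.0 * float(ndimage.distance_transform_edt(mask).max())
            if thickness >= endo_min_thickness_px:
                excluded = excluded | mask

    usable = bool(np.any(~excluded & (labels != PixelClass.CANDIDATE_EXCLUDED)))
    return excluded, usable


def percent_fibrosis(
    label_mask: np.ndarray,
    excluded: np.ndarray | None = None,
    section_id: str = "",
) -> SectionQuantification:
    """Quantify one classified section (optionally with an exclusion mask)."""
    labels = np.asarray(label_mask)
    if excluded is None:
        excluded = labels == PixelClass.CANDIDATE_EXCLUDED
    keep = ~excluded
    col = int(np.sum(keep & (labels == PixelClass.COLLAGEN)))
    myo = int(np.sum(keep & (labels == PixelClass.MYOCARDIUM)))
    q = SectionQuantification(
        collagen_px=col,
        myocardium_px=myo,
        excluded_px=int(labels.size - col - myo),
        usable=(col + myo) > 0,
        section_id=section_id,
    )
    return q


def quantify_section(
    image: np.ndarray,
    section_id: str = "",
    endo_min_thickness_px: int = ENDO_MIN_THICKNESS_PX,
    **classify_kwargs,
) -> SectionQuantification:
    """Full per-section pipeline: classify, exclude, quantify."""
    labels = classify_pixels(image, **classify_kwargs)
    excluded, usable = build_exclusion_mask(labels, endo_min_thickness_px)
    q = percent_fibrosis(labels, excluded, section_id=section_id)
    q.usable = q.usable and usable
    return q


def aggregate_patient(
    section_values,
    min_sections: int = DEFAULT_MIN_SECTIONS,
) -> dict:
    """Patient-level percent-fibrosis: unweighted mean over usable sections.

    ``section_values`` may be floats or :class:`SectionQuantification`
    objects (unusable sections are dropped).  Warns when fewer than
    ``min_sections`` usable sections are available; returns NaN mean (with a
    warning) when none are.
    """
    vals = []
    for s in section_values:
        if isinstance(s, SectionQuantification):
            if s.usable and np.isfinite(s.percent_fibrosis):
                vals.append(s.percent_fibrosis)
        elif np.isfinite(s):
            vals.append(float(s))
    n = len(vals)
    if n == 0:
        warnings.warn("no usable sections; patient excluded", stacklevel=2)
        return {"percent_fibrosis": float("nan"), "sd": float("nan"), "n_sections": 0}
    if n < min_sections:
        warnings.warn(
            f"only {n} usable sections (protocol minimum is {min_sections})",
            stacklevel=2,
        )
    arr = np.asarray(vals)
    return {
        "percent_fibrosis": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if n > 1 else 0.0,
        "n_sections": n,
    }
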
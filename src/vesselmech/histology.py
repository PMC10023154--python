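"""Rule-based color segmentation of stained arterial cross-sections.

Movat pentachrome separates elastic fibers (black), cell cytoplasm (red),
proteoglycans/glycosaminoglycans (blue) and collagen (gray-yellow); Alizarin
red marks calcium deposits dark red.  Pixels are classified by fixed
hue/saturation/value rules (configurable thresholds), so segmentation is
deterministic and invariant to image orientation.  Area fractions are always
reported relative to tissue pixels (optionally restricted to a layer mask,
e.g. the media), never to the whole image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

from .exceptions import ValidationError

__all__ = ["MovatConfig", "AlizarinConfig", "SegmentationResult",
           "segment_movat", "segment_alizarin", "replicate_average",
           "MOVAT_CLASSES"]

MOVAT_CLASSES = ("elastin", "cytoplasm", "proteoglycan", "collagen")

#: label codes shared by both stains
LABELS = {"background": 0, "elastin": 1, "cytoplasm": 2, "proteoglycan": 3,
          "collagen": 4, "unclassified": 5, "calcified": 6}


@dataclass(frozen=True)
class MovatConfig:
    """HSV thresholds of the Movat classifier (hue in degrees)."""

    red_band: tuple = (-20.0, 20.0)        # cytoplasm
    yellow_band: tuple = (35.0, 70.0)      # collagen
    blue_band: tuple = (190.0, 260.0)      # proteoglycans
    elastin_v_max: float = 0.25
    background_s_max: float = 0.15
    background_v_min: float = 0.85
    #: hue is meaningless for near-achromatic pixels; stained classes must
    #: clear this saturation floor or they remain unclassified
    min_saturation: float = 0.15


@dataclass(frozen=True)
class AlizarinConfig:
    """Thresholds of the Alizarin calcium classifier."""

    red_band: tuple = (-30.0, 30.0)
    calcified_s_min: float = 0.40
    calcified_v_max: float = 0.65
    background_s_max: float = 0.15
    background_v_min: float = 0.85


@dataclass
class SegmentationResult:
    label_map: np.ndarray
    tissue_mask: np.ndarray
    area_fractions: dict
    layer_fractions: dict | None = None
    n_tissue_pixels: int = 0

    def fraction(self, name: str, layer: bool = False) -> float:
        d = self.layer_fractions if layer else self.area_fractions
        return d[name]


def _hsv(image):
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("expected an RGB image (H, W, 3)")
    if image.dtype != np.uint8:
        image = np.clip(np.asarray(image, dtype=float), 0, 255).astype(np.uint8)
    hsv = rgb2hsv(image)
    hue_deg = hsv[..., 0] * 360.0
    return hue_deg, hsv[..., 1], hsv[..., 2]


def _in_hue_band(hue_deg, band):
    lo, hi = band
    lo %= 360.0
    hi %= 360.0
    if lo <= hi:
        return (hue_deg >= lo) & (hue_deg <= hi)
    return (hue_deg >= lo) | (hue_deg <= hi)  # band wraps through 0


def _fractions(label_map, mask, names):
    n = int(mask.sum())
    return {name: float((label_map[mask] == LABELS[name]).sum()) / n
            for name in names}


def segment_movat(image, config: MovatConfig | None = None, tissue_mask=None,
                  layer_mask=None) -> SegmentationResult:
    """Classify a Movat-stained section into the four tissue classes.

    Classification order: background (bright, desaturated) first, elastin
    (dark) next, then the hue bands; remaining tissue pixels are
    ``unclassified``.  Fractions use tissue pixels as the denominator; when
    ``layer_mask`` is given, ``layer_fractions`` restricts the denominator
    to tissue pixels inside the layer.
    """
    config = config or MovatConfig()
    hue, sat, val = _hsv(image)
    background = (sat <= config.background_s_max) & \
                 (val >= config.background_v_min)
    if tissue_mask is None:
        tissue_mask = ~background
    else:
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not tissue_mask.any():
        raise ValidationError("empty tissue: no tissue pixels in the image")

    labels = np.full(hue.shape, LABELS["unclassified"], dtype=np.uint8)
    stained = sat >= config.min_saturation
    labels[stained & _in_hue_band(hue, config.yellow_band)] = \
        LABELS["collagen"]
    labels[stained & _in_hue_band(hue, config.blue_band)] = \
        LABELS["proteoglycan"]
    labels[stained & _in_hue_band(hue, config.red_band)] = \
        LABELS["cytoplasm"]
    labels[val <= config.elastin_v_max] = LABELS["elastin"]
    labels[~tissue_mask] = LABELS["background"]

    names = MOVAT_CLASSES + ("unclassified",)
    fractions = _fractions(labels, tissue_mask, names)
    layer_fractions = None
    if layer_mask is not None:
        layer = np.asarray(layer_mask, dtype=bool) & tissue_mask
        if not layer.any():
            raise ValidationError("empty tissue: layer mask holds no tissue")
        layer_fractions = _fractions(labels, layer, names)
    return SegmentationResult(label_map=labels, tissue_mask=tissue_mask,
                              area_fractions=fractions,
                              layer_fractions=layer_fractions,
                              n_tissue_pixels=int(tissue_mask.sum()))


def segment_alizarin(image, config: AlizarinConfig | None = None,
                     tissue_mask=None, layer_mask=None) -> SegmentationResult:
    """Calcified area fraction of an Alizarin-red-stained section."""
    config = config or AlizarinConfig()
    hue, sat, val = _hsv(image)
    background = (sat <= config.background_s_max) & \
                 (val >= config.background_v_min)
    if tissue_mask is None:
        tissue_mask = ~background
    else:
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not tissue_mask.any():
        raise ValidationError("empty tissue: no tissue pixels in the image")

    calcified = (_in_hue_band(hue, config.red_band)
                 & (sat >= config.calcified_s_min)
                 & (val <= config.calcified_v_max))
    labels = np.full(hue.shape, LABELS["unclassified"], dtype=np.uint8)
    labels[calcified] = LABELS["calcified"]
    labels[~tissue_mask] = LABELS["background"]

    fractions = _fractions(labels, tissue_mask, ("calcified",))
    layer_fractions = None
    if layer_mask is not None:
        layer = np.asarray(layer_mask, dtype=bool) & tissue_mask
        if not layer.any():
            raise ValidationError("empty tissue: layer mask holds no tissue")
        layer_fractions = _fractions(labels, layer, ("calcified",))
    return SegmentationResult(label_map=labels, tissue_mask=tissue_mask,
                              area_fractions=fractions,
                              layer_fractions=layer_fractions,
                              n_tissue_pixels=int(tissue_mask.sum()))


def replicate_average(fraction_dicts, dispersion_bound: float = 0.05):
    """Specimen-level mean class fractions over >= 1 replicate sections.

    Returns ``(means, dispersion, warnings)`` where dispersion is the
    per-class max-min range across replicates; classes whose range exceeds
    ``dispersion_bound`` are flagged.
    """
    fraction_dicts = list(fraction_dicts)
    if not fraction_dicts:
        raise ValidationError("no replicates to average")
    names = fraction_dicts[0].keys()
    means, spread, warns = {}, {}, []
    for name in names:
        vals = np.array([d[name] for d in fraction_dicts], dtype=float)
        means[name] = float(vals.mean())
        spread[name] = float(vals.max() - vals.min())
        if spread[name] > dispersion_bound:
            warns.append(f"{name}: replicate range {spread[name]:.3f} "
                         f"exceeds {dispersion_bound:.3f}")
    return means, spread, warns
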
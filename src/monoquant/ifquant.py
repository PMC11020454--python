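"""Immunofluorescence quantification of marker intensity and nuclear localization.

Implements the two-score scheme used for β-catenin translocation in
monocytes: after background elimination, (i) the mean field intensity of the
marker channel standardized to the average DAPI value of the whole slide,
and (ii) a nuclear localization score — the marker signal on non-background
DAPI (nuclear) pixels standardized to the DAPI intensity of the same pixels.
Per-slide summaries are means over at least five usable fields; donors are
compared with paired two-sided t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from . import statcore
from .errors import (
    DegenerateImageError,
    EmptyForegroundError,
    InsufficientFieldsError,
    InvalidParameterError,
    PairingError,
)

__all__ = [
    "ImageFieldPair",
    "SlideQuant",
    "background_mask",
    "field_intensity_score",
    "nuclear_localization_score",
    "summarize_slide",
    "compare_donor_pairs",
]

logger = logging.getLogger(__name__)

MIN_FIELDS = 5


@dataclass
class ImageFieldPair:
    """Co-registered DAPI/marker pixel matrices for one microscope field."""

    dapi: np.ndarray
    marker: np.ndarray
    field_id: str = ""
    slide_id: str = ""
    bit_depth: int = 16

    def __post_init__(self):
        self.dapi = np.asarray(self.dapi)
        self.marker = np.asarray(self.marker)
        if self.dapi.shape != self.marker.shape:
            raise InvalidParameterError("DAPI and marker channels must share a shape")
        if self.dapi.ndim != 2 or self.dapi.size == 0:
            raise InvalidParameterError("channels must be non-empty 2-D matrices")
        cap = 2**self.bit_depth - 1
        for name, ch in (("dapi", self.dapi), ("marker", self.marker)):
            if np.any(np.asarray(ch, dtype=float) < 0):
                raise InvalidParameterError(f"{name} channel has negative intensities")
            if np.any(np.asarray(ch, dtype=float) > cap):
                raise InvalidParameterError(f"{name} exceeds the {self.bit_depth}-bit range")


@dataclass
class SlideQuant:
    """Per-slide quantification summary (means over usable fields)."""

    per_field_intensity: dict
    per_field_nuclear: dict
    slide_mean_intensity: float
    slide_mean_nuclear: float
    n_fields: int
    slide_id: str = ""
    excluded_fields: list = field(default_factory=list)


def background_mask(channel, method: str = "otsu", param: float | None = None) -> np.ndarray:
    """Boolean foreground mask (True = signal) for one channel.

    method="otsu" thresholds at the between-class-variance maximizer;
    "quantile" keeps pixels above the ``param`` quantile; "fixed" keeps
    pixels strictly above ``param``.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise InvalidParameterError("empty channel")
    if np.any(channel < 0):
        raise InvalidParameterError("negative intensities")
    if method == "otsu":
        if np.all(channel == channel.flat[0]):
            raise DegenerateImageError("constant image: no threshold separates classes")
        t = threshold_otsu(channel)
        return channel > t
    if method == "quantile":
        if param is None or not (0 <= param < 1):
            raise InvalidParameterError("quantile method needs param in [0, 1)")
        return channel > np.quantile(channel, param)
    if method == "fixed":
        if param is None:
            raise InvalidParameterError("fixed method needs a threshold param")
        return channel > param
    raise InvalidParameterError(f"unknown mask method {method!r}")


def field_intensity_score(
    fld: ImageFieldPair, slide_dapi_mean: float, mask_method: str = "otsu", mask_param=None
) -> float:
    """Mean foreground marker intensity standardized to the slide DAPI mean.

    The slide-level DAPI mean removes slide-to-slide illumination changes so
    that fields from different slides are comparable.
    """
    if not slide_dapi_mean > 0:
        raise InvalidParameterError("slide_dapi_mean must be positive")
    mask = background_mask(fld.marker, mask_method, mask_param)
    if not mask.any():
        raise EmptyForegroundError(f"field {fld.field_id}: no foreground marker pixels")
    return float(np.asarray(fld.marker, dtype=float)[mask].mean() / slide_dapi_mean)


def nuclear_localization_score(
    fld: ImageFieldPair, mask_method: str = "otsu", mask_param=None
) -> float:
    """Marker/DAPI intensity ratio over non-background DAPI (nuclear) pixels."""
    mask = background_mask(fld.dapi, mask_method, mask_param)
    if not mask.any():
        raise EmptyForegroundError(f"field {fld.field_id}: no foreground DAPI pixels")
    dapi = np.asarray(fld.dapi, dtype=float)[mask]
    marker = np.asarray(fld.marker, dtype=float)[mask]
    return float(marker.mean() / dapi.mean())


def slide_dapi_mean(
    fields, mask_method: str = "otsu", mask_param=None, foreground_only: bool = True
) -> float:
    """Average DAPI value of the entire slide.

    By default computed over foreground DAPI pixels pooled across all
    fields (background pixels carry no nuclear signal); set
    ``foreground_only=False`` to average every pixel.
    """
    pixels = []
    for fld in fields:
        dapi = np.asarray(fld.dapi, dtype=float)
        if foreground_only:
            try:
                mask = background_mask(dapi, mask_method, mask_param)
            except DegenerateImageError:
                continue
            if mask.any():
                pixels.append(dapi[mask])
        else:
            pixels.append(dapi.ravel())
    if not pixels:
        raise EmptyForegroundError("no DAPI foreground pixels on the slide")
    return float(np.concatenate(pixels).mean())


def summarize_slide(
    fields,
    mask_method: str = "otsu",
    mask_param=None,
    min_fields: int = MIN_FIELDS,
    dapi_foreground_only: bool = True,
) -> SlideQuant:
    """Quantify every field of a slide and average the usable ones.

    Fields whose masks leave no foreground are excluded and logged, never
    imputed. Raises InsufficientFieldsError below ``min_fields`` usable
    fields, the minimum for a slide summary entering donor comparisons.
    """
    fields = list(fields)
    dapi_mean = slide_dapi_mean(fields, mask_method, mask_param, dapi_foreground_only)
    per_int, per_nuc, excluded = {}, {}, []
    for i, fld in enumerate(fields):
        fid = fld.field_id or str(i)
        try:
            per_int[fid] = field_intensity_score(fld, dapi_mean, mask_method, mask_param)
            per_nuc[fid] = nuclear_localization_score(fld, mask_method, mask_param)
        except (EmptyForegroundError, DegenerateImageError) as exc:
            logger.warning("excluding field %s: %s", fid, exc)
            excluded.append(fid)
    if len(per_int) < min_fields:
        raise InsufficientFieldsError(
            f"only {len(per_int)} usable fields (< {min_fields}) on slide"
        )
    return SlideQuant(
        per_field_intensity=per_int,
        per_field_nuclear=per_nuc,
        slide_mean_intensity=float(np.mean(list(per_int.values()))),
        slide_mean_nuclear=float(np.mean(list(per_nuc.values()))),
        n_fields=len(per_int),
        slide_id=fields[0].slide_id if fields else "",
        excluded_fields=excluded,
    )


def compare_donor_pairs(control: dict, treated: dict, metric: str = "nuclear") -> statcore.TestResult:
    """Paired two-sided t-test of per-donor slide means, treated vs control."""
    if set(control) != set(treated):
        raise PairingError("control and treated donor sets differ")
    if len(control) < 2:
        raise PairingError("need at least two donors for a paired test")
    attr = {"intensity": "slide_mean_intensity", "nuclear": "slide_mean_nuclear"}.get(metric)
    if attr is None:
        raise InvalidParameterError(f"unknown metric {metric!r}")
    donors = sorted(control)
    a = [getattr(treated[d], attr) for d in donors]
    b = [getattr(control[d], attr) for d in donors]
    return statcore.paired_t(a, b)
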
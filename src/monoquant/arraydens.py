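"""Serial-exposure antibody-array densitometry.

A chemiluminescent membrane array is imaged repeatedly (one frame every few
seconds) while spot signal accumulates; bright spots eventually clip at the
camera's bit-depth maximum, which invalidates intensity ratios. For each
analyte the pipeline picks the best exposure — the latest frame acquired
before saturation of the analyte's spots or of any positive-control spot on
either membrane — then background-corrects duplicate spot densities,
normalizes the treated membrane by the positive-control ratio, and reports
the fold change of normalized treated signal over raw control signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist

from .errors import (
    GeometryError,
    InvalidParameterError,
    MissingDataError,
    SchemaError,
    UnquantifiableAnalyteError,
)

__all__ = [
    "ArrayLayout",
    "ExposureSeries",
    "AnalyteFoldChange",
    "spot_densities",
    "saturation_frame",
    "select_quantification_frame",
    "background_correct",
    "analyte_fold_change",
    "detection_call",
    "cluster_heatmap",
    "quantify_membrane_pair",
]

POS, NEG, BLANK = "POS", "NEG", "BLANK"
CONTROL_ROLES = {POS, NEG, BLANK}

#: a spot counts as saturated when at least this fraction of its disc clips
DEFAULT_SAT_FRACTION = 0.05


@dataclass
class ArrayLayout:
    """Spot grid of an antibody-array membrane.

    ``spot_map`` assigns each occupied (row, col) grid cell a role: an
    analyte name, "POS", "NEG" or "BLANK". Duplicate spots of the same
    analyte are derived from the map.
    """

    grid_shape: tuple
    spot_map: dict
    spot_radius_px: int
    spacing_px: int = 16
    margin_px: int = 12

    def __post_init__(self):
        roles = set(self.spot_map.values())
        if POS not in roles or NEG not in roles:
            raise SchemaError("layout must include POS and NEG control spots")
        nr, nc = self.grid_shape
        for (r, c) in self.spot_map:
            if not (0 <= r < nr and 0 <= c < nc):
                raise SchemaError(f"spot ({r},{c}) outside grid {self.grid_shape}")

    @property
    def analytes(self) -> list:
        return sorted({v for v in self.spot_map.values() if v not in CONTROL_ROLES})

    def coords_for(self, role) -> list:
        coords = [rc for rc, v in self.spot_map.items() if v == role]
        if not coords:
            raise SchemaError(f"no spot with role {role!r}")
        return sorted(coords)

    @property
    def duplicates(self) -> dict:
        return {a: self.coords_for(a) for a in self.analytes}

    def center_px(self, rc) -> tuple:
        r, c = rc
        return (self.margin_px + r * self.spacing_px, self.margin_px + c * self.spacing_px)

    def frame_shape(self) -> tuple:
        nr, nc = self.grid_shape
        return (
            2 * self.margin_px + (nr - 1) * self.spacing_px + 1,
            2 * self.margin_px + (nc - 1) * self.spacing_px + 1,
        )


@dataclass
class ExposureSeries:
    """Time-ordered frames of one membrane plus its spot layout."""

    frames: list
    frame_interval: float
    bit_depth: int
    layout: ArrayLayout
    membrane_id: str = ""
    condition: str = "control"
    #: intensity at which pixels clip; defaults to the bit-depth maximum.
    #: May exceed it (e.g. inf) for an idealized camera that never saturates.
    saturation_level: float | None = None

    def __post_init__(self):
        if len(self.frames) < 2:
            raise InvalidParameterError("an exposure series needs at least two frames")
        shapes = {np.asarray(f).shape for f in self.frames}
        if len(shapes) != 1:
            raise InvalidParameterError("frames differ in shape")
        if self.saturation_level is None:
            self.saturation_level = float(2**self.bit_depth - 1)


@dataclass
class AnalyteFoldChange:
    analyte: str
    frame_used: int
    control_density: float
    treated_density_normalized: float
    fold_change: float
    detected: bool
    undefined: bool = False


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def spot_densities(frame, layout: ArrayLayout, saturation_level: float | None = None, bit_depth: int = 16):
    """Per-spot raw density (mean disc intensity) and clipped-pixel fraction.

    A pixel counts toward ``saturated_fraction`` when it sits at or above
    ``saturation_level`` (the bit-depth maximum unless stated otherwise).
    """
    frame = np.asarray(frame, dtype=float)
    cap = float(2**bit_depth - 1) if saturation_level is None else float(saturation_level)
    dens, satur = {}, {}
    for rc in layout.spot_map:
        center = layout.center_px(rc)
        r = layout.spot_radius_px
        if (
            center[0] - r < 0
            or center[1] - r < 0
            or center[0] + r >= frame.shape[0]
            or center[1] + r >= frame.shape[1]
        ):
            raise GeometryError(f"spot {rc} disc exceeds frame bounds")
        mask = _disc_mask(frame.shape, center, r)
        px = frame[mask]
        dens[rc] = float(px.mean())
        satur[rc] = float((px >= cap).mean())
    return dens, satur


def saturation_frame(
    series: ExposureSeries, coords, sat_fraction_threshold: float = DEFAULT_SAT_FRACTION
):
    """Index of the first frame where any given spot is saturated, else None."""
    coords = list(coords)
    if not coords:
        raise InvalidParameterError("empty coordinate set")
    if not (0 < sat_fraction_threshold <= 1):
        raise InvalidParameterError("sat_fraction_threshold must lie in (0, 1]")
    for i, frame in enumerate(series.frames):
        _, satur = spot_densities(frame, series.layout, series.saturation_level, series.bit_depth)
        if any(satur[rc] >= sat_fraction_threshold for rc in coords):
            return i
    return None


def select_quantification_frame(
    control: ExposureSeries,
    treated: ExposureSeries,
    analyte: str,
    sat_fraction_threshold: float = DEFAULT_SAT_FRACTION,
) -> int:
    """Best exposure for an analyte: the latest frame strictly before any
    saturation of the analyte's spots or of the positive controls, on either
    membrane."""
    limits = []
    for series in (control, treated):
        coords = series.layout.coords_for(analyte)
        pos = series.layout.coords_for(POS)
        for cs in (coords, pos):
            sf = saturation_frame(series, cs, sat_fraction_threshold)
            if sf is not None:
                limits.append(sf)
    n_frames = min(len(control.frames), len(treated.frames))
    idx = (min(limits) if limits else n_frames) - 1
    idx = min(idx, n_frames - 1)
    if idx < 0:
        raise UnquantifiableAnalyteError(
            f"{analyte}: saturated at the first exposure on some membrane"
        )
    return idx


def background_correct(densities: dict, layout: ArrayLayout) -> dict:
    """Background-subtracted density per analyte.

    Background = mean raw density of NEG and BLANK spots pooled; duplicates
    of an analyte are averaged after subtraction; results floored at zero.
    """
    bg_coords = [rc for rc, v in layout.spot_map.items() if v in (NEG, BLANK)]
    if not bg_coords:
        raise SchemaError("layout has no NEG/BLANK spots for background estimation")
    missing = [rc for rc in layout.spot_map if rc not in densities]
    if missing:
        raise SchemaError(f"densities missing for spots {missing}")
    background = float(np.mean([densities[rc] for rc in bg_coords]))
    out = {}
    for analyte, coords in layout.duplicates.items():
        vals = [max(densities[rc] - background, 0.0) for rc in coords]
        out[analyte] = float(np.mean(vals))
    return out


def pos_reference(densities: dict, layout: ArrayLayout) -> float:
    """Mean background-corrected density of the positive-control spots."""
    bg_coords = [rc for rc, v in layout.spot_map.items() if v in (NEG, BLANK)]
    background = float(np.mean([densities[rc] for rc in bg_coords]))
    pos = [max(densities[rc] - background, 0.0) for rc in layout.coords_for(POS)]
    return float(np.mean(pos))


def analyte_fold_change(
    control_corrected: dict, treated_corrected: dict, control_pos: float, treated_pos: float
) -> dict:
    """Fold change of positive-control-normalized treated signal over raw
    control signal: FC(a) = treated(a) * (POS_control / POS_treated) / control(a).

    Analytes with a zero control density get ``fold_change=nan`` and an
    ``undefined`` flag rather than a fabricated value.
    """
    if not (control_pos > 0 and treated_pos > 0):
        raise InvalidParameterError("positive-control densities must be positive")
    scale = control_pos / treated_pos
    out = {}
    for a in control_corrected:
        num = treated_corrected[a] * scale
        den = control_corrected[a]
        if den == 0:
            out[a] = {"fold_change": float("nan"), "undefined": True}
        else:
            out[a] = {"fold_change": float(num / den), "undefined": False}
    return out


def detection_call(corrected_per_membrane, neg_sd: float, k: float = 3.0) -> set:
    """Analytes whose corrected density exceeds k*SD(negative controls) on
    every membrane considered ('clearly detected')."""
    if not k > 0:
        raise InvalidParameterError("k must be positive")
    membranes = list(corrected_per_membrane)
    if not membranes:
        return set()
    analytes = set(membranes[0])
    threshold = k * neg_sd
    return {a for a in analytes if all(m[a] > threshold for m in membranes)}


def cluster_heatmap(log2fc, row_labels=None, col_labels=None, ax=None):
    """Average-linkage hierarchical clustering of a donors x analytes log2FC
    matrix on both axes (Euclidean distance), with a zero-centered heatmap.

    Returns a dict with row/column leaf orders, the two linkage matrices and
    the matplotlib figure (None if rendering is skipped via ``ax=False``).
    """
    m = np.asarray(log2fc, dtype=float)
    if np.isnan(m).any():
        raise MissingDataError("log2FC matrix contains NaN; drop undetected analytes first")
    row_link = linkage(pdist(m, metric="euclidean"), method="average")
    col_link = linkage(pdist(m.T, metric="euclidean"), method="average")
    row_order = dendrogram(row_link, no_plot=True)["leaves"]
    col_order = dendrogram(col_link, no_plot=True)["leaves"]

    fig = None
    if ax is not False:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax_ = plt.subplots(figsize=(6, max(3, 0.3 * m.shape[1])))
        ordered = m[np.ix_(row_order, col_order)].T  # analytes on Y per the figure style
        lim = max(abs(ordered.min()), abs(ordered.max()), 1e-12)
        im = ax_.imshow(ordered, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
        if row_labels is not None:
            ax_.set_xticks(range(len(row_order)))
            ax_.set_xticklabels([row_labels[i] for i in row_order], rotation=90)
        if col_labels is not None:
            ax_.set_yticks(range(len(col_order)))
            ax_.set_yticklabels([col_labels[i] for i in col_order], fontsize=7)
        fig.colorbar(im, ax=ax_, label="log2(FC)")
        fig.tight_layout()
    return {
        "row_order": row_order,
        "col_order": col_order,
        "row_linkage": row_link,
        "col_linkage": col_link,
        "figure": fig,
    }


def quantify_membrane_pair(
    control: ExposureSeries,
    treated: ExposureSeries,
    sat_fraction_threshold: float = DEFAULT_SAT_FRACTION,
    detection_k: float = 3.0,
) -> dict:
    """Full densitometry pipeline for one control/treated membrane pair.

    Per analyte: pick the quantification frame, background-correct both
    membranes on that frame, normalize by the positive-control ratio and
    report the fold change plus a detection call against k*SD of the
    negative-control spots.
    """
    layout = control.layout
    results = {}
    for analyte in layout.analytes:
        try:
            idx = select_quantification_frame(control, treated, analyte, sat_fraction_threshold)
        except UnquantifiableAnalyteError:
            results[analyte] = AnalyteFoldChange(
                analyte, -1, float("nan"), float("nan"), float("nan"), False, undefined=True
            )
            continue
        dens_c, _ = spot_densities(
            control.frames[idx], layout, control.saturation_level, control.bit_depth
        )
        dens_t, _ = spot_densities(
            treated.frames[idx], treated.layout, treated.saturation_level, treated.bit_depth
        )
        corr_c = background_correct(dens_c, layout)
        corr_t = background_correct(dens_t, treated.layout)
        pos_c = pos_reference(dens_c, layout)
        pos_t = pos_reference(dens_t, treated.layout)
        fc = analyte_fold_change(
            {analyte: corr_c[analyte]}, {analyte: corr_t[analyte]}, pos_c, pos_t
        )[analyte]

        neg_vals_c = [dens_c[rc] for rc in layout.spot_map if layout.spot_map[rc] == NEG]
        neg_vals_t = [dens_t[rc] for rc in layout.spot_map if layout.spot_map[rc] == NEG]
        neg_sd = float(np.std(neg_vals_c + neg_vals_t, ddof=1)) if len(neg_vals_c + neg_vals_t) > 1 else 0.0
        detected = bool(
            detection_call([{analyte: corr_c[analyte]}, {analyte: corr_t[analyte]}], neg_sd, detection_k)
        )
        results[analyte] = AnalyteFoldChange(
            analyte=analyte,
            frame_used=idx,
            control_density=corr_c[analyte],
            treated_density_normalized=corr_t[analyte] * pos_c / pos_t,
            fold_change=fc["fold_change"],
            detected=detected,
            undefined=fc["undefined"],
        )
    return results
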
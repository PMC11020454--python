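"""Seeded synthetic-data generators for every input modality.

Each generator emulates one assay of the monocyte Wnt-3a study — paired
immunofluorescence slides, serial-exposure antibody-array membranes, donor
Cq panels, NB-distributed RNA-seq counts with donor batch effects, 4PL
ELISA plates, and paired transwell count tables — and returns the data
together with a machine-readable :class:`TruthRecord` holding every
parameter and the ground truth, so every downstream quantification stage is
testable without any external download.

All randomness flows through a single ``numpy.random.default_rng(seed)``
stream per call; the same seed and parameters give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arraydens import ArrayLayout, ExposureSeries
from .assaycurves import Curve4PL
from .destage import CountMatrix
from .errors import InvalidParameterError, SchemaError
from .ifquant import ImageFieldPair
from .qpcrpanel import CqTable

__all__ = [
    "TruthRecord",
    "gen_if_slide_pair",
    "gen_array_series",
    "default_chemokine_layout",
    "gen_cq_table",
    "gen_count_matrix",
    "gen_elisa_plate",
    "gen_transwell_table",
    "write_if_slides",
    "read_if_slides",
]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class TruthRecord:
    """Generator settings plus modality-specific ground truth."""

    modality: str  # if | array | qpcr | counts | elisa | transwell
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(_jsonable(asdict(self)), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "TruthRecord":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        return cls(**json.loads(text))


# --------------------------------------------------------------------------
# immunofluorescence slides

def _render_field(
    rng, shape, n_cells, nuc_radius, background, noise_sd, dapi_amp, marker_nuc_amp,
    marker_cyto_amp, bit_depth,
):
    """One two-channel field: nuclei as Gaussian-profile discs, cytoplasm as
    annuli around them."""
    h, w = shape
    dapi = np.full(shape, float(background))
    marker = np.full(shape, float(background))
    yy, xx = np.mgrid[:h, :w]
    margin = 3 * nuc_radius
    centers = np.column_stack(
        [rng.uniform(margin, h - margin, n_cells), rng.uniform(margin, w - margin, n_cells)]
    )
    sigma = nuc_radius / 1.6
    for cy, cx in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        profile = np.exp(-d2 / (2 * sigma**2))
        nuc = d2 <= nuc_radius**2
        cyto = (d2 > nuc_radius**2) & (d2 <= (2.2 * nuc_radius) ** 2)
        dapi[nuc] += dapi_amp * profile[nuc]
        marker[nuc] += marker_nuc_amp * profile[nuc]
        marker[cyto] += marker_cyto_amp
    cap = 2**bit_depth - 1
    dapi = np.clip(dapi + rng.normal(0, noise_sd, shape), 0, cap)
    marker = np.clip(marker + rng.normal(0, noise_sd, shape), 0, cap)
    return np.round(dapi).astype(np.uint16), np.round(marker).astype(np.uint16)


def gen_if_slide_pair(
    n_fields: int = 10,
    cells_per_field: int = 12,
    nuclear_enrichment: float = 1.5,
    background: float = 150.0,
    noise_sd: float = 60.0,
    seed: int = 0,
    field_shape=(160, 160),
    nuc_radius: int = 7,
    dapi_amp: float = 20000.0,
    marker_nuc_amp: float = 6000.0,
    marker_cyto_amp: float = 1500.0,
    bit_depth: int = 16,
):
    """Paired control/treated slides with a known nuclear-enrichment effect.

    The treated slide's nuclear marker amplitude is the control's times
    ``nuclear_enrichment``; DAPI statistics are identical in expectation
    between slides. Returns (control fields, treated fields, TruthRecord).
    """
    if n_fields < 1 or cells_per_field < 1:
        raise InvalidParameterError("n_fields and cells_per_field must be positive")
    if not nuclear_enrichment > 0:
        raise InvalidParameterError("nuclear_enrichment must be positive")
    cap = 2**bit_depth - 1
    if background + dapi_amp > cap or background + marker_nuc_amp * max(nuclear_enrichment, 1) > cap:
        raise InvalidParameterError("intensities exceed the declared bit depth")
    rng = np.random.default_rng(seed)
    slides = {}
    for slide, amp_scale in (("control", 1.0), ("treated", nuclear_enrichment)):
        fields = []
        for i in range(n_fields):
            dapi, marker = _render_field(
                rng, field_shape, cells_per_field, nuc_radius, background, noise_sd,
                dapi_amp, marker_nuc_amp * amp_scale, marker_cyto_amp, bit_depth,
            )
            fields.append(
                ImageFieldPair(dapi, marker, field_id=f"f{i:02d}", slide_id=slide, bit_depth=bit_depth)
            )
        slides[slide] = fields
    truth = TruthRecord(
        modality="if",
        params={
            "n_fields": n_fields, "cells_per_field": cells_per_field,
            "nuclear_enrichment": nuclear_enrichment, "background": background,
            "noise_sd": noise_sd, "seed": seed, "field_shape": list(field_shape),
            "nuc_radius": nuc_radius, "dapi_amp": dapi_amp,
            "marker_nuc_amp": marker_nuc_amp, "marker_cyto_amp": marker_cyto_amp,
            "bit_depth": bit_depth,
        },
        truth={"nuclear_enrichment": nuclear_enrichment},
    )
    return slides["control"], slides["treated"], truth


def write_if_slides(fields, out_dir):
    """Write one 16-bit grayscale TIFF per channel per field
    (``<slide>_<field>_<channel>.tif``)."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for fld in fields:
        for channel in ("dapi", "marker"):
            tifffile.imwrite(
                out_dir / f"{fld.slide_id}_{fld.field_id}_{channel}.tif",
                getattr(fld, channel).astype(np.uint16),
            )


def read_if_slides(out_dir, slide_id, bit_depth: int = 16):
    """Read back fields written by :func:`write_if_slides`."""
    import tifffile

    out_dir = Path(out_dir)
    fields = {}
    for path in sorted(out_dir.glob(f"{slide_id}_*_dapi.tif")):
        fid = path.stem.rsplit("_", 1)[0].split("_", 1)[1]
        dapi = tifffile.imread(path)
        marker = tifffile.imread(out_dir / f"{slide_id}_{fid}_marker.tif")
        fields[fid] = ImageFieldPair(dapi, marker, field_id=fid, slide_id=slide_id, bit_depth=bit_depth)
    return [fields[k] for k in sorted(fields)]


# --------------------------------------------------------------------------
# antibody-array exposure series

def default_chemokine_layout(analytes=None, spot_radius_px: int = 5) -> ArrayLayout:
    """A small membrane layout in the style of a commercial chemokine array:
    duplicate spots per analyte, duplicate POS/NEG controls and one BLANK."""
    if analytes is None:
        analytes = ["CCL2", "CCL5", "CCL7", "CXCL8", "CXCL10", "CCL22"]
    spot_map = {(0, 0): "POS", (0, 1): "POS", (0, 2): "NEG", (0, 3): "NEG", (0, 4): "BLANK"}
    n_cols = max(5, len(analytes))
    for i, a in enumerate(analytes):
        spot_map[(1 + i // n_cols, i % n_cols)] = a
        spot_map[(1 + (i + len(analytes)) // n_cols + 1, (i + len(analytes)) % n_cols)] = a
    rows = max(r for r, _ in spot_map) + 1
    return ArrayLayout(grid_shape=(rows, n_cols), spot_map=spot_map, spot_radius_px=spot_radius_px)


def gen_array_series(
    layout: ArrayLayout,
    true_abundance: dict,
    n_frames: int = 12,
    frame_interval: float = 2.0,
    saturation_cap: float = 65535.0,
    background: float = 300.0,
    seed: int = 0,
    pos_abundance: float = 60.0,
    gain: float = 120.0,
    noise_sd: float = 40.0,
    bit_depth: int = 16,
    treated_abundance: dict | None = None,
):
    """Control and treated exposure series with known abundance ratios.

    Spot signal accumulates linearly with exposure time (frame ``i`` is
    acquired at ``(i+1)*frame_interval`` seconds), then hard-clips at
    ``saturation_cap``. Duplicate spots share an expected density; POS spots
    carry a fixed known abundance on both membranes; NEG/BLANK spots carry
    background only.
    """
    if n_frames < 2:
        raise InvalidParameterError("need at least two frames")
    missing = set(layout.analytes) - set(true_abundance)
    if missing:
        raise SchemaError(f"no abundance for analytes {sorted(missing)}")
    extra = set(true_abundance) - set(layout.analytes)
    if extra:
        raise SchemaError(f"abundances for analytes absent from the layout: {sorted(extra)}")
    if any(v < 0 for v in true_abundance.values()):
        raise InvalidParameterError("abundances must be non-negative")
    treated_abundance = dict(treated_abundance or true_abundance)

    rng = np.random.default_rng(seed)
    h, w = layout.frame_shape()
    yy, xx = np.mgrid[:h, :w]
    cap = min(saturation_cap, 2**bit_depth - 1) if np.isfinite(saturation_cap) else np.inf

    def build(abund, condition):
        frames = []
        for i in range(n_frames):
            t = (i + 1) * frame_interval
            frame = np.full((h, w), float(background))
            for rc, role in layout.spot_map.items():
                if role == "BLANK" or role == "NEG":
                    rate = 0.0
                elif role == "POS":
                    rate = pos_abundance
                else:
                    rate = abund[role]
                cy, cx = layout.center_px(rc)
                disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= layout.spot_radius_px**2
                frame[disc] += gain * rate * t / 100.0
            frame = frame + rng.normal(0, noise_sd, (h, w))
            frames.append(np.clip(frame, 0, cap))
        return ExposureSeries(
            frames=frames,
            frame_interval=frame_interval,
            bit_depth=bit_depth,
            layout=layout,
            membrane_id=f"{condition}_membrane",
            condition=condition,
            saturation_level=cap,
        )

    control = build(true_abundance, "control")
    treated = build(treated_abundance, "treated")
    truth = TruthRecord(
        modality="array",
        params={
            "n_frames": n_frames, "frame_interval": frame_interval,
            "saturation_cap": saturation_cap, "background": background, "seed": seed,
            "pos_abundance": pos_abundance, "gain": gain, "noise_sd": noise_sd,
            "bit_depth": bit_depth,
        },
        truth={
            "control_abundance": dict(true_abundance),
            "treated_abundance": treated_abundance,
            "fold_change": {
                a: (treated_abundance[a] / true_abundance[a]) if true_abundance[a] > 0 else float("nan")
                for a in true_abundance
            },
        },
    )
    return control, treated, truth


# --------------------------------------------------------------------------
# qPCR Cq tables

def gen_cq_table(
    genes,
    housekeeping: str,
    groups: dict,
    group_effects: dict,
    cq_noise_sd: float = 0.2,
    seed: int = 0,
    n_replicates: int = 1,
    donor_shift_sd: float = 0.3,
):
    """Donor Cq panel with group-level log2 fold-change effects.

    In the Wnt arm, gene g of a donor in group k has its Cq lowered by
    ``group_effects[k][g]`` cycles, so the expected ΔΔCq is the negative of
    that effect and the expected recovered log2FC equals it. The
    housekeeping gene is unaffected by treatment.
    """
    genes = list(genes)
    if housekeeping not in genes:
        raise InvalidParameterError("housekeeping gene must be in the gene list")
    for k, eff in group_effects.items():
        if housekeeping in eff:
            raise InvalidParameterError("no treatment effect may target the housekeeping gene")
        if k not in groups:
            raise InvalidParameterError(f"effects given for unknown group {k!r}")
    if any(n < 1 for n in groups.values()):
        raise InvalidParameterError("each group needs at least one donor")

    rng = np.random.default_rng(seed)
    base_cq = {g: (20.0 if g == housekeeping else rng.uniform(22.0, 29.0)) for g in genes}
    rows = []
    for group, n_donors in groups.items():
        effects = group_effects.get(group, {})
        for i in range(n_donors):
            donor = f"{group}_{i+1}"
            shift = rng.normal(0, donor_shift_sd)
            for arm in ("control", "wnt"):
                sample = f"{donor}_{arm}"
                for g in genes:
                    effect = effects.get(g, 0.0) if arm == "wnt" else 0.0
                    mean_cq = base_cq[g] + shift - effect
                    for _ in range(n_replicates):
                        rows.append(
                            {
                                "sample": sample, "donor": donor, "treatment": arm,
                                "group": group, "gene": g,
                                "cq": mean_cq + rng.normal(0, cq_noise_sd),
                            }
                        )
    table = CqTable(pd.DataFrame(rows), housekeeping=housekeeping)
    truth = TruthRecord(
        modality="qpcr",
        params={
            "genes": genes, "housekeeping": housekeeping, "groups": dict(groups),
            "cq_noise_sd": cq_noise_sd, "seed": seed, "n_replicates": n_replicates,
            "donor_shift_sd": donor_shift_sd,
        },
        truth={"group_log2fc": {k: dict(v) for k, v in group_effects.items()}},
    )
    return table, truth


# --------------------------------------------------------------------------
# RNA-seq count matrices

def gen_count_matrix(
    n_genes: int = 2000,
    n_per_arm: int = 6,
    n_donors: int = 2,
    de_fraction: float = 0.05,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.05,
    donor_shift_sd: float = 0.25,
    lib_size_range=(0.7, 1.3),
    seed: int = 0,
    base_mean_log_mu: float = 4.5,
    base_mean_log_sd: float = 1.5,
):
    """NB-distributed counts with donor batch effects and a spiked DE set.

    The design mirrors the study's RNA-seq: two arms (control vs Wnt) with
    ``n_per_arm`` samples each, spread over ``n_donors`` donors so the donor
    factor is orthogonal to treatment. The first ``ceil(de_fraction *
    n_genes)`` genes receive a +/- ``effect_log2fc`` shift in the Wnt arm
    (alternating sign); per-(donor, gene) multiplicative batch effects have
    log2-scale SD ``donor_shift_sd``.
    """
    if n_genes < 10 or n_per_arm < 2:
        raise InvalidParameterError("need n_genes >= 10 and n_per_arm >= 2")
    if not (0 <= de_fraction <= 1):
        raise InvalidParameterError("de_fraction must lie in [0, 1]")
    if dispersion < 0:
        raise InvalidParameterError("dispersion must be non-negative")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    n_de = int(np.ceil(de_fraction * n_genes))
    true_lfc = np.zeros(n_genes)
    true_lfc[:n_de] = effect_log2fc * np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)

    samples, donors, treatments = [], [], []
    for arm in ("control", "wnt"):
        for j in range(n_per_arm):
            samples.append(f"{arm}_{j+1}")
            donors.append(f"d{j % n_donors + 1}")
            treatments.append(arm)
    lib = rng.uniform(lib_size_range[0], lib_size_range[1], len(samples))
    base = np.exp(rng.normal(base_mean_log_mu, base_mean_log_sd, n_genes)) + 1.0
    donor_mult = {
        d: 2.0 ** rng.normal(0.0, donor_shift_sd, n_genes) for d in sorted(set(donors))
    }

    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, (s, d, arm) in enumerate(zip(samples, donors, treatments)):
        mu = base * donor_mult[d] * lib[j]
        if arm == "wnt":
            mu = mu * 2.0**true_lfc
        if dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        sample_meta=pd.DataFrame({"donor": donors, "treatment": treatments}, index=samples),
    )
    truth = TruthRecord(
        modality="counts",
        params={
            "n_genes": n_genes, "n_per_arm": n_per_arm, "n_donors": n_donors,
            "de_fraction": de_fraction, "effect_log2fc": effect_log2fc,
            "dispersion": dispersion, "donor_shift_sd": donor_shift_sd,
            "lib_size_range": list(lib_size_range), "seed": seed,
        },
        truth={
            "de_genes": genes[:n_de],
            "true_log2fc": {g: float(true_lfc[i]) for i, g in enumerate(genes[:n_de])},
            "lib_factors": {s: float(v) for s, v in zip(samples, lib)},
        },
    )
    return cm, truth


# --------------------------------------------------------------------------
# ELISA plates

def gen_elisa_plate(
    curve: Curve4PL,
    concentrations,
    dilutions,
    od_noise_sd: float = 0.02,
    seed: int = 0,
    standards=None,
    n_replicates: int = 2,
):
    """OD plate following a known 4PL curve: a standard series plus samples.

    ``concentrations`` are the true (undiluted) sample concentrations;
    ``dilutions`` the matching fold-dilution factors (the reader sees
    concentration / dilution). Standards default to a two-fold series of
    eight points centered on the curve's inflection.
    """
    concentrations = list(concentrations)
    dilutions = list(dilutions)
    if len(concentrations) != len(dilutions):
        raise InvalidParameterError("concentrations and dilutions must pair up")
    if any(c < 0 for c in concentrations) or any(d < 1 for d in dilutions):
        raise InvalidParameterError("concentrations >= 0 and dilutions >= 1 required")
    if standards is None:
        standards = [curve.inflection * 2.0**k for k in range(-4, 4)]
    rng = np.random.default_rng(seed)
    rows = []
    for conc in standards:
        for _ in range(n_replicates):
            od = float(curve.evaluate(conc)) + rng.normal(0, od_noise_sd)
            rows.append({"role": "standard", "id": f"std_{conc:g}", "concentration": conc,
                         "od": od, "dilution": 1.0})
    for i, (conc, dil) in enumerate(zip(concentrations, dilutions)):
        for _ in range(n_replicates):
            od = float(curve.evaluate(conc / dil)) + rng.normal(0, od_noise_sd)
            rows.append({"role": "sample", "id": f"s{i+1}", "concentration": float("nan"),
                         "od": od, "dilution": dil})
    plate = pd.DataFrame(rows)
    truth = TruthRecord(
        modality="elisa",
        params={
            "curve": {
                "upper_asymptote": curve.upper_asymptote,
                "lower_asymptote": curve.lower_asymptote,
                "inflection": curve.inflection,
                "slope": curve.slope,
            },
            "od_noise_sd": od_noise_sd, "seed": seed, "standards": list(standards),
            "n_replicates": n_replicates,
        },
        truth={"concentrations": {f"s{i+1}": c for i, c in enumerate(concentrations)},
               "dilutions": {f"s{i+1}": d for i, d in enumerate(dilutions)}},
    )
    return plate, truth


# --------------------------------------------------------------------------
# transwell count tables

def gen_transwell_table(
    n_donors: int = 4,
    base_count: int = 4000,
    media_effects: dict | None = None,
    inhibitor_effects: dict | None = None,
    count_noise: float = 0.1,
    seed: int = 0,
    n_replicates: int = 2,
    donor_sd: float = 0.15,
    cell_class: str = "monocyte",
):
    """Paired transwell flow-count tables with known effect multipliers.

    ``media_effects`` maps each experimental condition (arm I/II/III) to the
    Wnt-media count multiplier (control media = 1). ``inhibitor_effects``
    maps conditions to the multiplier applied when the CCL2 inhibitor is
    present; those conditions also get inhibitor rows. Counts are
    ``round(expected * exp(N(0, count_noise)))`` so the noise-free limit is
    deterministic.
    """
    media_effects = dict(media_effects or {"I": 1.3, "II": 1.8})
    inhibitor_effects = dict(inhibitor_effects or {})
    if any(v <= 0 for v in media_effects.values()) or any(
        v <= 0 for v in inhibitor_effects.values()
    ):
        raise InvalidParameterError("effect multipliers must be positive")
    unknown = set(inhibitor_effects) - set(media_effects)
    if unknown:
        raise InvalidParameterError(f"inhibitor effects for unknown conditions {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_donors):
        donor = f"donor_{i+1}"
        donor_mult = float(np.exp(rng.normal(0, donor_sd)))
        for condition, media_mult in media_effects.items():
            arms = [("control", False), ("wnt", False)]
            if condition in inhibitor_effects:
                arms += [("control", True), ("wnt", True)]
            for media, inhib in arms:
                expected = base_count * donor_mult
                if media == "wnt":
                    expected *= media_mult
                if inhib:
                    expected *= inhibitor_effects[condition]
                for _ in range(n_replicates):
                    noise = float(np.exp(rng.normal(0, count_noise))) if count_noise > 0 else 1.0
                    rows.append(
                        {
                            "donor": donor, "condition": condition, "media": media,
                            "inhibitor": inhib, "cell_class": cell_class,
                            "count": int(round(expected * noise)),
                        }
                    )
    table = pd.DataFrame(rows)
    truth = TruthRecord(
        modality="transwell",
        params={
            "n_donors": n_donors, "base_count": base_count,
            "media_effects": media_effects, "inhibitor_effects": inhibitor_effects,
            "count_noise": count_noise, "seed": seed, "n_replicates": n_replicates,
            "donor_sd": donor_sd,
        },
        truth={"media_effects": media_effects, "inhibitor_effects": inhibitor_effects},
    )
    return table, truth
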
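"""ΔΔCq relative quantification and PCA centroid-distance scoring of donor panels.

Relative expression is computed with the ΔΔCq technique (housekeeping-gene
normalization within each sample, Wnt-treated arm normalized to the control
arm of the same donor; fold change = 2^-ΔΔCq). Per-donor log2 fold changes
over a chosen cytokine/chemokine gene panel are assembled into a donors x
genes matrix, embedded with a standardized two-component PCA, and each donor
is scored by its Euclidean distance in the (PC1, PC2) plane from the
centroid of the healthy-donor cloud; groups are compared with one-way ANOVA
plus Dunnett many-to-one tests against the healthy group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import statcore
from .errors import (
    DegenerateFeatureError,
    IncompletePanelError,
    InvalidParameterError,
    InvalidReferenceError,
    PairingError,
)

__all__ = [
    "CqTable",
    "PanelEmbedding",
    "ddcq_fold_change",
    "panel_matrix",
    "pca_embed",
    "centroid_distances",
    "group_distance_test",
]


@dataclass
class CqTable:
    """Long-format Cq measurements with donor/treatment/group metadata.

    ``data`` columns: sample, donor, treatment ("control"/"wnt"), group,
    gene, cq. Technical replicates may repeat (sample, gene) rows.
    """

    data: pd.DataFrame
    housekeeping: str

    REQUIRED = ("sample", "donor", "treatment", "group", "gene", "cq")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise InvalidParameterError(f"CqTable missing columns {missing}")
        if self.housekeeping not in set(self.data["gene"]):
            raise InvalidParameterError(
                f"housekeeping gene {self.housekeeping!r} absent from the table"
            )
        cq = self.data["cq"].to_numpy(dtype=float)
        if not np.all(np.isfinite(cq)) or np.any(cq <= 0):
            raise InvalidParameterError("Cq values must be finite and positive")

    def mean_cq(self, donor, treatment, gene) -> float:
        """Mean Cq across technical replicates; NaN if absent."""
        sel = self.data[
            (self.data["donor"] == donor)
            & (self.data["treatment"] == treatment)
            & (self.data["gene"] == gene)
        ]
        if sel.empty:
            return float("nan")
        return float(sel["cq"].mean())

    @property
    def donors(self):
        return sorted(self.data["donor"].unique())

    def donor_group(self, donor):
        return self.data.loc[self.data["donor"] == donor, "group"].iloc[0]


@dataclass
class PanelEmbedding:
    coords: dict            # donor -> (x, y)
    loadings: dict          # gene -> (pc1, pc2)
    explained_variance: tuple
    groups: dict            # donor -> group label
    healthy_centroid: tuple | None = None
    distances: dict | None = None


def ddcq_fold_change(table: CqTable, gene: str, donor) -> float:
    """2^-ΔΔCq fold change of ``gene`` in the Wnt arm vs the control arm.

    ΔCq = Cq(gene) - Cq(housekeeping) within each arm (Cq averaged over
    technical replicates before differencing); ΔΔCq = ΔCq(wnt) - ΔCq(control).
    """
    if gene == table.housekeeping:
        raise InvalidParameterError("fold change of the housekeeping gene is undefined")
    vals = {}
    for arm in ("control", "wnt"):
        g = table.mean_cq(donor, arm, gene)
        hk = table.mean_cq(donor, arm, table.housekeeping)
        if np.isnan(g) or np.isnan(hk):
            raise PairingError(f"donor {donor!r}: missing {arm} arm for gene {gene!r}")
        vals[arm] = g - hk
    ddcq = vals["wnt"] - vals["control"]
    return float(2.0 ** (-ddcq))


def panel_matrix(table: CqTable, genes) -> pd.DataFrame:
    """Donors x genes matrix of log2(ΔΔCq fold change); no imputation."""
    genes = list(genes)
    if table.housekeeping in genes:
        raise InvalidParameterError("panel genes must not include the housekeeping gene")
    donors = table.donors
    gaps = []
    rows = {}
    for d in donors:
        row = {}
        for g in genes:
            try:
                row[g] = np.log2(ddcq_fold_change(table, g, d))
            except PairingError:
                gaps.append((d, g))
        rows[d] = row
    if gaps:
        raise IncompletePanelError(gaps)
    return pd.DataFrame.from_dict(rows, orient="index")[genes]


def pca_embed(matrix: pd.DataFrame, groups: dict | None = None, standardize: bool = True) -> PanelEmbedding:
    """First two principal components of the donor panel.

    Columns are z-scored when ``standardize`` (sample sd, ddof=1). Sign
    convention: each component is flipped so its largest-magnitude gene
    loading is positive, making orientation reproducible.
    """
    if isinstance(matrix, pd.DataFrame):
        donors = list(matrix.index)
        genes = list(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        donors = list(range(x.shape[0]))
        genes = list(range(x.shape[1]))
    if x.shape[0] < 3:
        raise InvalidParameterError("PCA needs at least three donors")
    if np.isnan(x).any():
        raise InvalidParameterError("panel matrix contains missing values")
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            dead = [genes[i] for i in np.flatnonzero(sd == 0)]
            raise DegenerateFeatureError(f"zero-variance genes cannot be z-scored: {dead}")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(2, s.size)
    comps = vt[:k]
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            u[:, i] = -u[:, i]
    scores = u[:, :k] * s[:k]
    if k < 2:  # degenerate single-component case
        scores = np.column_stack([scores, np.zeros(len(donors))])
        comps = np.vstack([comps, np.zeros(len(genes))])
        s = np.append(s, 0.0)
    var = s**2 / max(x.shape[0] - 1, 1)
    total = var.sum() if var.sum() > 0 else 1.0
    return PanelEmbedding(
        coords={d: (float(scores[i, 0]), float(scores[i, 1])) for i, d in enumerate(donors)},
        loadings={g: (float(comps[0, i]), float(comps[1, i])) for i, g in enumerate(genes)},
        explained_variance=(float(var[0] / total), float(var[1] / total)),
        groups=dict(groups) if groups else {},
    )


def centroid_distances(embedding: PanelEmbedding, reference_group: str = "healthy") -> PanelEmbedding:
    """Euclidean distance of every donor from the reference-group centroid.

    The centroid is the componentwise mean of the reference donors' (x, y)
    coordinates; reference donors are scored against their own centroid.
    """
    ref = [d for d, g in embedding.groups.items() if g == reference_group]
    if not ref:
        raise InvalidReferenceError(f"no donors in reference group {reference_group!r}")
    pts = np.array([embedding.coords[d] for d in ref])
    centroid = pts.mean(axis=0)
    dists = {
        d: float(np.hypot(x - centroid[0], y - centroid[1]))
        for d, (x, y) in embedding.coords.items()
    }
    embedding.healthy_centroid = (float(centroid[0]), float(centroid[1]))
    embedding.distances = dists
    return embedding


def group_distance_test(embedding: PanelEmbedding, reference_group: str = "healthy") -> dict:
    """ANOVA + Dunnett comparison of centroid distances per group vs reference."""
    if embedding.distances is None:
        centroid_distances(embedding, reference_group)
    groups: dict = {}
    for d, g in embedding.groups.items():
        groups.setdefault(g, []).append(embedding.distances[d])
    return statcore.dunnett(groups, control_label=reference_group)
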
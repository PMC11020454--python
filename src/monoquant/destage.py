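"""Bulk differential-expression stage on a gene-count matrix.

Negative-binomial Wald differential expression of Wnt-treated vs control
samples with donor as an additive covariate, median-of-ratios size factors,
the padj < 0.05 & |fold change| > 2 significance filter, and a PCA of
log-normalized counts after regressing out the donor batch term.

The per-gene NB GLM fitting, trend-based dispersion moderation and Wald
test are delegated to pydeseq2 behind this module's interface; size-factor
estimation, the DE filter and the batch-removed PCA are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    InvalidParameterError,
    NormalizationFailureError,
)

__all__ = [
    "CountMatrix",
    "size_factors",
    "nb_wald",
    "de_filter",
    "batch_removed_pca",
]

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Integer gene x sample counts with donor/treatment sample metadata."""

    counts: pd.DataFrame          # genes x samples
    sample_meta: pd.DataFrame     # index = samples; columns donor, treatment

    def __post_init__(self):
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise InvalidParameterError("count columns and metadata rows must align")
        for col in ("donor", "treatment"):
            if col not in self.sample_meta.columns:
                raise InvalidParameterError(f"sample_meta missing {col!r}")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise InvalidParameterError("counts must be non-negative integers")
        arms = self.sample_meta["treatment"].value_counts()
        if (arms < 2).any() or len(arms) < 2:
            raise InvalidParameterError("need at least two samples per treatment arm")

    @property
    def gene_ids(self):
        return list(self.counts.index)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Over genes with nonzero counts in every sample: factor_j =
    median_g(count_gj / geometric_mean_g(count_g.)).
    """
    m = counts.to_numpy(dtype=float)
    ref_genes = np.all(m > 0, axis=1)
    if not ref_genes.any():
        raise NormalizationFailureError("no gene has nonzero counts in all samples")
    logs = np.log(m[ref_genes])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _check_design(meta: pd.DataFrame, batch: str | None):
    treat = meta["treatment"]
    if treat.nunique() < 2:
        raise DesignError("treatment factor has a single level")
    if batch is not None:
        tab = pd.crosstab(meta[batch], treat)
        if (tab.astype(bool).sum(axis=1) == 1).all():
            raise DesignError(f"{batch!r} is confounded with treatment")


def nb_wald(cm: CountMatrix, design: str = "~donor + treatment") -> pd.DataFrame:
    """Per-gene NB Wald test of Wnt vs control with size-factor offsets.

    Returns a DETable-style frame indexed by gene: base_mean, log2fc,
    wald_stat, p, padj (BH). All-zero genes are dropped before testing;
    independent filtering is off, so padj >= p componentwise.
    """
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    meta = cm.sample_meta.copy()
    _check_design(meta, "donor" if "donor" in design else None)
    counts = cm.counts
    nonzero = counts.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("dropping %d all-zero genes before testing", int((~nonzero).sum()))
    counts = counts.loc[nonzero]
    # pydeseq2 treats levels alphabetically; "control" < "wnt" gives the
    # wnt-vs-control contrast directly.
    dds = DeseqDataSet(
        counts=counts.T,
        metadata=meta,
        design=design,
        refit_cooks=False,
        quiet=True,
    )
    dds.deseq2()
    ds = DeseqStats(
        dds,
        contrast=["treatment", "wnt", "control"],
        cooks_filter=False,
        independent_filter=False,
        quiet=True,
    )
    ds.summary()
    res = ds.results_df
    table = pd.DataFrame(
        {
            "base_mean": res["baseMean"],
            "log2fc": res["log2FoldChange"],
            "wald_stat": res["stat"],
            "p": res["pvalue"],
            "padj": res["padj"],
        }
    )
    table.index.name = "gene"
    return table


def de_filter(table: pd.DataFrame, alpha: float = 0.05, fc_threshold: float = 2.0) -> dict:
    """Apply the significance filter padj < alpha and |fold change| > fc_threshold.

    The fold-change cut acts on |log2fc| > log2(fc_threshold); direction by
    the sign of log2fc. Returns counts and the up/down gene lists.
    """
    if not (0 < alpha < 1) or fc_threshold < 1:
        raise InvalidParameterError("alpha in (0,1) and fc_threshold >= 1 required")
    lfc_cut = np.log2(fc_threshold)
    ok = table["padj"].notna() & (table["padj"] < alpha) & (table["log2fc"].abs() > lfc_cut)
    up = table.index[ok & (table["log2fc"] > 0)].tolist()
    down = table.index[ok & (table["log2fc"] < 0)].tolist()
    return {
        "n_de": len(up) + len(down),
        "n_up": len(up),
        "n_down": len(down),
        "up": up,
        "down": down,
    }


def batch_removed_pca(
    cm: CountMatrix, batch: str = "donor", n_top_genes: int = 500
) -> dict:
    """PCA of log2(normalized count + 1) after removing the batch term.

    Per gene, an ordinary linear model with batch and treatment terms is
    fitted; the batch-coefficient contribution is subtracted (the treatment
    effect is retained). PCA then runs on the ``n_top_genes`` highest-
    variance genes of the adjusted matrix.
    """
    meta = cm.sample_meta
    _check_design(meta, batch)
    sf = size_factors(cm.counts)
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    y = np.log2(norm + 1.0)

    batch_dummies = pd.get_dummies(meta[batch], drop_first=True, dtype=float)
    treat_dummies = pd.get_dummies(meta["treatment"], drop_first=True, dtype=float)
    x = np.column_stack([np.ones(len(meta)), batch_dummies.to_numpy(), treat_dummies.to_numpy()])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("rank-deficient batch+treatment design")
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    n_batch = batch_dummies.shape[1]
    xb = batch_dummies.to_numpy()
    xb = xb - xb.mean(axis=0)  # keep grand means; remove only batch contrasts
    adjusted = y - (xb @ beta[1 : 1 + n_batch]).T

    var = adjusted.var(axis=1)
    top = np.argsort(var)[::-1][: min(n_top_genes, adjusted.shape[0])]
    sub = adjusted[top].T  # samples x genes
    sub = sub - sub.mean(axis=0)
    u, s, vt = np.linalg.svd(sub, full_matrices=False)
    coords = u[:, :2] * s[:2]
    ev = s**2 / (s**2).sum() if (s**2).sum() > 0 else s
    return {
        "coords": pd.DataFrame(
            coords, index=cm.counts.columns, columns=["PC1", "PC2"]
        ),
        "variance_explained": (float(ev[0]), float(ev[1]) if ev.size > 1 else 0.0),
        "adjusted_matrix": pd.DataFrame(
            adjusted, index=cm.counts.index, columns=cm.counts.columns
        ),
    }
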
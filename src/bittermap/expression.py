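"""Tissue-expression repertoire metrics from bulk RNA-seq counts.

Counts are normalised to FPKM (fragments per kilobase of transcript per
million mapped reads):

    FPKM[g, s] = counts[g, s] * 1e9 / (mapped_total[s] * length[g])

A gene is *expressed* in a tissue when FPKM exceeds 0.01 (strict) in at
least one replicate.  Repertoire metrics follow two denominator
conventions: percent-expressed metrics are relative to the genome's
receptor count, while tissue-uniqueness and extra-oral metrics are
relative to the number of expressed receptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RepertoireMetrics",
    "compute_fpkm",
    "expressed_flags",
    "repertoire_metrics",
    "tissue_colocalization",
    "count_extraoral_correlation",
    "TISSUES",
]

TISSUES = ("tongue", "brain", "stomach", "intestines", "liver",
           "dorsal skin", "ventral skin")

EXPRESSION_THRESHOLD = 0.01


@dataclass
class RepertoireMetrics:
    pct_expressed_any: float
    pct_expressed_per_tissue: dict[str, float]
    pct_unique_one_tissue: float
    pct_extraoral_not_tongue: float
    n_expressed: int
    n_unique_one_tissue: int
    n_extraoral_not_tongue: int
    genome_gene_count: int


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series,
                 mapped_totals: pd.Series) -> pd.DataFrame:
    """Cellwise FPKM for a genes x samples count matrix.

    ``lengths`` are gene lengths in bp (index = genes); ``mapped_totals``
    are per-sample genome-wide mapped read totals (index = samples).
    """
    lengths = lengths.reindex(counts.index)
    mapped_totals = mapped_totals.reindex(counts.columns)
    if lengths.isna().any() or mapped_totals.isna().any():
        raise ValueError("lengths/mapped totals must cover all genes/samples")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (mapped_totals <= 0).any():
        raise ValueError("mapped totals must be > 0")
    return counts * 1e9 / np.outer(lengths.to_numpy(), mapped_totals.to_numpy())


def expressed_flags(fpkm: pd.DataFrame, sample_tissue: pd.Series,
                    threshold: float = EXPRESSION_THRESHOLD,
                    mode: str = "any") -> pd.DataFrame:
    """Gene x tissue booleans: expressed iff FPKM > threshold (strict).

    With ``mode="any"`` (default) one replicate above threshold
    suffices; ``mode="mean"`` applies the threshold to the replicate
    mean instead (an alternative pooling convention).
    """
    if mode not in ("any", "mean"):
        raise ValueError("mode must be 'any' or 'mean'")
    sample_tissue = sample_tissue.reindex(fpkm.columns)
    if sample_tissue.isna().any():
        raise ValueError("every sample needs a tissue label")
    flags = {}
    for tissue in sample_tissue.unique():
        cols = sample_tissue.index[sample_tissue == tissue]
        if mode == "any":
            flags[tissue] = (fpkm[cols] > threshold).any(axis=1)
        else:
            flags[tissue] = fpkm[cols].mean(axis=1) > threshold
    return pd.DataFrame(flags)


def repertoire_metrics(flags: pd.DataFrame, genome_gene_count: int,
                       tongue_tissue: str = "tongue") -> RepertoireMetrics:
    """Repertoire summary of a gene x tissue expressed-flag table.

    Percent-expressed metrics (any tissue, per tissue) use the genome's
    receptor count as denominator; the unique-to-one-tissue and
    extra-oral-but-not-tongue percentages use the expressed-gene count.
    Raw counts are emitted alongside so either convention is
    recoverable.
    """
    if tongue_tissue not in flags.columns:
        raise ValueError(f"tissue {tongue_tissue!r} missing from flags")
    expressed_any = flags.any(axis=1)
    n_expressed = int(expressed_any.sum())
    if genome_gene_count < n_expressed:
        raise ValueError("genome gene count below the expressed-gene count")
    n_tissues = flags.sum(axis=1)
    n_unique = int(((n_tissues == 1) & expressed_any).sum())
    extraoral = flags.drop(columns=[tongue_tissue]).any(axis=1)
    n_extraoral_only = int((extraoral & ~flags[tongue_tissue]).sum())
    denom_exp = n_expressed if n_expressed else 1
    return RepertoireMetrics(
        pct_expressed_any=100.0 * n_expressed / genome_gene_count,
        pct_expressed_per_tissue={
            t: 100.0 * float(flags[t].sum()) / genome_gene_count
            for t in flags.columns
        },
        pct_unique_one_tissue=100.0 * n_unique / denom_exp,
        pct_extraoral_not_tongue=100.0 * n_extraoral_only / denom_exp,
        n_expressed=n_expressed,
        n_unique_one_tissue=n_unique,
        n_extraoral_not_tongue=n_extraoral_only,
        genome_gene_count=genome_gene_count,
    )


def tissue_colocalization(fpkm: pd.DataFrame, sample_tissue: pd.Series,
                          expressed_only: pd.DataFrame | None = None) -> pd.DataFrame:
    """Spearman correlation matrix between tissues.

    Per tissue, the gene vector is the replicate-mean FPKM; correlations
    use average ranks for ties.  All genes are used by default; pass an
    expressed-flag table (``expressed_only``) to restrict to genes
    expressed in at least one tissue.  Constant vectors yield NA
    entries; the diagonal is 1.
    """
    if expressed_only is not None:
        fpkm = fpkm.loc[expressed_only.any(axis=1)]
    if len(fpkm) < 3:
        raise ValueError("need at least 3 genes")
    sample_tissue = sample_tissue.reindex(fpkm.columns)
    means = fpkm.T.groupby(sample_tissue).mean().T
    tissues = list(means.columns)
    out = pd.DataFrame(np.eye(len(tissues)), index=tissues, columns=tissues)
    for i, a in enumerate(tissues):
        for b in tissues[i + 1:]:
            if means[a].nunique() <= 1 or means[b].nunique() <= 1:
                rho = np.nan
            else:
                rho = float(stats.spearmanr(means[a], means[b]).statistic)
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def count_extraoral_correlation(genome_counts, extraoral_pcts) -> dict[str, float]:
    """Pearson correlation between genome receptor count and the
    percent of expressed receptors found only extra-orally.

    Returns r, the t statistic ``r * sqrt(n - 2) / sqrt(1 - r^2)`` and
    its two-sided p-value on n - 2 df.
    """
    x = np.asarray(genome_counts, dtype=float)
    y = np.asarray(extraoral_pcts, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 species")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input vector")
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    if abs(r) >= 1.0:
        return {"pearson_r": r, "t": float("inf") * np.sign(r), "p": 0.0}
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return {"pearson_r": r, "t": float(t), "p": float(p)}
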
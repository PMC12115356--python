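"""TPM quantification, expressed-gene calling and deleted-chromosome detection.

A lost chromosome announces itself in bulk RNA-seq long before any formal
test: its share of the transcriptome collapses from the euploid expectation
(ratio ~1 relative to the control) to a small residual produced by reads
cross-mapping from homoeologous loci.  The detector below computes each
chromosome's share of total expression per genotype, takes the
aneuploid/euploid ratio of shares, and flags chromosomes falling under a
threshold placed midway between the two regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import CountMatrix, ExpressionMatrix, GeneAnnotation

__all__ = [
    "tpm",
    "expressed_genes",
    "chromosome_expression_ratio",
    "detect_deleted_chromosomes",
    "ChromosomeExpressionRatio",
]

TPM_SCALE = 1e6


def tpm(counts: CountMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Transcripts-per-million from raw counts and annotated gene lengths.

    TPM_ij = (c_ij / L_i) / sum_k (c_kj / L_k) * 1e6.  Each sample column
    sums to 1e6 except all-zero columns, which stay all-zero.
    """
    missing = counts.gene_ids.difference(ann.gene_ids)
    if len(missing):
        raise ValueError(
            f"no annotated length for {len(missing)} gene(s), e.g. {missing[:5].tolist()}"
        )
    lengths = ann.frame.loc[counts.gene_ids, "length"].to_numpy(dtype=float)
    rate = counts.values.to_numpy(dtype=float) / lengths[:, None]
    denom = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, rate / denom * TPM_SCALE, 0.0)
    frame = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.samples)
    return ExpressionMatrix(frame, genotypes=counts.genotypes.copy())


def expressed_genes(
    expr: ExpressionMatrix, genotype: str, min_replicates: str | int = "all"
) -> set[str]:
    """Genes with TPM > 0 in replicates of a genotype.

    The study's expressed-gene rule requires TPM > 0 in *all* biological
    replicates (the default); pass an integer to require only that many.
    """
    block = expr.genotype_values(genotype)
    positive = (block.to_numpy() > 0).sum(axis=1)
    need = block.shape[1] if min_replicates == "all" else int(min_replicates)
    return set(block.index[positive >= need])


@dataclass
class ChromosomeExpressionRatio:
    """Per-chromosome expression shares and their aneuploid/euploid ratio."""

    frame: pd.DataFrame  # index chromosome; share_euploid, share_aneuploid, ratio

    def ratio(self, chromosome: str) -> float:
        return float(self.frame.loc[chromosome, "ratio"])


def _chromosome_shares(expr, genotype: str, ann: GeneAnnotation) -> pd.Series:
    per_gene = expr.genotype_values(genotype).mean(axis=1)
    chrom = ann.frame.loc[per_gene.index, "chromosome"]
    totals = per_gene.groupby(chrom.to_numpy()).sum()
    total = totals.sum()
    if total == 0:
        raise ValueError(f"genotype {genotype!r} has zero total expression")
    return totals / total


def chromosome_expression_ratio(
    expr: ExpressionMatrix,
    ann: GeneAnnotation,
    euploid: str,
    aneuploid: str,
) -> ChromosomeExpressionRatio:
    """Each chromosome's share of total expression per genotype, and the ratio.

    Shares use the mean over replicates (robust to unbalanced replicate
    counts) and sum to 1 over chromosomes within each genotype.  A
    chromosome with zero euploid share gets ratio NaN and a flag.

    ``expr`` is normally a TPM :class:`ExpressionMatrix`; passing a raw
    :class:`CountMatrix` instead yields raw read-count shares (count-share
    mode), which is depth-sensitive but otherwise equivalent.
    """
    sh_eu = _chromosome_shares(expr, euploid, ann)
    sh_an = _chromosome_shares(expr, aneuploid, ann)
    frame = pd.DataFrame({"share_euploid": sh_eu, "share_aneuploid": sh_an}).fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frame["ratio"] = np.where(
            frame["share_euploid"] > 0,
            frame["share_aneuploid"] / frame["share_euploid"],
            np.nan,
        )
    frame["zero_euploid_share"] = frame["share_euploid"] == 0
    frame.index.name = "chromosome"
    return ChromosomeExpressionRatio(frame.sort_index())


def detect_deleted_chromosomes(
    ratios: ChromosomeExpressionRatio, threshold: float = 0.5
) -> list[str]:
    """Chromosomes whose expression-share ratio falls below threshold.

    Returned in ascending ratio order (most depleted first); empty when no
    chromosome is depleted.  The default threshold 0.5 sits midway between
    the euploid expectation (1.0) and the residual regime (~0.1) observed
    for true whole-chromosome losses.
    """
    f = ratios.frame
    hits = f[f["ratio"] < threshold].sort_values("ratio")
    return [str(c) for c in hits.index]
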
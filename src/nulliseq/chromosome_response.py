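"""Per-chromosome response to a whole-chromosome loss.

Builds the report tables of the analysis: cis/trans attribution of DEGs,
the chromosome summary (reference genes, expressed genes, DEGs, and their
ratios) with low / middle / high sensitivity grouping, the deleted-vs-rest
expressed-proportion test, the up/down balance chi-square, per-chromosome
mean-expression comparisons and coefficients of variation.

Conventions fixed here (and surfaced in the docs): the summary table takes
whatever expressed-gene set the caller defines (the pipeline defaults to
the intersection of the two genotypes' all-replicate expressed sets, which
is what lets a deleted chromosome's expressed proportion collapse); ratios
are reported half-up at two decimals while full precision is kept
internally; CoV uses the sample standard deviation (ddof = 1); ranking
ties break by chromosome name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import percent, round_half_up
from .genome_model import ExpressionMatrix, GeneAnnotation, OTHER, normalize_chromosome

__all__ = [
    "CisTransPartition",
    "cis_trans_partition",
    "chromosome_summary_table",
    "sensitivity_groups",
    "deleted_vs_rest_test",
    "updown_balance_test",
    "mean_expression_compare",
    "cov_per_chromosome",
    "format_summary_table",
]

log = logging.getLogger(__name__)

_EPS_VAR = 1e-12


@dataclass
class CisTransPartition:
    """DEGs split by residence on the deleted chromosome (cis) or not (trans)."""

    cis: list[str]
    trans: list[str]
    cis_fraction_pct: float  # 100 * |cis| / |DEGs|, 2 decimals

    @property
    def n_total(self) -> int:
        return len(self.cis) + len(self.trans)


def cis_trans_partition(
    deg_ids, ann: GeneAnnotation, deleted: str
) -> CisTransPartition:
    """Attribute each DEG to the deleted chromosome (cis) or elsewhere (trans)."""
    deleted = normalize_chromosome(deleted)
    if deleted not in set(ann.frame["chromosome"]):
        raise ValueError(f"deleted chromosome {deleted} not in annotation")
    deg_ids = list(deg_ids)
    chrom = ann.chromosome_of(deg_ids)
    cis = [g for g, c in zip(deg_ids, chrom) if c == deleted]
    trans = [g for g, c in zip(deg_ids, chrom) if c != deleted]
    frac = percent(len(cis), len(deg_ids)) if deg_ids else 0.0
    return CisTransPartition(cis, trans, frac)


def chromosome_summary_table(
    ann: GeneAnnotation,
    expressed: set[str],
    deg_ids,
    deleted: str,
    n_low: int = 5,
    n_high: int = 5,
) -> pd.DataFrame:
    """Per-chromosome RGs / EGs / DEGs with ratio columns and group labels.

    EGs is the size of the caller-supplied ``expressed`` gene set on each
    chromosome; ratios are EGs/RGs and DEGs/EGs as percentages (full
    precision; see :func:`format_summary_table` for the printed two-decimal
    form).  Subgenome (A, C) and Total aggregate rows are appended;
    scaffold genes, if any, aggregate under 'other' and stay out of the
    grouping.
    """
    deleted = normalize_chromosome(deleted)
    frame = ann.frame
    deg_ids = set(deg_ids)
    rows = []
    chrom_order = ann.chromosomes
    if (frame["chromosome"] == OTHER).any():
        chrom_order = chrom_order + [OTHER]
    for chrom in chrom_order:
        genes = frame.index[frame["chromosome"] == chrom]
        n_ref = len(genes)
        n_expr = len(expressed.intersection(genes))
        n_deg = len(deg_ids.intersection(genes))
        rows.append(
            {
                "chromosome": chrom,
                "n_reference": n_ref,
                "n_expressed": n_expr,
                "r_egs_rgs": 100.0 * n_expr / n_ref if n_ref else np.nan,
                "n_degs": n_deg,
                "r_degs_egs": 100.0 * n_deg / n_expr if n_expr else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("chromosome")
    table = sensitivity_groups(table, deleted, n_low=n_low, n_high=n_high)

    # Aggregate rows: subgenomes and Total (chromosome rows only).
    per_chrom = table[table.index != OTHER]
    aggregates = []
    for name, members in (
        ("A", [c for c in per_chrom.index if c.startswith("A")]),
        ("C", [c for c in per_chrom.index if c.startswith("C")]),
        ("Total", list(per_chrom.index)),
    ):
        if not members:
            continue
        sub = per_chrom.loc[members]
        n_ref = int(sub["n_reference"].sum())
        n_expr = int(sub["n_expressed"].sum())
        n_deg = int(sub["n_degs"].sum())
        aggregates.append(
            {
                "chromosome": name,
                "n_reference": n_ref,
                "n_expressed": n_expr,
                "r_egs_rgs": 100.0 * n_expr / n_ref if n_ref else np.nan,
                "n_degs": n_deg,
                "r_degs_egs": 100.0 * n_deg / n_expr if n_expr else np.nan,
                "group": "—",
            }
        )
    return pd.concat([table, pd.DataFrame(aggregates).set_index("chromosome")])


def sensitivity_groups(
    table: pd.DataFrame, deleted: str, n_low: int = 5, n_high: int = 5
) -> pd.DataFrame:
    """Assign low / middle / high sensitivity groups by DEGs/EGs ratio.

    The deleted chromosome is labelled "deleted" and excluded; the
    remaining chromosomes are ranked by r_degs_egs ascending (ties broken
    by chromosome name) with the bottom ``n_low`` labelled low, the top
    ``n_high`` high, the rest middle.  With fewer than n_low + n_high + 1
    chromosomes the split shrinks proportionally (with a warning).
    """
    deleted = normalize_chromosome(deleted)
    out = table.copy()
    chrom_rows = [c for c in out.index if c not in ("A", "C", "Total", OTHER)]
    remaining = [c for c in chrom_rows if c != deleted]
    out["group"] = ""
    if deleted in out.index:
        out.loc[deleted, "group"] = "deleted"
    if OTHER in out.index:
        out.loc[OTHER, "group"] = "—"
    n = len(remaining)
    if n < n_low + n_high + 1:
        scale = n / (n_low + n_high + 1) if n else 0
        n_low = max(1, int(round(n_low * scale))) if n else 0
        n_high = max(1, int(round(n_high * scale))) if n else 0
        if n:
            log.warning(
                "only %d chromosomes to group; using %d low / %d high", n, n_low, n_high
            )
    ranked = sorted(remaining, key=lambda c: (out.loc[c, "r_degs_egs"], c))
    for i, c in enumerate(ranked):
        if i < n_low:
            out.loc[c, "group"] = "Low"
        elif i >= n - n_high:
            out.loc[c, "group"] = "High"
        else:
            out.loc[c, "group"] = "Middle"
    return out


def deleted_vs_rest_test(table: pd.DataFrame, deleted: str) -> tuple[float, float]:
    """One-sample t of remaining chromosomes' EGs/RGs against the deleted one.

    One-sided (alternative: the remaining chromosomes' mean expressed
    proportion exceeds the deleted chromosome's); returns (t, p).  A
    degenerate zero variance among the rest is floored at a tiny epsilon so
    any strictly lower deleted value drives p toward 0.
    """
    deleted = normalize_chromosome(deleted)
    chrom_rows = [c for c in table.index if c not in ("A", "C", "Total", OTHER)]
    rest = [c for c in chrom_rows if c != deleted]
    if len(rest) < 3:
        raise ValueError("need >= 3 remaining chromosomes")
    values = table.loc[rest, "r_egs_rgs"].to_numpy(dtype=float)
    target = float(table.loc[deleted, "r_egs_rgs"])
    n = values.size
    sd = max(values.std(ddof=1), np.sqrt(_EPS_VAR))
    t = (values.mean() - target) / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return float(t), p


def updown_balance_test(n_up: int, n_down: int) -> tuple[float, float]:
    """Goodness-of-fit chi-square of up vs down DEG counts against 1:1.

    chi2 = (n_up - n_down)^2 / (n_up + n_down) with 1 df, two-sided p.
    """
    total = n_up + n_down
    if total <= 0:
        raise ValueError("need at least one DEG")
    chi2 = (n_up - n_down) ** 2 / total
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def mean_expression_compare(
    expr: ExpressionMatrix,
    ann: GeneAnnotation,
    chromosome: str,
    euploid: str,
    aneuploid: str,
) -> dict[str, float]:
    """Arithmetic mean expression of a chromosome's expressed genes, per genotype.

    Genes qualify when their replicate-mean TPM is positive in at least one
    genotype.  Means are compared with a paired two-sided t-test across
    genes; returns mean_eu, mean_an, t, p and n_genes.
    """
    chromosome = normalize_chromosome(chromosome)
    genes = ann.genes_on(chromosome).intersection(expr.gene_ids)
    eu = expr.genotype_values(euploid).loc[genes].mean(axis=1)
    an = expr.genotype_values(aneuploid).loc[genes].mean(axis=1)
    keep = (eu > 0) | (an > 0)
    eu, an = eu[keep], an[keep]
    if eu.empty:
        raise ValueError(f"no expressed genes on {chromosome}")
    if len(eu) < 2 or np.allclose(eu, an):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(an, eu)
    return {
        "mean_eu": float(eu.mean()),
        "mean_an": float(an.mean()),
        "t": float(t),
        "p": float(p),
        "n_genes": int(len(eu)),
    }


def cov_per_chromosome(
    expr: ExpressionMatrix,
    genotype: str,
    ann: GeneAnnotation,
    expressed: set[str] | None = None,
) -> dict[str, float]:
    """Coefficient of variation of expression across each chromosome's genes.

    CoV = sample sd / mean of the per-gene replicate-mean TPM over the
    chromosome's expressed genes (TPM > 0 in every replicate of the
    genotype unless an explicit gene set is given).  Chromosomes with < 2
    expressed genes or zero mean get NaN.
    """
    from .expression import expressed_genes

    if expressed is None:
        expressed = expressed_genes(expr, genotype)
    per_gene = expr.genotype_values(genotype).mean(axis=1)
    chrom = ann.frame.loc[per_gene.index, "chromosome"]
    out: dict[str, float] = {}
    for c in ann.chromosomes:
        vals = per_gene[(chrom == c) & per_gene.index.isin(expressed)]
        if len(vals) < 2 or vals.mean() == 0:
            out[c] = float("nan")
        else:
            out[c] = float(vals.std(ddof=1) / vals.mean())
    return out


def format_summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Report form of the summary table: ratio columns rounded half-up, 2 dp."""
    out = table.copy()
    for col in ("r_egs_rgs", "r_degs_egs"):
        out[col] = [
            round_half_up(v) if np.isfinite(v) else v for v in out[col].to_numpy()
        ]
    return out
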
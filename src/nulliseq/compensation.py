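"""Expression turnover, dose-response classification, homoeolog response.

After losing one chromosome pair of a tetraploid (gene dose 2/4 = 0.5), a
purely dose-driven response would halve expression (FC = 0.5).  Genes are
therefore classified against the dose model: ``dosage_effect`` (FC <= d),
``compensated`` (d < FC <= 1), ``overcompensated`` (FC > 1) — expression
above the euploid level despite the halved dose.  The two compensation
regimes the pipeline is built to distinguish are expression-level boosting
of the homoeologous A-subgenome partners versus widening of the
expressed-gene repertoire (more genes switched on), measured by the
homoeolog response test and the expressed-gene totals respectively.

Fold changes of genes silent in the euploid come from the pseudocount rule
of the differential module (FC = (mu_an + pc) / pc); this is a documented
convention, not an observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import percent
from .genome_model import ExpressionMatrix, GeneAnnotation, HomologMap, normalize_chromosome

__all__ = [
    "TurnoverReport",
    "DoseModel",
    "HomologReport",
    "expression_turnover",
    "classify_dose_compensation",
    "dose_response_r2",
    "homolog_response",
    "expressed_gene_totals",
]

DIRECTION_EPS = 1e-9


@dataclass
class DoseModel:
    """Expected fold change under a pure gene-dose response.

    For nullisomy in a tetraploid, copies drop from 2 of 4 present in the
    diploid leaf transcriptome baseline to 0, i.e. the dose of the missing
    chromosome's genes goes from 1 to 0.5; the dose-only expectation is
    FC = d = 0.5.
    """

    copies_euploid: int = 4
    copies_aneuploid: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.copies_aneuploid <= self.copies_euploid):
            raise ValueError("need 0 < copies_aneuploid <= copies_euploid")

    @property
    def dose(self) -> float:
        return self.copies_aneuploid / self.copies_euploid


@dataclass
class TurnoverReport:
    """Newly expressed (NVE) and silenced (NE) gene sets, with overcompensation."""

    newly_expressed: set[str]
    silenced: set[str]
    overcompensated: set[str] = field(default_factory=set)
    overcompensated_fraction_pct: float = float("nan")

    @property
    def n_newly_expressed(self) -> int:
        return len(self.newly_expressed)

    @property
    def n_silenced(self) -> int:
        return len(self.silenced)


def expression_turnover(
    expr: ExpressionMatrix,
    euploid: str,
    aneuploid: str,
    de: pd.DataFrame | None = None,
) -> TurnoverReport:
    """Genes switched on or off by the chromosome loss (strict replicate rule).

    Newly expressed: TPM = 0 in every euploid replicate and TPM > 0 in
    every aneuploid replicate; silenced is the reverse.  When a DE table
    with an ``fc`` column is supplied, the overcompensated subset of the
    newly expressed genes (FC > 1) and its percentage are filled in.
    """
    eu = expr.genotype_values(euploid).to_numpy()
    an = expr.genotype_values(aneuploid).to_numpy()
    genes = expr.gene_ids
    eu_all_zero = (eu == 0).all(axis=1)
    eu_all_pos = (eu > 0).all(axis=1)
    an_all_zero = (an == 0).all(axis=1)
    an_all_pos = (an > 0).all(axis=1)
    nve = set(genes[eu_all_zero & an_all_pos])
    ne = set(genes[eu_all_pos & an_all_zero])
    report = TurnoverReport(nve, ne)
    if de is not None and nve:
        fc = de.loc[de.index.intersection(list(nve)), "fc"]
        report.overcompensated = set(fc.index[fc > 1.0])
        report.overcompensated_fraction_pct = percent(
            len(report.overcompensated), len(nve)
        )
    return report


def classify_dose_compensation(
    de: pd.DataFrame, dose: DoseModel, genes=None
) -> tuple[pd.Series, dict[str, float]]:
    """Class per gene against the dose model, plus summary percentages.

    overcompensated: FC > 1; compensated: d < FC <= 1; dosage_effect:
    FC <= d (boundaries closed on the left).  The three classes partition
    the gene set.  Returns (per-gene class Series, summary dict with class
    counts and percentages at 2 decimals).
    """
    fc = de["fc"] if genes is None else de.loc[de.index.intersection(list(genes)), "fc"]
    d = dose.dose
    cls = pd.Series(
        np.where(fc > 1.0, "overcompensated", np.where(fc > d, "compensated", "dosage_effect")),
        index=fc.index,
        name="dose_class",
    )
    n = len(cls)
    summary: dict[str, float] = {"n_genes": n}
    for name in ("overcompensated", "compensated", "dosage_effect"):
        k = int((cls == name).sum())
        summary[f"n_{name}"] = k
        summary[f"{name}_pct"] = percent(k, n) if n else float("nan")
    return cls, summary


def dose_response_r2(fc_values, dose: DoseModel) -> float:
    """Coefficient of determination of observed FC against the dose prediction.

    The dose model predicts the constant FC = d for every gene, so
    R^2 = 1 - sum((FC - d)^2) / sum((FC - mean FC)^2).  Can be negative
    (the dose prediction fits worse than the mean).  Zero variance in FC is
    degenerate: 1.0 when every FC equals d exactly (perfect fit), NaN
    otherwise (sentinel).
    """
    fc = np.asarray(list(fc_values), dtype=float)
    if fc.size < 2:
        raise ValueError("need >= 2 fold changes")
    ss_tot = np.sum((fc - fc.mean()) ** 2)
    ss_res = np.sum((fc - dose.dose) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else float("nan")
    return float(1.0 - ss_res / ss_tot)


@dataclass
class HomologReport:
    """Response of A-subgenome homoeologs to the loss of their C partners."""

    n_pairs: int
    n_significant: int
    significant_fraction_pct: float
    mean_expr_eu: float
    mean_expr_an: float
    direction: str  # boost | reduction | flat
    per_gene: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def homolog_response(
    expr: ExpressionMatrix,
    hmap: HomologMap,
    ann: GeneAnnotation,
    deleted: str,
    euploid: str,
    aneuploid: str,
    alpha: float = 0.05,
    eps: float = DIRECTION_EPS,
) -> HomologReport:
    """Per-gene euploid-vs-aneuploid test of the deleted genes' A homoeologs.

    Pairs whose C gene lies on the deleted chromosome qualify when the A
    gene is expressed (replicate-mean TPM > 0) in at least one genotype.
    Each A gene gets a two-sided two-sample t-test across replicates; the
    report carries the significant fraction at ``alpha``, the mean A-side
    expression per genotype, and the net direction (boost when the
    aneuploid mean exceeds the euploid mean beyond ``eps``).
    """
    deleted = normalize_chromosome(deleted)
    pairs = hmap.pairs_with_c_on(deleted, ann)
    a_genes = pairs["a_gene"].unique()
    a_genes = [g for g in a_genes if g in expr.gene_ids]
    eu_block = expr.genotype_values(euploid).loc[a_genes]
    an_block = expr.genotype_values(aneuploid).loc[a_genes]
    keep = (eu_block.mean(axis=1) > 0) | (an_block.mean(axis=1) > 0)
    eu_block, an_block = eu_block[keep], an_block[keep]
    if eu_block.empty:
        raise ValueError(
            f"no expressed A-subgenome homoeolog of {deleted} genes found"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(
            an_block.to_numpy(), eu_block.to_numpy(), axis=1, equal_var=True
        )
    p = np.where(np.isnan(p), 1.0, p)
    per_gene = pd.DataFrame(
        {
            "mean_eu": eu_block.mean(axis=1),
            "mean_an": an_block.mean(axis=1),
            "t": t,
            "p": p,
        }
    )
    n_pairs = len(per_gene)
    n_sig = int((per_gene["p"] < alpha).sum())
    mean_eu = float(per_gene["mean_eu"].mean())
    mean_an = float(per_gene["mean_an"].mean())
    if mean_an > mean_eu + eps:
        direction = "boost"
    elif mean_an < mean_eu - eps:
        direction = "reduction"
    else:
        direction = "flat"
    return HomologReport(
        n_pairs=n_pairs,
        n_significant=n_sig,
        significant_fraction_pct=percent(n_sig, n_pairs),
        mean_expr_eu=mean_eu,
        mean_expr_an=mean_an,
        direction=direction,
        per_gene=per_gene,
    )


def expressed_gene_totals(
    expr: ExpressionMatrix,
    euploid: str,
    aneuploid: str,
    rule: str = "any",
    exclude: set[str] | None = None,
) -> dict[str, float]:
    """Genome-wide expressed-gene counts per genotype with a two-cell chi-square.

    The breadth metric counts genes with TPM > 0 in any replicate of the
    genotype (rule="any", the default); rule="all" applies the strict
    all-replicate rule instead.  ``exclude`` removes genes (typically the
    deleted chromosome's) from both counts.  chi2 compares the two totals
    against equality.
    """
    from .expression import expressed_genes

    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    min_reps = 1 if rule == "any" else "all"
    n_eu_set = expressed_genes(expr, euploid, min_replicates=min_reps)
    n_an_set = expressed_genes(expr, aneuploid, min_replicates=min_reps)
    if exclude:
        n_eu_set -= set(exclude)
        n_an_set -= set(exclude)
    n_eu, n_an = len(n_eu_set), len(n_an_set)
    if n_eu + n_an == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (n_an - n_eu) ** 2 / (n_an + n_eu)
        p = float(stats.chi2.sf(chi2, df=1))
    return {
        "n_expressed_eu": n_eu,
        "n_expressed_an": n_an,
        "chi2": float(chi2),
        "p": p,
    }
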
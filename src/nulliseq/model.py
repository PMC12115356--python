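"""The fitted-model surface of the pipeline.

:class:`NullisomyExperiment` bundles the inputs of one euploid-vs-nullisomy
comparison (counts, annotation, optional homoeolog map and gene sets);
``fit()`` runs every stage in order — TPM quantification, deleted-chromosome
detection, NB differential expression, cis/trans attribution, chromosome
summary and sensitivity grouping, expression turnover and dose-response
classification, homoeolog response, expressed-gene totals, and optional
gene-set enrichment — and returns a :class:`NullisomyResults` carrying the
estimates, the intermediate tables, and ``summary()`` / ``save()``.

The fit is fully deterministic: the same inputs and thresholds give
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import chromosome_response as cr
from . import compensation as comp
from . import differential as de
from . import enrichment as enr
from . import expression as ex
from .genome_model import (
    CountMatrix,
    GeneAnnotation,
    HomologMap,
    load_annotation,
    load_counts,
    load_homolog_map,
)

__all__ = ["NullisomyExperiment", "NullisomyResults", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class FitOptions:
    fdr: float = 0.05
    lfc: float = 1.0
    detection_threshold: float = 0.5
    pseudocount: float = 0.5
    homolog_alpha: float = 0.05
    enrichment_correction: str = "bh"
    eg_rule: str = "intersection"  # expressed-gene set for the summary table

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if self.lfc < 0:
            raise ValueError("lfc must be >= 0")
        if not (0 < self.detection_threshold < 1):
            raise ValueError("detection_threshold must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.eg_rule not in ("intersection", "union"):
            raise ValueError("eg_rule must be 'intersection' or 'union'")


class NullisomyExperiment:
    """Model of one euploid-vs-nullisomy transcriptome comparison.

    Parameters
    ----------
    counts : CountMatrix
        Raw counts for both genotypes (3 replicates each in the study design).
    annotation : GeneAnnotation
        Gene -> chromosome / length map covering every counted gene.
    euploid, aneuploid : str
        Genotype labels in the count matrix; by default the first genotype
        is the euploid control, the second the nullisomy line.
    homolog_map : HomologMap, optional
        A<->C homoeolog pairs; the homoeolog-response stage is skipped when
        absent.
    gene_sets : GeneSetCollection, optional
        Sets for the enrichment stage, skipped when absent.
    """

    def __init__(
        self,
        counts: CountMatrix,
        annotation: GeneAnnotation,
        euploid: str | None = None,
        aneuploid: str | None = None,
        homolog_map: HomologMap | None = None,
        gene_sets: enr.GeneSetCollection | None = None,
    ):
        counts.validate_against(annotation)
        names = counts.genotype_names()
        if euploid is None:
            euploid = names[0]
        if aneuploid is None:
            candidates = [g for g in names if g != euploid]
            if len(candidates) != 1:
                raise ValueError(
                    f"aneuploid genotype ambiguous among {candidates}; pass it explicitly"
                )
            aneuploid = candidates[0]
        for g in (euploid, aneuploid):
            counts.samples_of(g)  # raises on unknown genotype
        self.counts = counts
        self.annotation = annotation
        self.euploid = euploid
        self.aneuploid = aneuploid
        self.homolog_map = homolog_map
        self.gene_sets = gene_sets
        self._input_paths: dict[str, Path] = {}

    @classmethod
    def from_files(
        cls,
        counts_path,
        annotation_path,
        homolog_map_path=None,
        gene_sets_path=None,
        annotation_format: str = "tsv",
        euploid: str | None = None,
        aneuploid: str | None = None,
    ) -> "NullisomyExperiment":
        ann = load_annotation(annotation_path, format=annotation_format)
        counts = load_counts(counts_path)
        hmap = (
            load_homolog_map(homolog_map_path, ann) if homolog_map_path else None
        )
        sets = (
            enr.GeneSetCollection.from_gmt(gene_sets_path, set(ann.gene_ids))
            if gene_sets_path
            else None
        )
        model = cls(counts, ann, euploid, aneuploid, hmap, sets)
        model._input_paths = {
            k: Path(v)
            for k, v in {
                "counts": counts_path,
                "annotation": annotation_path,
                "homolog_map": homolog_map_path,
                "gene_sets": gene_sets_path,
            }.items()
            if v
        }
        return model

    def fit(self, **options) -> "NullisomyResults":
        """Run the full pipeline; returns a results object."""
        opts = FitOptions(**options)
        state: dict = {}

        def stage(name, fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as e:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, e) from e
            log.info("stage %-22s %.2fs", name, time.perf_counter() - t0)
            return out

        eu, an = self.euploid, self.aneuploid
        ann = self.annotation

        tpm = stage("tpm", lambda: ex.tpm(self.counts, ann))
        ratios = stage(
            "chromosome_ratio",
            lambda: ex.chromosome_expression_ratio(tpm, ann, eu, an),
        )
        detected = stage(
            "detect_deleted",
            lambda: ex.detect_deleted_chromosomes(ratios, opts.detection_threshold),
        )
        deleted = detected[0] if detected else None

        s = stage("size_factors", lambda: de.size_factors(self.counts))
        alpha = stage(
            "dispersion", lambda: de.estimate_dispersion(self.counts, (eu, an), s)
        )
        de_table = stage(
            "nb_wald_test",
            lambda: de.nb_wald_test(
                self.counts, (eu, an), s, alpha, pseudocount=opts.pseudocount
            ),
        )
        degs = stage(
            "call_degs", lambda: de.call_degs(de_table, fdr=opts.fdr, lfc=opts.lfc)
        )
        degs.insert(0, "chromosome", ann.frame.loc[degs.index, "chromosome"])
        deg_ids = degs.index[degs["status"] != "ns"]
        counts_ud = de.deg_counts(degs)
        fc_bins = stage("fc_bins", lambda: de.fc_bin_table(degs))
        chi2_updown = stage(
            "updown_balance",
            lambda: cr.updown_balance_test(counts_ud["up"], counts_ud["down"])
            if counts_ud["total"]
            else (0.0, 1.0),
        )

        expressed_eu = stage("expressed_eu", lambda: ex.expressed_genes(tpm, eu))
        expressed_an = stage("expressed_an", lambda: ex.expressed_genes(tpm, an))
        # Summary-table EG set: the intersection requires expression in both
        # genotypes, which is what lets the deleted chromosome's expressed
        # proportion collapse toward the cross-mapping residual; the union
        # (every gene expressed in either genotype) is selectable instead.
        if opts.eg_rule == "intersection":
            expressed_set = expressed_eu & expressed_an
        else:
            expressed_set = expressed_eu | expressed_an

        cis_trans = summary_table = deleted_test = None
        if deleted is not None:
            cis_trans = stage(
                "cis_trans",
                lambda: cr.cis_trans_partition(deg_ids, ann, deleted),
            )
            summary_table = stage(
                "chromosome_summary",
                lambda: cr.chromosome_summary_table(
                    ann, expressed_set, deg_ids, deleted
                ),
            )
            deleted_test = stage(
                "deleted_vs_rest",
                lambda: cr.deleted_vs_rest_test(summary_table, deleted),
            )

        mean_compare = stage(
            "mean_expression",
            lambda: {
                c: cr.mean_expression_compare(tpm, ann, c, eu, an)
                for c in ann.chromosomes
            },
        )
        cov = stage(
            "cov",
            lambda: pd.DataFrame(
                {
                    "cov_euploid": cr.cov_per_chromosome(tpm, eu, ann),
                    "cov_aneuploid": cr.cov_per_chromosome(tpm, an, ann),
                }
            ).assign(delta=lambda f: f["cov_aneuploid"] - f["cov_euploid"]),
        )

        turnover = stage(
            "turnover", lambda: comp.expression_turnover(tpm, eu, an, de=degs)
        )
        dose = comp.DoseModel()
        dose_classes, dose_summary = stage(
            "dose_classes",
            lambda: comp.classify_dose_compensation(
                degs, dose, genes=turnover.newly_expressed
            )
            if turnover.newly_expressed
            else (pd.Series(dtype=object), {"n_genes": 0}),
        )
        r2 = stage(
            "dose_r2",
            lambda: comp.dose_response_r2(
                degs.loc[dose_classes.index, "fc"], dose
            )
            if len(dose_classes) >= 2
            else float("nan"),
        )
        totals = stage(
            "expressed_totals",
            lambda: comp.expressed_gene_totals(
                tpm,
                eu,
                an,
                exclude=set(ann.genes_on(deleted)) if deleted else None,
            ),
        )

        homolog = None
        if self.homolog_map is not None and deleted is not None:
            homolog = stage(
                "homolog_response",
                lambda: comp.homolog_response(
                    tpm,
                    self.homolog_map,
                    ann,
                    deleted,
                    eu,
                    an,
                    alpha=opts.homolog_alpha,
                ),
            )

        enrichment = None
        if self.gene_sets is not None and len(deg_ids):
            enrichment = stage(
                "enrichment",
                lambda: enr.fisher_enrichment(
                    set(deg_ids), self.gene_sets, correction=opts.enrichment_correction
                ),
            )

        return NullisomyResults(
            model=self,
            options=opts,
            tpm=tpm,
            ratios=ratios,
            detected_deleted=detected,
            size_factors=s,
            dispersion=alpha,
            de_table=degs,
            fc_bins=fc_bins,
            updown_chi2=chi2_updown,
            expressed_eu=expressed_eu,
            expressed_an=expressed_an,
            cis_trans=cis_trans,
            summary_table=summary_table,
            deleted_vs_rest=deleted_test,
            mean_compare=mean_compare,
            cov=cov,
            turnover=turnover,
            dose_model=dose,
            dose_classes=dose_classes,
            dose_summary=dose_summary,
            dose_r2=r2,
            expressed_totals=totals,
            homolog=homolog,
            enrichment=enrichment,
        )


@dataclass
class NullisomyResults:
    """Everything one fitted nullisomy comparison produced."""

    model: NullisomyExperiment
    options: FitOptions
    tpm: "ex.ExpressionMatrix"
    ratios: ex.ChromosomeExpressionRatio
    detected_deleted: list[str]
    size_factors: pd.Series
    dispersion: pd.Series
    de_table: pd.DataFrame
    fc_bins: pd.DataFrame
    updown_chi2: tuple[float, float]
    expressed_eu: set[str]
    expressed_an: set[str]
    cis_trans: cr.CisTransPartition | None
    summary_table: pd.DataFrame | None
    deleted_vs_rest: tuple[float, float] | None
    mean_compare: dict[str, dict[str, float]]
    cov: pd.DataFrame
    turnover: comp.TurnoverReport
    dose_model: comp.DoseModel
    dose_classes: pd.Series
    dose_summary: dict[str, float]
    dose_r2: float
    expressed_totals: dict[str, float]
    homolog: comp.HomologReport | None
    enrichment: pd.DataFrame | None = None

    @property
    def deleted_chromosome(self) -> str | None:
        return self.detected_deleted[0] if self.detected_deleted else None

    def deg_counts(self) -> dict[str, int]:
        return de.deg_counts(self.de_table)

    def summary(self) -> str:
        """Human-readable run summary."""
        m = self.model
        counts = self.deg_counts()
        lines = [
            "Nullisomy transcriptome comparison",
            "=" * 50,
            f"euploid control : {m.euploid} ({len(m.counts.samples_of(m.euploid))} reps)",
            f"aneuploid line  : {m.aneuploid} ({len(m.counts.samples_of(m.aneuploid))} reps)",
            f"genes           : {len(m.counts.gene_ids)}",
            "",
            f"detected deleted chromosome(s): {self.detected_deleted or 'none'}",
        ]
        if self.deleted_chromosome:
            lines.append(
                f"  expression-share ratio of {self.deleted_chromosome}: "
                f"{self.ratios.ratio(self.deleted_chromosome):.3f}"
            )
        chi2, p = self.updown_chi2
        lines += [
            "",
            f"DEGs (q < {self.options.fdr}, |log2FC| >= {self.options.lfc}): "
            f"{counts['total']} ({counts['up']} up / {counts['down']} down; "
            f"chi2 = {chi2:.2f}, p = {p:.3g})",
        ]
        if self.cis_trans is not None:
            lines.append(
                f"cis (on {self.deleted_chromosome}): {len(self.cis_trans.cis)} "
                f"({self.cis_trans.cis_fraction_pct}%), trans: {len(self.cis_trans.trans)}"
            )
        if self.deleted_vs_rest is not None:
            t, p = self.deleted_vs_rest
            lines.append(
                f"deleted-vs-rest expressed proportion: t = {t:.2f}, p = {p:.3g}"
            )
        lines += [
            "",
            f"expressed genes ({m.euploid} / {m.aneuploid}, all-replicate rule): "
            f"{len(self.expressed_eu)} / {len(self.expressed_an)}",
            f"newly expressed: {self.turnover.n_newly_expressed}, "
            f"silenced: {self.turnover.n_silenced}",
        ]
        if self.dose_summary.get("n_genes"):
            lines.append(
                f"of newly expressed, overcompensated (FC > 1): "
                f"{self.dose_summary['n_overcompensated']} "
                f"({self.dose_summary['overcompensated_pct']}%); "
                f"dose-response R^2 = {self.dose_r2:.3f}"
            )
        tot = self.expressed_totals
        lines.append(
            f"breadth totals (any-replicate rule, deleted chromosome excluded): "
            f"{tot['n_expressed_eu']} vs {tot['n_expressed_an']} "
            f"(chi2 = {tot['chi2']:.2f}, p = {tot['p']:.3g})"
        )
        if self.homolog is not None:
            h = self.homolog
            lines.append(
                f"homoeolog response ({h.n_pairs} A partners of deleted genes): "
                f"{h.n_significant} significant ({h.significant_fraction_pct}%), "
                f"direction = {h.direction} "
                f"(mean TPM {h.mean_expr_eu:.1f} -> {h.mean_expr_an:.1f})"
            )
        if self.enrichment is not None and len(self.enrichment):
            top = self.enrichment.iloc[0]
            lines.append(
                f"top enriched set: {top['set']} (overlap {top['overlap']}, "
                f"q = {top['q']:.3g})"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # report bundle

    def save(self, out_dir) -> dict[str, Path]:
        """Write all report tables plus a machine-readable manifest.

        Writes are staged in a temporary directory and moved into place
        only on success, so a failed save leaves no partial bundle.
        Outputs carry no timestamps: the same fit saves byte-identically.
        """
        out_dir = Path(out_dir)
        tmp = Path(tempfile.mkdtemp(prefix="nulliseq_", dir=out_dir.parent if out_dir.parent.exists() else None))
        try:
            paths = self._write_reports(tmp)
            out_dir.mkdir(parents=True, exist_ok=True)
            final = {}
            for key, p in paths.items():
                dest = out_dir / p.name
                shutil.move(str(p), dest)
                final[key] = dest
            return final
        finally:
            shutil.rmtree(tmp, ignore_errors=True)

    def _write_reports(self, d: Path) -> dict[str, Path]:
        paths: dict[str, Path] = {}

        def tsv(key, frame, **kw):
            p = d / f"{key}.tsv"
            frame.to_csv(p, sep="\t", **kw)
            paths[key] = p

        tsv("deletion_detection", self.ratios.frame)
        tsv("deg_table", self.de_table, index_label="gene_id")
        tsv("fc_bins", self.fc_bins)
        if self.summary_table is not None:
            tsv(
                "chromosome_summary",
                cr.format_summary_table(self.summary_table),
                index_label="chromosome",
            )
        tsv("cov", self.cov, index_label="chromosome")
        turnover_frame = pd.DataFrame(
            {
                "gene_id": sorted(self.turnover.newly_expressed)
                + sorted(self.turnover.silenced),
                "class": ["newly_expressed"] * self.turnover.n_newly_expressed
                + ["silenced"] * self.turnover.n_silenced,
            }
        )
        tsv("turnover", turnover_frame, index=False)
        if self.homolog is not None:
            tsv("homolog_response", self.homolog.per_gene, index_label="a_gene")
        if self.enrichment is not None:
            tsv("enrichment", self.enrichment, index=False)

        comp_summary = {
            "dose": self.dose_model.dose,
            "dose_r2": self.dose_r2,
            "dose_classes": {
                k: v for k, v in self.dose_summary.items() if k != "n_genes"
            },
            "n_newly_expressed": self.turnover.n_newly_expressed,
            "n_silenced": self.turnover.n_silenced,
            "overcompensated_fraction_pct": self.turnover.overcompensated_fraction_pct,
            "expressed_totals": self.expressed_totals,
        }
        p = d / "compensation_summary.json"
        with open(p, "w") as fh:
            json.dump(comp_summary, fh, indent=1, sort_keys=True, default=float)
        paths["compensation_summary"] = p

        manifest = {
            "package_version": __version__,
            "euploid": self.model.euploid,
            "aneuploid": self.model.aneuploid,
            "options": asdict(self.options),
            "detected_deleted": self.detected_deleted,
            "deg_counts": self.deg_counts(),
            "stages_skipped": [
                name
                for name, obj in (
                    ("homolog_response", self.homolog),
                    ("enrichment", self.enrichment),
                    ("cis_trans", self.cis_trans),
                )
                if obj is None
            ],
            "input_sha256": {
                k: _sha256(v) for k, v in self.model._input_paths.items()
            },
        }
        p = d / "manifest.json"
        with open(p, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        paths["manifest"] = p
        return paths

    def plot_chromosome_ratios(self, ax=None):
        """Bar plot of per-chromosome expression-share ratios (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        f = self.ratios.frame
        ax.bar(f.index, f["ratio"])
        ax.axhline(self.options.detection_threshold, ls="--", c="red", lw=1)
        ax.set_ylabel("aneuploid / euploid expression share")
        ax.set_xlabel("chromosome")
        ax.tick_params(axis="x", rotation=90)
        return ax


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
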
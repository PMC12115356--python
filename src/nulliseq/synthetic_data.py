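"""Synthetic nullisomy RNA-seq experiments with known ground truth.

The generator emulates the study design this package analyses: an euploid
allotetraploid control (A + C subgenomes) and a nullisomy line that has lost
one C-chromosome pair, sequenced with a few biological replicates each.
Counts are negative-binomially distributed around gene-specific baselines;
the deleted chromosome keeps a small residual signal (cross-mapping of reads
from homoeologous loci); a fraction of genes on the remaining chromosomes is
perturbed in trans; and two dosage-compensation regimes can be switched on:

* ``boost`` — homoeologous A-subgenome partners of the deleted genes are
  up-shifted (expression-level compensation);
* ``breadth`` — a share of genes silent in the euploid becomes expressed in
  the aneuploid (compensation by widening the expressed-gene repertoire).

Every simulated gene carries its ground-truth labels, so downstream stages
(deletion detection, differential expression, turnover, homoeolog response)
can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome_model import (
    CountMatrix,
    GeneAnnotation,
    HomologMap,
    write_annotation,
    write_counts,
    write_homolog_map,
)

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_experiment", "write_fixture"]

_MODES = ("boost", "breadth", "none")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic nullisomy experiment.

    Defaults encode the study conditions downstream stages are exercised
    against: a 19-chromosome A+C layout, one deleted C chromosome whose
    residual expression ratio sits in the observed deletion regime
    (~0.09-0.14), roughly half of the genome silent, and the nullisomy dose
    model d = 0.5 (two of four chromosome copies lost).
    """

    n_chromosomes_A: int = 10
    n_chromosomes_C: int = 9
    genes_per_chromosome: int = 300
    deleted_chromosome: str = "C01"
    residual_fraction: float = 0.12
    trans_fraction: float = 0.15
    trans_log2fc_sd: float = 1.0
    dispersion: float = 0.1
    mean_log_mu: float = 3.0
    sd_log_mu: float = 1.5
    silent_fraction: float = 0.45
    compensation_mode: str = "none"
    boost_log2fc: float = 0.5
    breadth_activation_rate: float = 0.1
    homolog_fraction: float = 0.6
    n_replicates: int = 3
    euploid_name: str = "Ctr"
    aneuploid_name: str = "NC"
    gene_length_range: tuple[int, int] = (500, 5000)
    size_factors: list[float] | None = None  # per sample; unit depth if None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "residual_fraction",
            "trans_fraction",
            "silent_fraction",
            "breadth_activation_rate",
            "homolog_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.residual_fraction >= 1.0:
            raise ValueError("residual_fraction must be < 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.compensation_mode not in _MODES:
            raise ValueError(
                f"compensation_mode must be one of {_MODES}, got {self.compensation_mode!r}"
            )
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        self.deleted_chromosome = self.deleted_chromosome.upper()
        layout = self.chromosomes()
        if self.deleted_chromosome not in layout:
            raise ValueError(
                f"deleted chromosome {self.deleted_chromosome} absent from layout"
            )
        # The study concerns C-chromosome losses; A losses run but are flagged.
        self.deleted_is_A = self.deleted_chromosome.startswith("A")

    def chromosomes(self) -> list[str]:
        return [f"A{i:02d}" for i in range(1, self.n_chromosomes_A + 1)] + [
            f"C{i:02d}" for i in range(1, self.n_chromosomes_C + 1)
        ]

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "gene_length_range" in d:
            d["gene_length_range"] = tuple(d["gene_length_range"])
        d.pop("deleted_is_A", None)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("deleted_is_A", None)
        d["gene_length_range"] = list(self.gene_length_range)
        return d


@dataclass
class SimulationTruth:
    """Per-gene ground truth of one simulated experiment."""

    deleted_chromosome: str
    frame: pd.DataFrame  # index gene_id; flags + baseline/true effect columns
    homolog_map: HomologMap = field(repr=False, default=None)  # type: ignore[assignment]


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, alpha) with var = mean + alpha * mean^2; zero mean -> zero."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        r = 1.0 / alpha
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[GeneAnnotation, HomologMap, CountMatrix, SimulationTruth]:
    """Draw one euploid + nullisomy experiment from the generative model.

    Same config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    chroms = config.chromosomes()
    g = config.genes_per_chromosome
    n_genes = g * len(chroms)

    gene_chrom = np.repeat(chroms, g)
    gene_ids = np.array(
        [f"Bna{c}g{i + 1:04d}" for c in chroms for i in range(g)]
    )
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n_genes
    )
    ann = GeneAnnotation.from_records(zip(gene_ids, gene_chrom, lengths))

    # Baseline means: log-normal with a silent (mu = 0) fraction.
    mu = rng.lognormal(config.mean_log_mu, config.sd_log_mu, size=n_genes)
    silent = rng.random(n_genes) < config.silent_fraction
    mu[silent] = 0.0

    on_deleted = gene_chrom == config.deleted_chromosome
    is_A = np.char.startswith(gene_chrom.astype(str), "A")

    # Homoeolog map: pair gene i of C0k with gene i of A0k where the partner
    # chromosome exists, for a random homolog_fraction share of C genes.
    a_names = {f"A{i:02d}" for i in range(1, config.n_chromosomes_A + 1)}
    pairs: list[tuple[str, str]] = []
    for k in range(1, config.n_chromosomes_C + 1):
        c_name, a_name = f"C{k:02d}", f"A{k:02d}"
        if a_name not in a_names:
            continue
        chosen = rng.random(g) < config.homolog_fraction
        for i in np.flatnonzero(chosen):
            pairs.append((f"Bna{a_name}g{i + 1:04d}", f"Bna{c_name}g{i + 1:04d}"))
    hmap = HomologMap.from_pairs(pairs, ann)

    deleted_c_genes = set(
        hmap.pairs_with_c_on(config.deleted_chromosome, ann)["c_gene"]
    )
    homolog_of_deleted = np.isin(
        gene_ids,
        hmap.pairs[hmap.pairs["c_gene"].isin(deleted_c_genes)]["a_gene"].to_numpy(),
    )

    # Trans perturbation on non-deleted chromosomes.
    trans_candidates = np.flatnonzero(~on_deleted & (mu > 0))
    n_trans = int(round(config.trans_fraction * trans_candidates.size))
    trans_idx = rng.choice(trans_candidates, size=n_trans, replace=False)
    is_trans = np.zeros(n_genes, dtype=bool)
    is_trans[trans_idx] = True
    true_log2fc = np.zeros(n_genes)
    true_log2fc[trans_idx] = rng.normal(0.0, config.trans_log2fc_sd, size=n_trans)

    if config.compensation_mode == "boost":
        true_log2fc[homolog_of_deleted] += config.boost_log2fc

    newly_activated = np.zeros(n_genes, dtype=bool)
    activation_mu = np.zeros(n_genes)
    if config.compensation_mode == "breadth":
        silent_idx = np.flatnonzero(silent & ~on_deleted)
        act = silent_idx[rng.random(silent_idx.size) < config.breadth_activation_rate]
        newly_activated[act] = True
        activation_mu[act] = rng.lognormal(
            config.mean_log_mu, config.sd_log_mu, size=act.size
        )

    mu_eu = mu
    mu_an = mu * np.exp2(true_log2fc)
    mu_an[on_deleted] = mu[on_deleted] * config.residual_fraction
    mu_an = np.where(newly_activated, activation_mu, mu_an)

    n_rep = config.n_replicates
    labels = [f"{config.euploid_name}_{r}" for r in range(1, n_rep + 1)] + [
        f"{config.aneuploid_name}_{r}" for r in range(1, n_rep + 1)
    ]
    sf = config.size_factors or [1.0] * (2 * n_rep)
    if len(sf) != 2 * n_rep:
        raise ValueError("size_factors must have one entry per sample")

    cols = {}
    for j, label in enumerate(labels):
        base = mu_eu if j < n_rep else mu_an
        cols[label] = _nb_draws(rng, base * sf[j], config.dispersion)
    counts = CountMatrix(
        pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    )

    truth_frame = pd.DataFrame(
        {
            "chromosome": gene_chrom,
            "baseline_mu": mu_eu,
            "aneuploid_mu": mu_an,
            "is_deleted": on_deleted,
            "is_trans_perturbed": is_trans,
            "true_log2fc": true_log2fc,
            "is_newly_activated": newly_activated,
            "is_homolog_of_deleted": homolog_of_deleted,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = SimulationTruth(config.deleted_chromosome, truth_frame, hmap)
    return ann, hmap, counts, truth


def make_gene_sets(
    ann: GeneAnnotation,
    truth: SimulationTruth,
    n_random: int = 8,
    set_size: int = 50,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Synthetic gene sets for the enrichment stage.

    One set per simulated signal class (deleted-chromosome genes, trans
    targets) plus random background sets, so over-representation has both
    true positives and nulls to find.
    """
    rng = np.random.default_rng(seed)
    universe = ann.gene_ids.to_numpy()
    tf = truth.frame
    sets: dict[str, list[str]] = {
        "deleted_chromosome_genes": tf.index[tf["is_deleted"]].tolist(),
        "trans_targets": tf.index[tf["is_trans_perturbed"]].tolist(),
    }
    for i in range(n_random):
        size = min(set_size, universe.size)
        sets[f"random_set_{i + 1}"] = sorted(
            rng.choice(universe, size=size, replace=False).tolist()
        )
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def write_fixture(
    directory,
    ann: GeneAnnotation,
    hmap: HomologMap,
    counts: CountMatrix,
    truth: SimulationTruth,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write a simulated experiment as re-loadable TSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": directory / "annotation.tsv",
        "homolog_map": directory / "homolog_map.tsv",
        "counts": directory / "counts.tsv",
        "truth": directory / "truth.tsv",
    }
    write_annotation(ann, paths["annotation"])
    write_homolog_map(hmap, paths["homolog_map"])
    write_counts(counts, paths["counts"])
    truth.frame.to_csv(paths["truth"], sep="\t", index_label="gene_id")
    if config is not None:
        paths["config"] = directory / "config.json"
        with open(paths["config"], "w") as fh:
            json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
        gene_sets = make_gene_sets(ann, truth, seed=config.seed)
        paths["gene_sets"] = directory / "gene_sets.gmt"
        write_gmt(gene_sets, paths["gene_sets"])
    return paths
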
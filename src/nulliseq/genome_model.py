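"""Domain containers and I/O: gene annotation, homoeolog map, count matrices.

The genome layout is the allotetraploid *Brassica napus* convention: an A
subgenome (chromosomes A01..A10) and a C subgenome (C01..C09).  Chromosome
names are canonicalized to the two-digit form ("A01"), since upstream files
mix "A1", "chrA01" and "a01" freely and join bugs between dialects are the
single most common failure mode in this kind of analysis.  Genes on
unplaced scaffolds are retained but grouped under the pseudo-chromosome
label "other" in per-chromosome reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "HomologMap",
    "CountMatrix",
    "ExpressionMatrix",
    "normalize_chromosome",
    "load_annotation",
    "write_annotation",
    "load_homolog_map",
    "load_counts",
    "write_counts",
]

OTHER = "other"

_CHROM_RE = re.compile(r"^(?:chr)?([ac])0*([1-9]\d?)$", re.IGNORECASE)
_SCAFFOLD_RE = re.compile(r"(scaffold|contig|random|^un)", re.IGNORECASE)


def normalize_chromosome(name: str) -> str:
    """Canonicalize a chromosome name to two-digit form ("A01").

    Scaffold-like names are mapped to the sentinel "other".  Raises
    ValueError for names that are neither A/C chromosomes nor scaffolds.
    Idempotent: normalizing an already-canonical name is a no-op.
    """
    s = str(name).strip()
    m = _CHROM_RE.match(s)
    if m:
        return f"{m.group(1).upper()}{int(m.group(2)):02d}"
    if s == OTHER or _SCAFFOLD_RE.search(s):
        return OTHER
    raise ValueError(f"unparseable chromosome name: {name!r}")


def subgenome_of(chromosome: str) -> str:
    """'A' or 'C' for canonical chromosome names, 'other' for scaffolds."""
    if chromosome == OTHER:
        return OTHER
    return chromosome[0]


@dataclass
class GeneAnnotation:
    """Gene -> (chromosome, length, subgenome) lookup.

    frame is indexed by gene_id with columns chromosome, length, subgenome;
    gene order is the input order and is preserved by all I/O.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id(s) in annotation: {dups}")
        if (f["length"] < 1).any():
            bad = f.index[f["length"] < 1].tolist()
            raise ValueError(f"non-positive gene length for: {bad}")

    @classmethod
    def from_records(cls, records) -> "GeneAnnotation":
        """Build from (gene_id, chromosome, length) triples; names normalized."""
        genes, chroms, lengths, bad = [], [], [], []
        for gid, chrom, length in records:
            genes.append(str(gid))
            try:
                chroms.append(normalize_chromosome(chrom))
            except ValueError:
                bad.append((gid, chrom))
                chroms.append(OTHER)
            lengths.append(int(length))
        if bad:
            raise ValueError(f"unparseable chromosome names: {bad}")
        frame = pd.DataFrame(
            {
                "chromosome": chroms,
                "length": np.asarray(lengths, dtype=np.int64),
            },
            index=pd.Index(genes, name="gene_id"),
        )
        frame["subgenome"] = [subgenome_of(c) for c in frame["chromosome"]]
        return cls(frame)

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def chromosomes(self) -> list[str]:
        """Canonical chromosome names present, sorted; 'other' excluded."""
        names = sorted(set(self.frame["chromosome"]) - {OTHER})
        return names

    def chromosome_of(self, gene_ids) -> pd.Series:
        return self.frame.loc[gene_ids, "chromosome"]

    def genes_on(self, chromosome: str) -> pd.Index:
        mask = self.frame["chromosome"] == normalize_chromosome(chromosome)
        return self.frame.index[mask]

    def reference_gene_counts(self) -> dict[str, int]:
        """Chromosome -> number of annotated genes (the RGs of report tables).

        Chromosomes with zero genes are absent; scaffold genes are lumped
        under 'other'.
        """
        counts = self.frame.groupby("chromosome", sort=True).size()
        return {str(k): int(v) for k, v in counts.items()}

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class HomologMap:
    """A<->C homoeolog pairs, each oriented (a_gene, c_gene), no duplicates."""

    pairs: pd.DataFrame  # columns a_gene, c_gene

    def __post_init__(self) -> None:
        if self.pairs.duplicated().any():
            raise ValueError("duplicate homoeolog pair(s)")

    @classmethod
    def from_pairs(cls, pairs, ann: GeneAnnotation) -> "HomologMap":
        """Validate pairs against the annotation, auto-correcting orientation."""
        sub = ann.frame["subgenome"]
        a_side, c_side = [], []
        for x, y in pairs:
            for g in (x, y):
                if g not in sub.index:
                    raise ValueError(f"homoeolog gene {g!r} absent from annotation")
            sx, sy = sub[x], sub[y]
            if sx == "A" and sy == "C":
                a_side.append(x)
                c_side.append(y)
            elif sx == "C" and sy == "A":
                a_side.append(y)
                c_side.append(x)
            else:
                raise ValueError(
                    f"pair ({x}, {y}) is {sx}-{sy}; need one A and one C gene"
                )
        frame = pd.DataFrame({"a_gene": a_side, "c_gene": c_side})
        return cls(frame.drop_duplicates().reset_index(drop=True))

    def pairs_with_c_on(self, chromosome: str, ann: GeneAnnotation) -> pd.DataFrame:
        chrom = normalize_chromosome(chromosome)
        on = ann.frame.loc[self.pairs["c_gene"], "chromosome"].to_numpy() == chrom
        return self.pairs[on].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)


def _parse_sample_label(label: str) -> tuple[str, int]:
    genotype, _, rep = label.rpartition("_")
    if not genotype or not rep.isdigit():
        raise ValueError(
            f"sample label {label!r} is not of the form <genotype>_<replicate>"
        )
    return genotype, int(rep)


@dataclass
class _SampleMatrix:
    """Genes x samples matrix with genotype labels parsed from column names."""

    values: pd.DataFrame
    genotypes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.genotypes is None:
            self.genotypes = pd.Series(
                {c: _parse_sample_label(c)[0] for c in self.values.columns}
            )
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene_id(s) in matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def genotype_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.genotypes:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, genotype: str) -> list[str]:
        cols = [s for s, g in self.genotypes.items() if g == genotype]
        if not cols:
            raise KeyError(f"unknown genotype {genotype!r}")
        return cols

    def genotype_values(self, genotype: str) -> pd.DataFrame:
        return self.values[self.samples_of(genotype)]


@dataclass
class CountMatrix(_SampleMatrix):
    """Raw integer read counts, genes x samples.

    Column names follow the <genotype>_<replicate> dialect.  Each genotype
    must carry at least min_replicates samples (default 2; the study design
    is 3).
    """

    min_replicates: int = 2

    def __post_init__(self) -> None:
        super().__post_init__()
        arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.values = self.values.round().astype(np.int64)
        for g in self.genotype_names():
            n = len(self.samples_of(g))
            if n < self.min_replicates:
                raise ValueError(
                    f"genotype {g!r} has {n} replicate(s); need >= {self.min_replicates}"
                )

    def validate_against(self, ann: GeneAnnotation) -> None:
        missing = self.values.index.difference(ann.gene_ids)
        if len(missing):
            raise ValueError(
                f"{len(missing)} count-matrix gene(s) absent from annotation, "
                f"e.g. {missing[:5].tolist()}"
            )


@dataclass
class ExpressionMatrix(_SampleMatrix):
    """TPM expression values, genes x samples (non-negative reals)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")


# ---------------------------------------------------------------------------
# I/O


def load_annotation(path, format: str = "tsv") -> GeneAnnotation:
    """Read a gene annotation from TSV (gene_id, chromosome, length) or GFF3.

    GFF3 mode keeps only ``gene`` features, takes the ID attribute as the
    gene id and the 1-based inclusive feature span as the length.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
        required = {"gene_id", "chromosome", "length"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation TSV needs columns {sorted(required)}")
        records = df[["gene_id", "chromosome", "length"]].itertuples(index=False)
        return GeneAnnotation.from_records(records)
    if format == "gff3":
        records = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) != 9 or cols[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"gene feature without ID attribute: {line!r}")
                start, end = int(cols[3]), int(cols[4])
                records.append((gid, cols[0], end - start + 1))
        return GeneAnnotation.from_records(records)
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotation(ann: GeneAnnotation, path) -> None:
    out = ann.frame.reset_index()[["gene_id", "chromosome", "length"]]
    out.to_csv(path, sep="\t", index=False)


def load_homolog_map(path, ann: GeneAnnotation) -> HomologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("homoeolog map needs two columns (a_gene, c_gene)")
    return HomologMap.from_pairs(
        df.iloc[:, :2].itertuples(index=False, name=None), ann
    )


def write_homolog_map(hmap: HomologMap, path) -> None:
    hmap.pairs.to_csv(path, sep="\t", index=False)


def load_counts(path, min_replicates: int = 2) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return CountMatrix(df, min_replicates=min_replicates)


def write_counts(counts: _SampleMatrix, path) -> None:
    counts.values.to_csv(path, sep="\t", index_label="gene_id")
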
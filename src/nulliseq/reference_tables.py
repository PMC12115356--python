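"""Reported summary counts for three *B. napus* C-chromosome nullisomy lines.

Chromosome-level gene counts and genome-wide totals reported for the
euploid cultivar Oro compared against nullisomy lines lacking the C1, C2
or C8 chromosome pair (NC1, NC2, NC8).  These integers serve as
worked-example inputs: feeding them through the ratio and test operations
of this package reproduces the percentages and statistics the study
tables print, which is what the acceptance checks verify.

Only integer counts are stored; every ratio is recomputed.
"""

from __future__ import annotations

# Per-chromosome (reference genes, expressed genes, DEGs) for the Oro vs
# NC1 comparison, plus the reported sensitivity group of each chromosome.
# C01 is the deleted chromosome (no group).
NC1_CHROMOSOME_TABLE: list[tuple[str, int, int, int, str]] = [
    ("A01", 4296, 2350, 824, "High"),
    ("A02", 4203, 2066, 301, "High"),
    ("A03", 5946, 3210, 421, "Middle"),
    ("A04", 3014, 1527, 220, "High"),
    ("A05", 5002, 2007, 256, "Middle"),
    ("A06", 4533, 2388, 339, "High"),
    ("A07", 3904, 2185, 185, "Middle"),
    ("A08", 3222, 1732, 150, "Middle"),
    ("A09", 7218, 3479, 393, "Middle"),
    ("A10", 3021, 1748, 121, "Middle"),
    ("C01", 5168, 1509, 827, "deleted"),
    ("C02", 5574, 2218, 334, "High"),
    ("C03", 8178, 4067, 232, "Low"),
    ("C04", 6183, 2841, 195, "Middle"),
    ("C05", 5761, 2922, 160, "Low"),
    ("C06", 4597, 2270, 125, "Low"),
    ("C07", 5507, 2683, 151, "Low"),
    ("C08", 5349, 2548, 131, "Low"),
    ("C09", 6245, 2607, 226, "Middle"),
]

NC1_DELETED = "C01"

# Genome-wide DEG totals per comparison: total DEGs, upregulated DEGs, and
# DEGs residing on the deleted chromosome (the cis component).
DEG_TOTALS: dict[str, dict[str, int]] = {
    "NC1": {"total": 8028, "up": 3274, "cis": 1749, "deleted": "C01"},
    "NC2": {"total": 13620, "up": 6344, "cis": 2162, "deleted": "C02"},
    "NC8": {"total": 11718, "up": 4986, "cis": 2388, "deleted": "C08"},
}

# Cumulative fold-change-magnitude bins of the trans (remaining-chromosome)
# DEGs for NC1: bin bound -> (up, down).  The first bound (1) covers every
# DEG in that table.
NC1_FC_BINS: dict[float, tuple[int, int]] = {
    1: (3253, 3043),
    10: (921, 927),
    100: (368, 292),
    1000: (46, 27),
}

# Expression turnover per comparison: newly expressed (NVE), silenced (NE),
# and the overcompensated (FC > 1) subset of the newly expressed genes.
TURNOVER: dict[str, dict[str, int]] = {
    "NC1": {"nve": 2218, "ne": 3597, "overcompensated": 1318},
    "NC2": {"nve": 4945, "ne": 5302, "overcompensated": 3411},
    "NC8": {"nve": 5003, "ne": 4148, "overcompensated": 3596},
}

# Homoeologous A-subgenome partners of the deleted chromosome's genes:
# (number of homoeolog pairs, pairs with a significant expression change).
HOMOLOG_PAIRS: dict[str, tuple[int, int]] = {
    "NC1": (3109, 2242),
    "NC2": (3189, 1732),
    "NC8": (1651, 1000),
}

# Genome-wide expressed-gene totals (euploid, aneuploid) for the two lines
# reported to widen their expressed-gene repertoire.
EXPRESSED_TOTALS: dict[str, tuple[int, int]] = {
    "NC2": (48724, 49705),
    "NC8": (48605, 49961),
}
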
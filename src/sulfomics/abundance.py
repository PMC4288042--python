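"""Best-hit filtering, taxonomy assignment and normalized gene abundance.

Two distinct threshold profiles are applied exactly as used in practice for
metagenome annotation, rather than unified:

* class-level taxonomy of arbitrary genes: e-value < 1e-4 (strict) and
  query coverage >= 0.75 (inclusive), otherwise "unassigned";
* functional-gene identification: e-value <= 1e-4, query coverage > 0.70
  (strict) and bit score > 100 (strict).

Functional-gene abundance is normalized to gene length and sequencing
effort — hits per kilobase of gene per million reads — so counts are
comparable across genes and datasets.  Reconstructed 16S profiles get a
relative-abundance floor: entries below 0.01% are removed (no
renormalization by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "HitRecord",
    "UNASSIGNED",
    "filter_hits_functional",
    "assign_taxonomy_class",
    "normalize_abundance",
    "abundance_floor_16s",
    "best_hits",
    "abundance_table",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class HitRecord:
    """One best-hit record for a query gene (outfmt-6-like provenance)."""

    query_id: str
    gene_family: str
    subject_taxon_class: str
    subject_taxon_genus: str
    evalue: float
    bit_score: float
    query_coverage: float
    gene_length: int

    def __post_init__(self):
        if not (0.0 <= self.query_coverage <= 1.0):
            raise ValueError(f"query_coverage must be in [0,1], got {self.query_coverage}")
        if self.gene_length <= 0:
            raise ValueError("gene_length must be > 0")
        if self.evalue < 0 or self.bit_score < 0:
            raise ValueError("evalue and bit_score must be >= 0")


def filter_hits_functional(
    records,
    max_evalue: float = 1e-4,
    min_coverage: float = 0.70,
    min_bit_score: float = 100.0,
):
    """Functional-gene profile: e <= 1e-4, coverage > 0.70, bits > 100.

    Coverage and bit score are strict inequalities; a record at exactly 70%
    coverage or a bit score of exactly 100 is dropped.
    """
    return [
        r
        for r in records
        if r.evalue <= max_evalue
        and r.query_coverage > min_coverage
        and r.bit_score > min_bit_score
    ]


def assign_taxonomy_class(
    records,
    max_evalue: float = 1e-4,
    min_coverage: float = 0.75,
) -> list[str]:
    """Class-assignment profile: e < 1e-4 (strict) and coverage >= 0.75.

    Returns one label per input record, ``"unassigned"`` where the hit does
    not meet the profile.
    """
    return [
        r.subject_taxon_class
        if (r.evalue < max_evalue and r.query_coverage >= min_coverage)
        else UNASSIGNED
        for r in records
    ]


def normalize_abundance(raw_count: float, gene_length: int, total_reads: int) -> float:
    """Hits per kilobase of gene per million mapped reads.

    value = raw_count / ((gene_length / 1000) * (total_reads / 1e6)).
    """
    if gene_length <= 0:
        raise ValueError("gene_length must be > 0")
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if raw_count < 0:
        raise ValueError("raw_count must be >= 0")
    return raw_count / ((gene_length / 1000.0) * (total_reads / 1e6))


def abundance_floor_16s(otu_table: dict, floor: float = 1e-4, renormalize: bool = False) -> dict:
    """Drop 16S entries with estimated relative abundance < 0.01%.

    The comparison is strict: an entry at exactly the floor survives.
    Remaining values are returned unchanged unless ``renormalize`` is set,
    in which case they are rescaled to sum to 1.
    """
    kept = {k: v for k, v in otu_table.items() if v >= floor}
    if renormalize and kept:
        total = sum(kept.values())
        if total > 0:
            kept = {k: v / total for k, v in kept.items()}
    return kept


def best_hits(records) -> list[HitRecord]:
    """One record per query: highest bit score, ties by lower e-value, then
    input order."""
    best: dict[str, tuple[float, float, int]] = {}
    chosen: dict[str, HitRecord] = {}
    for i, r in enumerate(records):
        key = (-r.bit_score, r.evalue, i)
        if r.query_id not in best or key < best[r.query_id]:
            best[r.query_id] = key
            chosen[r.query_id] = r
    # preserve first-appearance order of queries
    seen = []
    emitted = set()
    for r in records:
        if r.query_id not in emitted:
            seen.append(chosen[r.query_id])
            emitted.add(r.query_id)
    return seen


def abundance_table(records, total_reads: int, rank: str = "class") -> pd.DataFrame:
    """Tidy abundance per (gene_family, taxon_group).

    Records should already be threshold-filtered.  ``raw_count`` is the
    number of hits in the group; ``normalized_abundance`` sums each hit's
    own length-and-depth normalization (hits per kb of gene per million
    reads), so genes of different lengths contribute comparably.
    """
    if rank == "class":
        attr = "subject_taxon_class"
    elif rank == "genus":
        attr = "subject_taxon_genus"
    else:
        raise ValueError(f"unknown rank {rank!r}")
    agg: dict[tuple[str, str], list[float]] = {}
    for r in records:
        key = (r.gene_family, getattr(r, attr))
        agg.setdefault(key, []).append(normalize_abundance(1, r.gene_length, total_reads))
    rows = [
        {
            "gene_family": fam,
            "taxon_group": tax,
            "raw_count": len(vals),
            "normalized_abundance": sum(vals),
        }
        for (fam, tax), vals in sorted(agg.items())
    ]
    return pd.DataFrame(rows, columns=["gene_family", "taxon_group", "raw_count", "normalized_abundance"])
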
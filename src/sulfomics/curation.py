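"""Genome-bin curation: taxonomic majority vote, GC/coverage outlier removal,
assembly statistics, marker-based completeness and reassembly selection.

A compositional bin is a hypothesis, not a genome.  The curation rules here
implement the standard manual-binning workflow as deterministic code: a
scaffold stays in a taxon-labelled bin only if strictly more than half of
its genes have best hits to the target taxon; contigs whose GC or coverage
depth sit far outside the bin median are flagged as contaminants; and draft
quality is summarised by assembly statistics plus the fraction of a
single-copy marker set recovered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import kmer

__all__ = [
    "GeneCall",
    "GenomeBin",
    "AssemblyStats",
    "DEFAULT_MARKER_SET",
    "majority_vote_filter",
    "gc_coverage_filter",
    "assembly_stats",
    "completeness",
    "select_best_assembly",
]

# Universal single-copy ribosomal proteins; a stand-in of the conventional
# size (19) for concatenated-marker completeness estimation.  The statistic
# depends only on set membership, so any inventory of the same form works.
DEFAULT_MARKER_SET: frozenset[str] = frozenset(
    {
        "rpL2", "rpL3", "rpL4", "rpL5", "rpL6", "rpL14", "rpL15", "rpL16",
        "rpL18", "rpL22", "rpL24",
        "rpS2", "rpS3", "rpS8", "rpS10", "rpS11", "rpS13", "rpS17", "rpS19",
    }
)
assert len(DEFAULT_MARKER_SET) == 19


@dataclass
class GeneCall:
    """A predicted gene: an interval on a contig plus its best-hit annotation.

    Coordinates are 1-based inclusive (GFF3 convention).  ``is_marker``
    carries a marker identifier when the gene is a single-copy phylogenetic
    marker, else None.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    function_label: str
    best_hit_taxon_class: str
    best_hit_taxon_genus: str
    evalue: float = 1e-30
    bit_score: float = 200.0
    query_coverage: float = 1.0
    is_marker: str | None = None

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad coordinates {self.start}..{self.end} on {self.contig_id}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AssemblyStats:
    total_bp: int
    n_scaffolds: int
    longest: int
    n50: int
    gc_percent: float
    n_genes: int


@dataclass
class GenomeBin:
    """A curated set of contigs attributed to one genome."""

    bin_id: str
    contig_ids: set[str]
    stats: AssemblyStats | None = None
    completeness_percent: float = 0.0
    duplicated_markers: int = 0
    notes: dict = field(default_factory=dict)


def majority_vote_filter(
    contig_ids,
    gene_calls,
    target_taxon: str,
    rank: str = "class",
    threshold: float = 0.5,
):
    """Retain contigs where > ``threshold`` of genes best-hit the target taxon.

    The vote is strict: a contig with exactly half matching genes is
    dropped.  Contigs carrying no genes cannot vote and are dropped with a
    ``no_genes`` flag rather than silently retained.

    Returns
    -------
    retained : set of contig_id
    report : DataFrame with columns contig_id, n_genes, n_match, fraction,
        status in {retained, dropped, no_genes}.
    """
    if rank == "class":
        attr = "best_hit_taxon_class"
    elif rank == "genus":
        attr = "best_hit_taxon_genus"
    else:
        raise ValueError(f"unknown rank {rank!r}; expected 'class' or 'genus'")

    contig_ids = list(contig_ids)
    wanted = set(contig_ids)
    n_genes: dict[str, int] = {c: 0 for c in contig_ids}
    n_match: dict[str, int] = {c: 0 for c in contig_ids}
    for g in gene_calls:
        if g.contig_id in wanted:
            n_genes[g.contig_id] += 1
            if getattr(g, attr) == target_taxon:
                n_match[g.contig_id] += 1

    rows = []
    retained = set()
    for c in contig_ids:
        if n_genes[c] == 0:
            rows.append((c, 0, 0, np.nan, "no_genes"))
            continue
        frac = n_match[c] / n_genes[c]
        status = "retained" if frac > threshold else "dropped"
        if status == "retained":
            retained.add(c)
        rows.append((c, n_genes[c], n_match[c], frac, status))
    report = pd.DataFrame(rows, columns=["contig_id", "n_genes", "n_match", "fraction", "status"])
    return retained, report


def gc_coverage_filter(
    contig_ids,
    gc: dict[str, float],
    depth: dict[str, float],
    gc_window: float = 0.05,
    cov_band: float = 3.0,
):
    """Remove contigs whose GC or depth deviates from the bin median.

    A contig survives iff |gc - median_gc| <= ``gc_window`` (GC fraction
    half-width) AND median_depth / ``cov_band`` <= depth <= median_depth *
    ``cov_band``.  Medians are computed on the incoming bin.  Bins of fewer
    than 3 contigs carry too little signal for a median; the filter is a
    no-op there and warns.

    Returns
    -------
    retained : set of contig_id
    report : DataFrame with per-contig gc, depth and removal reason.
    """
    contig_ids = list(contig_ids)
    if cov_band < 1:
        raise ValueError("cov_band is a multiplicative half-band and must be >= 1")
    if len(contig_ids) < 3:
        warnings.warn(
            f"bin of {len(contig_ids)} contig(s): GC/coverage filter skipped", stacklevel=2
        )
        report = pd.DataFrame(
            {
                "contig_id": contig_ids,
                "gc": [gc[c] for c in contig_ids],
                "depth": [depth[c] for c in contig_ids],
                "reason": "kept",
            }
        )
        return set(contig_ids), report

    med_gc = float(np.median([gc[c] for c in contig_ids]))
    med_depth = float(np.median([depth[c] for c in contig_ids]))
    lo, hi = med_depth / cov_band, med_depth * cov_band
    rows = []
    retained = set()
    for c in contig_ids:
        reasons = []
        if abs(gc[c] - med_gc) > gc_window:
            reasons.append("gc_outlier")
        if not (lo <= depth[c] <= hi):
            reasons.append("coverage_outlier")
        if reasons:
            rows.append((c, gc[c], depth[c], "+".join(reasons)))
        else:
            retained.add(c)
            rows.append((c, gc[c], depth[c], "kept"))
    report = pd.DataFrame(rows, columns=["contig_id", "gc", "depth", "reason"])
    return retained, report


def n50(lengths) -> int:
    """Length of the shortest contig in the minimal descending prefix whose
    cumulative length reaches half the assembly."""
    lengths = sorted((int(x) for x in lengths), reverse=True)
    if not lengths:
        raise ValueError("empty length list")
    half = sum(lengths) / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def assembly_stats(contigs, n_genes: int = 0) -> AssemblyStats:
    """Summary statistics of a contig set.

    ``contigs`` is an iterable of objects with a ``sequence`` attribute or of
    plain sequence strings.  GC percent is computed over all unambiguous
    bases pooled across contigs.
    """
    seqs = [c.sequence if hasattr(c, "sequence") else c for c in contigs]
    if not seqs:
        raise ValueError("assembly_stats of an empty contig set")
    lengths = [len(s) for s in seqs]
    gc_num = 0
    gc_den = 0
    for s in seqs:
        g = kmer.gc_content(s)
        counted = sum(1 for ch in s.upper() if ch in "ACGT")
        if counted:
            gc_num += g * counted
            gc_den += counted
    gc_percent = 100.0 * gc_num / gc_den if gc_den else float("nan")
    return AssemblyStats(
        total_bp=sum(lengths),
        n_scaffolds=len(lengths),
        longest=max(lengths),
        n50=n50(lengths),
        gc_percent=gc_percent,
        n_genes=n_genes,
    )


def completeness(gene_calls, marker_set) -> tuple[float, int]:
    """Marker-set completeness of a bin.

    completeness = 100 * |distinct markers observed| / |marker_set|.
    Extra copies of a marker are counted as ``duplicated_markers`` but can
    never raise completeness above what distinct membership supports.
    """
    marker_set = set(marker_set)
    if not marker_set:
        raise ValueError("marker_set must be non-empty")
    seen: dict[str, int] = {}
    for g in gene_calls:
        m = getattr(g, "is_marker", None)
        if m is not None and m in marker_set:
            seen[m] = seen.get(m, 0) + 1
    pct = 100.0 * len(seen) / len(marker_set)
    dup = sum(c - 1 for c in seen.values() if c > 1)
    return pct, dup


def select_best_assembly(candidates) -> int:
    """Pick the best reassembly by rank-sum over three criteria.

    Each candidate (an :class:`AssemblyStats` or anything with ``longest``,
    ``n50`` and ``n_scaffolds``) is ranked on longest contig (descending),
    N50 (descending) and number of scaffolds (ascending); the candidate
    with the smallest rank sum wins.  Rank-sum ties go to the higher N50,
    then to earliest input order.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("no candidate assemblies")
    longest = np.array([c.longest for c in cands], dtype=float)
    n50s = np.array([c.n50 for c in cands], dtype=float)
    nscaf = np.array([c.n_scaffolds for c in cands], dtype=float)
    ranksum = rankdata(-longest) + rankdata(-n50s) + rankdata(nscaf)
    order = sorted(range(len(cands)), key=lambda i: (ranksum[i], -n50s[i], i))
    return order[0]
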
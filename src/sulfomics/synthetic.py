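"""Synthetic multi-genome communities with ground truth.

Real sulfidic-biofilm metagenomes are not desk-reproducible, so every
downstream stage (profiling, ESOM binning, curation, abundance) is
exercised on simulated communities instead.  Each genome is an order-k
Markov chain over ACGT whose transition matrix is tilted to a target GC
and then randomly perturbed per genome, giving genome-specific
tetranucleotide signatures — the statistical structure compositional
binning assumes.  Genomes are fragmented into contigs with lognormal
lengths and lognormal depth noise around the genome's abundance, genes are
laid down as non-overlapping labelled intervals at a target density with
single-copy markers placed exactly once, and taxon labels can be corrupted
at a controlled mislabeling rate.  The true contig-to-genome map is kept
for adjusted-Rand-index scoring of bins.

Read-level simulation, sequencing error and assembly artefacts are out of
scope: contigs are clean substrings of the source genome.  Genes cut by a
fragment boundary survive as truncated records on both sides, mirroring
the partial gene calls real annotation pipelines emit at contig edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .abundance import HitRecord
from .curation import DEFAULT_MARKER_SET, GeneCall

__all__ = [
    "GenomeModel",
    "Contig",
    "CommunitySample",
    "simulate_genome",
    "fragment_genome",
    "simulate_community",
    "simulate_hit_table",
    "apply_mislabels",
    "ground_truth",
    "default_models",
    "default_community",
]

_BASES = "ACGT"

# function labels for non-marker genes; mostly hypothetical, plus the
# sulfur/nitrogen/carbon-cycle families the abundance stage tallies
_FUNCTION_POOL = (
    "hyp", "hyp", "hyp", "hyp", "hyp", "hyp", "hyp",
    "sqr", "fccB", "soxA", "soxB", "soxX", "soxY", "soxZ",
    "aclA", "aclB", "napA", "narG", "nirS", "psrA", "hydA",
)


@dataclass(frozen=True)
class GenomeModel:
    """Parameters of one simulated genome."""

    genome_id: str
    taxon_class: str
    taxon_genus: str
    gc_target: float
    genome_length: int
    abundance: float
    markov_order: int = 2
    composition_seedling: float = 0.2
    gene_density: float = 1.0  # genes per kb
    marker_set: frozenset[str] = DEFAULT_MARKER_SET

    def __post_init__(self):
        if not (0.2 < self.gc_target < 0.8):
            raise ValueError(f"gc_target must be in (0.2, 0.8), got {self.gc_target}")
        if self.genome_length < 50_000:
            raise ValueError(f"genome_length must be >= 50000, got {self.genome_length}")
        if self.abundance <= 0:
            raise ValueError("abundance must be > 0")
        if self.gene_density <= 0:
            raise ValueError("gene_density must be > 0")
        if self.markov_order < 0:
            raise ValueError("markov_order must be >= 0")
        if self.composition_seedling <= 0:
            raise ValueError("composition_seedling must be > 0")
        if not self.marker_set:
            raise ValueError("marker_set must be non-empty")


@dataclass
class Contig:
    contig_id: str
    sequence: str
    depth: float
    genome_id: str  # ground-truth origin
    genome_start: int = 0  # 0-based offset in the source genome

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CommunitySample:
    contigs: list[Contig]
    gene_calls: list[GeneCall]
    truth: dict[str, str]  # contig_id -> genome_id
    total_reads: int
    seed: int
    models: list[GenomeModel] = field(default_factory=list)


def _transition_matrix(model: GenomeModel, rng: np.random.Generator) -> np.ndarray:
    """Per-context base emission probabilities, GC-exact in every context.

    Log-probabilities get an iid Gaussian perturbation of scale
    ``composition_seedling`` (the genome's compositional identity), then
    each context row is re-tilted so P(G)+P(C) equals ``gc_target``
    exactly — the perturbation shapes the 4-mer signature without biasing
    realized GC.
    """
    gc = model.gc_target
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    n_ctx = 4**model.markov_order
    logits = np.log(base)[None, :] + model.composition_seedling * rng.normal(size=(n_ctx, 4))
    probs = np.exp(logits)
    probs[:, [1, 2]] *= (gc / (probs[:, 1] + probs[:, 2]))[:, None]
    probs[:, [0, 3]] *= ((1 - gc) / (probs[:, 0] + probs[:, 3]))[:, None]
    return probs


def _markov_sequence(probs: np.ndarray, length: int, order: int, rng: np.random.Generator) -> str:
    cum = probs.cumsum(axis=1)
    cum[:, -1] = 1.0
    # plain-python nested tuples: ~3x faster than row indexing into ndarray
    table = [tuple(row) for row in cum]
    u = rng.random(length)
    mask = 4**order if order > 0 else 1
    out = bytearray(length)
    lut = b"ACGT"
    ctx = 0
    for i in range(length):
        c0, c1, c2 = table[ctx][:3]
        x = u[i]
        b = 0 if x < c0 else 1 if x < c1 else 2 if x < c2 else 3
        out[i] = lut[b]
        if order > 0:
            ctx = (ctx * 4 + b) % mask
    return out.decode("ascii")


def simulate_genome(model: GenomeModel, seed) -> tuple[str, list[GeneCall]]:
    """Simulate one genome sequence plus its gene records.

    Returns the sequence (length exactly ``genome_length``) and gene calls
    whose ``contig_id`` is the genome id (genome coordinates, 1-based).
    Genes tile the genome without overlap at roughly ``gene_density`` per
    kb; every marker in ``marker_set`` is placed exactly once, on distinct
    genes, with the marker id doubling as the function label.
    """
    rng = np.random.default_rng(seed)
    probs = _transition_matrix(model, rng)
    sequence = _markov_sequence(probs, model.genome_length, model.markov_order, rng)

    lam = model.genome_length / 1000.0 * model.gene_density
    n_genes = int(rng.poisson(lam))
    n_genes = max(n_genes, len(model.marker_set))
    slot = model.genome_length // n_genes
    genes: list[GeneCall] = []
    for i in range(n_genes):
        glen = int(np.clip(rng.normal(0.75 * slot, 0.1 * slot), 90, slot - 1))
        start0 = i * slot + int(rng.integers(0, slot - glen))
        genes.append(
            GeneCall(
                gene_id=f"{model.genome_id}|g{i:05d}",
                contig_id=model.genome_id,
                start=start0 + 1,
                end=start0 + glen,
                strand="+" if rng.random() < 0.5 else "-",
                function_label=_FUNCTION_POOL[int(rng.integers(0, len(_FUNCTION_POOL)))],
                best_hit_taxon_class=model.taxon_class,
                best_hit_taxon_genus=model.taxon_genus,
            )
        )
    marker_idx = rng.choice(n_genes, size=len(model.marker_set), replace=False)
    for m, idx in zip(sorted(model.marker_set), marker_idx):
        genes[int(idx)].is_marker = m
        genes[int(idx)].function_label = m
    return sequence, genes


def fragment_genome(
    sequence: str,
    *,
    median_length: float,
    sigma: float,
    min_length: int = 2500,
    genome_abundance: float = 1.0,
    depth_sigma: float = 0.0,
    seed=0,
    genome_id: str = "genome",
) -> list[Contig]:
    """Cut a genome into non-overlapping contigs with lognormal lengths.

    Fragment lengths are ``median_length * exp(sigma * N(0,1))`` rounded to
    integers; fragments shorter than ``min_length`` (including a short
    terminal remainder) are discarded, so emitted contigs cover at most
    100% of the genome.  Each contig's depth is
    ``genome_abundance * exp(depth_sigma * N(0,1))``.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    pos = 0
    i = 0
    n = len(sequence)
    while pos < n:
        flen = int(round(median_length * float(np.exp(sigma * rng.normal())))) if sigma > 0 else int(
            round(median_length)
        )
        flen = max(flen, 1)
        take = min(flen, n - pos)
        if take >= min_length:
            depth = genome_abundance * float(np.exp(depth_sigma * rng.normal())) if depth_sigma > 0 else genome_abundance
            contigs.append(
                Contig(
                    contig_id=f"{genome_id}|c{i:05d}",
                    sequence=sequence[pos : pos + take],
                    depth=depth,
                    genome_id=genome_id,
                    genome_start=pos,
                )
            )
            i += 1
        pos += flen
    if not contigs:
        warnings.warn(
            f"{genome_id}: no fragment reached min_length={min_length}; empty contig list",
            stacklevel=2,
        )
    return contigs


def _project_genes(genes: list[GeneCall], contigs: list[Contig], min_partial: int = 300) -> list[GeneCall]:
    """Re-coordinate genome-level gene calls onto contigs.

    Genes cut by a fragment boundary are kept as truncated records (id
    suffixed ``_p``) when at least ``min_partial`` bp — or the whole gene,
    if shorter — lands on the contig: real annotation pipelines call and
    annotate partial genes at contig edges, and those genes vote in
    taxonomic curation like any other.
    """
    spans = [(c.genome_start, c.genome_start + len(c.sequence), c.contig_id) for c in contigs]
    out = []
    si = 0
    # genes tile without overlap, so starts and ends are both monotone
    for g in sorted(genes, key=lambda g: g.start):
        while si < len(spans) and spans[si][1] < g.start:
            si += 1
        j = si
        while j < len(spans) and spans[j][0] < g.end:
            s0, e0, cid = spans[j]
            lo = max(g.start, s0 + 1)
            hi = min(g.end, e0)
            if hi - lo + 1 >= min(min_partial, g.length):
                truncated = lo != g.start or hi != g.end
                out.append(
                    replace(
                        g,
                        contig_id=cid,
                        start=lo - s0,
                        end=hi - s0,
                        gene_id=g.gene_id + ("_p" if truncated else ""),
                    )
                )
            j += 1
    return out


def apply_mislabels(gene_calls, taxa, rate: float, rng: np.random.Generator) -> list[GeneCall]:
    """Corrupt best-hit taxon labels at the given rate.

    ``taxa`` is the pool of (class, genus) pairs; a corrupted gene receives
    a uniformly-drawn pair different from its own, so the expected fraction
    of wrong labels equals ``rate`` exactly.
    """
    if not (0 <= rate < 1):
        raise ValueError("mislabel rate must be in [0, 1)")
    taxa = list(taxa)
    out = []
    for g in gene_calls:
        if rate > 0 and rng.random() < rate:
            others = [t for t in taxa if t != (g.best_hit_taxon_class, g.best_hit_taxon_genus)]
            if others:
                cls, gen = others[int(rng.integers(0, len(others)))]
                g = replace(g, best_hit_taxon_class=cls, best_hit_taxon_genus=gen)
        out.append(g)
    return out


def simulate_community(
    models,
    seed: int,
    *,
    fragment_median: float = 4000,
    fragment_sigma: float = 0.5,
    min_length: int = 2500,
    depth_sigma: float = 0.3,
    mislabel_rate: float = 0.1,
    total_reads: int = 5_000_000,
) -> CommunitySample:
    """Simulate a whole community: genomes → contigs → labelled gene calls."""
    models = list(models)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(models) + 1)
    rng_global = np.random.default_rng(children[-1])
    taxa = [(m.taxon_class, m.taxon_genus) for m in models]

    contigs: list[Contig] = []
    gene_calls: list[GeneCall] = []
    for model, child in zip(models, children):
        g_seed, f_seed = child.spawn(2)
        sequence, genes = simulate_genome(model, g_seed)
        frags = fragment_genome(
            sequence,
            median_length=fragment_median,
            sigma=fragment_sigma,
            min_length=min_length,
            genome_abundance=model.abundance,
            depth_sigma=depth_sigma,
            seed=f_seed,
            genome_id=model.genome_id,
        )
        contigs.extend(frags)
        gene_calls.extend(_project_genes(genes, frags))

    gene_calls = apply_mislabels(gene_calls, taxa, mislabel_rate, rng_global)
    truth = {c.contig_id: c.genome_id for c in contigs}
    return CommunitySample(
        contigs=contigs,
        gene_calls=gene_calls,
        truth=truth,
        total_reads=total_reads,
        seed=seed,
        models=models,
    )


def simulate_hit_table(
    gene_calls,
    mislabel_rate: float,
    seed,
    *,
    taxa=None,
    evalue_gen=None,
    bit_gen=None,
    coverage_gen=None,
) -> list[HitRecord]:
    """Emulate a best-hit homology-search table for the given gene calls.

    The subject taxon equals the gene call's taxon except at
    ``mislabel_rate``, where a different pair from ``taxa`` (default: the
    pairs observed in the input) is substituted.  E-value, bit score and
    query coverage come from the given generators — callables
    ``f(rng, n) -> array`` — defaulting to log-uniform e-values in
    [1e-40, 1e-5], uniform bit scores in [110, 500) and uniform coverage
    in [0.72, 1).
    """
    if not (0 <= mislabel_rate < 1):
        raise ValueError("mislabel_rate must be in [0, 1)")
    gene_calls = list(gene_calls)
    rng = np.random.default_rng(seed)
    n = len(gene_calls)
    if n == 0:
        return []
    if taxa is None:
        taxa = sorted({(g.best_hit_taxon_class, g.best_hit_taxon_genus) for g in gene_calls})
    evalues = evalue_gen(rng, n) if evalue_gen else 10.0 ** (-rng.uniform(5, 40, size=n))
    bits = bit_gen(rng, n) if bit_gen else rng.uniform(110, 500, size=n)
    covs = coverage_gen(rng, n) if coverage_gen else rng.uniform(0.72, 1.0, size=n)
    flips = rng.random(n) < mislabel_rate

    records = []
    for i, g in enumerate(gene_calls):
        cls, gen = g.best_hit_taxon_class, g.best_hit_taxon_genus
        if flips[i]:
            others = [t for t in taxa if t != (cls, gen)]
            if others:
                cls, gen = others[int(rng.integers(0, len(others)))]
        records.append(
            HitRecord(
                query_id=g.gene_id,
                gene_family=g.function_label,
                subject_taxon_class=cls,
                subject_taxon_genus=gen,
                evalue=float(evalues[i]),
                bit_score=float(bits[i]),
                query_coverage=float(covs[i]),
                gene_length=g.length,
            )
        )
    return records


def ground_truth(sample: CommunitySample) -> dict[str, str]:
    """Total contig → genome map used for adjusted-Rand scoring of bins."""
    truth = dict(sample.truth)
    ids = [c.contig_id for c in sample.contigs]
    if sorted(truth) != sorted(ids):
        raise ValueError("sample.truth does not cover its contigs exactly")
    return truth


def default_models() -> list[GenomeModel]:
    """The default five-genome community.

    Three Epsilonproteobacteria genera plus Gamma- and Alphaproteobacteria
    stand-ins, with GC targets spanning the realistic 28–66% range and
    distinct abundances so the coverage-curation band is exercised.
    """
    spec = [
        ("arcobacter_like", "Epsilonproteobacteria", "Arcobacter", 0.28, 60.0),
        ("sulfurovum_like", "Epsilonproteobacteria", "Sulfurovum", 0.36, 35.0),
        ("sulfuricurvum_like", "Epsilonproteobacteria", "Sulfuricurvum", 0.46, 20.0),
        ("thiothrix_like", "Gammaproteobacteria", "Thiothrix", 0.56, 12.0),
        ("rhodobacter_like", "Alphaproteobacteria", "Rhodobacter", 0.66, 8.0),
    ]
    return [
        GenomeModel(
            genome_id=gid,
            taxon_class=cls,
            taxon_genus=gen,
            gc_target=gc,
            genome_length=450_000,
            abundance=ab,
        )
        for gid, cls, gen, gc, ab in spec
    ]


def default_community(seed: int = 42) -> CommunitySample:
    """The default fixture: 5 genomes, ~400 contigs ≥ 2.5 kb, 10% mislabels."""
    return simulate_community(default_models(), seed=seed)
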
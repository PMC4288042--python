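# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Synthetic communities

Each genome is an order-*k* Markov chain over ACGT (default *k* = 2, so
emission depends on the two preceding bases).  The base emission
distribution puts probability `gc_target/2` on each of G and C; every
context row then receives an iid Gaussian perturbation of scale
`composition_seedling` (default 0.2) on the log-probabilities and is
re-tilted so that P(G)+P(C) equals `gc_target` *exactly in every
context*.  The re-tilt matters: it decouples the two knobs, so
`composition_seedling` shapes the genome's tetranucleotide signature
without biasing realized GC, and realized GC converges to the target at
the binomial rate (≈ ±0.0005 SD at 1 Mb).

Genes are abstract non-overlapping intervals laid down at `gene_density`
(default 1 per kb, the bacterial norm) with lengths ~0.75 of the local
slot; each of the 19 single-copy markers is placed on a distinct gene
exactly once per genome.  Downstream rules consume only coordinates,
labels and scores, so no ORF translation is simulated.

Fragmentation cuts the genome into consecutive pieces with lognormal
lengths (default median 4 kb, σ = 0.5, floor 2.5 kb — matching the
window-profile floor, so every emitted contig is profileable); pieces
below the floor are discarded, which is why a genome's markers are not
all recoverable even from perfect bins.  Genes cut by a fragment
boundary survive as truncated records on both sides when at least 300 bp
lands on a contig, mirroring the partial gene calls real annotation
pipelines emit at contig edges; those partial genes vote in curation
like any other.  Contig depth is `abundance × exp(σ_d·N(0,1))` with
σ_d = 0.3, a typical within-genome depth dispersion.

The default community has five genomes of 450 kb: three
Epsilonproteobacteria (*Arcobacter*-, *Sulfurovum*- and
*Sulfuricurvum*-like at GC 0.28/0.36/0.46) plus Gamma- and
Alphaproteobacteria stand-ins (0.56, 0.66), abundances 60/35/20/12/8,
gene-level taxon mislabeling rate 0.1, seed 42 — roughly 400 contigs
≥ 2.5 kb.  Real genomes are 5–10× larger; 450 kb keeps the suite fast
while leaving several hundred windows per map.  Not emulated: sequencing
error, strain microheterogeneity, repeats and mobile elements, chimeric
contigs, and compositional convergence between unrelated genomes.  A
green binning test therefore establishes that the method recovers
genomes whose 4-mer signatures are genuinely distinct — the assumption
of compositional binning — not that it would resolve closely related
strains.

All randomness descends from one integer seed through
`numpy.random.SeedSequence.spawn`, so identical seeds give bit-identical
communities and the per-genome streams are independent of how many
genomes precede them.

## Tetranucleotide profiles

Contigs shorter than 2.5 kb are excluded (profile noise grows quickly
below that); longer contigs are cut into 5 kb windows, a terminal
remainder ≥ 2.5 kb standing alone and a shorter one merging into the
previous window, so no sequence above the floor is wasted.  Any 4-mer
window containing a non-ACGT base is skipped rather than imputed.
Reverse complements are collapsed to the lexicographically smaller
4-mer (136 features) because assembled contig strand is arbitrary; the
feature is the plain relative frequency (rows sum to 1), with per-column
z-scoring available behind a flag but off by default.

## Emergent SOM and bin extraction

The map is toroidal (no edge effects), sized at ~2 nodes per sample in a
golden-ratio rectangle with a 10×16 floor.  The emergent regime — more
nodes than samples — is essential: clusters settle as islands separated
by wide interpolation zones whose high U-values form the ridges the
segmentation relies on.  (A map sized well below the sample count, e.g.
~5√n nodes, was tried first and leaves no room for ridges: on the
default fixture segmentation collapsed to a single bin.)

Training is the classical online rule: 20 epochs, per-epoch seeded
shuffle of presentation order, BMU by Euclidean distance (ties to the
lexicographically smallest node), Gaussian neighborhood on the torus,
radius decaying exponentially from half the smaller grid dimension to 1
and learning rate from 0.5 to 0.05.  Weights are initialized on the
plane of the two leading principal components (deterministic; component
signs fixed by convention).  Mean quantization error is recorded at
initialization and each epoch; it ends below its starting value, but
transiently *rises* during the early ordering phase — the large radius
contracts the codebook toward the data mean — so monotonicity should
only be expected (and is only asserted) over the convergence half of
training.

Bin extraction replaces interactive map segmentation with a
deterministic rule: nodes whose U-value (mean distance to 8 toroidal
neighbors) exceeds the 0.6 quantile are removed; connected components
(8-connectivity, toroidal, union-find) of the remaining nodes become
bins; windows inherit their BMU's component (None on a ridge); contigs
take the strict-majority bin of their assigned windows, ties left
unassigned.  At quantile 1.0 nothing is removed and the torus yields a
single bin, the documented degenerate case.  On the default fixture the
result is insensitive to the quantile across 0.5–0.7.

## Curation

The majority vote is strict (> 0.5): a contig with exactly half its
genes matching the target taxon is dropped, and gene-less contigs are
dropped with a separate `no_genes` flag rather than silently retained.
GC/coverage curation keeps contigs within ±5 GC percentage points and a
3× multiplicative depth band of the incoming-bin medians — generous
bands that still remove gross contaminants (the benchmark plants ΔGC
0.15, 4× depth); bins under 3 contigs skip the filter with a warning
since medians would be meaningless.  N50 is the length of the shortest
contig in the minimal descending prefix reaching half the assembly.
Completeness is 100 × |distinct markers| / |marker set|; duplicates are
counted but never raise it.  Reassembly selection ranks candidates on
longest contig (desc), N50 (desc) and scaffold count (asc) and takes the
smallest rank sum, ties to the higher N50 then input order.

## Hit filtering and abundance

Two threshold profiles are kept exactly as used in practice, not
unified: class-level taxonomy requires e-value < 1e−4 (strict) and query
coverage ≥ 0.75 (inclusive); functional-gene identification requires
e-value ≤ 1e−4, coverage > 0.70 and bit score > 100 (both strict).  The
boundary conventions are load-bearing and tested.  "Best hit" means the
top record per query by bit score, ties by lower e-value, then input
order.  Abundance is normalized as raw_count / ((gene_length/1000) ×
(total_reads/10⁶)); within a (family, taxon) group each hit contributes
its own length normalization, so genes of different lengths are
comparable.  The 16S floor removes entries with estimated relative
abundance strictly below 10⁻⁴ and does not renormalize by default (the
workflow removes, then analyzes); renormalization sits behind a flag.

## Energetics

ΔG° = Σ νᵢΔGf°(i) over signed stoichiometric coefficients; ΔG°′ adds
ν_H⁺·(−RT ln 10·pH), i.e. −39.96 kJ per mol of product proton at pH 7,
298.15 K.  Only the proton is moved off unit activity; temperature is
fixed at 298.15 K (no van 't Hoff extrapolation to warmer sites), and no
activity-coefficient or H2S/HS⁻ speciation corrections are applied.

The default formation-energy table (kJ/mol, aqueous standard state):
H2S −27.9, SO4²⁻ −744.6, NO3⁻ −111.3, NO2⁻ −37.2, NH4⁺ −79.4, H2O
−237.2, and 0 for the elements' reference forms (O2, N2, S0, H2) and
H⁺.  It is a conventional literature compilation, carried as a swappable
input with provenance, and reproduces the well-determined published
reaction values within 1–2%; the ammonium pairings deviate ~3% under
this (or any single standard) table, so they are treated as
qualitative-ordering results only.

Three of the eight typeset reactions are not element/charge balanced as
printed.  Rebalancing solves the exact element+charge linear system over
the reaction's species plus {H2O, H⁺} as free species with the sulfide
coefficient pinned at 1, using rational arithmetic (sympy); an
underdetermined system takes the minimal-norm solution via the rational
pseudoinverse, an inconsistent one is rejected with a rank report.  The
aerobic-incomplete reaction as typeset produces H2 with no oxygen sink;
its repair is the conventional `H2S + ½O2 → S0 + H2O` (the spurious H2
dropped) rather than a min-norm solve over a species set containing H2,
which would yield a chemically meaningless H2/H2O mixture.

## Pipeline

One config object (YAML-loadable, unknown keys rejected) drives all
stages; every tabular output carries the tool version, seed and a
parameter digest in `#` header lines, and the run summary ends with a
digest over its content so bit-identical reruns are checkable at a
glance.  Each bin's curation target taxon is its own modal gene class —
automated stand-in for the expert choosing which taxon a bin represents.

## Known limitations

* Compositional binning needs composition-distinct genomes; the
  generator guarantees this by construction, real communities may not.
* Completeness is pure marker-set membership; no lineage-specific marker
  sets or contamination statistics beyond the duplicate count.
* The SOM is online and single-threaded; maps beyond ~10⁴ samples ×
  ~2·10⁴ nodes will be slow.
* Reaction energetics are standard-state except for pH; in-situ
  concentrations would shift all values.
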
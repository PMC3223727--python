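# Methods

`orfpipe` implements a genome-scale annotation-and-verification procedure
for predicted open reading frames (ORFs): enzyme (EC) function transfer,
subcellular localization prediction, structural verification from
sequencing reads, and Gateway primer design, exercised end to end on
synthetic data with known ground truth. This note records the models,
the defaults and why, the numerical choices, and what the synthetic data
does and does not show.

## Local alignment primitive

All sequence comparisons go through one affine-gap Smith–Waterman
primitive (Biopython's `PairwiseAligner` in local mode).

* **Protein scoring**: BLOSUM62, gap open −11 / extend −1 (the BLASTP
  defaults; the gap-open score applies to the first gapped column and
  the extend score to each subsequent one, so a gap of length L costs
  `11 + (L−1)`). **Nucleotide**: match +1 / mismatch −2 / gap −5/−2,
  with N scoring as a mismatch against everything.
* **Percent identity** is identities over alignment columns, gap columns
  included (as BLAST reports); an identities-over-shorter-sequence
  alternative is available for clustering (`pident_mode="shorter"`).
* **E-values** use the Karlin–Altschul form `K·m·n·exp(−λS)` with the
  full sequence lengths and, for proteins, the published BLAST gapped
  BLOSUM62/11/1 parameters λ = 0.267, K = 0.041. Absolute E-values are
  approximate (no edge or length corrections); only the 1e-3 threshold
  matters to the pipeline, and the decoy negative controls confirm it
  behaves as intended.
* Among co-optimal alignments the engine's first traceback is reported;
  this is deterministic for fixed inputs. Scores are checked in the test
  suite against an exhaustive enumeration of all local alignments of
  short random pairs.
* Coordinates are 0-based half-open everywhere; the BLAST-outfmt-6
  export alone is 1-based inclusive, for ecosystem compatibility.

## EC annotation

Step 1: **reciprocal best hits** between the ORF proteome and an
EC-labelled enzyme database at E-value ≤ 1e-3 (the threshold is applied
in both directions; score ties break to the lexicographically smallest
partner id). The matched entry's full EC set transfers to the ORF.
Entries carrying a free-text enzyme name without an EC (pathway-database style)
transfer the name and are counted separately from formal EC numbers.

Step 2: **single-linkage paralog clustering** of the entire proteome. An
edge joins two proteins when their local alignment reaches ≥ 35%
identity and covers ≥ 70% of *both* sequences (the coverage-on-both
reading of a per-pair length cutoff; a shorter-sequence-only mode is
available). Clusters are connected components, so two proteins below
the threshold can share a cluster through an above-threshold
intermediate. Unannotated members of a cluster containing directly
annotated proteins inherit the union of the cluster's direct EC sets;
clusters whose direct members disagree are flagged ambiguous in the
report rather than suppressed, preserving information for curation.

## Subcellular localization

A k-nearest-neighbor classifier over ten compartments (chloroplast,
cytosol, cytoskeleton, ER, extracellular, mitochondrion, nucleus,
peroxisome, plasma membrane, vacuolar membrane). Features are the 20
amino-acid frequencies plus `0.1·log10(length)`; the down-weighting
keeps composition, not protein size, in charge of the Euclidean metric.
This composition feature set is a deliberately simple stand-in for the
richer sorting-signal features of production predictors — the module's
contract is the neighbor-count probability arithmetic and the
consolidation logic, not any particular feature engineering.

With k = 32 (default), the tally N(cᵢ) of neighbor labels converts to
probabilities P(cᵢ) = N(cᵢ)/k. Distance ties at the k-th neighbor break
by reference id, making predictions order-independent. An
inverse-distance weighting variant renormalizes weights to sum to k so
the probability model is unchanged in form; the default is uniform.

Downstream rules: a protein is binned to a single compartment only when
P > 0.5 strictly (otherwise "other": multiple or ambiguous
compartments). Predictions are made twice, against plant-lineage and
animal-lineage reference sets, and consolidated with an 0.85 cutoff on
the top probability: both qualify → higher value wins, ties to plant
(the phylogenetically closer lineage for a green alga); one qualifies →
that lineage; neither → other. The 0.85 is applied to P(cᵢ) itself
(the alternative "ratio relative to other compartments" reading would
be more permissive; the stricter reading was chosen and is configurable
via the cutoff).

The estimator (`CompartmentKNN`) follows scikit-learn conventions
(`fit`/`predict`/`predict_proba`, `get_params`, trailing-underscore
fitted attributes) and composes with sklearn tooling.

## Verification from shotgun-style reads

Raw reads are contaminant-trimmed (local-alignment matches to vector or
adapter sequences at ≥ 90% identity over ≥ 10 nt within 5 nt of a read
end are clipped, iterating to a fixpoint so stacked vector+tail
prefixes disappear), then reads shorter than 20 nt are dropped. Mapping
uses edlib semi-global (infix) alignment of the whole read inside each
reference, both strands, keeping hits with ≥ 40 nt read span and ≥ 90%
identity over alignment columns; a read may map to several paralogous
references (a best-only mode exists). Per-base depth over each
reference gives percent coverage; a reference is **verified** when
strictly more than 98% of its bases are covered (98.0% exactly is not
verified), and references are binned at [95,100], [50,95), [20,50),
[0,20) percent, the lowest bin being called unsupported.

Coverage is computed from read mappings directly rather than from
assembled contigs; for reads that tile a reference the two notions
coincide at the > 98% criterion, and no de novo assembly is attempted.

## OST (end-read) verification

Each clone contributes a forward and a reverse Sanger-style read. After
vector clipping, the reverse read is reverse-complemented and merged
with the forward read when the longest suffix/prefix overlap of ≥ 20 nt
reaches ≥ 95% identity (position-wise comparison; disagreements take
the forward base; no-quality data makes a fancier consensus moot). The
merge is substitution-tolerant only — consistent with the read
simulator's default of substitution-only errors — so indel-bearing
overlaps would fall back to singlets. The 5' end of an ORF model is
confirmed when the forward read or the contig aligns across reference
base 0 at ≥ 95% identity; the 3' end analogously at the last base. A
full-length contig must exist, confirm both ends, and align over ≥ 98%
of the reference at ≥ 98% identity.

## Primer design

Forward primers anchor at the A of ATG, reverse primers at the codon
immediately before the stop, so the amplicon is the CDS minus its stop
codon. The gene-specific part grows from 18 to 30 nt until its Tm
enters [55, 65] °C (shortest qualifying length wins; Tm by the
SantaLucia nearest-neighbor model at 50 mM Na⁺ / 500 nM primer, Wallace
rule as a fallback). CDSs whose candidates never enter the window —
common at high G+C, where even the 18-mer overshoots 65 °C — are
reported as design failures rather than silently relaxed. The shipped
B1.1/B2.1 tails are the standard 12-nt partial attB adapters
(`AAAAAGCAGGCT` / `AGAAAGCTGGGT`); they are configuration values, not
ground truth — confirm them against your cloning system.

## Synthetic data: what it emulates and what it does not

The generator is first-class, tested code; its defaults are the study
conditions under which the pipeline's guarantees are stated.

* **Enzyme families**: 20 ancestor proteins of 150–600 residues (36 in
  the 200-ORF end-to-end configuration), each with a distinct synthetic
  EC; 5 members per family derived by point substitutions targeting 80%
  identity (substitution-only keeps the identity target analytic —
  expected realized identity equals the target); 20 random decoys.
* **Compartments**: per-compartment residue compositions mix uniform
  with a Dirichlet(0.5) draw at bias 0.9; plant and animal lineages get
  independently perturbed copies (10% remix); 50 references per
  compartment and lineage, 10 held-out queries per compartment drawn
  from the unperturbed composition.
* **CDSs**: codons are sampled per residue with probability ∝
  exp(β·GC), β calibrated per protein so the expected G+C matches the
  0.64 target (clamped to what the genetic code permits for that
  composition — with uniform amino-acid usage the ceiling is ≈ 0.63,
  so realized G+C sits within a point or two of the target).
* **Reads**: per-ORF read counts are Gamma–Poisson (shape 2, mean 25)
  with a 2% zero-read fraction, giving the heavy low-coverage tail that
  low-expression transcripts produce; read lengths ~ N(350, 60²)
  truncated at 40 nt; 1% substitution errors, indels off by default;
  30% of reads anchor at an amplicon end, as fragmentation of a
  PCR amplicon necessarily produces terminal fragments.
* **End reads**: 700 nt, prefixed with a fixed synthetic vector stub
  plus the attB tail; 10% of clones are truncated by 10–30% at a random
  end to create genuine end-verification failures. End reads default to
  error-free (post-QC Sanger reads are near-perfect at the ends used
  here); an error rate is configurable.

Determinism: one global seed expands into fixed per-stage child seeds
(`numpy` `SeedSequence` spawn keys), so identical config and seed give
byte-identical files, and stages can be regenerated independently.

What passing on this data does **not** show: performance on real
proteomes (real paralog families have indels, domain shuffling and
unequal rates; real compartment signals are sorting peptides, not bulk
composition; 454 homopolymer errors and splice structure are not
modelled). The synthetic results validate the *calculus* of each stage
— thresholds, probability arithmetic, coverage accounting — not
biological accuracy of any particular prediction.

## Problem sizes and numerical choices

The shipped test and acceptance configurations use a 200-ORF proteome,
500 reference proteins per lineage, ~5,000 reads and 200 clones —
sizes chosen so a full run completes in about two minutes on a single
core while every stage still operates far from trivial edge cases.
Degenerate inputs are defined rather than left to chance: empty
alignments report zero identity over zero columns; an all-X protein is
rejected for composition features; coverage of an unmapped reference is
0%; primer design on a malformed CDS raises naming the ORF. Tie-breaks
(alignment traceback, best-hit subject id, k-th neighbor id,
consolidation to plant) are all deterministic and documented above.

## Known limitations

* Exhaustive all-vs-all alignment scales quadratically; the pipeline is
  a desk-scale reference implementation, not a heuristic search engine.
* The Karlin–Altschul parameters are fixed per scheme, not derived from
  the matrix; absolute E-values should not be compared across schemes.
* `consolidate` trusts its two inputs to describe the same protein and
  the caller to have used the same k in both lineages.
* The end-read merger does not handle indel disagreements in the
  overlap; with indel-bearing data, prefer the shotgun route.
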
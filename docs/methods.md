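# Methods

This note documents the models and procedures implemented in `bapstools`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic benchmarks can and cannot show.

## Phage-likeness classification

### Representation

Contigs are represented as ordered gene lists. The bundled gene caller is
a deliberately simple six-frame ORF scanner: in each frame an ORF runs
from the first start codon (ATG/GTG/TTG) after the previous in-frame stop
to the next stop (stop included), minimum 90 nt; codons containing
ambiguous bases break an open ORF without emitting a gene; no partial
genes at contig edges. The scanner is deterministic and dependency-free
and over-calls relative to a trained gene finder (spurious short ORFs in
alternate frames). That is acceptable here because the classifier consumes
compositional statistics, which the spurious ORFs share with their genome
of origin, and because any Prodigal-compatible caller can be plugged in
behind the same contract (`call_genes(contig, caller=...)`). Coordinates
are 0-based half-open on the forward strand with strand stored separately
(BED convention); translation uses the bacterial code with GTG/TTG
initiators rendered as M.

Each gene maps to 93 features (schema version 1, hashed into every model
file): gene length; GC; GC skew; 64 codon frequencies; 20 amino-acid
frequencies; hydrophobic fraction (A,V,L,I,M,F,W,P); strand agreement
with the previous/next gene; intergenic distances clipped at 5,000 bp;
and local gene density per 10 kb in a ±5 kb window. First/last genes take
sentinel 0 for neighbour features so vectors stay fixed-length. Three
consecutive gene vectors concatenate into one triplet row (279 values);
a contig with *g* genes yields max(0, *g* − 2) rows. The triplet is the
training and scoring unit: it sees local gene organization while being
insensitive to contig length.

### Training

Positives are phage genomes; negatives are bacterial fragments whose
lengths are resampled from the positive set's empirical length
distribution (uniform start positions), so the model cannot learn length
as a shortcut. Prophage regions discovered by an external tool can be
excised from negative source genomes first (`mask_regions`, interval
union semantics with a new→old coordinate map).

The classifier is a LightGBM binary model. Defaults, recorded in the
model file: 500 trees, learning rate 0.05, depth ≤ 8 (63 leaves), binary
log-loss, early stopping (50 rounds) on a seeded 10% row split, negatives
downsampled (seeded) to at most 3× the positives. Training and scoring
are single-threaded with LightGBM's deterministic mode, so a fixed seed
gives byte-identical model files across runs; multi-threading would be
faster but is not reproducible bit-for-bit and is therefore not the
default. Models serialize to a single JSON file carrying the booster, the
feature-schema hash, seed and hyperparameters; scoring refuses a model
whose schema hash does not match the running code.

A contig's score is the arithmetic mean of its triplet probabilities —
the simplest order-independent aggregate, monotone in every triplet
probability. Contigs with fewer than three called genes cannot form a
triplet; they score 0 with an explicit `too_few_genes` flag rather than
being dropped silently.

## The classification cascade

Rules fire in a fixed order; every contig gets exactly one label and the
name of the stage that decided it.

1. **Length gate.** > 1,000,000 bp ⇒ bacterial (strict); < 5,000 bp ⇒
   non-candidate; both window endpoints are candidates. A complete phage
   genome is expected inside this window.
2. **Score gate.** Scores strictly below 0.8 are excluded.
3. **Reference hits** (hit tables are inputs, sorted best-first by the
   upstream search): top nucleotide-reference hit with subject > 1.2 Mb
   and alignment > 2,100 bp ⇒ bacterial; any description containing
   "plasmid" ⇒ plasmid; any phage-database hit, or description containing
   "phage" but not "prophage", is phage evidence. Keyword matching is
   case-insensitive substring; "prophage" is tested first so it always
   suppresses. Precedence bacterial > plasmid > phage. Hits to subjects
   between 1.0 and 1.2 Mb fall through to later rules.
4. **Lifestyle.** Integrase on the contig — or anywhere in its cluster —
   ⇒ temperate; *terL* with no integrase/transposase/anti-repressor and a
   clean cluster ⇒ lytic; otherwise phage-like-undetermined. The
   cluster-wide integrase rule is deliberately conservative: one temperate
   member relabels the entire cloud, so no lytic call can sit in a
   lysogeny-capable cluster.

Marker screening is pluggable: either a precomputed hit table (e.g. from
an HMM search) or the built-in screen, which flags a gene as a marker
when ≥ 50% of the marker protein's 5-mer amino-acid set is contained in
the gene's 5-mer set. Containment (marker k-mers within the gene) rather
than Jaccard makes the screen robust to the ORF scanner extending a gene
upstream of its true start. Marker classes beyond the canonical four are
treated as additional lysogeny markers and behave like integrase
(exclusionary), matching the conservative intent of the lifestyle rule.

## Sketch distances

Sketches are bottom-s MinHash: the s smallest SplitMix64 hashes (fixed
internal seed, so sketches are portable across runs and machines) of the
distinct canonical k-mers (lexicographic min of k-mer and reverse
complement; windows containing N skipped). Defaults k = 21, s = 1000 —
standard genome-scale choices where 21-mers are effectively unique and
s = 1000 bounds the Jaccard standard error at roughly
√(j(1−j)/s) ≤ 0.016.

Jaccard is estimated on the merged bottom set: take the s smallest hashes
of the union of two sketches and count the fraction present in both. The
denominator is min(s, |merged set|) so that identical genomes estimate
exactly 1 even when they have fewer than s distinct k-mers. The Mash
transform d = −ln(2j/(1+j))/k converts to a distance; j = 0 is capped at
d = 1 (the transform diverges), and d is clamped to [0, 1]. Sketch-ANI is
1 − d.

Networks connect genomes at d ≤ threshold (0.1 for phage networks);
connected components are the phage clouds, labelled by their
lexicographically smallest member so component ids are independent of
input order. ANI clustering is single linkage — the direct graph analogue
of "connected when within threshold". Reference matching reports two
nested tiers, d ≤ 0.2 (closely associated) and d ≤ 0.05 (strongly
associated). The non-overlapping match-length summarizer filters
alignment intervals (≥ 90% identity, ≥ 500 bp) before taking the union of
half-open query intervals, so repeated matches of one region count once.

## Abundance ratios

Within a sample, reads and contig lengths are pooled per role (phage /
host) before normalization — host chromosomes are usually fragmented
across contigs, and per-contig ratios would be noise. The statistic is
RPKM-style: reads ×10⁶ / library size / (pooled length in kb). It is the
minimal statistic normalized for both contig length and library size, and
it makes ratio = 1 correspond to equal per-base coverage, i.e. one phage
genome per host genome — the natural temperate baseline. Read fractions
per role sum to 1. A sample with no detectable host raises a
`host_not_detected` error instead of returning infinity, which keeps
downstream log10 handling safe. Ratios are invariant to scaling all
counts, hence to sequencing depth.

## Synthetic data

The generator emulates exactly the signal the classifier is meant to
exploit, nothing more. Two composition models differ in:

* codon usage — a sense-codon table exponentially tilted to an expected
  GC, Dirichlet-perturbed (concentration 60) with a class-fixed seed, then
  re-tilted so expected GC is pinned to the class target; codon bias and
  GC are therefore independent knobs;
* GC — 0.42 (phage-like) vs 0.52 (host-like), typical of AT-rich phages
  against their higher-GC enterobacterial hosts;
* gene geometry — log-normal gene lengths (median 800 nt, σ = 0.35,
  clipped to 90–3,000 nt) with exponential intergenic gaps of mean 40 bp
  (phage-like) vs 160 bp (host-like), giving phage-like genomes the higher
  coding density real phages show.

Genomes are alternating gap/gene sequences of exactly the requested
length, with true gene coordinates stored in contig metadata. The default
corpus genome length is 20 kb — small-lytic-phage scale, and enough for
~20–25 genes per genome. A divergence parameter interpolates the two
models toward their midpoint to shrink class separation on demand.

Toy marker genes are deterministic random amino-acid sequences
back-translated into clean ORFs; they are synthetic stand-ins, not real
phage proteins, and exist only to exercise the marker/lifestyle
machinery. Marker implantation inserts a marker ORF at an intergenic
position (mid-gene positions are rejected) and updates the true
coordinates. Read counts are multinomial with probabilities proportional
to copy number × length; the default simulated library is 200,000 reads,
a realistic small isolate library.

The 12-contig fixture suite (seed 7) covers every cascade branch with
constructed evidence tables, including a "prophage" keyword trap, an
integrase cluster-propagation pair, and an ORF-free contig that cannot be
scored. All generation is byte-identical under a fixed seed.

**What passing these benchmarks shows — and does not.** The synthetic
classes are separable by construction; perfect held-out AUC here
demonstrates that the feature extraction, triplet windowing, training and
aggregation machinery recover a real compositional signal, not that the
classifier would achieve that accuracy on real assemblies, where phage
and host composition overlap far more. Likewise the generator has no
packaging signals, no real protein families, no repeats, and no assembly
artefacts; cascade correctness on the fixture shows the rules fire
exactly as specified on clean evidence, not that real hit tables are this
unambiguous.

## Numerical conventions and degenerate inputs

* Window boundaries: 5 kb and 1 Mb inclusive candidates; "exceeding 1 Mb"
  and "below 0.8" strict — literal readings, fixed so counts are
  reproducible.
* GC skew of a gene with no G or C is 0; codon/amino-acid frequencies of
  an empty translation are 0-vectors.
* Empty hit lists are `no_call`, not errors; contigs missing from the
  cluster map are singletons.
* `mask_regions` on the whole genome returns an empty contig with a
  warning (alphabet validation happens at FASTA ingest, not construction,
  precisely to allow this).
* Fragment requests longer than the source genome are clipped to the full
  genome and flagged.
* All stochastic components take explicit integer seeds (NumPy
  `default_rng`); nothing reads global random state.

## Problem sizes

Benchmarks run at desk scale on one CPU: classifier recovery trains on
200 + 200 genomes of 20 kb and evaluates 50 + 50 held out (~55,000
triplet rows, a few minutes); sketch accuracy uses 100 random pairs of
1–10 kb against brute-force exact Jaccard; ratio recovery uses 4 true
ratios × 200 replicates at 200,000 reads. The corpus-scale analyses the
method targets (millions of assemblies, real reference databases, read
mapping) are out of scope: hit tables, cluster maps and count tables are
inputs.

## Known limitations

* The ORF scanner has no translation-initiation model; gene starts are
  greedy. Feature values therefore differ from Prodigal-based extraction,
  and a model trained with one caller should be scored with the same
  caller (the schema hash does not capture the caller).
* The k-mer containment marker screen is a similarity floor, not a
  profile search; distant marker homologues require the hit-table route.
* Sketch-ANI approximates alignment ANI only for moderately diverged
  genomes; below ~80% identity the Jaccard signal saturates toward 0.
* The mean aggregation dilutes a short phage region inside a mostly
  bacterial contig; this is by design (the tool finds whole phage
  contigs, not prophage regions).
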
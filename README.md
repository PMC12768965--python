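# bapstools

Complete lytic phage genomes turn up, unexpectedly, inside public
bacterial genome assemblies: a clinical *Salmonella* isolate sequenced for
surveillance can carry an entire 240 kb jumbo-phage genome as one of its
contigs, without any integration into the chromosome. `bapstools` is a
desk-scale implementation of the discovery stack for these bacterial
assembly-associated phage sequences, for bioinformaticians who want to
screen assemblies for phage content, classify phage lifestyle, relate the
finds to reference phages, and quantify phage load from read counts.

## What it does

**Phage-likeness scoring.** Genes are called on each contig (bundled
six-frame ORF scanner; any Prodigal-compatible caller plugs in), each gene
is summarized by a 93-dimensional feature vector (length, GC, GC skew,
codon and amino-acid usage, hydrophobicity, strand agreement and
intergenic distance to neighbours, local gene density), and consecutive
genes are windowed into overlapping triplets (stride 1, so *g* genes give
*g* − 2 triplets). A gradient-boosted tree ensemble (LightGBM) classifies
triplets; the contig score is the mean triplet phage probability

> score(c) = (1/T) Σᵢ P(phage | tripletᵢ) ∈ [0, 1],

gated at 0.8. Negatives for training are bacterial genome fragments drawn
to match the phage length distribution, after prophage-region masking.

**Classification cascade.** Each candidate contig receives exactly one
label through ordered rules: size window (5 kb ≤ L ≤ 1 Mb; larger ⇒
bacterial, smaller ⇒ non-candidate) → score gate (< 0.8 excluded) →
reference hits (top hit to a > 1.2 Mb subject with > 2,100 bp alignment ⇒
bacterial; description containing "plasmid" ⇒ plasmid; "phage" but never
"prophage" ⇒ phage evidence) → lifestyle: a terminase large subunit
(*terL*) with no integrase, transposase or anti-repressor ⇒ **lytic**;
integrase anywhere in the contig's ANI cluster ⇒ **temperate**
(one integrase taints the whole cluster); otherwise undetermined.

**Sketch distances and networks.** Bottom-s MinHash sketches (k = 21,
s = 1000) over canonical k-mers give the Mash distance
d = −ln(2j/(1+j))/k ≈ 1 − ANI. Thresholded graphs (d ≤ 0.1) yield phage
networks and single-linkage ANI clusters ("phage clouds"); reference
phages are matched at two tiers (d ≤ 0.2 closely, d ≤ 0.05 strongly
associated). A sweep-line union summarizes non-overlapping alignment
lengths (≥ 90% identity, ≥ 500 bp floors).

**Abundance ratios.** Per-contig mapped-read counts are pooled per role
and normalized RPKM-style (reads ×10⁶ / library size / kb), so
phage:host ratio 1 means one phage genome per host genome — the temperate
baseline; ratios ≫ 1 indicate active replication.

**Synthetic ground truth.** A seeded generator produces phage-like vs
host-like genomes (distinct codon usage, GC 0.42 vs 0.52, gene density),
implants toy marker genes, simulates read counts at known copy ratios,
and builds a 12-contig fixture covering every cascade branch — so the
whole stack is tested without downloads.

## Worked example

```bash
python examples/classify_cascade.py
```

prints the decision table of the 12-contig fixture:

```
contig                   label                    stage        expected
c01_megabase             bacterial                length_gate  bacterial [ok]
c02_short                non_candidate            length_gate  non_candidate [ok]
c03_lowscore             non_candidate            phager_gate  non_candidate [ok]
c04_bacterial_hit        bacterial                hits         bacterial [ok]
c05_plasmid_kw           plasmid                  hits         plasmid [ok]
c06_prophage_trap        phage_like_undetermined  lifestyle    phage_like_undetermined [ok]
c07_lytic                lytic                    lifestyle    lytic [ok]
c08_temperate            temperate                lifestyle    temperate [ok]
c09_cluster_integrase    temperate                lifestyle    temperate [ok]
c10_cluster_clean        temperate                lifestyle    temperate [ok]
c11_transposase          phage_like_undetermined  lifestyle    phage_like_undetermined [ok]
c12_fewgenes             non_candidate            phager_gate  non_candidate [ok]

label counts: {'non_candidate': 3, 'bacterial': 2, 'plasmid': 1, 'temperate': 3,
               'lytic': 1, 'phage_like_undetermined': 2}
```

`c10_cluster_clean` carries only *terL* yet is temperate: its cluster-mate
`c09` has an integrase, and a single integrase taints the whole cloud.
The "prophage" description on `c06` never counts as phage evidence.

`python examples/train_and_score.py` trains a small classifier and scores
held-out contigs (phage-like ≈ 0.97–0.99, host-like ≈ 0.01–0.02, an
ORF-free contig gets score 0 with flag `too_few_genes`);
`python examples/phage_network.py` builds a Mash network where 5 mutated
copies (~2% divergence, d ≈ 0.04) cluster with their reference while
unrelated genomes stay at d ≈ 1; `python examples/abundance_ratios.py`
recovers copy ratios 0.1–100 from simulated counts to within a few
percent.

The same operations are available from the shell:

```bash
baps synth suite --seed 7 -o suite/
phager train --pos phage.fasta --neg bacteria.fasta --seed 1 -o model.json
phager score --model model.json contigs.fasta -o scores.tsv
baps classify --fasta suite/contigs.fasta --scores suite/scores.tsv \
    --hits suite/hits.tsv --clusters suite/clusters.tsv \
    --markers suite/markers.fasta -o out/
baps sketch contigs.fasta -o sk.json && baps network sk.json --threshold 0.1 -o net
```

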
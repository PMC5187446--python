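# vgerm — individualized germline V gene databases from expressed repertoires

Antibody repertoire analysis needs a reference database of germline V gene
segments, but validated databases exist for very few species — and even
within a species, individuals carry alleles the reference lacks.  `vgerm`
infers the set of germline V alleles an individual actually expresses
directly from an IgM repertoire sequencing library, starting from an
arbitrary V database: incomplete, deliberately mutated, from another
species, or a single sequence.

It is aimed at immunogenetics and antibody-repertoire (AIRR-seq)
researchers who need per-individual IGHV/IGKV/IGLV genotypes, e.g. before
measuring gene usage or somatic hypermutation (SHM) levels.

## Method

An IgM library mixes naive (near-germline) and SHM-mutated V(D)J
rearrangements, plus sequencing error.  `vgerm` iterates:

1. **assign** every dereplicated read to its closest database V allele
   (affine local alignment; match +1 / mismatch −2 / gap −5,−2), detect J
   and the CDR3 (the amino-acid span from the conserved second cysteine C
   to the J anchor W-G-x-G), and quality-filter
   (V & J assigned, no stop codon, E ≤ 10⁻³, V coverage ≥ 90 %, J ≥ 60 %);
2. **cluster** the reads of each allele — 2 %-wide windows of percent
   difference to the allele, and UPGMA (average linkage) on Levenshtein
   distances of a 1,000-read subsample with a tight-subtree heuristic
   (both children ≥ 5 leaves, height ratio < 0.8) — and call one 60 %
   majority consensus per cluster;
3. **filter** candidates by independent-rearrangement evidence over the full
   data set: a true germline sequence occurs exactly in many reads carrying
   *distinct* CDR3 junctions (≥ 10) and J genes (≥ 3) in a cluster of
   ≥ 100 sequences; near-duplicates (≤ 2 internal bases apart) collapse to
   the better-supported sequence; candidates identical to a starting-database
   sequence are whitelisted.  Early iterations use a relaxed pregermline
   filter (≥ 2 CDR3s, ≥ 2 J genes, no cluster size).

The surviving candidates replace the database and the loop repeats (3
iterations by default); a final assignment pass yields a usage profile and
per-allele upstream (5′UTR + leader) consensus sequences.  SHM hotspot and
clonal-expansion artefacts fail the CDR3-diversity criterion, which is what
gives the final database its specificity.

A bundled simulator (`vgerm.simulate`) generates family-structured germline
sets, V(D)J rearrangements with diverse junctions, naive/SHM read mixtures,
sequencing error and artefact reads — with a per-read truth ledger, so the
whole pipeline is testable without external data.

## Worked example

Simulate a library of 8 germline alleles, delete two expressed alleles
(`VH1.2`, `VH2.3`) from the starting database, and rediscover them in one
iteration:

```bash
vgerm simulate --out sim --n-alleles 8 --n-reads 6000 --seed 7
# sim/start_V.fasta = truth database minus VH1.2 and VH2.3
vgerm run --database sim/start_V.fasta --j-database sim/truth_J.fasta \
    --reads sim/reads.fastq.gz --out run --iterations 1 --seed 1
vgerm compare sim/truth_V.fasta run/final_V_germline.fasta
```

prints

```
final database: 8 alleles -> run
shared: 8
  VH1.1 == VH1.1
  VH1.2 == VH1.1_S0263
  ...
  VH2.3 == VH2.2_S8425
only in sim/truth_V.fasta: 0
only in run/final_V_germline.fasta: 0
```

Every allele of the truth set is in the output and nothing else is: the six
alleles still in the starting database were confirmed (whitelisted under
their own names), and the two deleted alleles were rediscovered as new
sequences named after their nearest database allele plus a stable hash
(`VH1.1_S0263` is sequence-identical to the deleted `VH1.2`).  `run/` also
contains the per-iteration candidate tables with their evidence counts, the
usage profile (reads and unique CDR3s per allele, e.g. `VH1.1  668  641`)
and the recovered upstream consensus per allele.

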
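# Methods

## Problem and model

An expressed antibody heavy-chain (or light-chain) repertoire is a mixture of
naive, near-germline V(D)J rearrangements and somatically hypermutated ones,
both overlaid with PCR/sequencing error.  Given amplicon reads of such a
repertoire (IgM-enriched to keep SHM low) and an arbitrary starting database
of germline V segments — possibly incomplete, mutated, or from another
species — `vgerm` infers the individual's expressed germline V allele set.

The method iterates four steps:

1. **Assignment.** Every dereplicated read is aligned to each database V
   allele (affine-gap local alignment with free end gaps, match +1, mismatch
   −2, gap open −5, gap extend −2) and assigned to the best-scoring allele.
   J segments are assigned 3′ of the V; the CDR3 is detected at the
   amino-acid level between the conserved second cysteine at the V end and
   the J anchor (W-G-x-G heavy, F-G-x-G light).  A quality gate keeps reads
   with both V and J assigned, no stop codon, E-value ≤ 10⁻³, V coverage
   ≥ 90% and J coverage ≥ 60%.
2. **Cluster discovery.** Per database allele, reads are (a) binned into
   half-open 2% windows of percent difference to the allele, one consensus
   per populated window, and (b) a random subsample (default 1,000) is
   clustered by UPGMA on pairwise Levenshtein distances; subtrees that are
   internally tight relative to their sibling (both children ≥ 5 leaves,
   smallest internal merge height of one child < 0.8 × the largest internal
   merge height of the other) yield additional consensi.  A consensus over
   all reads of the allele covers the case where only a single novel allele
   is expressed.
3. **Consensus.** Cluster members are multiple-aligned (star alignment
   around the highest-count member); per column the base reaching a 60%
   majority (inclusive) of non-gap votes is emitted, gap-majority columns
   are deleted, N otherwise.  Duplicate counts weight votes.
4. **Filtering.** Candidates containing N or an in-frame stop are discarded.
   The remaining candidates are annotated against the *full* data set: exact
   occurrences of the candidate as a read's V-region sequence, and the
   distinct CDR3 junctions and J genes among those occurrences — the
   signature of independent rearrangements.  Intermediate iterations apply
   the *pregermline* filter (≥ 2 unique CDR3s, ≥ 2 unique J genes); the last
   iteration applies the *germline* filter (cluster of ≥ 100 sequences,
   ≥ 10 unique CDR3s, ≥ 3 unique J genes).  Candidates within 2 internal
   bases of a better-supported candidate are collapsed (the one with fewer
   unique CDR3s is dropped; ties keep the longer sequence).  A candidate
   identical to a starting-database sequence is whitelisted past all
   criteria.  Survivors become the database of the next iteration.

Three iterations are run by default (fixed count, not convergence-tested; an
optional early stop on an unchanged database is off by default).  A final
assignment pass against the finished database produces a per-allele usage
profile and, per allele, the consensus of the upstream 5′UTR+leader sequence
(reads with V percent difference ≤ 1%, right-aligned at the V start, only
sequences at least as long as the tenth longest contribute).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `iterations` | 3 | discovery rounds; last round uses the germline filter |
| `subsample_size` | 1000 | linkage-analysis subsample per allele |
| `window_width_percent` | 2 | percent-difference bin width |
| `min_window_members` / `min_subtree_size` | 5 | minimum cluster support |
| `subcluster_ratio` | 0.8 | tightness ratio of the subtree heuristic |
| `consensus_majority` | 0.6 | per-column base majority (inclusive) |
| `min_cluster_size` | 100 | germline filter, unique sequences per cluster |
| `min_unique_cdr3` / `min_unique_j` | 10 / 3 | germline evidence thresholds |
| pregermline CDR3 / J | 2 / 2 | relaxed thresholds for early iterations |
| `max_near_duplicate_diff` | 2 | collapse radius between candidates |
| `max_evalue`, `min_v_coverage`, `min_j_coverage` | 1e-3, 0.90, 0.60 | quality gate |
| `terminal_extension` | 12 nt | see below |
| `max_v_error_rate` | 1% | upstream-consensus read gate (no published value; configurable) |

The evidence thresholds are calibrated for libraries of several hundred
thousand reads; ~400,000 input reads are recommended for a complete
repertoire (smaller libraries yield valid but possibly incomplete
databases — the driver warns below that size).

## Numerical and design choices

* **Aligner.** The external assignment tool used by comparable pipelines is
  replaced by an internal numba-compiled affine local aligner with free end
  gaps (the V may be truncated at either end, the read has free flanks).  An
  edit-distance prescreen (edlib) limits exact alignments to alleles within
  4 edits of the best edit distance; the winner is always scored exactly.
  The E-value is the Karlin–Altschul surrogate `m·n·2^(−bit)` with the
  ungapped λ=1.33, K=0.621 parameters of the +1/−2 scheme.
* **Terminal extension.** A substitution within the first or last bases of a
  V segment makes the optimal local alignment clip the reference end, which
  would silently truncate the read's V sequence and propagate truncated
  candidate alleles across iterations.  Clipped terminal reference segments
  of ≤ 12 nt are therefore re-included (mismatches counted as errors)
  whenever the read covers them.  For reads whose V is genuinely 3′-trimmed
  by recombination this can pair a few junction bases with the V end; the
  effect is bounded by the extension cap and absorbed by the window width.
* **Reading frame** is inherited from the database allele (position 1 =
  codon position 1, the convention of curated V databases); CDR3 detection
  re-anchors the frame at the last fully aligned codon inside the terminal
  cysteine window so upstream indels cannot shift it.  The conserved
  cysteine is the last Cys within 7 codons of the reference V end; the exact
  motif convention of published CDR3 regular expressions is not printed
  anywhere authoritative, so the motifs are configurable.
* **UPGMA** is computed with `scipy.cluster.hierarchy.linkage
  (method="average")`; merge heights are the arithmetic mean of
  inter-cluster distances and are monotone.  Tests verify the heights
  against a brute-force agglomeration oracle.
* **Subcluster heuristic.** "Smallest distance in one subtree / largest in
  the other" is read as cophenetic merge heights; leaves contribute 0.  All
  inner nodes are scanned and only *innermost* qualifying subtrees are
  reported: a qualifying node whose descendant also qualifies is a union of
  bundles, and reporting the descendant instead keeps clusters pure and
  leaf-disjoint.  Consensus over any pure fragment of an allele's read
  bundle reproduces the allele, so fragmentation is harmless.
* **Consensus alignment** is a star alignment around the highest-count
  member rather than a progressive MSA; cluster members are near-identical
  (a germline sequence ± a few substitutions), where the two coincide.
  The 60% majority is inclusive and dereplication counts weight votes.
* **Window bins** are half-open `[2k, 2k+2)`.  Cluster size counts unique
  sequences (post-dereplication), not raw read copies; the linkage step
  clusters unique sequences within the subsample.
* **Exact-occurrence matching** is strict string equality by default
  (configurable terminal tolerance); database comparison and near-duplicate
  collapse use terminal-tolerant equality (default tolerance 3 nt per end),
  mirroring the rule that small terminal length differences are not errors
  but the longer sequence is preferred.
* **Whitelisting** compares against the run's *initial* database (iteration
  0), not the previous iteration's output, so known alleles expressed at low
  levels survive every round.
* **Merging** resolves overlap disagreements by the higher quality score,
  forward base on ties or absent qualities; reads > 10% N after merging are
  dropped.  Overlap parameters (min 16 nt, ≤ 20% mismatches) are
  configurable and not claimed to reproduce any external merger.
* **Determinism.** The only randomness in discovery is the linkage
  subsample; its per-allele seeds are derived from the single run seed, so
  repeated runs are identical by construction.

## The simulator

`vgerm.simulate` generates the study conditions every test runs under:

* a family-structured germline V set (families diverge at ~18% of
  positions from a shared framework; members of a family differ by
  ~`allele_divergence` (default 10) substitutions and by at least 4, as real
  alleles do), 285–300 nt, in frame, stop-free, ending in the conserved
  Y-Y-C motif;
* J alleles with a 6 nt in-frame CDR3 tail, the W-G-x-G anchor and FR4;
* reads of the form 5′UTR/leader (randomly 5′-truncated; 30% full length) +
  V + random in-frame junction (12–33 nt, no stops, no tryptophan codons,
  so no premature J anchor) + 5′-truncated J;
* a naive/mutated mixture: `naive_fraction` (default 0.55) of reads carry
  zero SHM, the rest a geometric number (mean `shm_mean`, default 4) of
  substitutions at uniform V positions (optional AID-hotspot weighting of
  WRC/GYW motifs);
* independent per-base sequencing errors (default 0.3%, the effective rate
  of overlap-merged 2×300 reads on a ~1.2%-error platform);
* artefact injection: clonal expansions (one rearrangement, many copies,
  a single CDR3) and hotspot artefacts (a recurrent V substitution carried
  by ≤ 9 distinct junctions) — the false-positive classes the germline
  filter exists to remove.

Every read is logged in a truth ledger (source alleles, SHM and error
positions, planted junction), the exact oracle for all pipeline tests.

**What the simulator does not model:** SHM indels, clonal lineage structure
beyond single expansions, context-dependent error profiles, chimeric PCR
reads, D-segment usage, allele-specific expression skew (available via
`expression_weights` but uniform by default), or primer artefacts.  Passing
tests therefore demonstrate the method's logic under its stated assumptions,
not performance on any particular instrument's error process.

## Problem sizes used by the test suite and acceptance script

The study library is 20 alleles in 4 families with 12,000 reads (600 per
allele, the same per-allele evidence density as a 50,000-read run of the
same design), 55% naive, mean 4 SHM, 0.3% error.  The subsample size stays
at the default 1,000 — the 100-sequence germline cluster threshold is
calibrated against it and both are kept at their published defaults.  Under
these conditions the suite asserts: 7/7 deleted-allele recovery with zero
non-truth output (≥ 6/7 required), identical final databases across minimal
/ perturbed / full starting databases and across subsample seeds, ≤ 1 allele
difference under 50% IgG-like admixture, zero artefact sequences after
germline filtering, and exact agreement of the aligner, Levenshtein, UPGMA
and consensus kernels with brute-force oracles.

## Known limitations

* Alleles closer than 3 internal substitutions to a better-expressed allele
  are collapsed by design (the near-duplicate rule); true near-identical
  allele pairs below that radius are not separable by this method.
* Candidates are only proposed among reads assigned to an existing database
  allele; a germline allele with no database sequence within the quality
  gate's reach (V coverage ≥ 90% after alignment) in any iteration is
  invisible.  This is the same reach limitation the iterative design
  mitigates but does not eliminate.
* The germline filter's cluster-size criterion makes low-expression alleles
  (< ~100 distinct quality-passing sequences) undetectable unless
  whitelisted — intended behaviour, inherited from the filter definition.
* Light chains run the identical pipeline with the F-G-x-G anchor; this is
  exercised by construction but the bundled simulator models heavy-chain
  geometry.
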
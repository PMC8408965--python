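# Methods

## The discovery problem

HT-SELEX iteratively selects, from a pool of random fixed-length
oligonucleotides, the molecules a transcription factor (TF) binds; the
sequenced rounds become progressively enriched for binding sites.  Most
analyses summarize such data into the TF's established ("canonical")
motif.  This package implements a conservative pipeline that instead asks
whether the selected rounds also contain *non-canonical* motifs: words as
enriched as the canonical sites, occurring independently of them, and
significantly distant from every canonical matrix of the TF.

## Pipeline

Given round #0 and a selected round R (fixed-length oligos, adapters
already trimmed) and the TF's canonical PWMs:

1. **Canonical occurrences.** Each canonical PWM is scanned over the
   selected round on both strands at a liberal match threshold
   (p ≤ 1e-4).  The score threshold is derived by exact dynamic
   programming over the discretized log-odds score distribution under a
   0-order background, so match counts agree exactly with exhaustive word
   enumeration.
2. **Background model.** An order-r Markov chain is fitted to round #0
   with double-strand counting and additive smoothing.  The order bound M
   is one less than the largest k at which every observed k-mer still has
   ≥ 100 occurrences; the order is chosen by splitting the shuffled
   library in half and maximizing R² between predicted and observed
   canonical M-mer frequencies on the held-out half.
3. **Effective length L.** For each k in [order+1, 15], the divergence
   between the selected round's k-mer distribution and the background is
   D_KL = Σ_{w∈S100} P_R(w) ln(P_R(w)/P_0(w)) + Q_R ln(Q_R/Q_0), where
   S100 holds the words counted ≥ 100 times and the Q terms cover all
   remaining words as one combined group (added once — a KL over a
   partition; adding it per word would not be a divergence).  L is the
   argmax, ties toward smaller k.
4. **L-mer ledger.** Canonical (strand-merged) L-mers counted ≥ 100 times
   and with dinucleotide entropy H = −Σ p_k log2 p_k at or above the
   minimum entropy of any canonical-motif match word (removes poly-A/C
   artifacts) enter the ledger with enrichment P_R(w)/P_0(w).
5. **Motif vs non-motif.** A word is a *motif L-mer* if one of its
   occurrence windows contains, or is contained in, a canonical match
   interval in at least one oligo.  Everything enriched strictly below
   the least enriched motif L-mer is discarded (ties survive).  Non-motif
   words must additionally show round-over-round frequency ratios ≥ 1
   across every consecutive round pair (a 0 → positive transition counts
   as enrichment, 0/0 fails) and must occur in at least one oligo free of
   motif L-mers.
6. **Clustering.** Motif and non-motif words are clustered separately.  A
   cluster head is an l-mer (l = 8, or L−2 when L < 8) covering the most
   unassigned words within m mismatches (m = 2, or 1 when l ≤ 5), both
   orientations considered; candidate heads are the l-substrings of the
   words themselves.  Covered words are aligned at their minimum-mismatch
   anchor (ties toward the middle of the word, then leftmost), reverse
   complemented when covered in the − orientation, N-padded, and counted
   into a PWM (an N contributes 0.25 to each base).  The process repeats
   until words are exhausted or five clusters exist; tied heads branch
   into independent runs (branch budget 8, excess ties resolved
   lexicographically) and the pooled clusters are deduplicated by member
   set, with any remaining member-sharing resolved after significance.
7. **Alone fraction.** A non-canonical cluster occurs in an oligo when any
   member word occurs on either strand; it occurs *alone* when no
   canonical-cluster member does.  Oligos are attributed greedily to
   clusters in decreasing member count so each counts once; clusters
   explaining < 5% of oligos alone are dropped.
8. **Significance.** Motif distance D is the minimum over all l'-column
   windows (l' = min(8, smaller trimmed width); flanks with information
   content < 0.25 bits trimmed first) and both orientations of the
   normalized Euclidean distance between probability blocks.  Each
   cluster's D_min to the canonical collection is referred to a normal
   model with the mean and n−1 standard deviation of the canonical
   clusters' own D_min values; one-tailed upper p-values are corrected
   per TF by Benjamini–Hochberg at 5% FDR.  TFs with fewer than two
   canonical D_min values (or zero variance) are unevaluable and yield
   no calls.  Significant clusters sharing a member word are reduced by
   keeping the larger D_min.

Downstream validation statistics (ChIP-peak alone fractions, e(m)
enrichment with pseudocount 1 against shuffled-L-mer /
dinucleotide-shuffled-peak / user-supplied matched controls, regulatory
overlap fractions, promoter Jaccard with its 10% eligibility gate,
conservation comparison by two-sample KS, and re-discovery in an
independent SELEX dataset) follow the definitions in the module
docstrings of `genomic_validation`.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_count` | 100 | word reliability floor for S100, the ledger, and M |
| `fimo_pvalue` | 1e-4 | canonical match threshold (liberal on purpose: weak canonical sites must anchor the rank cut) |
| `min_alone_fraction` | 0.05 | minimum share of oligos a non-canonical cluster must explain alone |
| `ror_floor` | 1.0 | round-over-round ratio floor |
| head l, m | 8, 2 (L−2, 1 if short) | cluster-head geometry |
| IC trim | 0.25 bits | uninformative-flank threshold before motif distance |
| FDR q | 0.05 | BH level, per-TF family |
| DP granularity | 1e-3 bits | score discretization; threshold error ≤ width·granularity/2 |
| log pseudocount | 1e-4 | added to PWM probabilities before log-odds (CIS-BP has exact zeros) |

## The simulator

`selex_sim` draws round #0 i.i.d. from a mononucleotide or Markov
background and produces each later round by resampling with replacement
under a mixture of binding components.  A draw first picks a component by
its mixture weight, then an oligo with probability ∝
exp(stringency × max(0, best log-odds score)) under that component's PWM;
the driving component is recorded as a provenance label in a sidecar
manifest, never in sequence.  Normalizing selection within each component
makes the mixture weights the stationary per-round composition of binding
events; weighting oligos by the raw sum of component terms instead would
let the dominant component's share compound across rounds (0.8/0.2
becomes ≈ 0.98/0.02 by round 3), which does not correspond to an
experiment in which a fifth of the binding material is of the second
mode.

Resampling reads from the previous round's reads reproduces a real
property of late SELEX rounds — bottlenecked pools with duplicated
molecules — but its strength depends on stringency.  The two standard
study conditions sit in the two regimes:

* **Discovery study** (`discovery_study`): two canonical PWMs (widths 12
  with soft 0.65/0.8 shoulders, combined weight 0.8, both given to the
  pipeline as the canonical set — TFs typically carry several canonical
  matrices, and the per-TF normal calibration needs at least two
  canonical clusters) plus one width-8 non-canonical PWM (weight 0.2,
  core at Hamming distance ≥ 4 from both canonical cores in every
  alignment and orientation); stringency 0.5 per bit, 3 rounds.  The
  shoulder columns give canonical sites a realistic affinity spread; the
  liberal 1e-4 match threshold then captures weakly selected canonical
  words, which is what makes the rank cut behave as intended.  At these
  conditions the non-canonical motif is recovered (consensus within one
  mismatch of the planted core) and BH-significant in 10/10 test seeds,
  with alone fractions matching the provenance oracle within a
  percentage point.
* **Length-recovery study** (`length_recovery_study`): one width-8 PWM
  (consensus certainty 0.75), stringency 0.15, 3 rounds, 50,000 oligos.
  The KL length statistic resolves site length when site-bearing reads
  are a few percent of the library: if selection drives the share toward
  one, either whole-oligo duplication keeps every long word above the
  100-count floor (bootstrap collapse) or random flank extensions of the
  core remain well counted, and in both cases the divergence keeps
  growing past the true width.  Stringency 0.15 lands the study in the
  resolvable regime and the chosen L is 8 (occasionally 7).

The acceptance experiments run at 20,000 oligos per round (discovery and
null) and 50,000 (length recovery); these sizes give stable statistics
while keeping a 10-seed experiment to a few minutes.  The simulator does
not model PCR bias, sequencing error, or adapter context, so passing
tests demonstrate correctness of the pipeline's inference under clean
mixture selection, not robustness to those artifacts.

The genomic fixture (`simulate_genome_with_peaks`) lays non-overlapping
peaks on a synthetic chromosome, plants non-canonical and canonical words
in configured blocks, scrubs the random background of chance occurrences
of either word, and emits regulatory/promoter/conservation annotations
whose expected statistics are recorded in a manifest; the validation
statistics then equal the manifest exactly.

## Numerical choices

* Score DP uses integer score bins of 1e-3 bits; scanning scores windows
  with the same integer matrix, so DP tail counts and match sets agree
  exactly with enumeration.  When no achievable score satisfies the
  requested p-value, the threshold lands past the maximum score and
  nothing matches.
* Backgrounds are strand-symmetrized before scanning so both strands
  share one score distribution.
* P_0 values are clamped at 1e-300 before ratios; a non-positive
  combined-group mass Q_0 skips the Q term with a warning (it arises
  when S100 covers the whole word space, where the term is vacuous).
* Dinucleotide entropy is computed on the canonical spelling of a word,
  forward orientation only.
* The train/validation split in order selection, and every other
  stochastic stage, derives its seed from the run seed by hashing the
  stage name (`pipeline.child_seed`), so stages are independently
  reproducible.
* Dinucleotide shuffling uses the Euler-walk construction (random last
  edges forming an arborescence to the final letter, remaining edges
  permuted), preserving the dinucleotide count multiset and the terminal
  letters exactly.

## Known limitations

* One effective length per TF; multi-modal site lengths are not detected.
* No affinity (K_d) modeling; enrichment is treated as monotone in
  affinity.
* Matched genomic controls (GC/repeat-matched) are consumed as a
  user-supplied FASTA, not generated.
* KS p-values are asymptotic; small groups (n < 10) are flagged.
* Conservation scores are read from a per-base TSV track; bigWig input
  is out of scope.
* Motif/visual curation steps of the original procedure (dimer vs flank
  interpretation of discovered motifs) are inherently manual and not
  implemented; the automated canonical-cluster similarity check only
  warns.
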
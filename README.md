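# selexmotif

Discovery of **non-canonical transcription-factor motifs** from HT-SELEX
round libraries.

HT-SELEX data are usually reduced to a TF's established (canonical)
motif.  `selexmotif` implements a conservative end-to-end pipeline that
looks for the signal such summaries discard: DNA words that are as
enriched as the canonical binding sites, rise consistently from round to
round, occur in oligos that carry no canonical site at all, and cluster
into position weight matrices significantly distant from every canonical
matrix of the TF.  A built-in SELEX simulator with planted binding modes
and provenance-labelled ground truth makes every stage testable without
external data.

## Method in brief

For a TF with round #0 library, selected round R, and canonical PWMs:

* fit an order-r Markov background to round #0 (order chosen by held-out
  R² on canonical M-mer frequencies) to supply word probabilities P₀(w);
* choose the effective site length L maximizing
  `D_KL = Σ_{w∈S₁₀₀} P_R(w) ln(P_R(w)/P₀(w)) + Q_R ln(Q_R/Q₀)`,
  where S₁₀₀ holds the words counted ≥ 100 times and Q collects all
  other words as one group;
* build the L-mer ledger: count ≥ 100, dinucleotide entropy at or above
  the minimum over canonical-motif match words, enrichment
  `P_R(w)/P₀(w)`;
* split words into *motif* L-mers (substring/superstring of a canonical
  match, found by FIMO-style scanning at p ≤ 1e-4 with an exact-DP score
  threshold) and *non-motif* L-mers; discard everything ranked below the
  least enriched motif L-mer, anything whose round-over-round enrichment
  ever drops below 1, and anything that never occurs alone;
* cluster words by maximal-coverage cluster heads (l = 8, ≤ 2
  mismatches, both orientations), align at anchors, N-pad, and count
  into PWMs; keep non-canonical clusters occurring alone in ≥ 5% of
  oligos;
* score each cluster's minimum trimmed sub-motif Euclidean distance
  D_min to the canonical collection, calibrate a normal model on the
  canonical clusters' own D_min values, and report clusters passing
  Benjamini–Hochberg FDR at 5%, de-duplicated so no L-mer supports two
  reported motifs.

Validation statistics for discovered motifs (ChIP-peak alone fractions,
`e(m)` enrichment against three controls, regulatory-region overlap,
promoter Jaccard, conservation KS comparison, independent-dataset
re-discovery) live in `selexmotif.genomic_validation`.  See
`docs/methods.md` for the full model description and design rationale.

## Worked example

Simulate a two-binding-mode experiment — 80% of binding events driven by
two canonical motifs (given to the pipeline as the canonical set), 20%
by a planted non-canonical motif with consensus `TTGGCCAA` — and run the
discovery pipeline:

```python
from selexmotif.selex_sim import (
    discovery_study, simulate_experiment, canonical_study_pwms,
)
from selexmotif.pipeline import discover

config = discovery_study(seed=1)          # 20,000 oligos x 40 bp, 3 rounds
sim = simulate_experiment(config)
result = discover(sim.rounds, canonical_study_pwms(), seed=1)

print(f"effective length L = {result.L}")
print(f"Markov order       = {result.order_report.optimal_order}")
print(f"canonical clusters = {len(result.canonical_clusters)}")
for c in result.significant:
    print(f"non-canonical motif: consensus={c.consensus} "
          f"D_min={c.dmin:.3f} p={c.pvalue:.2e} alone={c.alone_fraction:.3f}")
```

prints

```
effective length L = 15
Markov order       = 0
canonical clusters = 4
non-canonical motif: consensus=TTGGAATACTTGGCCAATAAGT D_min=0.272 p=4.06e-101 alone=0.196
```

The single significant non-canonical cluster contains the planted core
`TTGGCCAA` exactly (the flanking positions of the 15-mer alignment are
background), its distance to the canonical matrices is far outside the
canonical clusters' own D_min distribution (hence the extreme p-value),
and it occurs alone in 19.6% of the selected round's oligos — matching
the 20% mixture weight of the planted component.  On a canonical-only
null simulation the same pipeline reports zero significant motifs.

A command-line interface wraps the same stages for file-based runs:

```bash
selexmotif simulate --config sim.yaml --out rounds/
selexmotif discover --round0 rounds/round0.fasta \
    --rounds rounds/round1.fasta --rounds rounds/round2.fasta \
    --cisbp canonical.meme --out results/ --seed 1
selexmotif validate --members results/significant_members.tsv \
    --cisbp canonical.meme --peaks peaks.bed --genome genome.fa \
    --out validation/
```

`discover` writes the full audit trail: the per-L-mer ledger with every
filter decision, the KL profile, the background model, cluster PWMs in
MEME minimal format with member alignments, and the significance table.

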
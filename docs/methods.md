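# Methods

## Model

`neoscreen` scores a candidate neoantigen core peptide by a product of
stage scores, each standing for one step of T-cell epitope
presentation.  For MHC class I:

    NPS_I = TS · PHS · A · R / TIC

and for class II, whose pathway has no proteasome or TAP step:

    NPS_II = TS · A · R

The model is multiplicative on purpose: failure at any obligatory stage
(gene not expressed, core not liberated by the proteasome) zeroes the
score regardless of how well the peptide binds MHC.  The continuous
factors then order the survivors: A (fold-change of MHC binding caused
by the mutation) and R (TCR recognition probability) increase the
score, TIC (shifted log TAP IC50; larger = worse transport) divides it.

### Assumptions

* Variants are independent: two mutations falling in one window are
  scored as two separate candidates, not merged into a haplotype
  peptide.
* Expression is gated at gene level; isoform-level TPM is not modelled.
* Presentation is attributed to the best-binding allele (minimum mutant
  IC50) of the configured panel; other alleles are reported in the
  per-core table but do not drive the headline ranking.
* The TCR repertoire is summarised by a static epitope pool; R depends
  only on sequence similarity to that pool, not on repertoire dynamics.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| TPM threshold | 3 | TPM | expression gate, strict `>` |
| cleavage threshold | 0.7 | probability | proteasome gate, strict `>`, OR over N'/C' |
| affinity cutoff | 500 | nM IC50 | candidacy filter, strict `<` |
| flank n | 22 / 27 | residues | MCP half-width, class I / II |
| core length | 9 / 15 | residues | scored segment, class I / II |
| a | 26 | raw alignment score | displacement of the recognition curve: one pool entry scoring exactly a gives R = 1/2 |
| k | 1 | 1/score | slope of the recognition curve |
| TBS log base | 10 | — | TAP score scale (configurable) |
| ε (TIC guard) | 1e-6 | — | lower bound on the TIC divisor |
| gap open / extend | 11 / 1 | score | affine gaps: a gap of length g costs 11 + g |

The TAP score uses base-10 logarithms: on that scale typical TAP IC50
predictions (10²–10⁵ nM) give TBS values of 2–5, matching the scale on
which the shift `TIC = TBS + |TBS_min|` and the ε-guard are defined.
`TBS_min` is taken over all mutation-containing candidate cores of the
current run (sample-level), recorded in the run log; the core attaining
it has TIC = 0 and is protected by the ε-guard, which is flagged in the
output rather than silently applied.

## Numerical and procedural choices

* **Alignment.** `|s,e|` is the exact Smith–Waterman local alignment
  score (Gotoh affine-gap DP) under BLOSUM62 — not a heuristic BLASTp
  score.  Exact DP is deterministic and never below the heuristic's
  value, so R is, if anything, slightly conservative toward higher
  recognition.  Gap accounting follows the BLASTp convention: opening
  costs 11 and every gapped residue (including the first) costs 1.
  Raw scores are the default scale for a = 26; bit-score rescaling
  (gapped BLOSUM62 Karlin–Altschul parameters) is available.
* **Recognition probability.** R = S/(1+S) is computed through
  log-sum-exp, so arbitrarily large similarities cannot overflow; the
  result is clamped one ulp below 1.0 so the analytic bound R < 1
  survives float64 saturation.  An empty pool gives R = 0 exactly.
* **Cleavage coordinates.** N' is read at the residue immediately
  preceding the core's N-terminus within the MCP, C' at the core's
  C-terminal residue.  A core flush with the MCP N-terminus takes
  N' = 1: a free terminus needs no upstream cut.
* **Missing wild-type counterpart.** Cores downstream of a frameshift
  have no meaningful wild-type segment; their Aff(WT) is imputed as the
  500 nM candidacy bound, so A ≥ 1 exactly when the mutant passes the
  filter.  Such rows carry the `wt_affinity_imputed` flag.
* **Ties.** Ranking is by descending NPS, then higher A, then lower
  mutant IC50, then lexicographic peptide — a total order, so reruns
  are byte-identical.  Allele ties on mutant IC50 break
  lexicographically.  Zero-NPS candidates stay in the full table after
  all positive candidates, because rank-based evaluation needs every
  peptide ranked.
* **Degenerate inputs.** All-zero expression tables, non-positive IC50
  values, out-of-range probabilities and empty CDR3 panels raise
  validation errors; an MCP shorter than the core length yields an
  empty core list with a warning; cores containing 'X' are disqualified
  and logged, not fatal.
* **TIS reading.** The T-cell interaction score is the fraction of
  CDR3 sequences whose three-predictor pair score reaches the 0.75
  threshold.  The aggregation is a convention, so the alternative
  reading (mean pair score) is exposed behind an explicit
  `method="mean_pair_score"` argument rather than silently chosen.
* **Evaluation conventions.** Peptide↔label matching is exact identity
  after case-folding; duplicated peptides keep their first (best)
  rank.  A labelled peptide the tool never ranked scores RS = 1 and
  enters RCS at the worst rank T, so both metrics share one
  convention.  The reported classification cutoff is the score
  threshold maximising balanced accuracy (smallest threshold on ties);
  AUC is the tie-corrected Mann–Whitney estimator.

## Synthetic data

The fixture generator emulates the pipeline's complete input surface:
random proteomes, SNP tables, per-gene FPKM, per-residue cleavage
probabilities, TAP and MHC IC50 tables, and an epitope pool.  Planted
positives clear every stage by construction — expressed gene, cleavable
C-terminus, sub-100 nM mutant binding with A ≥ 15, and an exact
epitope-pool self-match driving R ≈ 1 — while every non-planted core is
written with mutant IC50 ≥ 1000 nM and therefore fails candidacy.
Default sizes (8–10 proteins, 24–40 variants, 25 % planted) keep a full
two-class run in seconds.

What passing tests on these fixtures do show: the stage logic gates,
filters, ranks and round-trips exactly as specified, deterministically.
What they do not show: predictive performance on real tumours.  The
synthetic predictor scores carry no biology — real cleavage, TAP and
MHC predictions are correlated with sequence and with each other,
expression is not bimodal, and real positives do not separate this
cleanly.  Recovery of planted candidates validates the plumbing and the
score algebra, not immunogenicity prediction.

## Known limitations

* Haplotype peptides (co-occurring nearby variants) are not assembled.
* Proteasomal splicing, eluted-ligand likelihood modes and allele
  frequency weighting are out of scope.
* The epitope pool is a user input; no species or assay filtering is
  applied beyond residue hygiene and deduplication.
* External predictor adapters are limited to the canonical TSV schema;
  vendor-format parsers are intentionally not bundled.
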
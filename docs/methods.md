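# Methods

`cmsforge` re-creates, as a tested pipeline over synthetic data with planted
ground truth, the computational route by which a mitochondrial cytoplasmic
male sterility (CMS) gene and its nuclear restorer (Rf) are identified and
characterized: comparative mitogenomics → chimeric-ORF decomposition →
RNA-editing and cleavage assays → qRT-PCR expression → segregation and
fine-mapping genetics → PPR-cluster duplication ordering. This note records
the models behind each stage, the parameters that matter, what the
generators do and do not emulate, and the numerical choices.

## Synthetic data and planted truth

Every input the pipeline consumes is generated by `cmsforge.simulate`, one
named NumPy generator per operation, seeded explicitly; regenerating any
artifact with the same seed is byte-identical. Defaults are the study
conditions the pipeline is meant to reproduce:

| parameter | default | meaning |
|---|---|---|
| genome_length | 457,380 bp | finished CMS mitogenome (backbone + insert) |
| gc_prob | 0.4383 | per-base G+C probability |
| n_references / ref_divergence | 3 / 0.005 | non-CMS panel, substitutions per site |
| chimera_spec | (donorA, 421, 0.79), (donorB, 71, 1.0), (unknown, 57) | three-part chimeric ORF, donor identities |
| edit_sites | (62, 0.762), (65, 0.821) | C-to-U sites, 1-based from ATG, per-clone edit probability |
| cleavage_position | 415 | downstream nucleotide of the cut |
| n_clones / RACE ends / background | 500 / 200 / 0.10 | clone-set sizes (artifact choices; no counts are fixed by the underlying experiments) |
| true_folds | root 3.3, stem 11.5, leaf 8.2, panicle 6.7, anther 8.5 | sterile / restorer transcript ratio |
| ct_noise_sd / replicates | 0.05 cycles / 3 | qPCR noise model |

The chimeric insert is an ATG-initiated, stop-free ORF ending in TAA
(549 bp = 182 codons + stop). Codons 21 (CCA, Pro) and 22 (TCC, Ser) are
fixed so that C→U edits at transcript positions 62 and 65 (each the middle
base of its codon) produce Pro→Leu and Ser→Phe. Candidate ORFs are
rejection-sampled until the planted frame is the only reading frame of ≥ 50
codons in the insert, so planted truth and ORF calls correspond one-to-one.

Three constructions make boundary recovery exact rather than approximate:

- **Mutation-free boundary windows.** The 20 bp at each end of a
  donor-derived segment carry no divergence mutations, so exact seed words
  anchor the decomposer's chains precisely at the planted boundaries.
- **Mismatching donor flanks.** In each donor genome the four bases on
  either side of the embedded source region are forced to differ from the
  insert's continuation, so ungapped extension cannot creep across a
  boundary.
- **Mismatching junction bases.** The backbone bases immediately adjacent
  to the insertion point are forced to differ from the insert's first/last
  bases; otherwise a k-mer window crossing the junction can chance-match
  the references (probability ~1/4 per edge) and shave bases off the
  uncovered region.

Divergence (reference panel, donor identity) is substitution-only; the
generators do not emulate indels, sequencing-quality profiles, repeats, or
mitochondrial recombination. Passing tests therefore demonstrate correctness
of the inference logic under a clean rearrangement-plus-substitution model,
not robustness to indel-rich or repeat-mediated divergence (see
Limitations).

## Mitogenome comparison (`mitocompare`)

"CMS-specific / highly diverged" is operationalized as *uncovered by exact
k-mer anchor chains against every reference* — no divergence metric is
implied beyond that. Anchors are exact shared 15-mers (both strands;
circular sequences virtually extended by k−1 bases). Anchors sharing a
diagonal (q−r forward, q+r reverse) are merged into chains, splitting where
the query gap exceeds 2,000 bp; chain spans define coverage, so isolated
substitutions inside a chain do not break it. Per-reference uncovered
intervals are intersected across the panel, merged across gaps < 1,000 bp
and filtered at ≥ 500 bp. Defaults (k = 15, max gap 2 kb, min length 500 bp,
merge gap 1 kb) keep multi-kb novel regions intact while ignoring SNP noise
at mitogenome scale.

Two random ~450 kb sequences share a few hundred 15-mers by chance; a
single stray anchor inside a novel insert would otherwise count as
"coverage" and nibble or split the reported region. Chains are therefore
required to contain ≥ 2 anchors to count toward coverage; genuinely
conserved blocks yield densely anchored chains, so the filter costs nothing
real. Because chaining is by exact diagonal, an indel between query and
reference starts a new chain rather than extending one — adequate for the
substitution-only model, but a gap-tolerant chainer would be needed for
indel-divergent genomes.

## ORF calling and chimera decomposition (`orfs`)

ORFs are called by a six-frame scan under the standard genetic code (plant
mitochondria use it), ATG-initiated, first in-frame stop terminates; nested
ORFs sharing a stop report only the longest; ambiguous bases never act as
start or stop. The floor of 50 aa reflects the smallest ORFs one would
follow up at this scale.

Decomposition finds, per donor, exact 12-mer seed matches grouped by
(strand, diagonal) into chains — a chain can span at most the ORF, so
same-diagonal seeds are merged across arbitrary internal gaps and the
identity floor, not a gap limit, rejects bad chains. Chain ends are refined
by ungapped extension scored +1/−1 with an X-drop of 4, trimmed back to the
maximum-scoring endpoint. Under the substitution-only donor model this
equals a banded gapped extension (no gaps can arise) and identity =
matches / alignment columns holds exactly. Hits below 70% identity or
shorter than 30 bp are discarded as noise (the 30 bp floor also suppresses
chance 12-mer seeds, ~1–2 expected per 550 bp ORF vs a 50 kb donor).

The reported tiling maximizes total donor-assigned length over
non-overlapping hits (exhaustively verified against subset enumeration in
tests), breaking ties by fewer segments, then leftmost starts. Uncovered
stretches ≥ 30 bp become "unknown" segments; shorter interior gaps are
split at their midpoint between the neighbors, edge gaps absorbed into the
single neighbor. Origin classification counts distinct sources — assigned
donor ids plus interior unknown runs (an interior unassigned stretch is
evidence of a third fragment; an edge stretch is merely unaligned): ≥ 2
sources → chimeric; one donor → native (self-species) or foreign; none →
unknown.

## Transcript assays (`transcripts`)

Editing: each cDNA clone is globally aligned to the reference ORF (edlib
NW); clones under 90% identity are dropped and logged. Sites are called
where the reference base is C, informative depth (C+T) ≥ 20, and the T
fraction ≥ 0.05; the rate is T/(C+T) with a Wilson 95% CI (statsmodels) and
the codon consequence annotated from the standard code. Coordinates are
1-based from the A of the ATG. The thresholds are deliberately permissive —
the signals of interest (rates of 0.7–0.85) pass with wide margin — and the
estimator is the plain binomial MLE, verified unbiased (|bias| < 0.01 over
200 simulations at n = 500) with ≥ 90% CI coverage.

Cleavage: RLM-RACE clone 5' ends are mapped by best infix alignment of each
clone's first 40 bases; the modal start position p is accepted as a cut
between p−1 and p when it has ≥ 50% support and ≥ 10 ends. A tie at the
mode is ambiguous → not detected; an input that is all degradation
background is likewise not detected, mirroring the no-product control of a
line lacking the restorer.

## Expression (`expression`)

Classic 2^(−ΔΔCt) with amplification efficiency fixed at 2.0 (ideal):
replicate Ct values are averaged per (group, gene, tissue); ΔCt =
Ct_target − Ct_reference; fold = 2^(−(ΔCt_sample − ΔCt_calibrator)).
Replicate SDs propagate to the fold as se = fold · ln2 · sd(ΔΔCt). The
degraded fraction in the calibrator is 1 − 1/fold (clamped at 0 below
fold 1); we report the computed value (0.882 at fold 8.5) and do not round
it to a coarser approximation. The two primer pairs flanking and upstream
of the cleavage site are modeled as two target-gene labels carrying the same
planted folds. Note the sampling arithmetic: with noise sd 0.05 cycles and
3 replicates, sd(ΔΔCt) = 0.05·2/√3 ≈ 0.058 cycles, i.e. ~4% relative error
on the fold at one sigma — so individual tissue estimates sit within ~5% of
truth typically but not universally; tests bound every tissue at 4 sigma
and the headline anther fold at 5%.

## Genetics (`genetics`)

Segregation: Pearson chi-square goodness of fit, df 1, no continuity
correction (all counts of interest are large), α = 0.05. BSA: windows of 10
SNPs of mean |pool allele-frequency difference|, threshold 0.3, candidate =
longest contiguous super-threshold run (the upstream microarray chemistry
is not modeled, only the pool-difference scan). Fine-mapping assumes a
single dominant restorer under sporophytic restoration: a fertile testcross
plant carries Rf, a sterile one does not. For each recombinant, the locus
may sit in any inter-marker segment whose flanking genotypes admit its
inferred locus genotype; the final interval is the intersection over all
plants, and contradictory recombinants (no admissible placement) raise an
error naming the offenders. Adding a non-recombinant never changes the
interval.

## PPR duplication ordering (`ppr`)

Pairwise identities are end-to-end global alignments (Biopython
PairwiseAligner; match +1, mismatch −1, gap open −2, extend −0.5), identity
= matches / alignment columns. Trees are UPGMA on distance 1 − identity with
node height d/2, implemented in-package to control tie-breaking (ties join
the lexicographically first cluster pair, making trees reproducible);
scipy's average linkage and a naive re-agglomeration oracle cross-check it
in tests. Internal nodes sorted by height give the duplication order oldest
→ youngest. The family generator duplicates one random gene per generation
and then mutates every gene at 0.01 substitutions/site, so each generation
adds ~2% pairwise divergence; at the default 600 bp the youngest simulated
duplication is recovered as the lowest join in ≥ 95/100 seeded runs (at
much shorter sequences the binomial noise on ~6 mutations per branch erodes
this). Identities on real clustered PPR genes depend on unstated alignment
parameters and accession sequence, so acceptance for this stage is
property-based rather than value-based. Cross-species ortholog detection is
out of scope; the same identity/tree machinery applies to user-supplied
orthologous-region FASTA.

## Trial summarization (`trial`)

The packaged table (`data/table1.tsv`) holds paired WA/FA test-cross F1
trait cells as "mean ± sd" text (ASCII `+-` accepted; decimal point only).
Ranges and means are computed on the cell means; paired WA − FA differences
use the shared base cross id (1.1/1.2, ...); unpaired hybrids are excluded
from paired statistics and logged. Significance testing of trait
differences would need per-plant raw data the table does not contain; only
descriptive summaries are reproduced.

## Pipeline and determinism

`run_pipeline` executes fixture → mitocompare → ORF/chimera, then the
independent assay/expression/genetics/PPR stages, and writes a sorted,
6-decimal-rounded `summary.json`; identical config + seed gives a
byte-identical file. Config is a flat dataclass (unknown keys rejected)
with per-stage seeds kept in lockstep with the run seed unless overridden.
Any stage failure aborts with the stage name and cause.

## Problem sizes in the test suite

The default full-scale fixture (457,380 bp, 3 references) is generated once
per test session and exercised end-to-end. Broad per-seed properties use
scaled sizes chosen to keep the suite brisk while leaving the statistics
meaningful: 40 kb genomes with 2 references for the 50-seed insert-recall
and coverage-conservation properties; 80 nt transcripts for the 200-run
editing-estimator calibration; 60–80-plant panels for fine-mapping
properties.

## Known limitations

- Substitution-only divergence throughout; no indels, repeats, or
  recombination in genomes or clones, and the decomposer/chainer would need
  gap-tolerant extension for indel-divergent real data.
- k-mer-uncovered is a proxy for "highly diverged"; it cannot grade
  intermediate divergence, only presence/absence of exact-match coverage.
- qPCR efficiency is fixed at 2.0; no standard-curve calibration.
- Fine-mapping assumes fully penetrant single-locus dominant restoration
  and error-free marker calls; genotyping error would surface as
  "contradictory recombinants" rather than being modeled.
- The BSA scan models pooled allele frequencies directly, not array
  hybridization intensities.
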
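# Methods

This note records what each stage computes, the assumptions behind it, the
parameters that matter, and what the synthetic-data generators do and do
not emulate.

## CU-motif model

A CU motif is operationalised as a **maximal contiguous pyrimidine run** of
length ≥ `min_len` (default 3 nt) containing at least one cytosine and at
least one uracil. Maximality — the positions immediately flanking the run
are not pyrimidines — is the only reading under which motifs cannot
overlap and a count cannot double-count sub-windows; it is also why motif
counts are invariant under T↔U respelling (the scanner reads T as U, so
DNA- and RNA-form UTRs give identical results). Two deliberate
conservatisms:

- IUPAC ambiguity codes, including Y (C or U), break runs: an ambiguous
  base cannot be verified to contribute both base classes, so treating it
  as a pyrimidine could only inflate counts.
- Scanning is strand-specific; the input is taken as the mRNA sense
  strand and no reverse complement is examined.

`min_len` may be lowered to 2 for exploration but the default of 3 defines
the statistic. Internally all coordinates are 0-based half-open; reports
print 1-based inclusive spans.

## Binding-region clustering

PTB binding requires several closely spaced pyrimidine tracts, not a
single motif. A *binding region* is a run of ≥ `min_motifs` (default 4)
consecutive motifs whose span — first motif start to last motif end — is
at most `window` (default 150 nt). Because the 150-nt figure originates
as an approximation, both parameters are exposed (`--window`,
`--min-motifs`), and a start-to-start span convention is available behind
`span_mode` (default off). Overlapping qualifying windows are merged into
the maximal run of motifs each of whose `min_motifs`-sized sub-windows
qualifies; two merged regions can still share boundary motifs, which is
intentional (each is independently maximal).

## RRM detection and PTB typing

Detection is reference-based: four ~90-aa RRM profiles are each locally
aligned to the query protein (Smith–Waterman, BLOSUM62, affine gaps with
open 10 / extend 1, i.e. a gap of length k costs 10 + k). A hit survives
if it reaches `min_identity` (default 40 %) over its alignment columns and
covers at least `min_cover` (default 0.6) of the profile; the thresholds
sit far below the 80–88 % identity typical of true PTB1/6 orthologues and
far above what unrelated sequence reaches, so the classification is not
sensitive to them. Surviving hits are assigned greedily by descending
score with no query overlap (ties: earlier query start, then profile
order); greedy vs. optimal assignment differs negligibly with four short
profiles. Hits out of profile order are flagged with a warning, never
reordered. RNP1/RNP2 box coordinates are carried on each profile and
mapped through the retained alignment into query coordinates; a box
widened or truncated by indels is flagged, a fully deleted box is reported
absent.

The type call is the field's RRM-count rule: 4 qualifying RRMs →
PTB1/6-type (the CmRBP50-like chaperone clade), 3 → PTB7-type
(splicing-associated clade), anything else → unclassified.

**Packaged profiles.** The default profile set
(`data/rrm_profiles_synthetic.fasta`) is a constructed, clearly-labelled
synthetic stand-in: four RRM-like blocks (85–95 aa) with RNP2 (6 aa) and
RNP1 (8 aa) boxes at canonical offsets. It satisfies every structural
constraint of a real RRM profile set and is what the recovery experiments
use, since those are plant-then-recover and profile-agnostic. For
annotating real proteins, users should supply profiles cut from an
experimentally anchored PTB (CmRBP50 or StPTB1) via
`rrm_detect.load_profiles`; the FASTA header syntax is
`rnp1=offset:len rnp2=offset:len` (0-based offsets).

## Orthologue scoring

Coverage and identity mirror the BLAST conventions the survey tables use:
**coverage** is the aligned query span as a percentage of query length
(query-relative, so not symmetric), **identity** is identical residue
pairs over alignment columns including gap columns, both rounded to
integers. Only the single best-scoring local alignment is used;
compositional score adjustments and multi-HSP tiling are not
re-implemented, so small systematic deviations from database-reported
percentages are expected — integer-rounding agreement is the bar.
Candidates are ranked by (coverage, identity, score) descending; full
ties keep input order and log a warning.

## Conservation, distances, trees

`annotate_conservation` reproduces the three-way colouring used for PTB
orthologue alignments: against two reference rows (e.g. StPTB1 and
StPTB6), a non-reference residue is *reference-identical* if it equals the
agreeing references (if the references disagree, matching either counts,
with an ambiguity flag), else *shared-in-≥2* if at least two non-reference
rows share it, else *nonconserved*; gaps are always nonconserved. The
three categories partition every annotated cell.

Distances are uncorrected p-distances (mismatches over compared columns)
with pairwise gap deletion by default (complete deletion by flag); the
Poisson correction d = −ln(1 − p) puts branch lengths on the
substitutions-per-site scale and is undefined at p = 1, which raises an
error rather than returning infinity. Trees are standard neighbor
joining (Q-criterion, Studier–Keppler branch lengths, via scikit-bio);
the matrix is label-sorted first so tie-breaking does not depend on input
order, and negative branch-length estimates are clamped to zero with a
warning. On an additive matrix NJ reconstructs the generating tree
exactly (topology and lengths), which is what the generate-then-recover
tests assert.

Midpoint rooting is implemented in-package: the diameter (longest
leaf-to-leaf path) is found by exhaustive leaf-pair enumeration, ties are
broken by the lexicographically smallest endpoint-label pair, and the
root is inserted on the edge containing the path midpoint, leaving both
diameter endpoints equidistant from the root (balance error < 1e−9 in the
test suite). An all-zero-length tree is rooted at an arbitrary internal
node with a warning. The original survey's trees came from a web
pipeline whose exact distance/tree stage is unstated; NJ on alignment
distances plus midpoint rooting is the assumed standard stage, so
topology-level concordance rather than branch-exact reproduction is the
appropriate expectation for real data.

## 2^−ΔΔCt expression analysis

Technical replicates are collapsed by mean per biological replicate
before any statistics (the standard guard against pseudo-replication).
Per biological replicate, ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts
the mean calibrator ΔCt; the per-replicate fold is 2^−ΔΔCt and the
reported fold is the mean with SE = sd/√n. The calibrator condition is
reported as fold 1 exactly, by construction. Significance is a
two-sided two-sample Student's t-test on ΔCt — testing on the ΔCt scale
rather than the fold scale because Ct noise is approximately Gaussian in
cycles — with Welch's correction behind a flag. Stars use strict
inequalities (p < 0.05/0.01/0.001; p = 0.05 exactly is ns). With one
biological replicate the fold is still reported but p is absent (ns) with
a warning. When both groups are exactly noise-free the t statistic is
degenerate; equal means report p = 1, unequal p = 0.

## Synthetic-data generators

One global seed fans out to fixed per-component streams (numpy
`SeedSequence` spawn keys), so generators are individually reproducible
and adding one call never perturbs another component's draws.

- **UTRs** (`gen_utr`): plants the requested number of valid CU runs
  (length 3–8 nt, each guaranteed ≥ 1 C and ≥ 1 U) separated by at least
  one purine, in a background with 30 % pyrimidine content (purine-biased
  to suppress accidental runs). Positions flanking planted motifs are
  forced to purines, and any accidental valid run arising in the
  background is broken by resampling one of its pyrimidines — so the
  scanner provably finds exactly the planted motifs. Defaults cover the
  surveyed regime (UTRs of 74–503 nt carrying 2–20 motifs).
- **Proteins** (`gen_ptb_protein`): concatenates the first n RRM profiles
  (n = 3 or 4) with random linkers of 15–40 aa and applies i.i.d.
  substitutions at the requested rate; planted spans are recorded
  pre-mutation.
- **Ct tables** (`gen_ct_table`): target Ct = base − log2(fold) plus
  i.i.d. N(0, sd) noise per technical measurement; the reference gene is
  constant up to the same noise. Defaults are three biological × three
  technical replicates, 0.2-cycle noise — the design of a typical
  RT-qPCR comparison.
- **Trees** (`gen_additive_tree`): random unrooted binary topologies by
  sequential edge attachment, branch lengths uniform in (0.05, 1), with
  the exact additive path-distance matrix.

What the generators deliberately do **not** emulate: real UTR base
composition and motif clustering beyond the planted configuration,
homology between RRMs, codon structure, amplification-efficiency drift,
and alignment uncertainty (generated alignments are exact). Passing
recovery tests therefore demonstrate correctness of the computations
under the stated statistical model, not performance on real genome
annotations — for which the thresholds above are exposed as parameters.

## Problem sizes in the test and reproduction scripts

The property suite runs the scanner against a brute-force oracle on 1000
random 500-mers, planted-motif recovery for k = 0..25 over 200 seeds,
region detection against an exhaustive oracle on 500 configurations, RRM
recovery at 20 % substitution over 200 seeds (≥ 95 % required),
local-alignment scores against a cell-by-cell DP oracle on 500 short
pairs, NJ recovery of 100 additive 8-taxon trees, and ΔΔCt fold recovery
over 500 seeded tables per fold. `scripts/acceptance.py` uses 100 protein
seeds, 50 trees and 200 Ct tables per fold; these sizes give stable
summary statistics while keeping a full run in seconds.

## Known limitations

- Identity/coverage can differ by a point from database-reported values
  for real orthologue pairs (no compositional adjustment, single-HSP).
- The RRM caller is alignment-based, not an HMM; profiles diverged far
  beyond ~35 % identity from the reference set will be missed.
- Which transcript isoform's annotated 3′ UTR to scan is the user's
  choice; the tools require explicit per-isoform input sequences.
- Published counts for one well-studied UTR disagree between sources
  (16 vs 17 motifs for the same 503-nt sequence); the tabulated survey
  value (17) is used as the reference regime in tests, and exact
  calibration against annotated UTRs requires obtaining those sequences.
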
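# Methods

## The model

A nonsense SNV is screened for the "manufactured splice rescue"
configuration: the same substitution that converts a sense codon into a
stop (TAA/TAG/TGA) also completes a cryptic donor (5') splice site whose
use would excise the stop. The screen assumes:

- **One canonical transcript per gene.** Consequences are called only on
  canonical transcripts; when the annotation carries no canonical tag, the
  transcript with the longest spliced CDS is chosen (ties broken by
  lexicographically smallest transcript id). This fallback is a repository
  decision — annotation sources disagree on what "canonical" means — and
  is deterministic by construction.
- **Deletion to the natural exon end.** Using the gained donor splices the
  variant's exon at the new junction to the next *natural* acceptor, so
  the excised mRNA segment runs from the base after the junction through
  the exon's 3' end. Alternative acceptor gains, NMD-escape mechanisms
  other than the DP<3 proxy, and re-initiation are not modelled.
- **Last-exon exclusion.** Stops in the last exon are removed before any
  donor-gain logic: they largely escape NMD and are already treated
  cautiously in interpretation, so they are outside the screen's question.
- **Standard nuclear genetic code**, single-nucleotide variants only.

## Delta-position convention

Donor-gain delta positions (DP) use a contiguous pre-mRNA numbering
relative to the variant with **no position zero** (…−2, −1, +1, +2…);
negative means 5' of the variant after strand correction. The reported
base is the **last exonic base** of the new junction
(`dp_convention="last-exonic"`, the default), so
`deleted_nt = exon_end − DG_position`. This makes the canonical mechanism
geometry internally consistent: a stop occupying donor-motif positions
+2..+4 implies a junction two pre-mRNA positions upstream of the variant,
DP = −2. The alternative `"first-intronic"` convention (the reported base
is one position 3') is selectable and shifts `deleted_nt` by one; choose
it for annotation sources that reference the intron side. Raw
SpliceAI-format DPs are treated as reference-genome-oriented and are
negated for minus-strand transcripts during strand correction
(`already_stranded` skips this for pre-oriented sources; a guard flag
prevents double correction).

## Candidacy and the decision tree

At each threshold τ ∈ {0.2, 0.5, 0.8} (high recall → high precision), a
stop-gain call is a rescue candidate iff DS_DG ≥ τ (inclusive comparison;
a configurable flag switches to strict) and strand-corrected DP_DG < 3
(strict). Candidates walk the tree: frame (`deleted_nt mod 3`) → CDS
fraction (`deleted_nt / cds_len_nt`, strict < 0.10 for the
rescue-plausible branch — "coding transcript" is interpreted as the
spliced CDS length in nucleotides, including the stop codon) → protein
domain overlap of the deleted residue interval (closed intervals; ≥1
shared residue counts, adjacency does not). Degenerate geometries — a
gained donor outside the variant's exon, at/after the natural exon end, or
a deletion crossing a CDS boundary — receive an explicit DEGENERATE label
rather than being forced into a branch, and are surfaced in logs. Calls
whose stop codon spans an exon junction are flagged in the output so they
can be excluded in sensitivity analyses.

## Protein-consequence rendering

For in-frame <10% deletions the predicted product is rendered
HGVS-protein style. The alternate CDS is built by substituting the variant
base and excising the deleted segment; both proteins are translated and
diffed (maximal common prefix, then maximal common suffix). Exact
reconstitution of flanking residues gives `p.(Xaa#_Yaa#del)`; a hybrid
junction codon encoding a new residue gives `p.(Xaa#_Yaa#delins…)`. A
hybrid codon that is itself a stop raises a "rescue produces truncation"
error (logged; the category is unchanged). The test suite verifies every
rendered string against an independent route that re-splices the genomic
sequence at the new junction and diffs the translations. Repeat-region
placement follows prefix-first trimming (5'-most), which coincides with
the normalized form for all fixtures used here.

## The PWM donor stand-in

Running a deep splicing network is out of scope; annotations are consumed
in the SpliceAI INFO format. For self-contained operation the package
ships a deterministic position-weight-matrix scorer over donor positions
−3..+6 (consensus MAG|GTRAGT; per-position base frequencies chosen to
reflect the strong +1/+2 GT requirement and the weaker flanking
preferences; background 0.25 per base). A site's probability is a logistic
transform of its summed log2 odds (midpoint 7.0, scale 1.0); the delta
score of a variant is the largest increase in site probability over all
junction placements within a 50-nt window, counting only alternate-allele
9-mers that carry the obligate GT. The logistic parameters are fixed so
that the two design anchors hold on synthetic sequence: a variant
completing a full consensus donor scores ≥ 0.8, and a variant creating no
GT dinucleotide scores ≤ 0.05. The scorer is *not* a splicing predictor
for real genomes — it exists to exercise the pipeline deterministically
and to cross-check planted fixtures; improvements of pre-existing GT sites
score by the same probability difference and may exceed the no-GT floor.

## Statistics

- **2×2 chi-square**: Pearson statistic, df=1, two-sided, no continuity
  correction by default (Yates available by flag). Identical degenerate
  proportions (both groups entirely LP/P or entirely not) report statistic
  0 rather than a zero-margin error.
- **Rank-sum W** (Mann–Whitney statistic of the first group): exact
  two-sided p by enumeration of all group assignments when both n ≤ 8
  (permutation-exact, so ties are conditioned on), otherwise a normal
  approximation with tie and continuity correction; this matches the
  asymptotic two-sided Mann–Whitney of standard references to 1e-6, which
  the tests verify against an independent implementation.
- **Comparator set** for the LP/P and star-rating comparisons: all
  non-candidate stop-gain calls in genes containing ≥1 candidate ("the
  remaining nonsense variants in the same genes"); star-rating comparisons
  are restricted to LP/P-classified variants. Star ratings derive from
  ClinVar-style review statuses via the fixed public mapping (practice
  guideline = 4 … no assertion = 0; unknown statuses map to 0 with a
  warning). LP/P means classifications P or LP only.
- No multiple-testing adjustment is applied (the comparisons are reported
  individually, unadjusted).

## The synthetic-data generator

`generate_cohort` emulates what the screen consumes: multi-exon
protein-coding genes (defaults: 2–8 exons of 60–300 nt, introns of
80–500 nt with GT…AG ends, 6–30 nt UTRs, alternating strands, ten genes
per chromosome), nonsense variants planted per a category mix (default 97%
plain nonsense, 3% candidates split 40/20/20/20 across out-of-frame /
in-frame ≥10% / in-frame <10% without / with domain overlap — a small
candidate fraction of the order seen in population screens), SpliceAI-like
INFO strings (candidate delta scores uniform on [0.85, 0.99] so that
planted categories are invariant across all three thresholds;
non-candidates ≤ 0.05), and ClinVar-like labels with a planted LP/P
deficit (0.75 for candidates vs 0.90 otherwise) and star distributions
with means ≈1.10 vs ≈1.34.

Candidate plants realize the canonical geometry exactly: a C>T edit at
codon base 1 (CAA→TAA or CGA→TGA) whose stop occupies donor positions
+2..+4, with the surrounding reference rewritten to the donor consensus
except the +2 base the variant supplies — so the reference is never
already a donor, and the planted DP is always −2. This forces the junction
to codon phase 2, so in-frame plants are only feasible on exons whose CDS
end ≡ 2 (mod 3); the generator retries across genes when a gene cannot
host a category. TAG stops are planted only as non-candidates (donor +4
must be A). Plain-nonsense plants are rejection-sampled until the PWM
scores them ≤ 0.05. Deletions with conflicting domain requirements are
kept residue-disjoint so a consistent domain table always exists. Every
plant is re-verified at generation time with the sequence-surgery oracle
(explicit re-splicing and translation), never with the coordinate-based
callers under test; a single root seed drives all randomness and identical
seeds give byte-identical files.

What the generator does **not** emulate: realistic human gene-length/GC
distributions, mutation-rate or allele-frequency structure, annotation
errors, imperfect splice predictions (planted scores are noiseless), or
linkage between variants. Passing the recovery tests therefore shows the
*machinery* is correct under the stated geometry, not that real-cohort
rates would be reproduced.

The packaged worked-example transcript (`tsc2_like_fixture`) is a
**synthetic** stand-in, not the real TSC2 sequence: it reproduces the
published example's coding geometry (CDS 5424 nt / 1807 residues, variant
c.4081C>T = codon 1361 CGA→TGA, junction at c.4079, variant exon ending at
c.4493 → 414 nt excised, 7.6% of the CDS, hybrid codon GA+T = Asp) so the
renderer's output `p.(Glu1360_Ser1498delinsAsp)` can be checked end to
end, with the published donor-gain score (0.80) carried in the fixture VCF.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale cohorts chosen as the
package's own study conditions: 50 genes / 300 variants for end-to-end
recovery, ≥1000 planted candidates for the frame-rule/oracle agreement,
2000 null simulations per test for type-I calibration, and 200 replicates
at n=500/5000 for the planted-effect power check. Floating-point screen
tables are written with shortest-round-trip float rendering so outputs are
byte-identical across runs and read back exactly. GTF input is expected to
include the stop codon within CDS features (the model invariant is
ATG…stop); Ensembl-style GTFs that exclude it load in lenient mode, which
demotes sequence-level validation failures to warnings.

## Known limitations

- The screen predicts *candidacy*, not splicing outcome: no RNA-level or
  functional validation is modelled, and in-silico donor scores are taken
  at face value.
- Whether an in-frame deletion that touches a domain (or even one that
  does not) abolishes protein function is out of scope.
- Frameshift outcomes of real mis-splicing (e.g. partial intron retention)
  beyond the modelled junction-to-exon-end deletion are not considered.
- The PWM stand-in is a pipeline exerciser, not a splicing predictor.
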
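# splicerescue

Screen nonsense variants for **manufactured splice rescue** — the
configuration in which a single-nucleotide stop-gain variant simultaneously
creates a cryptic 5' (donor) splice site at or upstream of the new stop
codon. If the spliceosome uses that donor, the premature stop is excised in
a partial-exon deletion; when the deletion is in frame and small, the
result can be a truncated but functional protein rather than the
loss-of-function that nonsense variants are presumed to cause. Variants in
this configuration deserve caution before PVS1-level ("very strong")
pathogenicity evidence is applied.

The package is aimed at variant-interpretation and splicing researchers who
want a tested, reusable implementation of the screen that runs end to end
on standard file formats (FASTA, GTF, VCF, TSV) — including a synthetic
cohort generator with planted ground truth, so every stage is verifiable
without multi-gigabyte population databases.

## The screen

For each SNV on a canonical protein-coding transcript:

1. **Stop-gain calling** — the variant must convert a sense codon into
   TAA, TAG or TGA (codons assembled in transcript orientation, exon
   junctions handled). Calls in the last exon are excluded: a stop there
   generally escapes nonsense-mediated decay (NMD) and is already
   interpreted cautiously.
2. **Donor-gain candidacy** — from SpliceAI-format annotations
   (`ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL`), or
   from the package's deterministic position-weight-matrix (PWM) stand-in
   scorer, the variant is a candidate at threshold *τ* iff

   ```
   DS_DG ≥ τ      (τ ∈ {0.2, 0.5, 0.8})
   DP_DG < 3      (strand-corrected, pre-mRNA orientation)
   ```

   The DP<3 rule keeps only donors at or upstream of the stop codon —
   a donor downstream of the stop would not prevent NMD. The delta
   position refers to the last exonic base of the new junction, in a
   contiguous pre-mRNA numbering with no position zero (…−2, −1, +1…).
   Because TAA and TGA match the +2..+4 positions of the donor consensus
   MAG|GTRAGT (TAG cannot: +4 must be A), the canonical mechanism places
   the junction two positions upstream of the variant: DP = −2.
3. **Frame arithmetic** — the mis-splicing outcome is modelled as a
   deletion from the base after the new junction through the natural 3'
   end of the variant's exon: `deleted_nt = exon_end − DG_position`, in
   frame iff `deleted_nt mod 3 = 0`.
4. **Decision tree** — candidates are classified as out-of-frame /
   in-frame ≥10% of the CDS / in-frame <10% without or with protein-domain
   overlap; the plausible rescues are the in-frame <10% cases. For those,
   the predicted protein consequence is rendered in HGVS style
   (`p.(Glu1360_Ser1498delinsAsp)`-type strings), verified against a
   translation-diff of the explicitly re-spliced coding sequence.
5. **Cohort statistics** — donor-gain score bins ([0.8–1], [0.5–0.8),
   [0.2–0.5)), TAA/TGA-vs-TAG enrichment among candidates (2×2
   chi-square), the deficit of pathogenic/likely-pathogenic (LP/P)
   classifications among candidates versus other nonsense variants in the
   same genes, ClinVar-style star-rating comparisons (rank-sum W, exact by
   enumeration for small samples), and headline rates.

## Worked example

Generate a 12-gene cohort with planted rescue candidates, screen it, and
compute the cohort statistics:

```bash
splicerescue simulate --n-genes 12 --variants-per-gene 6 --seed 9 \
    --mix "NOT_CANDIDATE=0.7,CANDIDATE_OUT_OF_FRAME=0.15,CANDIDATE_IN_FRAME_GE10=0.05,CANDIDATE_IN_FRAME_LT10_NO_DOMAIN=0.05,CANDIDATE_IN_FRAME_LT10_DOMAIN=0.05" \
    --out cohort/
splicerescue screen --genome cohort/genome.fa --gtf cohort/annotation.gtf \
    --vcf cohort/variants.vcf --domains cohort/domains.tsv --out screen/
splicerescue stats --genome cohort/genome.fa --gtf cohort/annotation.gtf \
    --vcf cohort/variants.vcf --classifications cohort/classifications.tsv \
    --domains cohort/domains.tsv --out stats.json
```

`screen/summary.json` then reports, per threshold, category counts that
match the generator's ground truth exactly, e.g. at threshold 0.2:

```json
"0.2": {"NOT_CANDIDATE": 54, "CANDIDATE_OUT_OF_FRAME": 7,
        "CANDIDATE_IN_FRAME_GE10": 5,
        "CANDIDATE_IN_FRAME_LT10_NO_DOMAIN": 5,
        "CANDIDATE_IN_FRAME_LT10_DOMAIN": 1}
```

and `stats.json` contains the LP/P comparison — with this seed the
planted deficit is visible as a lower LP/P proportion among candidates
(0.72 vs 0.84; a small cohort, so the chi-square p-value of 0.30 is not
significant at this size — the power checks in the test suite use
n=500/5000):

```json
"lp_p_comparison": {"summary_a": 0.722, "summary_b": 0.844,
                    "statistic": 1.063, "p_value": 0.302}
```

In library form the same screen is three calls: `generate_cohort`,
`run_screen`, `compute_cohort_stats`. A packaged synthetic transcript with
the coding geometry of the published TSC2 example
(`splicerescue.tsc2_like_fixture`) reproduces its protein consequence,
`p.(Glu1360_Ser1498delinsAsp)`, from `c.4081C>T` with a donor gain at
delta position −2.

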
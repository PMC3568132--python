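# Methods

## Problem setting

`famexome` implements a prioritization pipeline for rare germline variants in
high-risk breast-cancer families in which the known high-penetrance genes
(BRCA1/BRCA2) have been excluded.  The design assumption is a dominant-acting,
rare, shared allele: within a family with many early-onset cases, a causal
variant should be carried by both sequenced affected members, absent from
unrelated controls and from common-variant databases, functionally
consequential, and well supported by the sequencing evidence.  Each of those
expectations becomes one filter stage; what survives is a short candidate
list that is then weighed with case-control, segregation and prediction
evidence rather than declared causal.

## Read QC

Two pre-alignment rules remove reads that are uninformative for variant
calling: more than `max_uncalled = 5` positions with no base call (N), or one
nucleotide occupying more than `max_mono_fraction = 0.70` of the total read
length (low-complexity/contamination reads).  Both thresholds are strict
("more than"), so boundary reads are kept; N is excluded from the mono-base
numerator but not the denominator.  Mates are filtered independently — no
mate rescue is modeled.  The thresholds are configuration, defaulting to the
values above.

## Allele-balance scores

Every call carries per-allele read depths and per-allele Phred-scaled quality
mass.  Two percentage-scale ratios summarize allele balance:

    DS = 100 · depth_alt / depth_ref        (Depth Score)
    QS = 100 · phred_alt / phred_ref        (Quality Score)

Both are undefined — never zero — when the reference-allele denominator is
zero or missing, and an undefined score always fails a score filter (it
cannot certify membership in a window).  The variant:reference orientation is
a deliberate choice: on a percentage scale a balanced heterozygote sits at
100, and the SNV acceptance window's upper bound of 210 only makes sense if
values above 100 (excess variant evidence) are legal.  The alternative
orientation (reference:variant) is symmetric and can be emulated by swapping
window bounds; it is not separately implemented.

## The filtering cascade

Stages, in order, with SNVs and INDELs tracked as separate funnels:

1. **detected** — heterozygous SNVs (`het_only = True` by default; a
   dominant rare allele in an outbred pedigree is expected heterozygous) and
   all INDEL calls.
2. **shared_in_family** — key-level intersection of the two sequenced
   members' sets; identity for single-member families.  The surviving record
   (evidence fields included) is the index member's copy; the index member is
   configurable and defaults to the first sequenced member.
3. **not_in_control_panel** — exclusion against the pooled (union) call set
   of the unrelated control panel.
4. **not_in_dbsnp** — exclusion against the known-variant database.
   Membership for both exclusions is allele-aware, `(chrom, pos, ref, alt)`:
   position-only matching would silently drop novel alleles at known sites.
5. **consequence** — SNVs drop `intronic`, `intergenic`, `synonymous`;
   INDELs drop `intronic`, `intergenic` only (a "synonymous" label on an
   indel is not trusted as harmless).  3'-UTR and splicing labels are
   retained.  Labels arrive as input annotation; no annotation engine is
   included.
6. **score_and_gene** — SNVs: DS and QS both defined and inside the
   inclusive window `[20, 210]`.  INDELs: DS defined and strictly `< 140`,
   variant-allele Phred mass `> 10`, caller site quality `> 10`, and at least
   3 reads supporting *each* allele.  An optional gene allowlist (cancer-
   plausible genes; user input, not curated by the package) is applied in
   the same funnel stage; gene-then-score and score-then-gene orders give
   identical counts, so the order is not configurable.

Exclusion stages commute with each other and with the consequence filter;
the stage order is fixed only for funnel accounting.

### Funnel accounting

The funnel table mirrors the study-style summary: each family's stage-1
value is the mean of its sample counts; later stages are family-level counts.
The Average row is the mean over families, rounded half-away-from-zero to
integers; the Percentage-remaining row divides the *rounded* stage averages
by the rounded stage-1 average and is reported to two decimals (half-up).
Deriving percentages from the rounded averages, not the unrounded
intermediates, is what reproduces the published summary rows exactly — the
two conventions differ at one table cell (44.285 unrounded vs 44.284 from
integers), and the printed value matches the integer-derived one.

## Threshold calibration

Score thresholds are tuned on a control panel whose calls already present in
the known-variant database act as approximate truth.  A grid — window lows
0–50 (step 5) crossed with highs 100–300 (step 10) for SNVs; DS ceilings
50–300 (step 10) for INDELs, with the other stringent INDEL criteria held
fixed — is evaluated exhaustively for *known retention* (fraction of known
calls kept; undefined-score known calls count as lost) and *total retained*.
Among grid points meeting the retention target (default 0.95) the point with
the smallest total retained wins; ties break toward higher retention, then
lexicographically smaller thresholds.  If no point meets the target the
maximum-retention point is returned flagged `meets_target = False` — which
is the expected outcome for INDELs, whose unfiltered call sets are
artifact-dominated.  The actual grid searched in the original tuning is
unknown; the default grid is a package decision, exposed in `GridSpec`.

## Case-control, segregation and prioritization statistics

Carrier counts become 2×2 **allele** tables under the rare-variant
assumption of heterozygous carriers: `a = carriers_cases`,
`b = 2·n_cases − carriers_cases`, likewise for controls.  (Allele-based, not
carrier-based: the published candidate-table frequencies are allele
frequencies, e.g. 10/6818 = 0.00147.)

* **Fisher's exact test**, two-sided, point-probability rule: p is the sum
  of hypergeometric probabilities of all tables with the observed margins
  whose point probability is ≤ the observed one (relative tolerance 1e-7
  absorbs floating-point ties).  This matches the convention of the standard
  association-analysis software family.  Implemented over `scipy.stats.
  hypergeom` pmfs; tests cross-check it against exact rational enumeration
  and against `scipy.stats.fisher_exact` independently.
* **Odds ratio** is the cross-product `(a·d)/(b·c)` with a Woolf CI,
  `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`.  Zero cells give NA (default) or
  the Haldane +0.5 correction, by policy.  The CI is reported but is not a
  headline quantity: published CIs for these candidates are not recoverable
  by Woolf from the printed counts, and the method actually used is unstated.
* **MAF screen**: a candidate observed in controls at minor allele frequency
  `carriers/(2·n)` strictly above 1% (configurable) is discarded.
* **Segregation**: among affected relatives available for typing with known
  carrier status, the carrier fraction; the variant segregates at fraction
  ≥ 0.5 (inclusive boundary, configurable).  Affected non-carriers diagnosed
  at ≥ 70 years (configurable; the literature exemplar is a 76-year-old
  non-carrier in a CHEK2 1100delC family) are flagged as candidate
  phenocopies rather than counted as evidence against the allele.
* **Prioritization**: selected iff (OR > 2 *or* absent from controls) and
  damaging in ≥ 1 predictor and (segregation passes or was not assessable);
  output ranked selected-first, then OR descending with NA last.  No
  multiple-testing correction is applied, matching the exploratory design.

## Synthetic data

The generators exist so the whole pipeline runs and is tested without any
sequencing download.  Defaults emulate the seven-family study design:
family sizes (2,2,2,2,1,1,1); per-sample heterozygous SNV counts uniform in
[26 500, 30 700] and INDEL counts in [25 200, 36 200] (inside the published
per-sample ranges); 5% extra homozygous SNVs; within-family sharing 31% of a
member's background (binomial); control-panel membership 0.82 and database
membership 0.87 per site, drawn independently, which sheds variants at
roughly the published stage rates.  Evidence models: database-member SNVs
draw depths 8–25 with alt/ref ratios in [0.5, 1.5] (DS, QS ≈ 50–150), while
artifact calls draw shallow reference depths (0–5), unrelated alt depths and
low qualities, giving heavy-tailed, often-undefined scores; INDEL evidence
is a 25% true / 75% artifact mixture regardless of membership, so stringent
INDEL criteria retain only a minority of known calls — reproducing the
qualitative SNV-versus-INDEL calibration asymmetry.  One implanted causal
variant per family (shared, novel, nonsynonymous, allowlisted gene,
filter-passing evidence at a reserved coordinate) provides a recovery truth.

Deliberately **not** modeled: reference-genome context, alignment and
mapping quality, LD/haplotype structure, indel left-normalization ambiguity,
population stratification, relatedness beyond the sharing fraction, and any
correlation between database membership and allele frequency.  Passing tests
therefore demonstrate the pipeline's *logic* (filters, accounting,
statistics) at realistic magnitudes, not calling accuracy on real exomes.

All generators are pure functions of `SyntheticConfig` (seed included);
identical configs produce byte-identical files.

## Numerical choices and degenerate inputs

* Rounding: funnel averages half-away-from-zero to integers; percentages
  half-up to 2 decimals (`decimal.Decimal`, not banker's rounding).
* Undefined DS/QS (zero/missing reference evidence) fail score filters; an
  all-N read has mono-base fraction 0; an empty site set is an identity
  filter; an empty variant table loads as an empty list.
* Boundary semantics follow the printed wording: read-QC thresholds strict,
  SNV score window inclusive, INDEL DS ceiling and quality minima strict,
  INDEL read support inclusive, MAF ceiling strict, segregation fraction
  inclusive.
* Ties in calibration break deterministically (retention, then thresholds).
* Fisher p is clamped to ≤ 1; the point-probability comparison uses relative
  tolerance 1e-7.

## Problem sizes

The test suite and the acceptance script run the synthetic study at two
scales: the default study-scale magnitudes (one generation, ~650 000 calls)
for magnitude and funnel checks, and scaled-down cohorts (~100–160 calls per
sample, 100 seeded replicates) for the brute-force-equivalence, recovery and
determinism suites, where the oracle is evaluated per variant.  The
exhaustive Fisher sweep covers all 134 030 tables with total ≤ 40.

## Known limitations

* Consequence and gene annotations are consumed as given; no annotation
  engine, transcript model or predictor is bundled.
* Indel calls are compared as written; representation differences between
  callers (left-alignment) are not normalized.
* The gene allowlist is user input; the original manual gene-function
  curation is not reproducible and not attempted.
* Published headline candidate lists depend on real exome data and manual
  curation and are out of reach of synthetic reproduction; the package
  reproduces the arithmetic that is closed over printed inputs and the
  pipeline's structural properties.
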
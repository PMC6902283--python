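# Methods

## Composite denominators

A case can only contribute an abnormality that its tests could have found.
The package therefore computes two per-setting denominators:

- **chromosomal**: cases with karyotype or aCGH, plus FISH-only cases run on
  the common-aneuploidy panel (probes for chromosomes X, Y, 13, 18, 21 — a
  panel able to return a chromosomal diagnosis).
- **pCNV**: cases with aCGH, plus FISH-only cases run on a targeted
  microdeletion/microduplication panel.

A single rule covers both settings; in the bundled reference census it
yields 3,608/1,004 (prenatal) and 4,443/3,276 (pediatric).  Numerators are
restricted to denominator-eligible cases, so an ADR is always a proper
proportion.  The simulation module demonstrates why this construction
matters: when only a fraction of cases receive aCGH, the pCNV ADR computed
on the pCNV denominator remains an unbiased estimator of pCNV incidence
(times assay sensitivity), independent of the aCGH assignment fraction.

## Abnormality taxonomy and classification

Findings are ISCN-subset karyotype strings, CNV interval descriptors, or
pre-coded leaves.  The karyotype grammar covers modal number, sex
complement, ±chromosome tokens, and del/dup/t/rob/inv/i/r/add/der/+mar
events with breakpoint arguments, including mosaics (`45,X/46,XX`).  It is
deliberately not a full ISCN grammar — only the subset needed for the
spectrum-table classes; anything else raises a parse error rather than
passing silently as normal.

Classification rules, in order:

1. modal 69 → triploidy; 92 → tetraploidy;
2. autosomal gains/losses → trisomy 21/18/13 or other autosomal aneuploidy
   (aneuploidy outranks structure, so a translocation trisomy 21 counts as
   trisomy 21);
3. abnormal sex complement → the specific sex-chromosome aneuploidy leaf;
4. structural events: any imbalance-producing event (del, dup, add, marker,
   ring, isochromosome, der) → unbalanced rearrangement; a Robertsonian
   fusion at modal 45 → balanced Robertsonian; remaining t/inv → other
   balanced.

Mosaics are classified by the first abnormal clone; the mosaic fraction is
ignored.

CNV intervals (1-based, closed, GRCh37 lengths bundled) classify by a fixed
decision order: span > 10 Mb → unbalanced rearrangement (karyotype-visible
scale; the conventional bound for "submicroscopic" is 5–10 Mb and the upper
end is used as the inclusive default, configurable); else ≥50 % reciprocal
overlap with a recurrent genomic-disorder locus → recurrent disorder; else
overlap with a terminal chromosome window → subtelomeric pCNV; else
interstitial pCNV.  Terminal windows default to the upper ends of the
conventional ranges — 15 Mb for autosomes 1–12 and 10 Mb for 13–22 — and the
sex chromosomes use the large-chromosome window (they are comparable in size
to mid-range autosomes; the convention enumerates autosomes only).  Window
membership is any-overlap by default, with a containment policy available;
both choices are exposed because reporting practice varies.

The 22-locus table (22q11.21, 15q11-q13, 16p11.2, Xp22.31, 1q21, 7q11.23,
16p13.11, 17q12, 3q29, 17p12, 17p13.3, 8p23.1, 5q35, 15q13, 2q13, 17p11.2,
7q35-q36, 17q21.31, 17q11.2, 22q13.33, 4q35, Xq28) ships as editable package
data with cytoband-anchored GRCh37 boundaries.  These are configuration
defaults covering the low-copy-repeat critical regions, not authoritative
coordinates; locus assignment is dosage-invariant (a deletion and a
duplication of the same interval map to the same locus).

A case's per-finding leaves are all retained; the single *primary* class is
chosen by group precedence numerical > structural > pCNV (configurable).  A
case with both a chromosomal abnormality and a pCNV increments both ADR
numerators — the two spectra are separate questions.

## Rates and comparison

ADR and RF are kept at full precision internally and rendered half-up at two
decimals, with ratio rendering done through decimal arithmetic on the
integer counts so exact ties (e.g. 22/320 = 6.875 %) round predictably.
Within the pCNV spectrum, locus rows split cases by dosage (del-only,
dup-only, del & dup).  Setting contrasts use the Pearson chi-square on the
2×2 detection table without continuity correction (the default; correction
available behind a flag — at these cell sizes the significance conclusions
are insensitive to the choice).  ADRs with different denominators are never
summed.

The bundled reference spectrum tables carry a note column marking the few
aggregate cells whose published values equal the sum of already-rounded
sub-rows rather than a direct rounding (plus two exact-tie cells rounded
down and one cell inconsistent with any rounding of its counts, asserted at
its recomputed value); the golden tests check the documented mechanism for
those cells and direct equality everywhere else.

## Prevalence calibration

Both calibration panels use the pediatric setting, where referral is
phenotype-driven and the caseload approximates a prevalence-proportional
sample.  Prevalence (percent) is regressed on ADR (percent) by closed-form
OLS; R² is the squared Pearson correlation and the slope test uses
t = r·√((n−2)/(1−r²)) on n−2 df.  Two conventions, verified by round-trip
against the tabulated extrapolations, matter for reproducibility:

- coefficients are applied at their quoted 4-decimal rounding, and ADRs
  enter at their 2-decimal table rendering (`as_line(ndigits=4)` and
  `build_calibration_sets(adr_ndigits=2)`; full precision available);
- deletion-syndrome ADRs count every case carrying a deletion at the locus,
  i.e. del-only plus del-&-dup cases.

The aneuploidy panel (trisomy 21, 45,X, trisomy 18, trisomy 13 against
live-birth incidences) refits exactly.  For the five-syndrome
genomic-disorder panel the reported prevalences are ranges; the midpoint is
the default resolution policy (low/high available), and since the exact
pairs behind the quoted coefficients (slope 0.0348, intercept 0.0039) are
under-determined by those ranges, that line ships as a fixed reference
constant used for downstream extrapolation rather than being refit.
Predictions at or below zero raise an out-of-range error: the line is only
trusted inside its calibrated span.  No uncertainty intervals are attached
to extrapolated prevalences (point estimates only).

## Diagnostic efficacy

The served-population model defaults to 2,000,000 people × 1 %/yr birth rate
× 10 years = 200,000 newborns, i.e. 20 units of 10,000; detected cases per
10k is the 10-year count ÷ 20 and expected cases per 10k is 10,000/N for a
1-in-N incidence.  Efficacy = 100·detected/expected, banded at 90 and 50.

Two modes are exposed.  `exact` keeps full precision.  `replicate`
reproduces the reference table's arithmetic: each column is first rendered
at that row's tabulated precision and efficacy is computed on the rendered
values; a bundled profile carries the row precisions and three documented
aggregate expected-value overrides (64, 33, 97 per 10k), one
detected-count override (the published PWS/AS figure implies 17
syndrome-confirmed pediatric cases of the 31 tabulated 15q11-q13
deletions), and one single-cell rendering override (prenatal 45,X).
Overrides never apply outside replication mode and never to cohorts that
cannot support them.  DGS detected counts use deletion cases only.
Statewide coverage fractions are computed as detected/(births×incidence),
with expected-value overrides available where an externally quoted
expectation differs from the computed one.

## Synthetic cohorts

The generator draws, per case: a calendar year, a test combination from the
setting's assignment mix (defaulting to the reference census proportions:
e.g. under a third of prenatal cases have aCGH, pediatric testing is
microarray-first), an underlying abnormality from the incidence spectrum
(default: the reference cohort's per-category rates, referenced to the
appropriate composite denominator), and per-test detection outcomes.  The
default sensitivity model is structural — karyotype sees chromosomal classes
but no pCNVs; aCGH sees all dosage imbalances but no balanced
rearrangements; aneuploidy FISH sees only X/Y/13/18/21 aneuploidies;
targeted FISH only its configured loci — because true per-assay
sensitivities are not part of the reference conditions; every probability is
a config hook.  Detected chromosomal abnormalities are rendered as ISCN
strings, pCNVs as coordinates sampled inside the correct region class
(recurrent CNVs sit exactly on locus intervals; sporadic CNVs are uniform
draws with log-uniform 0.1–5 Mb sizes, rejection-sampled to stay in class),
so the full parsing/classification path is exercised.  Co-occurring
abnormalities are generated with a small configurable probability (default
0.001) to exercise the precedence logic.

What the generator does not emulate: referral-indication structure (maternal
age, ultrasound findings), prenatal screening cascades, prenatal→pediatric
follow-up linkage, mosaicism fractions, and realistic continuous sensitivity
curves.  Passing recovery tests therefore validate the estimators under the
stated sampling model, not the clinical representativeness of any cohort.

The deterministic `reference_cohort()` is different: it rebuilds the exact
published census and spectrum counts of the 10-year reference series from
bundled data tables (chromosomal abnormalities placed on karyotyped cases,
pCNVs on aCGH-tested cases, del-&-dup cases as two findings at one locus)
and is the golden input for the end-to-end tests and the acceptance script.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely at desk scale: the
reference cohort is 8,117 cases, recovery simulations use 10³–10⁴ cases with
2–3 replicates (replicates reseed deterministically from the spec seed), and
the CNV classification oracle checks 1,000 random intervals; the whole suite
completes in seconds.  Display rounding is half-up on decimal
representations throughout; statistical tails come from scipy (chi-square,
t).  Degenerate inputs fail loudly: zero denominators, empty karyotype
strings, out-of-build coordinates, all-equal calibration ADRs and
non-positive extrapolations raise typed errors rather than returning
sentinel values.

## Known limitations

- The ISCN parser covers the spectrum-table subset only (no derivative
  breakpoint arithmetic, no sub-band precision, no uniparental disomy).
- Locus boundaries and terminal windows are conventions; results at the
  margins (a CNV straddling a window edge, a partial locus overlap near
  50 %) depend on the configured thresholds.
- Prevalence extrapolation assumes the pediatric caseload samples disorders
  proportionally to prevalence with equal ascertainment — known to fail for
  mildly phenotypic disorders, which is exactly the under-detection the
  comparison against reported incidences is designed to expose.
- The efficacy table assumes no overlap between prenatal and pediatric
  detections of the same individual.
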
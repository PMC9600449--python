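# Methods

## Scope and data model

The package treats a targeted amplicon panel (52 B-cell-lymphoma genes;
the bundled default layout tiles each gene with 4 amplicons and CDKN2A
with 8, the count being configurable because panel designs differ) as
two parallel measurement channels: per-amplicon read counts, used as a
copy-number proxy, and annotated small-variant calls. Amplicon intervals
follow BED conventions (0-based, half-open); variant positions are
1-based (VCF convention); the mismatch is deliberate so that each file
matches its standard exactly. Clinical time is always months from
diagnosis; calendar dates never enter the package.

## Sample and variant QC

Two sample-level rules guard against failed FFPE libraries: mean
amplicon read count < 100, and Ts:Tv > 5 among the sample's raw SNV
calls (cytosine deamination in FFPE tissue produces C>T/G>A artefacts,
inflating transitions). "Read count" is interpreted as the mean over the
sample's panel amplicons — the exclusion is phrased per sample, and the
mean is the statistic an amplicon-depth report provides. Ts:Tv is
computed on raw, pre-filter calls, since the artefacts it is meant to
catch are largely removed by the later VAF filter; the QC report records
this provenance. A sample whose calls contain transitions but no
transversions has an effectively infinite ratio and fails; a sample with
no SNVs at all has an undefined ratio and is not failed on it.

Variant retention requires VAF ≥ 0.10 and a reportable class: class 4/5
outright; class 3 only when CADD-PHRED ≥ 20 (a conventional damaging
cut-off, exposed in the config because reasonable analysts differ) or
when ≥ 2 of the four in-silico predictors (SIFT, PolyPhen, LRT,
MutationTaster) call the variant damaging ("multiple" read minimally as
two). Class-3 variants with no annotation at all are dropped as
unevaluable and logged as such — a missing annotation is never treated
as zero. The driver hotspots MYD88 L265P and CD79B Y196 (any
substitution at that residue, since clinically the residue, not the
specific alt, is reported) are exempt from the VAF floor and retained at
any positive VAF; this matters because hotspot clones are detected well
below 10% VAF in low-purity biopsies. Every decision is logged with the
rule that fired, and the cascade is idempotent by construction.

## CDKN2A loss calling

Each library is normalized by the median count over **all** panel
amplicons (not only the target gene's), making the statistic depth
invariant. Per target-gene amplicon, the systematic efficiency is
estimated from a panel of normal libraries as the mean of log2
normalized coverage; the log scale stabilizes multiplicative noise. The
normal interval at level `ci_level` (default 0.99) is a **prediction
interval** for one new library:

    mean ± t_{n-1,(1+ci)/2} · s · √(1 + 1/n)

on the log2 scale, back-transformed. A plain normal approximation
(mean ± z·s) is also available (`method="z"`), but with n = 18 normal
libraries it ignores estimation error and covers held-out normals at
only ≈ 0.977 instead of 0.99 — the t-based construction is the default
precisely so that the stated 99% level is the level the caller operates
at. Empirical quantiles are not an option at n = 18 for a 99% interval.
Libraries with zero coverage at an amplicon are excluded for that
amplicon with a warning; fewer than 3 usable libraries is an error.

A tumor library is normalized the same way, divided by the per-amplicon
efficiency factor, and compared against the lower bound only (the method
targets deletions; amplification calling is out of scope). Loss is
called when **more than 2 — i.e. ≥ 3 — consecutive** amplicons, in
genomic order and never joining across chromosomes, fall below their
bounds. Dosage arithmetic for expected signal: a monoallelic loss in a
tumor of purity ρ leaves 1 − ρ/2 of the diploid signal; biallelic,
1 − ρ. At the default noise level the caller therefore resolves
monoallelic losses down to ρ ≈ 0.55 and biallelic losses far lower,
while a loss-free sample triggers in < 10⁻⁶ of cases (per-amplicon lower
tail 0.005; a ≥ 3-run among 8 amplicons is rare by enumeration).

## Paired-biopsy stability

Alterations are matched by canonical keys: exact site
(gene, chrom, pos, ref, alt) for small variants — VAF is ignored, as
clonal fractions are not tracked — and gene-level keys for CNV loss and
rearrangements, which cannot collide with variant keys. The union of
both time points is partitioned into stable / lost / gained; the
partition and the lost↔gained swap symmetry are asserted, not assumed.
A gene that loses one variant and gains another of the same mutation
type is flagged `same_gene_different_site`, the pattern expected from
ongoing somatic hypermutation rather than clonal replacement; both
members still count once as lost and once as gained. Driver stability
(MYD88-mut, CD79B-mut, CDKN2A-loss) is assessed at hotspot level
whenever a hotspot was observed at either time point, else at gene
level. Cohort tallies can be restricted to drivers or non-drivers;
because keys alone do not identify hotspots, the hotspot key set is
collected from the underlying samples.

## Cohort summarization

The oncoprint is a gene × patient categorical matrix
(hotspot_mutation / other_mutation / loss / rearrangement / multiple /
none), genes ordered by descending alteration frequency; its marginals
are asserted equal to the frequency table's. Driver coverage is the
fraction of patients with a MYD88 or CD79B mutation and/or CDKN2A loss;
an unassessable CDKN2A status contributes false to its disjunct rather
than propagating missingness. Relapse-group contingency tables use the
Pearson chi-square without continuity correction (the default choice for
2×2 cohort comparisons; Yates is available); a table with an empty
margin returns an undefined flag instead of a p-value. The
mutational-burden dichotomy splits at the cohort median computed from
the data at hand, never a hard-coded 6. A feature-export stub produces
the per-sample table an external DLBCL genetic-subtype classifier
expects; classification itself is a web service and out of scope.

## Survival

Endpoints: PFS = relapse/progression or lymphoma death; OS = death of
any cause; DSS = lymphoma death with other-cause deaths censored at the
death time (the standard cause-specific convention; competing-risks
modeling is out of scope). All endpoints are administratively censored
at 60 months. Kaplan–Meier estimation and log-rank tests go through
lifelines. The per-gene univariable Cox screen fits one binary covariate
at a time with a scalar Newton–Raphson on the Efron partial likelihood;
this in-package solver exists because the screen is run tens of
thousands of times in null calibrations, and it is verified against
lifelines' CoxPHFitter to ~10⁻⁴ on identical data (with and without
ties) in the test suite. Genes with fewer than `min_carriers` (default
2) mutated patients, or mutated in everyone, are not testable; fits that
diverge (separation) are flagged non-estimable and excluded from the
Bonferroni denominator m, which is recorded on every result. Bonferroni
uses m = number of estimable tested genes, the defensible middle ground
between "all 52 panel genes" and "all mutated genes".

## Synthetic-data generator

The generator is the package's study-conditions module, not a test
helper. Defaults encode the cohort the pipeline targets: 57 patients,
16 paired, 18 normal libraries, mean amplicon depth 1000.

* **Coverage.** Counts are negative-binomial with size r
  (`depth_dispersion`, default 200 → ≈ 7.7% CV at depth 1000 — the
  residual per-amplicon noise of a well-behaved amplicon assay after
  normalization, slightly above the Poisson floor of 3.2%) around
  depth_mean × efficiency × dosage. Per-amplicon efficiencies are
  log-normal (sd 0.2 on the log scale) and **shared across all samples
  generated from one config**, which is what makes a panel of normals
  informative. Dosage implements the purity dilution above.
* **Variants.** Hotspots are emitted with marginal per-patient
  probabilities (MYD88 L265P 39/57; CD79B Y196 0.42, a value the printed
  tables do not pin down); non-hotspot gene mutations are independent
  per gene with probabilities calibrated so the marginal mutated-gene
  frequencies match the cohort table (e.g. MYD88 0.79 = 1 − (1 − 0.684)
  (1 − 0.335)). Somatic VAFs are Beta(4, 6) (mean 0.4); FFPE artefacts
  are exclusively C>T/G>A transitions at VAF < 0.10 with class ≤ 3,
  Poisson(2) per sample, so the Ts:Tv rule is exercisable by
  construction; benign background polymorphisms (class 1/2,
  heterozygous-like VAF, Poisson(12) per sample) reproduce the fact that
  raw caller output is dominated by non-reportable calls, which is what
  stabilizes a sample's Ts:Tv statistic.
* **Paired evolution.** Driver hotspots and CDKN2A loss persist with
  probability 1 by default — the generator's null hypothesis is driver
  stability, with an override for sensitivity analyses. Non-driver
  variants persist with `retention_prob` (default 0.6, a free parameter
  chosen near the observed shared fraction of pooled variants, not a
  published value); SHM-target genes (PIM1, MYC, BTG1, CDKN2A) gain
  Poisson(0.4) new point variants each; CDKN2A loss is acquired with
  probability 2/16.
* **Survival.** Event times are exponential with rate
  λ₀·exp(Σβx), λ₀ = ln 2 / 44 per month (median OS 44 months), with
  independent exponential censoring (default rate 0.01/month).

Reproducibility: all draws derive from the config seed; per-sample
substreams are keyed by CRC32 of the sample id, so outputs are
bit-identical across runs and independent of sample order.

What the generator does **not** emulate: read-level errors and sequence
context, indel realism beyond type labels, purity-driven VAF
co-variation between variants of one tumor, inter-amplicon correlation
from multiplex PCR competition, GC-dependent efficiency drift between
batches, and clonal hierarchy (gains/losses are independent events, not
a phylogeny). Tests passing on this generator therefore demonstrate that
the algorithms implement their stated rules and recover known structure
at realistic noise — not that the thresholds are optimal for any
particular real dataset.

## Reconstruction cohort

Per-patient data of the motivating study exist only as raw reads and
figure images, so `lymphpanel.reconstruction` builds a clearly-labelled
**synthetic** 57-patient cohort whose marginal counts equal the printed
ones (MYD88 45 with 39 L265P, CD79B 31 with 24 double-mutated, CDKN2A
loss 36, MYC rearranged 14 with one BCL6 double hit, 39 vs 18 relapse
split with MYC 14/39 vs 2/18, median burden 6, range 0–26, 21/16/20
lymphoma-death/other-death/alive). It is a regression target for the
summarizer's arithmetic, not data. The printed per-gene counts are
mutually inconsistent with the printed NF-κB-pathway union (45 + 31 −
24 = 52 ≠ 48), so the per-gene counts are honoured and the pathway
aggregate computes to 52/57. Outcome labels are assigned through a fixed
permutation so that clinical status is uncorrelated with the index-based
gene assignments; the survival screen on this fixture is therefore null
by construction, as a fixture should be.

## Verification sizes and numerical choices

The acceptance checks run: filter-cascade equivalence against an
independent straight-line predicate on 10⁴ randomized records; CNV
operating characteristics on 200 simulated samples per condition
(monoallelic ρ = 0.6, biallelic ρ = 0.4, loss-free, and engineered
exactly-2-run samples); interval calibration on 10⁴ held-out normal
libraries (coverage 0.99 ± 0.01); paired partition/symmetry on 10³
random pairs and the closed-form stable fraction on 1000 simulated
patients; Kaplan–Meier against a hand-computed product-limit table; Cox
recovery of HR 6.52 at n = 2000 within 10% on the log scale; and the
null family-wise error of the Bonferroni screen over 500 replicates of
52 genes at n = 200. The FWER point estimate is compared against its
3-sigma binomial sampling bound for a true rate of 0.05 (a point
assertion on a 500-replicate estimate would reject a calibrated screen
~40% of the time). Newton iterations stop at |Δβ| < 10⁻⁹; |β| > 20 is
treated as separation. Chi-square tests agree with the textbook formula
to 10⁻¹⁰. Ties in Cox use the Efron approximation throughout.

## Known limitations

Single-gene CNV calling only — no segmentation, no allele-specific copy
number. The Ts:Tv filter is a blunt instrument at low raw-call counts
(the ratio of < 10 calls is noisy); real pipelines see hundreds of raw
calls per sample, which the background-variant rate only approximates.
Wald p-values from the Cox screen are asymptotic and can misbehave at
very low carrier counts; `min_carriers` exists for that reason but 2 is
permissive. The reconstruction cohort supports marginal-level regression
tests only; any joint-distribution statistic computed from it (e.g.
gene co-occurrence) is an artefact of the deterministic assignment.
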
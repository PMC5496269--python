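# Methods

## The interpretation model

`saamp` operationalizes a three-part interpretation workflow for IDUA
variants. First, a variant observed in a patient is looked up in a curated
severity knowledge base; a hit yields a literature-derived severity set.
Second, variants absent from the knowledge base are scored by an ensemble
of general-purpose effect predictors and classified pathogenic/benign —
the ensemble cannot grade *severity*, so such alleles contribute "unknown"
severity to phenotype inference, and the classification is recorded as
supporting evidence only. Third, the severities of the two alleles combine
into a clinical phenotype prediction under the recessive-disease rules
described below.

## Predictor thresholds

Seven predictors contribute categorical calls. The thresholds are the
tools' published operating conventions:

| tool     | scale                  | damaging call        | rule         |
|----------|------------------------|----------------------|--------------|
| SIFT     | tolerance index [0,1]  | deleterious          | ≤ 0.05       |
| PolyPhen | PSIC score [0,1]       | probably_damaging    | > 0.85       |
| I-Mutant | ΔΔG (kcal/mol)         | large_decrease       | < −0.5       |
| PROVEAN  | alignment score        | deleterious          | < −2.5       |
| PANTHER  | subPSEC                | deleterious          | < −3         |
| SNPs&GO  | disease probability    | disease              | > 0.5        |
| PHD-SNP  | disease probability    | disease              | > 0.5        |

All boundaries except SIFT's are strict, so a boundary score falls in the
non-extreme class (ΔΔG of exactly −0.5 is neutral, PROVEAN −2.5 is
neutral, PSIC 0.85 is possibly_damaging, probability 0.5 is neutral). SIFT
is the deliberate exception: the tool's own convention is ≤ 0.05 →
deleterious, and the packaged score table contains a variant (F143L,
rs373342547) printed with score 0.05 and a Deleterious label. Prose
descriptions of SIFT sometimes state the rule as a strict inequality; the
data and the tool convention win here, and the package's concordance test
(re-deriving every printed label from its numeric score, zero mismatches
over all 93 × 4 labels) passes only under ≤.

PolyPhen's *possibly_damaging* and I-Mutant's *large_increase* count as
not-damaging for funnel and PI purposes: the screening design retains only
the strongest category of each tool.

## Pathogenic index and cutoffs

PI = damaging_count / available_count, kept internally as an exact
`Fraction`. The two operating points are defined on counts of seven —
pathogenic at ≥ 3 damaging calls (sensitive) or ≥ 4 (specific) — and the
familiar decimals 0.43 and 0.57 are *display roundings* of 3/7 and 4/7
(half-up, two decimals). A literal `PI ≥ 0.43` comparison would
misclassify the 3-of-7 boundary because 3/7 = 0.4286 < 0.43; classification
therefore always uses the count rule. With fewer than seven tools
available the threshold generalizes to k = ⌈c · n_available⌉ (c = 3/7 or
4/7), which reproduces the seven-tool behaviour exactly and errs toward
re-testing rather than silently changing the operating point; a profile
with zero available tools is an error, not a benign call.

Benchmark evaluation reports the confusion matrix with sensitivity =
TP/(TP+FN) and specificity = TN/(TN+FP); an empty truth class makes the
corresponding metric undefined (`None`), never 0. Percentages for display
are rounded half-up to whole percent.

## Screening funnel

The funnel applies SIFT, PolyPhen, I-Mutant and PROVEAN as successive
filters and finishes with a conjunction of PANTHER, SNPs&GO and PHD-SNP.
Each stage is an independent per-variant predicate, so permuting the first
four stages cannot change the final survivor set (property-tested
exhaustively over all 24 orders on the packaged tables); the funnel's
value is the per-stage attrition bookkeeping. Two call modes exist because
published tables occasionally contradict themselves: label mode trusts
printed categorical labels; threshold mode re-derives calls from numeric
values. The packaged consensus table contains one variant (G265R,
rs369090960) labelled Disease with probability 0.12 — label mode keeps it
(28 survivors), threshold mode drops it (27), and the conflict is reported
by the profile rather than resolved silently. A profile missing a stage's
tool is eliminated with a distinct "not evaluated" mark by default;
`strict=True` turns that into an error naming the variant and stage.

## Severity knowledge base

The knowledge base transcribes the published severity tables cell-for-cell
into two TSVs (missense+nonsense; splicing+deletions/insertions), with
columns name / printed name / class / severity set / low-reliability flag /
source table. Conventions:

* Class follows table placement, not name syntax: stop-loss (X654C/G/R)
  and start-loss (M1T, M1I) entries sit with missense; `3308del12` and
  `c.1-2C>G` with splicing; `D444/445` (stored verbatim, no position) with
  deletions/insertions. Under this convention the category totals are 22
  nonsense (all severe), 32 splicing, 45 deletions/insertions.
* Multi-valued cells ("mild, intermediate") become severity sets; "unknown"
  is a singleton set; superscript-flagged entries get
  `low_reliability=True` (8 entries).
* Lookups are case-sensitive after whitespace normalization, with a
  case-insensitive fallback that warns.

The source text's prose summaries do not all match its printed tables. The
transcription carries 183 entries (84 missense) against a prose claim of
185 (86 missense) — the missense/nonsense table's last row ends after a
single cell — and the prose severity breakdowns for splicing (20/5/1/4)
and deletions/insertions (38 severe) are not exactly recoverable from the
printed cells, which include dual-labelled entries ("intermediate,
severe") and the two category reassignments above. The package's position
is that printed cells outrank prose tallies; `validation_report()` (and
`saamp kb-validate`) reports both sides of every discrepancy — including
the screen table's 91-row caption vs 93 printed rows and the miRNA-site
counts — without asserting either.

## Diallelic combination

Atomic severities combine by four rules: severe×severe → Hurler;
mild×severe → Scheie and intermediate×severe → Hurler-Scheie;
intermediate×intermediate → {Hurler-Scheie, Scheie}; any mild allele →
Scheie. The any-mild rule takes precedence, making mild×intermediate an
unambiguous Scheie; it agrees with the mild branch of the second rule, so
no pair is rule-dependent. Any unknown severity propagates to an unknown
phenotype. Set-valued severities combine by Cartesian closure — the union
of atomic results over all pairs — because collapsing a multi-valued
curation to a worst case would fabricate certainty. The combination is
total and symmetric over all 4×4 atomic pairs (brute-force asserted).

## UTR annotation

A UTR variant flags as functionally significant when its recognized
regulatory element differs between alleles; "no pattern" is an explicit
`None`, a first-class state distinct from an empty string, so both element
loss (IRES → none) and gain (none → 15-LOX-DICE) flag. Polymorphic miRNA
target sites flag when class C (site created) or D (conserved site
disrupted); N (non-conserved disruption) and O (ancestral allele
undetermined) do not. The module annotates supplied records; motif
discovery and seed matching belong to the upstream databases.

## Synthetic benchmark generator

The generator emulates the structure of a curated benchmark — n_pathogenic
+ n_benign variants, each with up to seven binary tool calls — not the
tools' numeric score distributions (binary calls are all the PI consumes).
Defaults: per-tool sensitivity = specificity = 0.85 (a plausible
single-tool operating point that leaves the ensemble visible headroom),
no missingness, independent tools, legacy-style synthesized names (which
double as parser fuzz input). Label balance is exact and output is
byte-reproducible given the seed. Under independence the ensemble metrics
have closed binomial forms — sensitivity at cutoff k is P(X ≥ k) with
X ~ Binomial(7, 0.85), specificity is P(Y < k) with Y ~ Binomial(7, 0.15) —
and the test suite checks observed metrics at k = 3, 4 on a 1000+1000
benchmark against these within 3σ Monte-Carlo bands. An optional
correlation knob (shared latent per-variant difficulty, logistic link)
exists because real predictors trained on overlapping data correlate; it
defaults to off and is an extension beyond the published design.

What passing these tests shows is internal consistency and correct
arithmetic under the independence model; it does not certify real-world
operating characteristics, because real per-tool errors are correlated and
the curated benchmark's per-tool outputs are not published. The headline
sensitivity/specificity of the curated 81+15 benchmark (94%/80% at the
sensitive cutoff; 79%/93% at the specific one) therefore cannot be
recomputed here — reproducing it would require re-running the seven
external web tools on those 96 mutations. The same applies to the upstream
285→201→149→107→93 screen attrition (upstream scores unpublished), and the
structural results (RMSD, minimized energies, surface accessibility),
which ship as data only.

## Problem sizes and numerical choices

Packaged data: 93-row screen table, 28-row consensus table, 183-entry
severity KB, 6 + 13 UTR records, 10 surface-accessibility records.
Synthetic benchmarks in tests use 1000+1000 variants (calibration) and
~1000 small random benchmarks (evaluator equivalence); both run in seconds.
Display rounding is half-up (publication style) via `decimal`, never
banker's rounding; PI comparisons are exact rational arithmetic; generator
randomness is a single `numpy` `default_rng(seed)` stream per run.

## Known limitations

* The knowledge base is a transcription of published curation; it inherits
  that curation's reliability flags and ambiguities and contains no
  post-publication mutations.
* Ensemble classification is binary; severity for novel variants is out of
  scope by design (the general-purpose predictors cannot grade it).
* The legacy-name parser does not validate HGVS, map genomic coordinates,
  or handle transcripts; `D444/445` -style names are preserved verbatim
  with their table-assigned class.
* No external predictor is invoked; all scores must be supplied (or come
  from the packaged tables).
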
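# Methods

## Station model

Nodal stations are string codes mapped to one of three distance bands:
locoregional `[0, 5]` cm, intermediate `(5, 10]` cm, central `(10, ∞)` cm.
"Within 5 cm" is read inclusively; the convention lives in one function
(`station_map.classify_distance`) so a different reading is a one-line
config change. The shipped registry is illustrative: it carries the two
codes that matter for the motivating cohorts (241 for sigmoid, 251 for
superior-rectum tumors), JSCCR-flavoured codes elsewhere, and guarantees
at least one station per band for each of the eight tumor sites. Real
staging work should supply a complete registry TSV.

## Suspicion rule

Node size bins are `(0,5)` / `[5,10]` / `(10,∞)` mm — the published bin
labels "<5", "5–10", ">10" leave the boundaries ambiguous only if the
middle bin is read exclusively, so both 5 mm and 10 mm are assigned to the
middle bin, the only consistent partition. The rule (small: all 3
criteria; mid: ≥ 2; large: always) is monotone in both size bin and
criteria count; property tests assert exactly that, plus equivalence with
an independent 24-row truth-table oracle. Suspicion is always recomputed
from size and criteria — a stored flag that disagrees is a hard load
error, because a silently inconsistent flag would corrupt every
downstream concordance statistic.

## Concordance

The matching unit is the patient-station, never the node: CT typically
sees ~60 % as many nodes as the pathologist harvests, so node-to-node
identity is undefined. Counts (CT nodes, suspicious nodes, harvested
nodes, metastatic nodes) are aggregated per patient-station; the four-way
category (positive / negative / false-positive / false-negative) follows
from whether suspicious and metastatic counts are zero or positive. SPRs
pool counts before dividing (ratio of sums, not mean of ratios) and an
SPR with zero metastatic nodes is reported as undefined (`NA`), never 0
or ∞.

The node-level 2×2 needs a histology label per CT node. Since CT nodes
carry none, a CT node counts as metastasis-exposed iff its own patient's
station contains ≥ 1 metastatic harvested node. This *station-context
reconstruction* is a modelling choice, not a measured quantity; it is the
only labelling under which CT-node-level association statistics are
computable at all, and every such statistic in this package should be
read with that in mind. Patient-level test positivity is ≥ 1 suspicious
node and disease positivity ≥ 1 metastatic node (no patient-level rule is
published; this is the natural screening convention).

Chi-square is plain Pearson by default — the published expected cells and
per-cell contributions are reproduced exactly only without continuity
correction — with Yates behind a flag. Odds ratios are (a·d)/(b·c) with
Woolf (log-normal) 95 % intervals; when a cell is zero, 0.5 is added to
every cell (Haldane–Anscombe) and the result flagged. Fisher's exact p is
available behind a flag. Zero denominators in diagnostic metrics yield
explicit undefined markers per metric.

## Odds-ratio calibration

For pattern prevalences `w`, overall metastasis rate `m` and conditional
probabilities `p`, the one-vs-rest odds ratio of pattern k is
`odds(p_k)/odds(q_k)` with `q_k = (m − w_k p_k)/(1 − w_k)`. Given targets
`r`, each `p_k` solves a strictly monotone scalar equation
(`odds(p_k) = r_k · odds(q_k)`), bracketed on `(0, min(1, m/w_k))` and
solved by Brent's method to machine precision. The solved vector must
then satisfy `Σ w_k p_k = m`; if it does not (tolerance 1e-8), the
targets are **infeasible** and the solver raises rather than returning a
distorted fit. This is not a numerical corner case: the five one-vs-rest
odds ratios of a closed population jointly determine its overall rate, so
`(w, r, m)` cannot all be chosen freely.

The study publishes prevalences for only two patterns (homogenous
43.72 %, linear 28.83 %). Completing the simplex by hand (e.g. 0.15 /
0.08 / 0.0445 for dotted / central / peripheral) makes the published
odds-ratio targets and the published overall rate 9.39 % *jointly
infeasible* — the unique solution of the five OR equations under that
completion implies a pooled rate of 0.54. The package therefore **solves**
the three free prevalences for exact joint consistency
(`complete_prevalences`). The feasible completions form a one-parameter
family (dotted roughly in [0.005, 0.013], central ≈ 0.26, peripheral
filling the remainder); the shipped default picks the member whose
dotted:peripheral prevalence ratio equals the count ratio implied by the
published confidence-interval widths — the dotted interval
(log-width SE ≈ 0.46) is far narrower than the peripheral one
(SE ≈ 1.34), implying ≈ 8.5× the effective counts. The resulting default
prevalences are (0.4372, 0.01316, 0.2883, 0.25978, 0.00155) in the order
(homogenous, dotted, linear, central, peripheral), with conditional
metastasis probabilities (0.0630, 0.4348, 0.0557, 0.1702, 0.2514); the
analytic round-trip reproduces all five target ORs to < 1e-12. A genuine
consequence of the consistency solve is that the central pattern carries
most of the non-dominant prevalence while peripheral is very rare; the
completion is what the published statistics jointly require at rate
9.39 %, not an observed distribution.

Target ORs are stored as odds of metastasis; the homogenous default is
1/1.99 because that pattern is reported as protective (the published
table prints 1.99 with the orientation only resolvable from the text).
Estimates of the protective orientation are reported as the reciprocal.

## Cohort generator

One random stream per cohort, split hierarchically per patient
(`SeedSequence.spawn`), so the first k patients are identical across
cohort sizes and runs are byte-reproducible. Per patient:

- sex ~ Bernoulli(78/112); age ~ truncated normal (65.6, 10.99) on
  [27, 88] years; tumor site ~ the published 8-site frequencies.
- harvested nodes ~ negative binomial (mean 16, dispersion 6) clipped to
  [1, 60]; the clipped median is 15. Published dispersion for this count
  is ambiguous ("15 ± 1.34" alongside range 1–60), so the family and
  dispersion are package choices targeting the median and range.
- CT-visible nodes ~ Binomial(harvested, 1079/1809).
- nodes are allocated to the patient's site-applicable stations by
  band weights (0.56 / 0.27 / 0.17, matching the locoregional share of
  CT nodes) split evenly within a band.
- the patient is node-positive with probability 38/112. Positive
  patients draw 1–4 metastatic stations (probabilities 29:6:3:1,
  locoregional-biased 0.74 / 0.17 / 0.09); harvesting and CT attention
  concentrate on metastatic stations via a ×2.5 allocation boost —
  surgical protocols deliberately harvest ringed stations thoroughly.
- harvested nodes inside metastatic stations are metastatic i.i.d. with a
  within-station rate computed **analytically** from the configuration
  (enumeration over sites, station-count draws and weighted station
  subsets) so that the expected cohort node-metastasis rate equals the
  configured 0.0939 exactly; no Monte-Carlo tuning is involved.
- CT nodes draw sizes from a log-normal (median 6 mm, log-SD 0.5)
  rejected-and-resampled outside [2, 34] mm; enhancement patterns from
  the class-conditional distributions implied by the calibration
  (`P(k|context) ∝ w_k p_k`, `P(k|no context) ∝ w_k (1−p_k)`), where a
  node's context is its station's realized metastasis label — the same
  label the analysis pipeline later reconstructs, which is what makes the
  odds ratios recoverable: one-vs-rest ORs built from class-conditional
  pattern draws are invariant to the context base rate.
- the three suspicion criteria are drawn independently per criterion
  given context (sensitivities 0.85 / 0.50 / 0.35, specificities 0.72 /
  0.93 / 0.97), chosen so the suspicion rule flags ≈ 22 % of CT nodes and
  the criteria frequencies order as published (roundness commonest).
  Inter-criterion correlation is an acknowledged extension point.

## What the generator does and does not emulate

It reproduces the marginals above and the pattern-OR structure. It does
**not** model: node-size dependence on metastasis status (sizes are
drawn independently of context, although the real cohort reports larger
nodes as more often metastatic), inter-criterion correlation,
inter-observer variation in pattern reading, per-station anatomical
asymmetries beyond the band weights, survival, or tumor dimensions.
Passing recovery tests therefore show that the *pipeline* recovers the
generating parameters under clustered, station-structured sampling — not
that the generator is a faithful digital twin of any hospital cohort.

## Problem sizes and numerics

The recovery study uses 200 cohorts of 112 patients (~1 800 harvested
and ~1 030 CT nodes each), the size at which a single study of this
design operates; medians across cohorts are reported because
small-count odds-ratio estimates are right-skewed. The large-sample
recovery check uses one cohort of 21 000 patients (~200 000 CT nodes).
Brent root-finding uses xtol 1e-15; the calibration consistency residual
tolerance is 1e-8; chi-square decomposition identities are asserted to
1e-9.

## Known limitations

- The published patient-level accuracy figures (sensitivity 80 %,
  specificity 69 %, PPV 0.42, NPV 0.92) are not derivable from the
  published node-level counts, and the published per-band and per-site
  SPRs have no published inputs; none of these are reproduction targets.
  The pipeline reports both node-level and patient-level metrics for
  whatever cohort it is given.
- The published node-level table's metastatic column (412 of 1079 CT
  nodes) exceeds the harvested metastatic count (170), which is what
  motivates the station-context labelling; how the original labels were
  constructed is not stated.
- The default station registry is a plausible skeleton, not the official
  atlas.
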
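# Methods

## Impact networks and layer decomposition

An impact network is a simple directed graph. Nodes are gene/protein
identifiers (opaque strings); an edge k → t records that perturbing
enzyme k changed the phosphorylation state of protein t in a screen.
Self-loops (an enzyme affecting its own phosphorylation) are dropped at
build time and counted: the layer definitions below are only consistent
on self-loop-free graphs, where "targeted by a kinase" cannot be
satisfied by the node itself. Duplicate edges collapse to a single
relationship — repeated phospho-peptides for the same enzyme–target pair
are treated as one piece of evidence, not as multiplicity. Nodes declared
in a universe but absent from any edge are retained so they can be
classified as outgroup rather than silently dropped.

Layering applies to the within-class (kinase–kinase) subnetwork:

| layer    | simple scheme        | stringent scheme        |
|----------|----------------------|-------------------------|
| TOP      | out > 0 and in = 0   | out ≥ 2 and in ≤ 1      |
| MID      | out > 0 and in > 0   | out ≥ 2 and in ≥ 2      |
| BOT      | out = 0 and in > 0   | out ≤ 1 and in ≥ 2      |
| OUTGROUP | out = 0 and in = 0   | otherwise (out ≤ 1, in ≤ 1) |

Both schemes are total functions of the in/out degrees, so the labels
always partition the node set. The stringent scheme's rationale is
robustness: a TOP assignment survives one spurious incoming edge
(tolerated as noise), whereas under the simple scheme a single such edge
flips TOP to MID. The converse nesting holds by arithmetic on the
thresholds: stringent-TOP ⇒ simple TOP or MID, stringent-BOT ⇒ simple
BOT or MID. Nodes matching no stringent rule are labelled OUTGROUP; the
partition stays total and downstream profiling excludes OUTGROUP rather
than the assignment dropping it.

Enzymes annotated as both writer and eraser are rejected with an error:
no principled layer semantics exists for them, and silently picking a
class would bias class comparisons. Phosphatases are not layered;
`phosphatase_placement` reports, per phosphatase, the count of impacted
kinases in each layer, phosphatase–phosphatase edges in both directions,
and incoming kinase edges, flagging enzymes with no relationships as
outgroup-grid members. Interpretation (e.g. "phosphatases mainly reach
the middle and bottom layers") is left to the caller; the placement table
is raw counts.

`restrict_to_measured` implements the rule that only measured
genes/proteins enter an analysis: unmeasured nodes are removed *before*
layering or profiling, with counts logged.

## Statistical tests

All group comparisons reduce to three procedures.

**Rank-sum (Mann–Whitney).** The reported statistic is U of the first
sample (pairs with x > y, ties ½). For combined n ≤ 20 the p-value is
exact: the full permutation distribution of U over all C(n, n₁) label
assignments, computed via `scipy.stats.permutation_test` with exhaustive
enumeration. Average ranks make the enumeration valid under ties. Above
n = 20 the normal approximation with tie and continuity corrections is
used. Exact two-sided p-values are twice the smaller one-sided value,
clipped to 1. On tie-free samples of 5–10 per group the two paths agree
within 0.02; heavily tied integer data at such sizes can push the
asymptotic path ~0.1 away from exact, which is why the exact path is the
small-sample default.

**Fisher 2×2.** Exact hypergeometric test; the two-sided p sums the
point masses of all tables no more probable than the observed one (the
dominant convention). Zero margins are rejected.

**Spearman.** Rank correlation with average ranks; t-approximation for
n ≥ 10, exhaustive pairing permutation below.

One-tailed directions are always an explicit caller argument and default
to two-sided. A data-dependent default (testing in the direction of the
observed difference) would guarantee p ≤ 0.5 under the null and is
deliberately not offered; instead the battery configuration carries the
claimed direction of each asymmetry. No multiple-testing correction is
applied by default — each comparison reports its raw p — matching how
such batteries are conventionally reported; Benjamini–Hochberg can be
applied downstream on the report table.

Significance markers: `***` p < 10⁻⁶, `**` p < 10⁻³, `*` p < 0.05, empty
otherwise; the `+` symbol variant marks group-versus-genome comparisons.

## Asymmetry battery

`run_battery` executes a configured list of (metric, kind, tail) rows
between two classes, optionally adding class-versus-background rank-sum
rows for selected metrics. Group sizes always count measured
(non-missing) values. The default plan covers abundance, essentiality,
PPI degree, responsiveness (fraction and perturbation counts), half-life,
three phosphorylation-capacity flags, conserved-site counts and NGI
counts, with tails encoding the claimed asymmetry directions (erasers
more abundant and with more NGIs; writers more essential, connected,
responsive, phosphorylatable, shorter-lived). The genome-wide background
includes the focal class by default (genome-wide denominators); a flag
excludes it by id. Per-row failures (e.g. a wholly unmeasured metric) are
recorded and the battery continues.

## Layer profiles

One-versus-rest: the focal layer against the union of the other kinase
layers, OUTGROUP excluded by default (overridable), pooled rather than
pairwise. `profile_numeric_by_layer` is by construction identical to
calling the rank-sum test on (focal values, pooled rest values); the
fraction variant likewise reduces to one Fisher table. Impact breadth is
the out-degree in the full all-target network. Phosphatases can be
profiled as a fifth group against a chosen subset of layers (default
MID+BOT).

## Dynamics model

dY^P/dt = k − p·Y^P, with kinase activity k (amount·time⁻¹) and
phosphatase activity p (time⁻¹); the unphosphorylated substrate is
assumed non-rate-limiting, so the model is linear. Closed forms:
Y^P_st = k/p; from Y^P(0) = 0, Y^P(t) = (k/p)(1 − e^(−pt));
t₁/₂ = ln 2 / p, independent of k. Consequences checked by tests: either
doubling k or halving p doubles the steady state, but only the p change
doubles the response time; scaling both rates by c preserves the steady
state and divides t₁/₂ by c.

Units are abstract (the model is scale-free). The numeric integrator is
classical fixed-step RK4 with per-interval substeps, refined by halving
until a further halving changes no grid value by more than 10⁻⁹;
divergence beyond 10× the relevant scale aborts with an error. Arbitrary
nonnegative initial conditions are supported numerically (the closed form
covers only Y^P(0) = 0). The empirical response time is the linear
interpolation of the first crossing of half the steady state. Scenario
comparisons integrate over 12 half-lives of the slower scenario, where
the trajectory sits within ~2·10⁻⁴ of steady state.

Out of scope by design: Michaelis–Menten saturation, substrate depletion,
stochastic kinetics.

## Synthetic data generator

The generator provides study conditions, not fitted models of real data.
Per class: abundance and half-life are log-normal (parameterized by
median and log-sd — abundances are positive and right-skewed like
ppm-scale proteomics data); PPI degree and NGI counts are negative
binomial (overdispersion typical of interaction counts); essentiality and
phospho-capacity are Bernoulli flags; responsiveness is zero-inflated
(Bernoulli responder status × shifted-geometric perturbation count),
matching the "differentially expressed in ≥ 1 perturbation" framing.
Missingness is missing-at-random per metric (abundance, PPI degree,
half-life), default 1.5%, since real analyses consider only measured
genes. A single global seed feeds fixed per-(class, metric) substreams,
so adding a metric never shifts the draws of existing ones.

Default yeast conditions: 137 kinases / 50 phosphatases / 4,925
background proteins; abundance medians 30.4 / 63 / 45 ppm; essentiality
23% / 10% / 18.9%; half-life medians 33 / 42 / 44 min; responsive
fractions 0.33 / 0.30 / 0.44 with mean perturbation counts 5 / 2.5 / 5;
phospho-capacity flag rates ~0.40–0.45 for kinases vs ~0.08–0.12 for
phosphatases; NGI: 67% / 74% with ≥ 1 NGI and nonzero means 2.2 / 5.
Where only a median and a rank-sum p-value are established for a metric,
the dispersion is set so the test at these sample sizes lands near that
significance level — for abundance, log-sd 1.75 makes the 137-vs-50
comparison at medians 30.4/63 significant at p ≈ 0.008. Location
parameters with no published anchor (background abundance, PPI degree
means) are plausible round values; they control effect sizes of
directional checks, not any exactly asserted quantity.

Planted networks draw edges independently within four strata (top→mid,
top→bot, mid→bot, mid→mid), then top up each TOP/MID node to `min_out`
outgoing and each MID/BOT node to `min_in` incoming edges. TOP nodes
never receive an edge, BOT nodes never emit one, OUT nodes stay isolated
— so the simple scheme inverts the construction exactly when no noise is
added. Infeasible degree floors are rejected up front. Spurious edges are
sampled uniformly from absent non-self node pairs, from a separate
substream, leaving the noise-free part byte-identical at the same seed.

What the generator does *not* emulate: correlations between metrics
within a gene (each metric is drawn independently given the class),
peptide-level mass-spectrometry structure, the degree distribution of
the real impact network (the stratified-probability model is a stand-in;
no claim of fidelity is made), and class definitions themselves.
Passing tests on synthetic data therefore validate the *machinery* —
layer inference, test exactness, direction recovery at realistic sample
sizes — not biological conclusions about any real proteome.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 200 random directed
graphs (≤ 30 nodes) for oracle equivalence of both layering schemes; 50
random planted specs for noiseless recovery; ~70 constructed TOP-node
cases for the spurious-edge robustness split; 100 random small-sample
cases each for rank-sum and Fisher enumeration agreement; 2,000 null
replicates (25 vs 25) for type-I calibration; 200 replicates of the
137/50 yeast conditions for asymmetry-direction recovery; and a 10×10
(k, p) ∈ [0.1, 10]² grid for trajectory/closed-form agreement. These
sizes give stable rates (binomial s.e. ≤ ~1.5 points on the recovery
percentages) at a few seconds of runtime each.

## Known limitations

- The exact rank-sum path enumerates C(n, n₁) assignments and is
  restricted to combined n ≤ 20; beyond that the asymptotic path is
  used even when ties are heavy.
- Fisher's two-sided "probability-mass" rule is one of several
  conventions; one-sided tests are unaffected.
- Phosphatase placement reports raw counts; it does not decide whether
  placement should use simple- or stringent-style thresholds for
  phosphatase edges.
- The battery treats essentiality (lethal-phenotype) and disease
  association as one "critical" flag column whose meaning is
  organism-specific; cross-organism pooling of that column is not
  meaningful.
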
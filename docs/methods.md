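# Methods

## The expanded alphabet and its grammar

Mammalian CpG methylation is symmetric: both cytosines of the CG/CG duplex
step carry the mark. We encode a methylated step as the two-letter unit
`mg` — `m` for 5-methylcytosine, `g` for the guanine paired with a 5mC on
the opposite strand. Because a `g` always implies an opposite-strand `m`
one position earlier, the two letters are not independent and the sequence
grammar enforces the pairing. Two validity modes exist:

* **fragment**: every `m` is immediately followed by `g` and every `g`
  immediately preceded by `m` — complete double-stranded molecules; partial
  (hemi-) methylation is out of scope by design.
* **window**: k-mers cut out of fragments may begin with `g` (the pairing
  `m` lies before the window) or end with `m` (the pairing `g` lies after
  it). A trailing `m` therefore *implies* a following `g` — an implication
  that matters for context matching (below).

Tables are keyed on the canonical member of each {k-mer, reverse
complement} pair under the fixed order `A < C < G < T < g < m`. Any fixed
total order works; this one is frozen because serialized tables key on it.
Under this grammar the pentamer universe has 1024 standard strings → 512
canonical keys, plus 950 window-valid methylated strings → 475 additional
canonical keys, 987 total; no odd-length k-mer can equal its own reverse
complement, so deduplication is exactly 2:1.

## Mining and the query tables

A shape-record pool holds per-fragment feature arrays: MGW and ProT per
base pair, Roll and HelT per step (step *k* between base pairs *k* and
*k*+1). Mining slides a pentamer window over each fragment and emits, per
window, MGW/ProT at the central base pair and Roll/HelT at window steps
2–3 and 3–4. Emission is strand independent: each window is recorded once
under its canonical key, with the two step slots swapped when the canonical
form is the window's reverse complement (step 2–3 of a pentamer is step 3–4
of its reverse complement; MGW and ProT at the central base pair read the
same from either strand). The assigned table value is the arithmetic mean
over *all* emitted occurrences in the pool — occurrences are pooled with
equal weight rather than averaged per fragment first; with balanced
designed pools the two conventions coincide, and pooling is the simpler
estimator to reason about.

Tunable mining parameters:

* `margin` (default 1 bp): window centers must lie at least 2 + margin
  base pairs from each fragment end. The geometric minimum is 2; the extra
  base pair keeps fray-affected terminal values out of the averages. The
  appropriate exclusion width for real trajectory data is not knowable from
  first principles, so it is a parameter, not a constant.
* `min_occurrences` (default 1): universe keys mined fewer times are a
  hard error at build time by default (published tables are complete);
  `on_missing="na"` downgrades this for deliberately small pools.
* windows containing any non-finite feature value are skipped entirely, so
  occurrence counts refer to fully observed windows.

## Profiles and Δshape

For a length-*N* fragment-valid sequence, MGW/ProT at position *i*
(0-based 2 … *N*−3) come from the pentamer centered at *i* — exactly
*N* − 4 defined values. A step (*i*, *i*+1) is reported by up to two
windows: the step-3–4 slot of the pentamer centered at *i* and the
step-2–3 slot of the one centered at *i*+1. The assembly rule for interior
steps is genuinely underdetermined — the table stores two estimates of the
same physical step from shifted windows — so it is an explicit policy flag
(`step_policy`): `"mean"` (default; the symmetric choice), `"left"`, or
`"right"`. Boundary steps use the single available contribution; *N* − 3
step values are defined in total. Undefined entries are NaN in memory and
`NA` in files, and profile axes keep full length so positions align with
input coordinates (1-based in human-facing reports, 0-based half-open in
BED).

Δshape is the elementwise difference between the profile of the methylated
sequence queried on the methylation-aware table and the unmethylated
sequence queried on the standard table. A sequence without marks has
Δshape ≡ 0 *by definition*, and the implementation short-circuits that case
rather than differencing two independently estimated tables whose shared
keys carry independent sampling noise.

### Context-matched ΔMGW

When a CpG contributes only one base to a query window (its C at the last
window position, or its G at the first), the mPQT key implies the
out-of-window partner base, but the plain PQT key averages over all four —
and shape depends weakly on that sixth position. Differencing the two
tables then conflates the methylation effect with a context effect. The
correction takes the unmethylated term from a CpG-context table instead:
per-position MGW/ProT means over hexamers ending in CG (`NNNNCG`; 256
keys) or, when CpGs flank the window on both sides, heptamers with CG
flanks (`CGNNNCG`). Both terms then share the implied context and the
context bias cancels; with the synthetic generator's position-6
interaction switched on, the correction is exact on a balanced pool while
the naive estimate is biased by 3η/4 (η the interaction size, the 3/4
being the fraction of flank bases the pentamer key wrongly averages over).
This matters in practice for Pbx-Hox sites, where CpGs at offsets 6/7 and
10/11 of the 12-bp site each place a single C at the edge of the window of
the adjacent AY position.

## A-tract analysis

A-tracts (≥3 A/T without a TpA step) are rigid and intrinsically narrow.
The analysis pairs per-occurrence MGW values at the tract's central base
pair between matched unmethylated and methylated pools (pairing is by
fragment identifier; per-fragment rather than per-snapshot pairing is a
choice, recorded here). Two one-sided tests of the narrowing alternative
(methylated < unmethylated) are available: Wilcoxon signed-rank (default
for the 3-bp pentamer series AAACG → TTTCG) and the paired t test (default
for the 4-bp hexamer series AAAACG → TTTTCG, MGW read at hexamer position
3). Significance stars: * for 0.01 < P ≤ 0.05, ** for 0.001 < P ≤ 0.01,
*** below. All-zero difference vectors return P = 1 directly (the
signed-rank statistic is undefined there).

## Shape-to-affinity modeling

Hexamer cleavage counts (3 bp on each side of the phosphate cleavage site)
are filtered at an absolute count ≥ 25 — applied per row, so a methylated
variant can pass while its unmethylated partner fails and vice versa —
then converted to free energies ΔΔG/RT = −ln(c/c̄). The reference c̄ is
the mean retained count of the variant class by default, with median or a
named reference hexamer as alternatives; energies are invariant to global
rescaling of counts, which is the property that matters. The exact
normalization used upstream of published cleavage tables is a preprocessing
detail we do not reproduce.

Featurization maps a k-mer to a fixed layout (k MGW, k ProT, k−1 Roll,
k−1 HelT → 22 entries for a hexamer). Windows reaching past the k-mer ends
are queried as wildcard patterns averaging over all concrete flanks, so
every internal position gets a value. The layout is serialized inside model
files to prevent silent mismatches.

`ShapeAffinityRegressor` minimizes ‖y − Xw − b‖² + λ₁‖w‖₁ + λ₂‖w‖².
Features are standardized internally (the penalties act on the
standardized scale) and coefficients are reported on the original scale;
zero-variance columns are dropped with a warning and get zero
coefficients. The λ₁ > 0 path uses cyclic coordinate descent
(scikit-learn's solver, tolerance 1e-8, deterministic ordering); λ₁ = 0
uses the exact ridge/least-squares closed form, so the unpenalized fit
agrees with the normal equations to numerical precision. Defaults
λ₁ = λ₂ = 0.01 are deliberately weak; `cross_validate_penalties` offers a
seeded 5-fold grid search when data volume justifies it. Because the model
is affine, the methylation-induced energy shift is predicted without the
intercept: ΔΔΔĜ/RT = **W**·Δshape — the linearity is the point, since it
lets the Δshape vector feed the model directly.

The Pbx-Hox comparator validates 12-mers against `NTGAYNNAYNNN` (Y = C/T),
classifies the methylated CpG offset in 1-based site coordinates (6/7,
9/10, 10/11, other), and computes ΔΔΔG/RT = −ln(a_meth/a_unmeth) per
paired record — positive values mean methylation suppresses binding.

## The synthetic generator

The generator replaces a molecular-simulation pipeline with a seeded
statistical stand-in, and its structure encodes one important consistency
requirement: the two step slots that overlapping pentamer windows report
for the same physical step must agree, or a noise-free pool could not
reproduce its own table. Truth is therefore planted at two levels —
base-pair features (MGW, ProT) as functions of the canonical **pentamer**
around the base pair, step features (Roll, HelT) as functions of the
canonical **tetramer** around the step (the context the two windows
share). A pentamer's feature tuple is assembled from these.

Planted base values: MGW ~ N(5.1, 0.35) Å, ProT ~ N(−7.0, 2.5)°, Roll ~
N(−1.0, 3.0)°, HelT ~ N(34.5, 1.5)° — the scales of B-DNA shape tables.
Methylation effects, applied on top of the demethylated context's base
value:

| effect | default | where |
| --- | --- | --- |
| Roll | +6° | the measured step is `mg` |
| ProT | −5° | the window-central base is `m` or `g` |
| HelT | −2° | an `mg` step is adjacent to the measured step |
| MGW | −0.3 Å | the window carries any mark |

Each applied effect adds a per-context Gaussian jitter (sd `effect_sd`,
default 0.5°; ×0.2 for MGW), making effect sizes context dependent —
without it every Δshape entry of a given type would be one constant and
downstream regression targets would be degenerate. An optional position-6
MGW interaction (`pos6_mgw`, default 0) adds η when the base three
positions from the window center, just outside the window, extends a CpG-
like context; it is stated symmetrically in both directions so the two
strand readings of a fragment agree, and it exists to exercise the
context-table correction.

Fragment design covers the pentamer universe greedily: keys are visited in
canonical order, and an uncovered key receives a fragment whose core embeds
it (cores with boundary marks are completed to full `mg` units), flanked by
a 4-bp flank and its reverse complement on the right — flanks are CpG-free
and A-terminated so no CpG step forms at junctions. Fragments added for one
key count toward every pentamer they contain. Occurrence noise is i.i.d.
Gaussian per array entry (sd `sigma`, default 0.5) — the simplest stand-in
for snapshot-averaged estimates; real trajectory noise is neither
independent across positions nor homoscedastic, which is a stated limit of
what recovery tests can show. Cleavage counts are multinomial with
probabilities ∝ exp(−W·x); binding tables draw lognormal affinity noise
around planted per-offset effects.

Everything is reproducible: equal seeds give identical truth models,
pools, and tables.

## What the tests do and do not show

Problem sizes were chosen so the full suite runs in seconds: parameter
recovery uses coverage-1 pools with 100 occurrences per key at σ = 0.5
(≈ 72k records), the DNase chain simulates 4096 hexamers at depth 2×10⁷,
strand-symmetry is property-checked on 1000 random sequences plus all 987
keys exhaustively. Passing them shows the machinery is self-consistent:
grammar and enumeration are exact, mining inverts simulation, Δshape
recovers planted effects at the configured magnitudes, and the affinity
chain recovers planted weights. It does **not** validate the planted
magnitudes against physical reality — the generator's defaults reproduce
the reported scale of methylation effects, not molecular-simulation
output — and conclusions about real DNase or SELEX data require the real
mined tables and measured counts, which are outside this package's scope.

## Known limitations

* CpG methylation only — no hemimethylation, CHG/CHH contexts, or
  hydroxymethylation; the grammar rejects them by construction.
* Four shape features; no electrostatic potential, slide, or shift.
* The energy reference for cleavage counts and the elastic-net penalty
  values are configuration choices, not reproductions of any particular
  upstream pipeline.
* Context tables cover hexamers ending in CG and CG-flank heptamers; more
  distant context dependencies remain averaged.
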
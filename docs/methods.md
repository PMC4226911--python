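# Methods

## The screen model

The package models a protein-level reporter screen: cells are
co-transfected with a tagged target-expressing vector, a GFP vector that
reports transfection efficiency and loading, and one mimic miRNA per
well; band intensities for the tagged target (DLK1), GFP, and endogenous
Tubulin are quantified per lane of each Western blot membrane. The
generative model for a band intensity is multiplicative throughout:

```
DLK1    = base_DLK1 · membrane · efficiency · fold(treatment) · noise
GFP     = base_GFP  · membrane · efficiency ·                   noise
Tubulin = base_Tub  · membrane ·                                noise
```

with `membrane ~ LogNormal(0, σ_m)` per blot, `efficiency ~
LogNormal(0, σ_e)` per transfected well (shared by the DLK1 and GFP
bands of that well's lanes, including across blot replicates of the same
lysate), and independent `noise ~ LogNormal(0, σ_b)` per band. A
lognormal model is the natural choice for densitometry: intensities are
positive and the dominant error sources (loading, transfer, antibody
binding, scanning gain) act as factors, not offsets. Tubulin is
endogenous, so it carries the membrane effect but *not* the transfection
efficiency — which is exactly why GFP- and Tubulin-corrected amounts
differ under efficiency variation, and why a screen offers both
normalizers.

Unusable measures are modeled as Bernoulli dropout per (well × blot)
lane. Defaults: 121 miRNAs, 2 scrambled negative controls (NC1, NC2),
one siRNA planted at fold 1/3; 5 transfections × 2 blots with dropout
0.17, so the expected usable-measure count per miRNA is 10 × 0.83 = 8.3.
Membranes hold 12 miRNA lanes plus one lane per control, so every blot
carries its own controls. Default log-scale SDs: σ_m = 0.30, σ_e = 0.20,
σ_b = 0.15 — membrane-to-membrane variation dominating lane noise, as is
typical for blot densitometry. The blot-to-blot vs
transfection-to-transfection variance split is not fixed by the model;
both SDs are exposed rather than pinned to a ratio.

What the generator does *not* emulate: pixel-level imaging artifacts,
background subtraction, band saturation, mRNA-level kinetics, or any
sequence-dependence of the planted folds. Passing recovery tests
therefore demonstrates that the statistical pipeline is correct under
its stated error model, not that the model captures every failure mode
of real blots.

## Normalization

Each band is divided by its membrane × channel arithmetic mean computed
over non-siRNA lanes ("relative" amounts); the relative DLK1 amount of a
lane is then divided by its relative GFP or Tubulin amount ("corrected"
amounts). The siRNA is excluded from the membrane means — it is a
deliberate extreme outlier that would otherwise drag every other lane's
relative value — for all three channels, the most conservative reading
of the procedure. The arithmetic mean is the default (a geometric option
exists, arguably more natural under the multiplicative model); lanes
missing a channel are dropped with a warning, never imputed; all joins
are on explicit (membrane, lane) keys.

## Effect estimation and testing

The fold effect is the ratio of arithmetic means, treatment over
reference, matching how screen effects are reported; ratios below one
are phrased as "k-fold reduction" with k the reciprocal. Two reference
modes exist: the pooled NC1+NC2 measures, and the "global" mode where a
treatment is compared against all other non-siRNA measures (leaving the
treatment out of its own reference — a plug-in grand mean would
understate the reference uncertainty). Measures are pooled across
transfections and blots as independent observations (the screen's
"usable measures" unit); a transfection-averaging option exists for
sensitivity analysis, as does mean-of-means NC aggregation.

The test is a two-sided Welch t-test — the source procedure names no
test, group sizes are unequal, and nothing justifies assuming equal
variances; a pooled-variance option is exposed. Degenerate groups follow
explicit conventions: both groups constant and equal → p = 1; constant
and different → p = 0; single-measure treatments are flagged untestable
rather than dropped. Significance uses the Bonferroni threshold α/m with
m the number of miRNA tests.

The 95% interval for the fold effect is computed on the log scale (Welch
interval for the difference of mean logs, exponentiated), i.e. an
interval for the ratio of geometric means. Under the multiplicative
model the planted fold *is* the geometric-mean ratio, so interval
coverage is clean (the acceptance suite verifies ~95% coverage over 200
replicates); the arithmetic ratio of means is kept as the point estimate
for comparability with reported screen effects — under equal noise
structure in treatment and reference, the lognormal bias factors cancel
there too.

The overall "miRNA effect" is a classical one-way fixed-effects ANOVA on
corrected amounts grouped by treatment, controls excluded; the
membrane/transfection hierarchy is deliberately not modeled (no
mixed-effects machinery — a documented non-goal).

## Seed-match counting

Site strings on the target sense strand, guide positions 1-based:
6mer = revcomp(g[2..7]); 7mer-m8 = revcomp(g[2..8]); 7mer-A1 =
revcomp(g[2..7]) + A; 8mer = revcomp(g[2..8]) + A; 6mer-offset =
revcomp(g[3..8]). The terminal A is a target adenosine opposite guide
position 1, not a complement. Inputs are uppercased and T→U mapped, so
DNA and RNA spellings scan identically; coordinates are 0-based
half-open; ambiguity codes are rejected inside guide positions 1–8.

Two counting modes: *hierarchical* (default) assigns each occurrence to
the longest matching class — concretely, classes are visited
longest-first and a match whose footprint lies inside an already-counted
longer match's footprint is suppressed; *overlapping* counts every class
independently. Hierarchical is the default because reported site counts
of the "two 6mers in the ORF" kind are naturally exclusive counts;
overlapping mode supports weighted score families. Same-class
occurrences at different offsets (poly-U runs and the like) all count.
Sites are assigned to regions by their start coordinate; the full-length
count scans the whole sequence and is authoritative when sites fall
outside annotated regions.

The affinity score is a weighted site-count sum (unit weights by
default, i.e. the plain total); the score–effect association is a
Pearson correlation with the two-sided p from the t transform on n−2
degrees of freedom, controls excluded, with constant inputs flagged
undefined rather than reported as r = 0. Externally computed per-miRNA
scores (e.g. from an alignment-based predictor) can be attached by name
and run through the same correlation.

## Transcript simulation and planted sites

`simulate_transcript` samples a background (uniform over A/C/G/U by
default, configurable), writes the requested site strings at requested
or randomly chosen non-overlapping positions, and accepts the draw only
if a hierarchical scan finds *exactly* the planted sites for every
constrained miRNA — otherwise it resamples, up to a bounded number of
attempts (default 10,000) before erroring, so dense plants fail loudly
instead of looping. MiRNAs not named in any plant are unconstrained.

The worked example of the strongest inhibitor (two ORF 6mers plus one
3′ UTR 6mer on the reporter layout) is generated this way as a synthetic
stand-in: the real guide and reporter sequences live in supplementary
material not distributed here, so the *pattern* is reproduced on
synthetic sequence and labelled as such.

## Reporter layout arithmetic

`build_reporter_transcript` does the construct bookkeeping from
component lengths (vector 5′ base, non-native upstream, 5′ UTR, coding
sequence, epitope tag, restriction-site linker, 3′ UTR, vector 3′ tail).
Defaults describe the DLK1 reporter: a 1,405-bp insert in a 1,436-nt
transcript of which 1,337 nt (93.1%) are native target sequence, with 36
extra upstream, 33 extra internal, and 30 extra downstream bases. The
returned skeleton carries region coordinates for seed scanning; the
5′ UTR region spans everything upstream of the start codon, the ORF
includes the in-frame tag, and linker/vector tails are `other`.

## Oligo design

*Mimic duplexes*: passenger = reverse complement of guide positions
1..L−2 with UU appended, giving equal-length strands, L−2 Watson–Crick
pairs, and symmetric 2-nt 3′ overhangs; the passenger's 5′-NH₂
modification is recorded as metadata. G:U wobbles are never counted as
pairs — the duplex is a perfect-complement design. Declared mixed
(IUPAC) guide bases complement to the partner IUPAC code.

*Scrambled controls*: each source miRNA is shuffled by uniform letter
permutation (a dinucleotide-block option exists) n_shuffles times
(default 10, over 5 source miRNAs, selecting 2 — the design's published
shape); candidates with any 8mer/7mer-A1/7mer-m8/6mer match to the
target full-length are discarded (a zero total in overlapping mode is
equivalent to zero in hierarchical mode, so the filter is
mode-independent); survivors are ranked by the same four-class seed
total against a user-supplied background transcript set — a documented
stand-in for genome-wide conserved-target prediction, not an equivalent
— with deterministic (burden, source name, shuffle index) tie-breaking.

*Isomir selection*: per precursor arm, the most abundant isomir by
summed reads (per-library option exposed) is always kept; 5′-shifted
isomirs are added when their total exceeds one third of the
miRBase-reference isomir's reads or when any single library exceeds 200
reads; arms with no registered reference skip the fraction rule with a
warning (the floor still applies) and are treated as unregistered star
arms, kept when observed. Selection is monotone in both thresholds.

## Numerical and interface choices

All randomness flows through `numpy.random.default_rng` seeded from the
config, so identical configs give byte-identical output tables. Tabular
interchange is headered TSV with `#` provenance lines (version, seed,
config hash); sequences are FASTA; regions are BED-like 0-based
half-open; summaries and configs are JSON. The analysis drivers under
`analysis/` and the acceptance script run the full 121-miRNA screen
(~3,800 band records) in seconds; the statistical property checks in the
test suite use 200-replicate Monte Carlo at reduced panel sizes (4–24
miRNAs), which keeps the full suite under half a minute while leaving
Monte-Carlo error on coverage and type-I-error estimates at the
percent level.

## Known limitations

- The error model is exchangeable within its strata; correlated
  artifacts (lane bleed, position effects within a gel, batch-correlated
  antibody behavior) are not represented.
- Welch tests on lognormal data are slightly anticonservative at n ≈ 8;
  the calibration tests bound, but do not remove, this.
- Seed scanning is pattern-matching only: no thermodynamics, no
  conservation, no 3′-supplementary pairing, no alignment-based scores
  (external scores can be attached for correlation instead).
- The worked-example sequences are synthetic stand-ins; only their site
  pattern, not their sequence, matches the published example.
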
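# Methods

## Karyotype metrics and classification

Each chromosome pair is described by its long- and short-arm lengths LA ≥ SA
> 0 (µm). Derived quantities are the total length TA = LA + SA, the arm
ratio r = LA/SA and the centromeric index CI = SA/TA; these satisfy
CI = 1/(1+r) identically, which the tests verify to 1e-12. Morphology
classes follow the Levan convention with the thresholds

    m: 1.0 ≤ r ≤ 1.7   sm: 1.7 < r ≤ 3.0   st: 3.0 < r ≤ 7.0   t: r > 7.0

and boundary values assigned to the more metacentric class. The thresholds
and the boundary rule were fixed by requiring that classification of the
bundled *C. linea* table's printed arm-ratio column reproduce its printed
type column on all 25 rows (it does; e.g. r = 1.69 is called m, r = 3.16
st). No rounding happens inside computations; report output rounds to two
decimals, half away from zero, matching the source table's presentation.

The fundamental number counts chromosome arms: NF = 2·(m + sm) + (st + t),
with class counts taken per chromosome (twice the pair counts). This rule
reproduces the published NF for *C. linea* (94) and *O. tongiorgii* (92).
The *O. persa* block of the source table is internally inconsistent (three
mutually incompatible printed compositions; NF = 90 follows from none of
them under any standard arm-counting rule), so it is bundled as printed but
not used as a reference value; see `src/karyocoi/data/PROVENANCE.md`.

Two classification inputs are supported: arm ratios recomputed from LA/SA
(the default for user data) and a table's printed arm-ratio column
(`arm_ratios=` / `--use-printed-ar`). The distinction matters because the
bundled table's pair 9 has arms inconsistent with its printed ratio and
type; for reproducing the published summary the printed column is the
authority.

## Idiograms

The haploid idiogram orders pairs by decreasing total length, ties broken by
higher centromeric index (more metacentric first) and then pair id; the
source figure states no tie-break, so these are declared choices. Each glyph
stacks the short arm above the centromere mark; heights are proportional to
total length (optionally normalized to the largest chromosome). Output is
hand-built SVG so rendering is a pure function of layout and style —
identical inputs give byte-identical documents, which the tests assert. A
diploid rendering (two glyphs per pair) is available behind a flag. Style
(colors per class, glyph width, spacing) can be loaded from a TOML file.

## Nucleotide distances

Distances operate on upper-case A/C/G/T with `-` and every ambiguity code
treated as missing; missing sites are excluded pairwise by default.
Alignment-wide complete deletion and a coverage-cutoff mode (drop columns
with < 95% of sequences present, then pairwise) are provided for workflows
that prefilter columns. With transition proportion P, transversion
proportion Q over the L comparable sites:

- K2P: d = −½ ln((1−2P−Q)√(1−2Q)). Domain violations (saturation) yield a
  NaN cell flagged undefined rather than an exception, so large matrices
  degrade gracefully; group-mean and tree construction refuse undefined
  cells explicitly.
- K2P+Γ: each −ln x replaced by α(x^(−1/α) − 1); monotonically larger than
  the uncorrected distance for finite α and convergent to it as α → ∞
  (tested at α = 1e6 to 1e-4).
- TN93: purine (A↔G) and pyrimidine (C↔T) transitions separated, base
  frequencies estimated empirically from the compared sites of the pair.
  With uniform frequencies and an equal transition split it reduces to K2P
  (tested to 1e-9), and it matches an independent transcription of the
  closed form on random pairs to 1e-12.

Distances are substitutions/site internally; percentages appear only in
reporting layers (×100). Between-species divergence is the arithmetic mean
over all cross-species pairs (the conventional barcoding summary);
within-species means are reported separately.

## Trees

Neighbor joining uses the standard Q-criterion agglomeration with ties
broken by the lowest (i, j) index pair, making output deterministic on
degenerate inputs. Negative branch estimates are clamped to zero with the
deficit moved to the sister branch, preserving leaf-to-leaf path lengths.
On additive matrices the method is exact: tests enumerate every labelled
unrooted 4- and 5-taxon topology by brute force, build additive matrices
with random branch lengths, and require exact topology recovery with path
lengths reproduced to 1e-9; a 6-taxon case is cross-checked against
dendropy's independent NJ implementation.

Bootstrap supports resample alignment columns with replacement, rebuild the
tree per replicate, and attach to each internal edge of the point-estimate
tree the percentage of replicates containing the same bipartition (a
replicate with an undefined distance is redrawn up to a bounded retry
count). Supports go on the point tree, not a consensus. Monophyly of a
species is decided after rooting on a declared outgroup: the tree is
rerooted on the edge separating the outgroup from everything else (a
scattered outgroup is an error), and the species is monophyletic iff the
smallest clade containing its leaves contains nothing else.

## Synthetic data

The measurement generator draws, per pair, a total length uniform in a
configurable range (default 1.5–9.5 µm, spanning the bundled tables) and an
arm ratio uniform within the class interval, optionally shrunk by a margin
at class boundaries; arms are derived and perturbed multiplicatively by
N(0, sd) noise, with long ≥ short re-enforced by bounded resampling. With
zero noise, classification recovers the generating labels exactly; with 2%
noise and a 0.15 boundary margin, per-chromosome recovery stays ≥ 95%
(tested at 1000 chromosomes).

The sequence generator evolves a root sequence drawn from the stationary
frequencies along a tree whose branch lengths are expected
substitutions/site, using TN93 transition probabilities (matrix
exponential per branch) and discrete-gamma rate heterogeneity: k
equal-probability categories represented by their means (k = 5, shape
α = 0.4292 by default — the model class and shape reported for COI barcode
data), one category fixed per site across the tree. Category means average
to 1, so branch lengths keep their unit meaning. Defaults for what the
model class leaves open are a fish-COI-like base composition
(A 0.25, C 0.28, G 0.17, T 0.30) and transition/transversion multipliers
κ_R = κ_Y = 5 — plausible mitochondrial values chosen once as realistic.
Alignments are gap-free (no indel model). All generators are deterministic
given their seed; CLI runs record seeds in provenance files.

The packaged barcoding scenario mirrors the Kor-basin sampling: 4 + 6 + 2
specimens of three species (two congeners at 0.10 expected
substitutions/site, a second genus at 0.40), within-species divergence
0.005 (a free choice; the source prints no intraspecific distances), and a
distant outgroup.

## Recovery tests, tolerances and known limitations

Estimator unbiasedness is tested with model-matched simulations: plain K2P
on data simulated without rate heterogeneity and with uniform frequencies,
at true divergences 0.05, 0.103 and 0.40 (600 sites, 200 replicates each),
requiring the mean estimate within 2 Monte-Carlo standard errors of truth.
Mixing a heterogeneous-rate generator with the uncorrected estimator
measures model misspecification, not estimator bias — plain K2P under
strong gamma heterogeneity underestimates a 0.40 divergence by roughly a
third, which is expected behavior, not an implementation defect.

Applying the continuous-gamma correction to data simulated with 5 discrete
categories overestimates deep divergences (~8% at 0.40 asymptotically — a
discretization effect), and the correction's convexity (x^(−1/α) with
α ≈ 0.43) makes single-alignment deep-split estimates widely scattered at
600 sites. The scenario-recovery test therefore averages species-mean
distances over 10 seeds and uses bands of ±0.02 around 0.10 and ±0.08
around 0.40 that accommodate these measured systematic effects.

Monophyly recovery on the packaged scenario (K2P distances, NJ, outgroup
rooting) succeeds for all three species in ≥ 95 of 100 seeded runs — at
these divergences the signal is overwhelming, and the observed rate is
100/100.

What passing these tests does and does not show: the generators emulate
clean, gap-free, recombination-free sequence evolution on a known tree and
noise-free-to-mildly-noisy measurement tables. Real barcode data add
alignment error, indels, ambiguity codes, heterogeneous sampling and model
misspecification; real measurement tables add operator effects and
transcription errors (the bundled table itself contains documented ones).
Passing here validates the algorithms and their implementations, not the
biological conclusions drawn from any particular data set.

Problem sizes used throughout the test suite (600-site alignments, ≤ 200
replicates, 100-seed scenario sweeps) keep the full run in the tens of
seconds on one CPU while leaving Monte-Carlo error well inside the asserted
bands.
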
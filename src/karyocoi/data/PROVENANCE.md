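# Fixture provenance

Bundled arm-measurement tables for the three Kor-basin loaches, transcribed
from the published per-chromosome measurement table (25 pairs per species;
LA/SA in µm, plus the printed TA, AR, CI and chromosome-type columns kept
verbatim so that printed and recomputed values can be compared).

## Cleaning edits (applied to the bundled copies only, never to user data)

- `cobitis_linea.tsv` pair 25: short arm printed as "99" (missing decimal
  point); stored as 0.99, consistent with the printed TA 5.06 = 4.07 + 0.99.
- `cobitis_linea.tsv` pair 1: centromeric index printed as "29" (missing
  decimal point); stored as 0.29.
- `oxynoemacheilus_tongiorgii.tsv`: the source block prints its chromosome
  type column BEFORE the numeric columns (CT, LA, SA, TA, AR, CI); reordered
  to the common schema pair_id, LA, SA, TA, AR, CI, CT.
- Chromosome-type labels normalized to lower case (M → m, Sm → sm, St → st).
- Trailing zeros restored where the source drops them (e.g. "2.6" → 2.60,
  "6.7" → 6.70, "1.7" → 1.70, "2.1" → 2.10, "2.4" → 2.40, "2.3" → 2.30);
  value-preserving formatting only.

## Known internal inconsistencies in the source (NOT edited)

- `cobitis_linea.tsv` pair 9: LA 4.86 / SA 1.58 imply AR ≈ 3.08 and
  CI ≈ 0.25, but the printed AR is 1.63, printed CI 0.28 and printed type m.
  Which figures are the typo cannot be decided from the source; both the
  measured arms and the printed columns are stored as found. This is the one
  row excluded when recomputed CI is compared against printed CI at ±0.01.
- `cobitis_linea.tsv` pair 23: recomputed AR 1.70/... = 2.17 vs printed 2.15
  (0.02 discrepancy; does not affect the class call).
- `oxynoemacheilus_persa.tsv`: the source reports this species' karyotype
  three mutually inconsistent ways (abstract, discussion, and the type-column
  tally here, which gives 9 m + 12 sm + 4 st pairs); its printed NF (90) is
  not reproducible from any of them under the stated arm-counting rule. The
  table is bundled as printed.
- `oxynoemacheilus_tongiorgii.tsv`: several rows have LA + SA ≠ printed TA
  (e.g. pair 22: 0.94 + 0.74 = 1.68 vs printed TA 2.09) and the printed type
  column does not tally to the species' stated composition; kept as printed.
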
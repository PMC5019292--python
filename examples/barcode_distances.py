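"""Between-species barcode divergence on a synthetic three-species scenario.

Simulates a COI-like alignment on a tree with two close congeners (~0.10
substitutions/site apart) and a distant genus (~0.40), then reports the
between-species mean distances in percent — the standard DNA-barcoding
summary — under plain K2P and under K2P with gamma rate-heterogeneity
correction (shape 0.4292, matching the simulation).
"""

from karyocoi import (
    SubstModelParams,
    group_mean_distance,
    make_kor_scenario,
    pairwise_matrix,
    simulate_alignment,
)

_, config = make_kor_scenario(seed=42)
alignment = simulate_alignment(config)

for model, params in [("k2p", None), ("k2p+g", SubstModelParams(gamma_shape=0.4292))]:
    matrix = pairwise_matrix(alignment, model=model, model_params=params)
    between, within = group_mean_distance(matrix, alignment.species_map)
    print(f"between-species mean {model} (%):")
    print((between * 100).round(1).to_string())
    print()

# Plain K2P compresses deep divergences when site rates vary (the simulation
# uses strong gamma heterogeneity, shape 0.4292). The gamma correction
# recovers the shallow ~10% split well; at the deep split it is strongly
# convex, so single-alignment estimates scatter widely around (and above)
# the generating 40% — see the methods note. Within-species divergence
# (simulated at 0.5%) stays far below either: the "barcode gap" that makes
# species assignment from COI possible.
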
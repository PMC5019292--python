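"""Optional check against the study's deposited COI barcodes (needs download).

The twelve Kor-basin barcodes are GenBank accessions KP050529-KP050540
(4 Oxynoemacheilus persa, 6 O. tongiorgii, 2 Cobitis linea). Download them,
align (e.g. with mafft --auto) and supply the aligned FASTA plus a
two-column species map (taxon_id <TAB> species):

    python examples/real_data_check.py aligned.fasta species_map.tsv

Reported between-species mean K2P percentages can then be compared with the
published 10.3% (O. persa vs O. tongiorgii), 38.4% (C. linea vs O. persa)
and 41.3% (C. linea vs O. tongiorgii).
"""

import sys

from karyocoi import group_mean_distance, io, pairwise_matrix

if len(sys.argv) != 3:
    sys.exit(__doc__)

alignment = io.load_alignment(sys.argv[1], sys.argv[2])
between, within = group_mean_distance(
    pairwise_matrix(alignment, "k2p"), alignment.species_map
)
print("between-species mean K2P (%):")
print((between * 100).round(1).to_string())
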
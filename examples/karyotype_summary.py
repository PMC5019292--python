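"""Summarize the spined-loach karyotype from the bundled measurement table.

Loads the 25 chromosome-pair arm measurements of Cobitis linea, classifies
each pair on the table's printed arm-ratio column, and prints the diploid
number, the class composition and the fundamental number (total arm count).
"""

from karyocoi import io, summarize_karyotype

measurements, table = io.load_fixture("cobitis_linea")
summary = summarize_karyotype(
    measurements, "Cobitis linea", arm_ratios=[float(x) for x in table.printed_ar]
)

print(f"species            : {summary.species_label}")
print(f"chromosome pairs   : {summary.n_pairs}")
print(f"diploid number 2n  : {summary.diploid_number}")
print(f"karyotype formula  : {summary.formula}")
print(f"fundamental number : {summary.fundamental_number}")
# 2n=50 with 2 metacentric, 20 submetacentric and 3 subtelocentric pairs;
# NF counts two arms per bi-armed (m/sm) chromosome, one per st/t.
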
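"""Probe order gained through self-association with tandem duplication.

Predicts on a sequence and on the sequence concatenated with itself.  Pair
statistics spanning the junction create plots no monomer terminus can have,
so a chain that is disordered alone but ordered as a dimer gains plot
density (and loses predicted disorder) near the junction.
"""

import admap

table = admap.make_table("two-class", seed=11)
train = admap.make_annotated_set(40, seed=11, table=table)
curve = admap.calibrate(train, table)

# order-prone (W) termini around a disorder-prone (K) core
sequence = "W" * 15 + "K" * 30 + "W" * 15
result = admap.tandem_predict(sequence, table, curve)

N = len(sequence)
junction = result.tandem.raw_counts[N - 8 : N + 8].sum()
termini = result.monomer.raw_counts[:8].sum() + result.monomer.raw_counts[-8:].sum()

print(f"monomer length        : {result.monomer.N}")
print(f"tandem length         : {result.tandem.N}")
print(f"terminal counts (mono): {termini}")
print(f"junction counts (tand): {junction}")
print(f"monomer disordered    : {result.monomer.segments}")
print(f"copy-1 disordered     : {result.copies[0].segments}")
# Junction counts exceeding the monomer's terminal counts is the map-level
# signature of order created by dimerization.
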
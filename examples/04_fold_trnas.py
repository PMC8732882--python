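"""Predict tRNA cloverleaf secondary structures.

Each tRNA is folded by exhaustive search over canonical arm placements,
maximizing paired bases (Watson-Crick plus G·U wobble).  Mitochondrial
tRNA-Ser(GCU) characteristically lacks the DHU arm; the fold reports it as
degenerate.  The dot-bracket string shows paired positions.
"""

import mitochar as mc

genome, _ = mc.generate_mitogenome(mc.default_template(), seed=1)

folded = []
for f in genome.features:
    if f.category != "tRNA":
        continue
    seq = mc.extract_feature(genome, f)
    try:
        cl = mc.fold_cloverleaf(seq, anticodon=f.anticodon)
    except mc.FoldError:
        cl = mc.fold_cloverleaf(seq)  # overlap-degraded: fold unconstrained
    folded.append((f.name, cl))

report = mc.structure_report(folded)
print(report[["name", "length", "anticodon", "pairs", "dhu_present"]]
      .to_string(index=False))
print(f"\ndegenerate (DHU-less) structures: {report.attrs['n_degenerate']}")

ser = next(cl for name, cl in folded if name == "tRNA-Ser(GCU)")
print(f"\ntRNA-Ser(GCU), {len(ser.sequence)} nt, no DHU arm:")
print(ser.sequence)
print(ser.dot_bracket())
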
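"""Codon usage and RSCU across the 13 protein-coding genes.

RSCU (relative synonymous codon usage) is a codon's count divided by the
mean count of its synonymous family: 1 means no preference, >1 means the
codon is used more often than its synonyms.  Incomplete trailing codons
(from T--/TA- stops) are excluded; terminal stop codons are tallied
separately.
"""

import mitochar as mc

genome, _ = mc.generate_mitogenome(mc.default_template(), seed=1)
cds = [(f.name, mc.extract_feature(genome, f))
       for f in genome.features if f.category == "PCG"]
usage = mc.codon_usage(cds)
frame = mc.codon_usage_frame(usage)

print(f"{usage.n_codons} codons tallied over {len(cds)} genes")
print(f"stop-codon usage: {usage.stop_counts}\n")

top = frame.dropna().sort_values("RSCU", ascending=False).head(8)
print("most preferred codons (highest RSCU):")
print(top.to_string(index=False))
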
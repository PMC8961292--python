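"""Number Gγ sequences under the CGγN scheme.

Builds the twelve-isoform reference, assigns labels to Gγ1 and to the
C-terminal h2 peptide, and prints the landmark positions: the NPF motif at
h2.8–h2.10 and the prenylated CAAX cysteine at h2.17.
"""

from npfsite import assign_cggn, build_reference, label_of, number_h2_fragment, residue_of

reference = build_reference()
g1 = assign_cggn(reference.isoform("Ggamma1").sequence)

print("Gγ1 NPF motif:", ", ".join(g1.rendered(p) for p in (62, 63, 64)))
print("Gγ1 CAAX cysteine:", g1.rendered(residue_of(g1, "h2.17")))

g2 = assign_cggn(reference.isoform("Ggamma2").sequence)
print("Gγ2 NPF proline:", g2.rendered(residue_of(g2, "h2.9")))
print("Gγ2 helix-2 C-terminus:", ", ".join(g2.rendered(p) for p in (49, 50, 51)))

peptide = number_h2_fragment("KGIPEDKNPFKELKGGC")
print("h2 peptide, position 9 =", label_of(peptide, 9).rendered,
      "| position 17 =", label_of(peptide, 17).rendered)
# The proline of the peptide's NPF lands on h2.9 and its terminal cysteine on
# h2.17 — the peptide is exactly the h2 segment of Gγ1.
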
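"""Ballesteros–Weinstein numbering and the NPF-site plausibility score.

Numbers the bovine rhodopsin sequence by annotated-reference transfer and
scores the eight TM1/ICL1/H8 pocket positions against the chemistry an
NPF-binding cleft requires (hydrophobic floor, charged/polar rim).
"""

from npfsite import assign_bw, extract_site_residues, npf_site_score, rhodopsin_reference

numbered = assign_bw(rhodopsin_reference().sequence)
for author in (306, 313, 316):
    print(f"residue {author} ({numbered.sequence[author - 1]}) -> {numbered.numbering[author]}")

site = extract_site_residues(numbered)
profile = npf_site_score(site)
for entry in profile.positions:
    aa = next(iter(entry.frequencies))
    flag = "match" if entry.matches_expected else "MISS"
    print(f"  {str(entry.label):>6} {aa} ({entry.dominant_class:11s}) {flag}")
print(f"NPF-site score: {profile.score:.3f}")
# 7 of 8 pocket positions carry the expected chemistry; only Thr at 8.57
# misses the hydrophobic floor, giving 0.875.
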
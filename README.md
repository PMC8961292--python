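# npfsite

Structural-bioinformatics toolkit for analyzing how the C-terminus of the
heterotrimeric G-protein γ subunit could be recognized by class A GPCRs.

Gγ subunits end in two landmarks: an Asn-Pro-Phe (**NPF**) tripeptide — the
motif recognized by Eps15-homology (EH) domains — and a CAAX cysteine that is
farnesylated or geranylgeranylated. The αB/αC helix cleft of an EH domain
that binds NPF peptides is structurally echoed by the pocket that TM1, the
first intracellular loop (ICL1) and helix 8 (H8) form on the cytoplasmic face
of class A GPCRs, which suggests that this pocket is an NPF-binding site used
during the initial GPCR–Gβγ encounter. `npfsite` makes the machinery behind
that structural argument reusable and testable:

* **CGγN numbering** (`npfsite.cggn`) — a common numbering scheme for the
  twelve human Gγ isoforms over segments `h1, H1, h1h2, H2, h2`, anchored so
  that the NPF motif is `h2.8–h2.10` and the CAAX cysteine is `h2.17`
  (e.g. Gγ1 Pro63^Gγh2.9).
* **Ballesteros–Weinstein numbering** (`npfsite.gpcr_numbering`) — positions
  `1.xx / 12.xx / 7.xx / 8.xx` assigned to class A sequences by alignment
  transfer from an annotated bovine rhodopsin reference (Asn55 = 1.50,
  Pro303 = 7.50, Phe313 = 8.50).
* **Contact analysis** (`npfsite.contacts`) — interface contacts under a
  strict `< 4 Å` any-atom criterion, a PIC-style interaction typology
  (hydrophobic / ionic / hydrogen bond / aromatic), and contact persistence
  across conformational states.
* **Site geometry and scoring** (`npfsite.site_mapping`) — Kabsch
  superposition, helix-axis fitting with azimuthal phases, the H8 rotation
  angle onto the EH-domain αC helix (clockwise from the distal end of H8),
  a conservation profile over a user-supplied alignment, an NPF-site
  plausibility score over the eight pocket positions
  {1.55, 1.56, 1.59, 12.50, 8.49, 8.50, 8.54, 8.57}, and the Tyr7.53–Phe8.50
  "lock" that marks an inactive receptor.
* **Synthetic fixtures** (`npfsite.synthetic`) — deterministic ideal helices,
  pocket–peptide complexes with exhaustive ground-truth contact lists, and
  Gγ-like sequences with known labels, so everything above is testable
  without downloading coordinates.
* **Recipes** (`npfsite.recipes`) — named, logged reproductions of the
  contact/distance analyses over user-supplied PDB/mmCIF files, with declared
  chain roles, recorded checksums and byte-deterministic tables.

## Worked example

```python
from npfsite import assign_cggn, build_reference, residue_of
from npfsite import assign_bw, extract_site_residues, npf_site_score, rhodopsin_reference

g1 = assign_cggn(build_reference().isoform("Ggamma1").sequence)
print(g1.rendered(63))                      # Pro63^Gγh2.9
print(residue_of(g1, "h2.17"))              # 71  (the farnesylated cysteine)

rho = assign_bw(rhodopsin_reference().sequence)
print(rho.numbering[316], rho.numbering[313], rho.numbering[306])   # 8.53 8.50 7.53
profile = npf_site_score(extract_site_residues(rho))
print(round(profile.score, 3))              # 0.875
```

The score says 7 of rhodopsin's 8 pocket positions carry the chemistry an
NPF-binding cleft requires (hydrophobic floor, charged/polar rim); only Thr
at 8.57 misses the hydrophobic expectation. The `examples/` directory holds
one short narrative script per capability (numbering, contacts, rotation
geometry, recipes); each prints the numbers it computes and what they mean.

Recipes run from the shell once structure files are supplied locally, e.g.

```bash
npfsite reproduce --recipe fig7_distance --config cfg.yml
```

with a config declaring the file path and chain roles for each accession.

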
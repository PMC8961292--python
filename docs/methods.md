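# Methods

## The CGγN numbering scheme

Human Gγ subunits share a five-part architecture derived from the two solved
isoform structures: an N-terminal coil (`h1`), helix 1 (`H1`), a hinge
(`h1h2`), helix 2 (`H2`) and the functionally critical C-terminal region
(`h2`). CGγN names each position `Gγ<segment>.<index>`. Three landmarks pin
the scheme in all twelve isoforms:

* the NPF motif occupies `h2.8`–`h2.10`;
* the prenylated CAAX cysteine occupies `h2.17`;
* helix H2 ends at `H2.22`, immediately before `h2.1`.

The reference is built by **anchored back-fill** rather than by re-running a
multiple aligner: within each isoform, columns are assigned consecutively
backwards from the NPF asparagine (`h2.8`) toward the N-terminus, and forward
from the phenylalanine with the CAAX cysteine right-justified at `h2.17`
(isoforms with fewer than six residues between Phe and Cys take their gap
immediately before the cysteine column, as forced by Gγ5). This is exactly
the manual-adjustment step a profile aligner would need anyway, and it makes
the three anchors true by construction; the reference builder still validates
them at build time. Length variation between isoforms is absorbed at the
N-terminus of `h1` (right-justified) — the twelve sequences have no internal
indels between `H1` and the NPF motif under this layout.

Segment extents not determined by the landmarks (the `h1/H1/h1h2` boundaries;
frozen here as 11, 19 and 3 columns with `H2` = 22 and `h2` = 17) only affect
labels that no anchored landmark constrains; labels in those segments are
flagged *provisional* in tabular output.

Query sequences are numbered by **reference transfer**: global alignment
(BLOSUM62, affine gap open 10 / extend 1, via Biopython's `PairwiseAligner`)
against each reference isoform, label inheritance across the aligned columns
of the best-scoring isoform, and a hard post-condition that an NPF trimer of
the query landed on `h2.8`–`h2.10` (multiple NPF occurrences are resolved by
alignment score; failure raises a "not numberable" error rather than
guessing). Isolated C-terminal peptides are numbered as `h2` fragments by the
same anchored fill. The bundled isoform sequences are curated from public
records; the positions asserted by the test suite are the anchored landmarks,
and other positions should be re-verified against current database records
before production annotation use.

## Ballesteros–Weinstein numbering

Labels over TM1 (`1.30–1.59`), ICL1 (`12.48–12.51`), TM7 (`7.33–7.56`) and
H8 (`8.47–8.60`) are carried by a frozen annotation of the bovine rhodopsin
sequence (Asn55 = 1.50, Lys66/Lys67 = 12.48/12.49, Pro303 = 7.50,
Phe313 = 8.50) and transferred to queries across a global alignment with free
end gaps. Reference transfer was chosen over per-helix x.50 motif detection
because it is deterministic, covers ICL1 (which has no x.50 motif), and is
directly checkable against the rhodopsin anchors. Queries below 25 %
identity over the labelled TM1+H8 columns are rejected as not class A-like;
insertions relative to the reference stay unlabelled.

## Contact analysis

Interface contacts use a strict `< 4.0 Å` any-atom Euclidean criterion:
atoms at exactly the cutoff are excluded, and backbone atoms are included by
default (side-chain-only is a selection flag). The engine is a k-d-tree
neighbor search property-tested against an exhaustive double loop. Hydrogens
are stripped on reading by default — solution-NMR depositions carry
hydrogens while crystal structures usually do not, which inflates contact
counts — with an explicit flag to keep them (the recipes keep hydrogens for
the hydrogen-bearing entries to mirror the published tables; the inflation
is monotone: adding hydrogens can only add records).

The intra-chain typology applies published interaction-calculator defaults:
hydrophobic side chains of {A,V,L,I,P,F,M,W} within 5.0 Å; side-chain N of
{K,R,H} to side-chain O of {D,E} within 6.0 Å (ionic); donor–acceptor heavy
atoms within 3.5 Å (hydrogen bond, no angle term — heavy-atom distance only);
ring centroids 4.5–7.0 Å (aromatic–aromatic), centroid–S within 5.3 Å and
cation–π within 6.0 Å. All thresholds are overridable. Contact persistence
across conformations re-measures each contacting residue pair in an
alternative model under a user-declared chain mapping (no automatic sequence
alignment) and flags the pair *broken* when its minimum distance reaches the
original cutoff.

## Geometry

**Superposition** is least-squares rigid (Kabsch) via
`scipy.spatial.transform.Rotation.align_vectors` on centered coordinates,
always returning a proper rotation; inputs of fewer than three points or
collinear point sets are rejected. **Helix axes** are least-squares lines
(principal component) through sliding four-residue centroids of the Cα
trace, requiring at least six residues and oriented N→C. Azimuthal phases
about the axis are measured in `[0°, 360°)`, *clockwise as viewed from the
distal (C-terminal) end* — the viewpoint in which the H8 pocket rotation is
quoted — against a deterministic in-plane reference (global x, falling back
to y, projected perpendicular to the axis).

The **H8 rotation angle** superposes the EH2 αB Cα onto the receptor
TM1/ICL1 Cα through the four αB correspondence pairs
(Gly33↔12.50, Lys37↔1.59, Leu40↔1.56, Leu41↔1.55), fits the H8 axis, and
averages on the circle the azimuthal offsets between the four H8 positions
(8.49, 8.50, 8.54, 8.57) and their αC partners (Glu55, Leu50, Trp54, Val47).
Cβ positions (Cα for glycine) are used for the phases because the rotation
aligns side-chain facing, not backbone. The αC "SLE"↔H8 "NKQ" triple is
available as optional, unverified pairs (only its glutamate partner is
text-anchored) and takes caller-supplied serine/leucine residue numbers.

## NPF-site score and conservation profile

The aggregate score is deliberately simple plumbing that operationalizes a
qualitative argument: over the eight pocket positions, expected chemistry is
*hydrophobic* at {1.55, 1.56, 12.50, 8.50, 8.54, 8.57} and *charged or
polar* (anything non-hydrophobic) at {1.59, 8.49}; the score is the
equal-weight fraction of present positions that match, absent positions
excluded from the denominator. The five-way chemical partition is
polar {G,S,T,Y,C}, neutral {Q,N}, basic {K,R,H}, acidic {D,E}, hydrophobic
{A,V,L,I,P,W,F,M}. Tyrosine is additionally *accepted* at the hydrophobic
positions — its ring packs like a hydrophobic side chain there, and
rhodopsin itself presents Tyr at 1.55 — while still being classed polar in
the partition. Conservation profiles take any user-supplied class A
alignment (the exact published sequence set is not recoverable), map its
columns through a numbered reference row, and report per-position residue
frequencies (gaps excluded), dominant chemical class and expected-chemistry
match.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of their specs (seed included), so every
fixture is bit-reproducible. Ideal helices use textbook α-helix parameters
(1.5 Å rise, 100° twist, 2.3 Å Cα radius, all configurable); backbone and Cβ
atoms are placed by idealized cylindrical offsets, with Cβ radially outward
so its azimuth equals the Cα azimuth. The toy pocket crosses two helices at
~60° and places a tripeptide probe at exact Cα–Cα target distances, with the
ground-truth contact list enumerated exhaustively at build time. Gγ-like
sequences are seeded mutation/indel variants of the reference isoforms with
the NPF ± 2 window and the CAAX cysteine protected, carrying their
ground-truth labels through the edits.

None of this is stereochemically realistic: there are no rotamers, no steric
relaxation (probe atoms may approach pocket atoms arbitrarily closely), no
membrane, and the synthetic correspondence pairs encode their rotation
exactly rather than through two independently folded domains. Passing tests
therefore demonstrate that the *measurement machinery* is correct —
contact enumeration matches an oracle, applied rotations and transforms are
recovered, labels survive indels — not that any particular deposited
structure shows a particular number. The analyses defined over specific
deposited entries run through the recipes whenever those files are supplied
by the user.

## Numerical choices and degenerate inputs

Distances are reported in Å, rounded to 3 decimals in tables (2 for the
single-distance recipe); PDB round trips preserve coordinates to the
format's 3-decimal precision. Angles are degrees in `[0°, 360°)`; circular
means are computed on unit vectors. Alternate locations resolve to the
highest-occupancy conformer, ties toward altloc `A`. Selections resolve in
(chain, residue number, insertion code, atom name) order, so identical
selections always produce identical lists and recipe tables are
byte-deterministic. Empty selections are empty results, not errors, except
where an operation needs at least one atom on each side. Multi-model files
default to the first model and recipes record the index used, along with
input checksums and the hydrogen policy.

## Problem sizes

The test suite and the acceptance script run on fixtures of at most ~1,000
atoms, 100 generated sequences and 5 seeds per geometric recovery — sizes at
which the exhaustive oracles (double-loop contact search, rotation-grid
superposition) remain exact and the whole battery completes in seconds.

## Known limitations

* CGγN is defined for the twelve human isoforms; other species are
  best-effort via alignment transfer and not validated.
* The `h1/H1/h1h2` boundaries are provisional (see above).
* The hydrogen-bond rule has no geometric (angle) term.
* No solvent accessibility, energetics, docking or pose generation; manual
  docking poses are out of scope, and figure rendering is limited to numeric
  tables and frequency profiles.
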
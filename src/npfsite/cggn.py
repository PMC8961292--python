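"""Common Gγ numbering (CGγN) for heterotrimeric G-protein γ subunits.

Gγ subunits share a five-part architecture: an N-terminal coil (``h1``), a
first α helix (``H1``), a hinge/loop (``h1h2``), a second α helix (``H2``)
and a C-terminal region (``h2``) that carries the two functional landmarks of
the family — the Asn-Pro-Phe (NPF) motif recognized by EH-domain-like pockets,
and the CAAX cysteine that is farnesylated or geranylgeranylated.  The CGγN
scheme names each position ``Gγ<segment>.<index>``, e.g. the NPF proline of
Gγ1 is Pro63^Gγh2.9.

Three anchors pin the scheme in every isoform:

* the NPF motif occupies ``h2.8``–``h2.10``;
* the prenylated CAAX cysteine occupies ``h2.17`` (isoforms with fewer
  residues between Phe and Cys take gaps immediately before ``h2.17``);
* helix H2 ends at ``H2.22``, the eighth position before the NPF asparagine.

Segment extents other than these anchors are not uniquely determined by the
printed landmarks; the boundaries frozen here (h1 ≤ 11, H1 = 19, h1h2 = 3,
H2 = 22, h2 = 17 columns) reproduce every anchored label by construction, and
labels in ``h1``/``H1``/``h1h2`` are flagged *provisional* in tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._data import load_gamma_isoforms

__all__ = [
    "CGammaNLabel",
    "ReferenceIsoform",
    "ReferenceAlignment",
    "NumberedSequence",
    "NotNumberableError",
    "build_reference",
    "assign_cggn",
    "number_h2_fragment",
    "label_of",
    "residue_of",
    "SEGMENTS",
]

#: segment names in N→C order with their column counts
SEGMENTS: tuple[tuple[str, int], ...] = (
    ("h1", 11),
    ("H1", 19),
    ("h1h2", 3),
    ("H2", 22),
    ("h2", 17),
)
_SEGMENT_RANK = {name: i for i, (name, _) in enumerate(SEGMENTS)}
_SEGMENT_LEN = dict(SEGMENTS)
#: segments whose extents are anchored only by secondary-structure assignment
PROVISIONAL_SEGMENTS = frozenset({"h1", "H1", "h1h2"})

#: Fig-legend accessions of the twelve human isoforms (nucleotide records whose
#: coding sequences translate to the bundled protein sequences)
ACCESSIONS: dict[str, str] = {
    "Ggamma1": "NG_051196.1",
    "Ggamma2": "NM_053064.5",
    "Ggamma3": "AF493871",
    "Ggamma4": "AF493872.1",
    "Ggamma5": "AF493873.1",
    "Ggamma7": "AF493874.1",
    "Ggamma8": "AF493875.1",
    "Ggamma9": "AF493876.1",
    "Ggamma10": "AF493877.1",
    "Ggamma11": "AF493878.1",
    "Ggamma12": "AF493879.1",
    "Ggamma13": "AF493880.1",
}

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


class NotNumberableError(ValueError):
    """Raised when a sequence cannot receive CGγN labels (e.g. no NPF motif)."""


@dataclass(frozen=True, order=True)
class CGammaNLabel:
    """One CGγN position, e.g. ``h2.9``; sorts in N→C segment order."""

    sort_key: tuple[int, int] = field(init=False, repr=False, compare=True)
    segment: str = field(compare=False)
    index: int = field(compare=False)

    def __post_init__(self) -> None:
        if self.segment not in _SEGMENT_RANK:
            raise ValueError(f"unknown segment {self.segment!r}; expected one of "
                             f"{[s for s, _ in SEGMENTS]}")
        if not 1 <= self.index <= _SEGMENT_LEN[self.segment]:
            raise ValueError(
                f"index {self.index} out of range for segment {self.segment} "
                f"(1..{_SEGMENT_LEN[self.segment]})"
            )
        object.__setattr__(self, "sort_key", (_SEGMENT_RANK[self.segment], self.index))

    def __str__(self) -> str:
        return f"{self.segment}.{self.index}"

    @property
    def rendered(self) -> str:
        """Rendered with the scheme prefix, e.g. ``Gγh2.9``."""
        return f"Gγ{self.segment}.{self.index}"

    @classmethod
    def parse(cls, text: str) -> "CGammaNLabel":
        t = text.replace("Gγ", "").replace("Ggamma", "")
        segment, _, index = t.partition(".")
        return cls(segment=segment, index=int(index))


def _anchor_columns(sequence: str) -> dict[int, CGammaNLabel]:
    """Map 1-based residue positions of a Gγ-like sequence to CGγN labels.

    Anchored back-fill from the C-terminal-most NPF motif: the Asn takes
    ``h2.8`` and consecutive positions fill consecutive columns toward the
    N-terminus; after the Phe, up to six residues fill ``h2.11``.. left to
    right and the CAAX cysteine is right-justified at ``h2.17``.
    """
    n = sequence.rfind("NPF") + 1  # 1-based Asn position
    if n == 0:
        raise NotNumberableError("sequence has no NPF motif; not numberable under CGγN")
    labels: dict[int, CGammaNLabel] = {}

    # backwards from h2.8
    columns_back: list[CGammaNLabel] = []
    for segment, length in SEGMENTS:
        for idx in range(1, length + 1):
            columns_back.append(CGammaNLabel(segment=segment, index=idx))
    h2_8 = columns_back.index(CGammaNLabel(segment="h2", index=8))
    for offset in range(h2_8 + 1):
        pos = n - offset
        if pos < 1:
            break
        labels[pos] = columns_back[h2_8 - offset]
    labels[n + 1] = CGammaNLabel(segment="h2", index=9)
    labels[n + 2] = CGammaNLabel(segment="h2", index=10)

    # forwards: CAAX cysteine right-justified at h2.17
    tail = sequence[n + 2 :]  # after Phe
    cys_rel = tail.rfind("C")
    if cys_rel >= 0 and cys_rel <= 6 and len(tail) - cys_rel <= 4:
        between = cys_rel  # residues strictly between Phe and Cys
        for i in range(between):
            if 10 + 1 + i <= 16:
                labels[n + 3 + i] = CGammaNLabel(segment="h2", index=11 + i)
        labels[n + 3 + between] = CGammaNLabel(segment="h2", index=17)
    else:
        for i, _aa in enumerate(tail):
            if 11 + i > 17:
                break
            labels[n + 3 + i] = CGammaNLabel(segment="h2", index=11 + i)
    return labels


@dataclass(frozen=True)
class ReferenceIsoform:
    name: str
    accession: str
    sequence: str
    numbering: Mapping[int, CGammaNLabel]  # 1-based position -> label

    def position_of(self, label: CGammaNLabel) -> int:
        for pos, lab in self.numbering.items():
            if lab == label:
                return pos
        raise KeyError(f"{self.name}: no position labelled {label}")


@dataclass(frozen=True)
class ReferenceAlignment:
    """The twelve-isoform reference with per-position CGγN labels."""

    isoforms: tuple[ReferenceIsoform, ...]

    def isoform(self, name: str) -> ReferenceIsoform:
        for iso in self.isoforms:
            if iso.name == name:
                return iso
        raise KeyError(f"no reference isoform {name!r}; have {[i.name for i in self.isoforms]}")

    def validate_anchors(self) -> None:
        """Assert the three CGγN anchor invariants for every isoform."""
        for iso in self.isoforms:
            seq = iso.sequence
            inverse = {str(lab): pos for pos, lab in iso.numbering.items()}
            for idx, aa in zip((8, 9, 10), "NPF"):
                pos = inverse.get(f"h2.{idx}")
                assert pos is not None and seq[pos - 1] == aa, (
                    f"{iso.name}: NPF anchor violated at h2.{idx}"
                )
            pos = inverse.get("h2.17")
            assert pos is not None and seq[pos - 1] == "C", (
                f"{iso.name}: CAAX cysteine not at h2.17"
            )
            pos = inverse.get("H2.22")
            assert pos is not None and inverse["h2.1"] == pos + 1, (
                f"{iso.name}: H2.22 must immediately precede h2.1"
            )


@lru_cache(maxsize=1)
def build_reference() -> ReferenceAlignment:
    """Construct the reference numbering for the twelve human Gγ isoforms.

    Anchor-based construction (see module docstring); validated against the
    anchor invariants before being returned.
    """
    isoforms = []
    for name, seq in load_gamma_isoforms().items():
        isoforms.append(
            ReferenceIsoform(
                name=name,
                accession=ACCESSIONS[name],
                sequence=seq,
                numbering=_anchor_columns(seq),
            )
        )
    ref = ReferenceAlignment(isoforms=tuple(isoforms))
    ref.validate_anchors()
    return ref


@dataclass(frozen=True)
class NumberedSequence:
    """A query sequence with CGγN labels on its assignable positions."""

    sequence: str
    numbering: Mapping[int, CGammaNLabel]
    source: str = ""  # reference isoform the labels were transferred from

    @property
    def unassigned(self) -> tuple[int, ...]:
        return tuple(p for p in range(1, len(self.sequence) + 1) if p not in self.numbering)

    def rendered(self, position: int) -> str:
        """E.g. ``Pro63^Gγh2.9``."""
        label = label_of(self, position)
        aa = self.sequence[position - 1]
        return f"{_AA3.get(aa, aa)}{position}^{label.rendered}"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in range(1, len(self.sequence) + 1):
            label = self.numbering.get(pos)
            rows.append(
                {
                    "position": pos,
                    "residue": self.sequence[pos - 1],
                    "segment": label.segment if label else "",
                    "index": label.index if label else pd.NA,
                    "label": label.rendered if label else "",
                    "provisional": bool(label and label.segment in PROVISIONAL_SEGMENTS),
                }
            )
        return pd.DataFrame(rows)


def label_of(seq: NumberedSequence, residue_number: int) -> CGammaNLabel:
    """Label at a 1-based position; raises on unassigned positions."""
    try:
        return seq.numbering[residue_number]
    except KeyError:
        raise KeyError(f"position {residue_number} carries no CGγN label") from None


def residue_of(seq: NumberedSequence, label: CGammaNLabel | str) -> int:
    """Inverse of :func:`label_of`: the 1-based position carrying *label*."""
    if isinstance(label, str):
        label = CGammaNLabel.parse(label)
    for pos, lab in seq.numbering.items():
        if lab == label:
            return pos
    raise KeyError(f"no position labelled {label}")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def assign_cggn(query: str, reference: ReferenceAlignment | None = None) -> NumberedSequence:
    """Assign CGγN labels to a Gγ-family sequence by reference transfer.

    The query is globally aligned (BLOSUM62, affine gap 10/1) against each of
    the twelve reference isoforms; labels are inherited across the aligned
    columns of the best-scoring isoform.  Query residues aligned to gaps stay
    unassigned.  The assignment is rejected unless an NPF trimer of the query
    lands exactly on ``h2.8``–``h2.10`` (a sequence with several NPF motifs is
    resolved by the alignment score).
    """
    query = query.upper().replace("*", "")
    if len(query) < 20:
        raise NotNumberableError(f"query too short for CGγN assignment ({len(query)} < 20 aa)")
    if "NPF" not in query:
        raise NotNumberableError("query has no NPF motif; not numberable under CGγN")
    reference = reference or build_reference()

    aligner = _make_aligner()
    best: tuple[float, ReferenceIsoform, Align.Alignment] | None = None
    for iso in reference.isoforms:
        alignment = aligner.align(iso.sequence, query)[0]
        if best is None or alignment.score > best[0]:
            best = (alignment.score, iso, alignment)
    assert best is not None
    _, iso, alignment = best

    numbering: dict[int, CGammaNLabel] = {}
    ref_blocks, query_blocks = alignment.aligned
    for (r0, r1), (q0, q1) in zip(ref_blocks, query_blocks):
        for r, q in zip(range(r0, r1), range(q0, q1)):
            label = iso.numbering.get(r + 1)
            if label is not None:
                numbering[q + 1] = label

    numbered = NumberedSequence(sequence=query, numbering=numbering, source=iso.name)
    # the NPF anchor must be reproduced exactly
    ok = False
    for start in _all_npf_starts(query):
        if all(
            numbering.get(start + off) == CGammaNLabel(segment="h2", index=8 + off)
            for off in range(3)
        ):
            ok = True
            break
    if not ok:
        raise NotNumberableError(
            "alignment did not place an NPF trimer on h2.8–h2.10; "
            "query may not be Gγ-like"
        )
    return numbered


def _all_npf_starts(seq: str) -> list[int]:
    out, i = [], seq.find("NPF")
    while i != -1:
        out.append(i + 1)
        i = seq.find("NPF", i + 1)
    return out


def number_h2_fragment(fragment: str) -> NumberedSequence:
    """Number a C-terminal (h2) peptide on its own, without a full-length query.

    Used for synthesized h2 peptides such as the Gγ1 C-terminal 17-mer
    KGIPEDKNPFKELKGGC: the NPF anchors ``h2.8``–``h2.10`` and a terminal CAAX
    cysteine is right-justified at ``h2.17``.
    """
    fragment = fragment.upper()
    if "NPF" not in fragment:
        raise NotNumberableError("fragment has no NPF motif; not numberable under CGγN")
    labels = _anchor_columns(fragment)
    labels = {p: lab for p, lab in labels.items() if lab.segment == "h2"}
    return NumberedSequence(sequence=fragment, numbering=labels, source="h2-fragment")
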
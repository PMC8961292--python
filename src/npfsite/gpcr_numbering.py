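"""Ballesteros–Weinstein (BW) numbering for class A GPCR sequences.

Positions are written ``<segment>.<index>`` where the segment is a
transmembrane helix (here TM1 and TM7), the first intracellular loop
(``12.xx``) or helix 8 (``8.xx``); ``x.50`` marks the most conserved residue
of each helix (Asn1.50, Pro7.50, Phe8.50 by the class A convention used
here).  Labels are assigned by *annotated-reference transfer*: the bundled
bovine rhodopsin sequence carries a frozen residue→label map over
TM1/ICL1/TM7/H8, and a query inherits labels across the columns of a global
pairwise alignment.  This is deterministic and directly testable against the
printed rhodopsin anchors (Tyr306=7.53, Phe313=8.50, Cys316=8.53, ...);
motif-based per-helix detection is deliberately not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._data import load_rhodopsin

__all__ = [
    "BWLabel",
    "AnnotatedReference",
    "NumberedGPCR",
    "NotClassALikeError",
    "rhodopsin_reference",
    "assign_bw",
    "extract_site_residues",
    "NPF_SITE_POSITIONS",
]


class NotClassALikeError(ValueError):
    """Raised when a query is too dissimilar from the class A reference."""


@dataclass(frozen=True, order=True)
class BWLabel:
    """One BW position; renders as e.g. ``1.56``, ``12.50``, ``8.53``."""

    segment: int  # 1, 12, 7 or 8
    position: int  # two-digit index around the x.50 anchor

    def __str__(self) -> str:
        return f"{self.segment}.{self.position}"

    @classmethod
    def parse(cls, text: str) -> "BWLabel":
        seg, _, pos = text.partition(".")
        return cls(segment=int(seg), position=int(pos))


#: the eight positions forming the TM1/ICL1/H8 NPF-recognition pocket
NPF_SITE_POSITIONS: tuple[BWLabel, ...] = tuple(
    BWLabel.parse(t) for t in ("1.55", "1.56", "1.59", "12.50", "8.49", "8.50", "8.54", "8.57")
)

# frozen annotation of the bovine rhodopsin reference: author residue ranges
# and the BW index of the first residue of each range.  Anchors: Asn55=1.50,
# Lys66/Lys67=12.48/12.49, Pro303=7.50, Phe313=8.50.
_RHODOPSIN_SEGMENTS: tuple[tuple[int, int, int, int], ...] = (
    # (segment, first_residue, last_residue, bw_of_first)
    (1, 35, 64, 30),    # TM1: 1.30..1.59
    (12, 66, 69, 48),   # ICL1: 12.48..12.51
    (7, 286, 309, 33),  # TM7: 7.33..7.56
    (8, 310, 323, 47),  # H8: 8.47..8.60
)


@dataclass(frozen=True)
class AnnotatedReference:
    """A reference sequence with a frozen residue→BW-label map."""

    name: str
    sequence: str
    numbering: Mapping[int, BWLabel]  # 1-based residue -> label

    def position_of(self, label: BWLabel) -> int:
        for pos, lab in self.numbering.items():
            if lab == label:
                return pos
        raise KeyError(f"{self.name}: no residue labelled {label}")


@lru_cache(maxsize=1)
def rhodopsin_reference() -> AnnotatedReference:
    """The annotated bovine rhodopsin reference (sequence of PDB entry 1U19)."""
    seq = load_rhodopsin()
    numbering: dict[int, BWLabel] = {}
    for segment, first, last, bw_first in _RHODOPSIN_SEGMENTS:
        for off in range(last - first + 1):
            numbering[first + off] = BWLabel(segment=segment, position=bw_first + off)
    ref = AnnotatedReference(name="RHO_BOVIN", sequence=seq, numbering=numbering)
    # sanity anchors of the annotation itself
    for pos, aa, label in ((55, "N", "1.50"), (306, "Y", "7.53"), (313, "F", "8.50"),
                           (316, "C", "8.53")):
        assert seq[pos - 1] == aa and str(numbering[pos]) == label, (
            f"reference annotation inconsistent at {label}"
        )
    return ref


@dataclass(frozen=True)
class NumberedGPCR:
    """A query sequence with BW labels transferred from the reference."""

    sequence: str
    numbering: Mapping[int, BWLabel]
    identity_tm1_h8: float  # fractional identity over the labelled TM1+H8 columns

    def position_of(self, label: BWLabel | str) -> int:
        if isinstance(label, str):
            label = BWLabel.parse(label)
        for pos, lab in self.numbering.items():
            if lab == label:
                return pos
        raise KeyError(f"no residue labelled {label}")

    def residue_at(self, label: BWLabel | str) -> str:
        return self.sequence[self.position_of(label) - 1]

    def segment_sequence(self, segment: int) -> str:
        """Extracted subsequence of one numbered segment (e.g. 8 for helix 8)."""
        positions = sorted(p for p, lab in self.numbering.items() if lab.segment == segment)
        return "".join(self.sequence[p - 1] for p in positions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in sorted(self.numbering):
            lab = self.numbering[pos]
            rows.append(
                {
                    "position": pos,
                    "residue": self.sequence[pos - 1],
                    "segment": lab.segment,
                    "label": str(lab),
                }
            )
        return pd.DataFrame(rows, columns=["position", "residue", "segment", "label"])


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    # free end gaps: receptor constructs are often truncated relative to rhodopsin
    aligner.end_gap_score = 0.0
    return aligner


def assign_bw(
    query: str,
    reference: AnnotatedReference | None = None,
    min_identity: float = 0.25,
) -> NumberedGPCR:
    """Assign BW labels to a class A GPCR sequence by reference transfer.

    The query is globally aligned to the annotated rhodopsin reference
    (BLOSUM62, affine gap 10/1, free end gaps) and labels are inherited across
    aligned columns; query insertions relative to the reference stay
    unlabelled.  Queries under *min_identity* fractional identity over the
    labelled TM1+H8 columns are rejected as not class A-like.
    """
    query = query.upper().replace("*", "")
    reference = reference or rhodopsin_reference()
    alignment = _make_aligner().align(reference.sequence, query)[0]

    numbering: dict[int, BWLabel] = {}
    tm1_h8_total = tm1_h8_matches = 0
    ref_blocks, query_blocks = alignment.aligned
    for (r0, r1), (q0, q1) in zip(ref_blocks, query_blocks):
        for r, q in zip(range(r0, r1), range(q0, q1)):
            label = reference.numbering.get(r + 1)
            if label is None:
                continue
            numbering[q + 1] = label
            if label.segment in (1, 8):
                tm1_h8_total += 1
                tm1_h8_matches += reference.sequence[r] == query[q]
    n_tm1_h8_reference = sum(1 for lab in reference.numbering.values() if lab.segment in (1, 8))
    identity = tm1_h8_matches / n_tm1_h8_reference
    if identity < min_identity:
        raise NotClassALikeError(
            f"identity over TM1+H8 is {identity:.2f} < {min_identity:.2f}; "
            "query does not look class A-like"
        )
    if tm1_h8_total < n_tm1_h8_reference * 0.5:
        raise NotClassALikeError("alignment covers less than half of the TM1+H8 reference")
    return NumberedGPCR(sequence=query, numbering=numbering, identity_tm1_h8=identity)


def extract_site_residues(numbered: NumberedGPCR) -> dict[BWLabel, str]:
    """Residue identities at the eight NPF-site positions; absent positions omitted."""
    out: dict[BWLabel, str] = {}
    for label in NPF_SITE_POSITIONS:
        try:
            out[label] = numbered.residue_at(label)
        except KeyError:
            pass
    return out
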
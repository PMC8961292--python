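"""Bundled reference sequences.

The package ships amino-acid sequences only: the twelve human Gγ isoforms
underlying the CGγN reference, and the bovine rhodopsin polypeptide used as
the annotated class A numbering reference.  The set is curated from public
sequence records; positions outside the anchored landmarks asserted by the
test suite should be re-verified against current database records before use
in production annotation pipelines.
"""

from __future__ import annotations

from functools import lru_cache
from importlib.resources import files

from Bio import SeqIO


def _read_fasta(name: str) -> dict[str, str]:
    path = files("npfsite._data") / name
    with path.open() as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


@lru_cache(maxsize=1)
def load_gamma_isoforms() -> dict[str, str]:
    """Human Gγ isoform protein sequences, keyed Ggamma1..Ggamma13 (no Ggamma6)."""
    return _read_fasta("gamma_isoforms.fasta")


@lru_cache(maxsize=1)
def load_rhodopsin() -> str:
    """Bovine rhodopsin sequence (348 aa), author numbering == sequence position."""
    return next(iter(_read_fasta("rhodopsin.fasta").values()))
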
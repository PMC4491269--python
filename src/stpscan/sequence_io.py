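"""FASTA input/output and redundancy filtering for peptide sequences.

Sequences are plain single-letter amino-acid strings. The 20 standard
residues plus the ambiguity codes X, B, Z and U are accepted; ambiguity
codes are carried through unchanged and treated as ordinary non-cysteine
residues by every downstream stage, since only cysteine identity matters
to the motif grammar.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUITY_RESIDUES = set("XBZU")
VALID_RESIDUES = STANDARD_RESIDUES | AMBIGUITY_RESIDUES


class SequenceError(ValueError):
    """Raised for sequences that fail validation."""


@dataclass(frozen=True)
class PeptideSequence:
    """A validated peptide chain: free-text id plus uppercase residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in VALID_RESIDUES:
                raise SequenceError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[PeptideSequence]:
    """Read a FASTA file into a list of validated peptide sequences.

    Order is preserved and residues are uppercased. Characters outside
    the accepted alphabet raise :class:`SequenceError` naming the record
    and 1-based position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return [
        PeptideSequence(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[PeptideSequence], path: str | Path) -> None:
    """Write sequences to ``path`` in FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _identity_aligner() -> PairwiseAligner:
    # Needleman-Wunsch with match 1 / mismatch 0 / linear gap -1.
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches divided by alignment length.

    This is a deterministic textbook definition, deliberately NOT a
    reimplementation of CD-HIT's word-based identity.
    """
    aln = _identity_aligner().align(a, b)[0]
    matches = 0
    length = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            length += 1
            if a[i] == b[j]:
                matches += 1
    # count gap columns: alignment length = aligned columns + gaps
    gaps = (len(a) - sum(a1 - a0 for a0, a1 in aln.aligned[0])) + (
        len(b) - sum(b1 - b0 for b0, b1 in aln.aligned[1])
    )
    length += gaps
    return matches / length if length else 0.0


def dedup_by_identity(
    seqs: Sequence[PeptideSequence], threshold: float = 0.9
) -> list[PeptideSequence]:
    """Greedy redundancy filter at a global pairwise-identity threshold.

    Scans in input order; a sequence is dropped when its identity to any
    already-retained sequence is >= ``threshold``. Retained sequences
    come back in their original order. Idempotent by construction.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept: list[PeptideSequence] = []
    for s in seqs:
        if all(pairwise_identity(s.residues, k.residues) < threshold for k in kept):
            kept.append(s)
    return kept
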
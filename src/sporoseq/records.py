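"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_VALID_NT = frozenset("ACGT")


@dataclass
class TranscriptRecord:
    """A transcript sequence with optional locus metadata.

    Locus metadata (``scaffold``, ``strand``, ``rank``) places the transcript
    in genomic context so that fragments of one gene can be recognised as
    neighbours.  ``rank`` is the 0-based order of the transcript along its
    scaffold; ``start``/``end`` are 1-based inclusive coordinates when known.
    """

    id: str
    sequence: str
    scaffold: Optional[str] = None
    strand: Optional[str] = None
    rank: Optional[int] = None
    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_NT
        if bad:
            raise ValueError(
                f"transcript {self.id!r} contains non-ACGT characters: {sorted(bad)}"
            )
        if self.strand is not None and self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id!r}: strand must be '+' or '-'")

    @property
    def has_locus(self) -> bool:
        return (
            self.scaffold is not None
            and self.strand is not None
            and self.rank is not None
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MergeCandidate:
    """A proposed merge of two transcripts under one consolidation rule.

    ``rule`` is one of ``overlap`` (exact suffix-prefix overlap between
    rank-adjacent fragments), ``homology_join`` (adjacent fragments hitting
    complementary intervals of the same database subject) or ``splice_dup``
    (a long exact shared block indicating alternative splice forms of one
    gene).  ``evidence`` holds the rule-specific measurements.
    """

    id_a: str
    id_b: str
    rule: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError("a transcript cannot be merged with itself")
        if self.rule not in ("overlap", "homology_join", "splice_dup"):
            raise ValueError(f"unknown merge rule {self.rule!r}")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))
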
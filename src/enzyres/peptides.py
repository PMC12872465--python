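"""Peptide sequences as token lists, with phosphoserine support.

Sequences use one-letter amino-acid codes.  Phosphoserine is written
``(pS)`` in string form and carried internally as the token ``"pS"`` so
that a single residue position can hold the modification.  Residue
composition treats ``pS`` as serine (the phosphate is a flag, not a
residue), which makes composition invariant under dephosphorylation.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
PHOSPHOSERINE = "pS"
VALID_TOKENS = CANONICAL_RESIDUES | {PHOSPHOSERINE}

_TOKEN_RE = re.compile(r"\(pS\)|pS|[A-Z]")


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains an unknown residue code."""


def parse_sequence(sequence: str) -> tuple[str, ...]:
    """Split a sequence string into residue tokens.

    ``"CCF(pS)WRCRC"`` -> ``('C','C','F','pS','W','R','C','R','C')``.
    """
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(sequence):
        if m.start() != pos:
            raise InvalidSequenceError(
                f"unparseable characters at position {pos} in {sequence!r}"
            )
        tok = m.group()
        if tok in ("(pS)", "pS"):
            tok = PHOSPHOSERINE
        elif tok not in CANONICAL_RESIDUES:
            raise InvalidSequenceError(f"unknown residue {tok!r} in {sequence!r}")
        tokens.append(tok)
        pos = m.end()
    if pos != len(sequence):
        raise InvalidSequenceError(
            f"unparseable characters at position {pos} in {sequence!r}"
        )
    return tuple(tokens)


def format_sequence(tokens: tuple[str, ...]) -> str:
    """Inverse of :func:`parse_sequence` (``pS`` rendered as ``(pS)``)."""
    return "".join(f"({t})" if t == PHOSPHOSERINE else t for t in tokens)


def residue_composition(sequence: str | tuple[str, ...]) -> Counter:
    """Multiset of residues; phosphoserine counts as serine."""
    tokens = parse_sequence(sequence) if isinstance(sequence, str) else sequence
    return Counter("S" if t == PHOSPHOSERINE else t for t in tokens)


def phospho_count(sequence: str | tuple[str, ...]) -> int:
    tokens = parse_sequence(sequence) if isinstance(sequence, str) else sequence
    return sum(1 for t in tokens if t == PHOSPHOSERINE)


@dataclass(frozen=True)
class Peptide:
    """An input peptide with an identifying label and optional role tags.

    Role tags mark the special kinetic behaviours of the network design:
    ``slow_substrate:<enzyme>`` (low-turnover, tight-binding substrate that
    acts as an effective reversible inhibitor of that enzyme) and
    ``proinhibitor`` (phosphorylated precursor whose inhibitory form is
    released by alkaline phosphatase).
    """

    sequence: str
    label: str = ""
    role_tags: tuple[str, ...] = field(default=())

    def __post_init__(self):
        parse_sequence(self.sequence)  # validation

    @property
    def tokens(self) -> tuple[str, ...]:
        return parse_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.tokens)
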
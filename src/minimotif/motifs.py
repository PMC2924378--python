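"""Minimotif consensus patterns, sequence scanning, and frequency scores.

A minimotif consensus is a short pattern over the 20 canonical amino
acids: each position is a fixed residue (``Y``), an alternative set
(``[ST]``), or a wildcard (``x``).  The frequency score of a motif in a
source protein of length L is the expected number of chance occurrences
of the pattern in a random length-L sequence under a background residue
composition:

    score = (L - k + 1) * prod_i sum_{a in class_i} f(a)

with k the pattern length and f the background frequencies (uniform
1/20 by default).  Low scores mean complex, rare patterns; the
frequency-score filter retains a minimotif when its score is at or
below a threshold (published sweep: 0.02, 0.03, 0.04).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterator, Mapping

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "PatternSyntaxError",
    "MotifPattern",
    "Minimotif",
    "MatchSite",
    "BackgroundFrequencies",
    "parse_pattern",
    "scan",
    "match_probability",
    "frequency_score",
    "read_minimotif_table",
    "read_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class PatternSyntaxError(ValueError):
    """The pattern text does not follow the consensus grammar."""


@dataclass(frozen=True)
class MotifPattern:
    """Ordered residue classes; each a frozenset of canonical letters."""

    positions: tuple[frozenset[str], ...]
    text: str = ""

    def __post_init__(self) -> None:
        if not self.positions:
            raise PatternSyntaxError("a pattern needs at least one position")

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.positions):
            return False
        return all(c in cls for c, cls in zip(window, self.positions))


@dataclass(frozen=True)
class Minimotif:
    """(source accession, consensus pattern, activity, target accession)."""

    source: str
    pattern: MotifPattern
    activity: str
    target: str

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("source and target accessions must be non-empty")


@dataclass(frozen=True)
class MatchSite:
    """One pattern occurrence; start is 1-based inclusive."""

    accession: str
    start: int
    matched: str


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Background probability of each of the 20 canonical residues."""

    freq: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.freq) != _AA_SET:
            raise ValueError("background must cover exactly the 20 canonical residues")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total!r}, not 1")
        if any(not 0.0 <= v <= 1.0 for v in self.freq.values()):
            raise ValueError("background frequencies must lie in [0, 1]")

    @classmethod
    def uniform(cls) -> "BackgroundFrequencies":
        return cls({aa: 1.0 / 20.0 for aa in AMINO_ACIDS})

    def class_probability(self, residue_class: frozenset[str]) -> float:
        return sum(self.freq[a] for a in residue_class)


_WILDCARD = frozenset(AMINO_ACIDS)


def parse_pattern(text: str) -> MotifPattern:
    """Parse consensus text into a :class:`MotifPattern`.

    Grammar (case-insensitive): one or more of an amino-acid letter, the
    wildcard ``x``, or a bracketed alternative set ``[ST]``.  ``x``
    inside brackets is a literal letter and is rejected (not canonical).
    """
    if not text:
        raise PatternSyntaxError("empty pattern")
    upper = text.upper()
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(upper):
        c = upper[i]
        if c == "[":
            j = upper.find("]", i + 1)
            if j == -1:
                raise PatternSyntaxError(f"unbalanced bracket in pattern {text!r}")
            letters = upper[i + 1 : j]
            if not letters:
                raise PatternSyntaxError(f"empty bracket class in pattern {text!r}")
            bad = set(letters) - _AA_SET
            if bad:
                raise PatternSyntaxError(
                    f"non-amino-acid letter(s) {sorted(bad)} in pattern {text!r}"
                )
            positions.append(frozenset(letters))
            i = j + 1
        elif c == "X":
            positions.append(_WILDCARD)
            i += 1
        elif c in _AA_SET:
            positions.append(frozenset(c))
            i += 1
        else:
            raise PatternSyntaxError(
                f"unexpected character {c!r} at position {i + 1} in pattern {text!r}"
            )
    return MotifPattern(tuple(positions), text=upper)


def scan(sequence: str, pattern: MotifPattern | str, accession: str = "") -> list[MatchSite]:
    """All (possibly overlapping) occurrences of *pattern* in *sequence*.

    Non-canonical residues (B, Z, X, U, ...) in the sequence never match
    any class, wildcards included.  Starts are 1-based, ascending.
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    seq = sequence.upper()
    k = len(pattern)
    sites = []
    for start in range(len(seq) - k + 1):
        window = seq[start : start + k]
        if pattern.matches(window):
            sites.append(MatchSite(accession=accession, start=start + 1, matched=window))
    return sites


def match_probability(
    pattern: MotifPattern | str, bg: BackgroundFrequencies | None = None
) -> float:
    """Probability that one random window satisfies the pattern."""
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    if bg is None:
        bg = BackgroundFrequencies.uniform()
    p = 1.0
    for cls in pattern.positions:
        p *= bg.class_probability(cls)
    return p


def frequency_score(
    pattern: MotifPattern | str,
    protein_length: int,
    bg: BackgroundFrequencies | None = None,
) -> float:
    """Expected chance occurrences of *pattern* in a length-L sequence.

    Zero when the protein is shorter than the pattern (no windows).
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    if protein_length < 0:
        raise ValueError("protein_length must be >= 0")
    windows = max(protein_length - len(pattern) + 1, 0)
    return windows * match_probability(pattern, bg)


# ---------------------------------------------------------------------------
# I/O helpers

MINIMOTIF_COLUMNS = ["source_accession", "motif", "activity", "target_accession"]


def read_minimotif_table(stream: IO[str] | str) -> list[Minimotif]:
    """Read a minimotif TSV with a header row naming the four columns."""
    frame = pd.read_csv(stream, sep="\t", dtype=str, comment="#")
    missing = [c for c in MINIMOTIF_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"minimotif table is missing column(s) {missing}")
    motifs = []
    for row in frame.itertuples(index=False):
        motifs.append(
            Minimotif(
                source=str(row.source_accession),
                pattern=parse_pattern(str(row.motif)),
                activity=str(row.activity),
                target=str(row.target_accession),
            )
        )
    return motifs


def read_fasta(stream: IO[str] | str) -> dict[str, str]:
    """Read FASTA into accession -> sequence (first word of the header)."""
    from Bio import SeqIO

    handle: IO[str]
    close = False
    if isinstance(stream, str):
        handle = open(stream, encoding="utf-8")
        close = True
    else:
        handle = stream
    try:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if close:
            handle.close()
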
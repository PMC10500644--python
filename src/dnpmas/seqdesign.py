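"""Unique amino-acid-pair labeling design.

Selective isotope labeling of a protein with one 13C-labeled and one
15N-labeled amino-acid type produces a single filtered correlation signal
(NCO/NCOCX/CON) wherever the two types are adjacent in sequence.  If that
ordered dipeptide occurs exactly once, the signal is site-specific: a
"unique pair".  This module scans a primary sequence for such pairs and
annotates them as candidate labeling sites.

Conventions
-----------
* Dipeptides are ordered and counted over all overlapping windows of
  length 2 (step 1), so a sequence of length L contributes L-1 counts.
* Uniqueness of "XY" is independent of the count of "YX": the 13C label
  goes on the first residue, the 15N label on the second, and the
  one-bond CO->N transfer is directional.
* Positions are 1-based, matching conventional residue numbering
  (e.g. M237-R238 in a GPCR's third intracellular loop).
* Residue types prone to metabolic isotope scrambling can be flagged but
  are never silently dropped: whether scrambling disqualifies a site
  depends on the expression system, so filtering is advisory.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .errors import DataError

#: The 20 standard proteinogenic amino acids, one-letter codes, sorted.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue types commonly reported as scrambling-prone under metabolic
#: labeling (amide/carboxyl nitrogen exchange via transaminases).  Shipped
#: as a suggestion only; the default exclusion set is empty.
SUGGESTED_SCRAMBLING_PRONE: frozenset[str] = frozenset("NDQE")

_NUCLEOTIDE_LETTERS = frozenset("ACGTUN")


@dataclass
class ResiduePair:
    """A candidate labeling site: an adjacent, ordered residue pair.

    ``residue_first`` is the 13C-labeled type, ``residue_second`` the
    15N-labeled type.  ``position_first`` is 1-based.
    """

    position_first: int
    residue_first: str
    residue_second: str
    is_homopair: bool = False
    region: str | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def position_second(self) -> int:
        return self.position_first + 1

    @property
    def dipeptide(self) -> str:
        return self.residue_first + self.residue_second

    def __str__(self) -> str:  # e.g. "M237-R238"
        return (
            f"{self.residue_first}{self.position_first}-"
            f"{self.residue_second}{self.position_second}"
        )


@dataclass
class RegionMap:
    """Named sequence intervals (1-based, inclusive); may overlap."""

    regions: list[tuple[str, int, int]]

    def validate(self, sequence_length: int) -> None:
        for name, start, end in self.regions:
            if not (1 <= start <= end <= sequence_length):
                raise DataError(
                    f"region {name!r} [{start}, {end}] outside sequence "
                    f"of length {sequence_length}"
                )

    def annotate(self, position: int) -> str | None:
        """Names of all regions containing ``position``, or None."""
        names = [n for n, s, e in self.regions if s <= position <= e]
        return ";".join(names) if names else None


def _check_sequence(sequence: str, strict: bool) -> str:
    sequence = sequence.upper().replace("*", "")
    if len(sequence) < 2:
        raise DataError("sequence must contain at least 2 residues")
    if strict:
        bad = sorted(set(sequence) - set(AMINO_ACIDS))
        if bad:
            raise DataError(f"non-standard residue letters {bad} (strict mode)")
    return sequence


def count_dipeptides(sequence: str, strict: bool = True) -> dict[str, int]:
    """Count every ordered, overlapping dipeptide in ``sequence``.

    For a clean sequence of length L, the counts sum to L-1.  In
    non-strict mode, windows touching a non-standard letter are skipped.
    """
    sequence = _check_sequence(sequence, strict)
    standard = set(AMINO_ACIDS)
    counts: Counter[str] = Counter()
    for i in range(len(sequence) - 1):
        a, b = sequence[i], sequence[i + 1]
        if a in standard and b in standard:
            counts[a + b] += 1
    return dict(counts)


def find_unique_pairs(
    sequence: str,
    exclude_residues: Iterable[str] = (),
    regions: RegionMap | None = None,
    strict: bool = True,
) -> list[ResiduePair]:
    """All positions whose ordered dipeptide occurs exactly once.

    Pairs containing a residue from ``exclude_residues`` are kept but
    flagged ``scrambling-prone``; homopairs (both residues of one type,
    which would carry both labels) are flagged via ``is_homopair``.
    Region annotation, when a :class:`RegionMap` is given, never changes
    membership of the result.
    """
    sequence = _check_sequence(sequence, strict)
    excluded = {r.upper() for r in exclude_residues}
    counts = count_dipeptides(sequence, strict=strict)
    if regions is not None:
        regions.validate(len(sequence))

    pairs: list[ResiduePair] = []
    standard = set(AMINO_ACIDS)
    for i in range(len(sequence) - 1):
        a, b = sequence[i], sequence[i + 1]
        if a not in standard or b not in standard:
            continue
        if counts[a + b] != 1:
            continue
        flags: set[str] = set()
        if a in excluded or b in excluded:
            flags.add("scrambling-prone")
        pairs.append(
            ResiduePair(
                position_first=i + 1,
                residue_first=a,
                residue_second=b,
                is_homopair=(a == b),
                region=regions.annotate(i + 1) if regions else None,
                flags=flags,
            )
        )
    return pairs


def pair_alphabet_size(alphabet: Iterable[str] = AMINO_ACIDS) -> int:
    """Number of ordered residue pairs available to the labeling scheme.

    For the 20 standard amino acids this is 400, which is why a protein
    of a few hundred residues typically offers many unique pairs.
    """
    letters = set(alphabet)
    if not letters:
        raise DataError("alphabet must not be empty")
    return len(letters) ** 2


def count_residue(sequence: str, residue: str) -> int:
    """Occurrences of a single residue type (0 if absent)."""
    if len(residue) != 1:
        raise DataError("residue must be a single letter")
    return sequence.upper().count(residue.upper())


def looks_like_nucleotide(sequence: str) -> bool:
    """Heuristic alphabet check: True if every letter is a nucleotide code.

    Any sequence over {A, C, G, T, U, N} is treated as nucleotide; this is
    ambiguous only for unusually composition-biased peptides, and callers
    can override.
    """
    letters = set(sequence.upper()) - {"\n", " ", "-"}
    return bool(letters) and letters <= _NUCLEOTIDE_LETTERS


def translate_nucleotide(sequence: str) -> str:
    """Translate a coding nucleotide sequence (frame 1, standard code).

    Translation stops at the first stop codon.  Trailing bases that do
    not fill a codon are ignored.
    """
    seq = sequence.upper().replace("U", "T").replace(" ", "").replace("\n", "")
    if len(seq) < 6:
        raise DataError("nucleotide sequence too short to translate")
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate(to_stop=True))


def pairs_to_records(pairs: Sequence[ResiduePair]) -> list[Mapping[str, object]]:
    """Flatten pairs for tabular (TSV) output."""
    return [
        {
            "position": p.position_first,
            "pair": p.dipeptide,
            "labels": f"13C-{p.residue_first}/15N-{p.residue_second}",
            "site": str(p),
            "is_homopair": p.is_homopair,
            "region": p.region or "",
            "flags": ",".join(sorted(p.flags)),
        }
        for p in pairs
    ]
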
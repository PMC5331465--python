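"""Variant notation and mutant-library generators.

A variant is an ordered set of single-residue substitutions written in the
usual ``L93A`` notation, joined with ``+`` for multiple substitutions; the
canonical label orders substitutions by position.  ``WT`` denotes the
empty variant.  Library generators cover the three campaign strategies:
alanine scanning, site saturation and combinatorial rounds.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Mapping, NamedTuple, Sequence, Set, Tuple

from .errors import InvalidInputError, VariantParseError

__all__ = [
    "AMINO_ACIDS",
    "Substitution",
    "Variant",
    "parse_variant",
    "alanine_scan_library",
    "site_saturation_library",
    "combinatorial_library",
    "LibraryNotice",
]

#: the 20 canonical residues, alphabet order
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

_TOKEN = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class LibraryNotice(UserWarning):
    """Non-fatal library-generation event (skipped position etc.)."""


class Substitution(NamedTuple):
    position: int  # 1-based residue index
    wt_aa: str
    new_aa: str

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.new_aa}"


@dataclass(frozen=True)
class Variant:
    """An ordered set of substitutions; the unit of screening."""

    substitutions: Tuple[Substitution, ...] = ()

    def __post_init__(self):
        subs = tuple(sorted(
            (Substitution(int(p), w, n) for p, w, n in self.substitutions),
            key=lambda s: s.position,
        ))
        positions = [s.position for s in subs]
        if len(set(positions)) != len(positions):
            raise VariantParseError(
                f"duplicate positions in variant: {positions}"
            )
        for s in subs:
            if s.wt_aa == s.new_aa:
                raise VariantParseError(
                    f"substitution {s.label} is a no-op (wt == new)"
                )
            if s.wt_aa not in AMINO_ACIDS or s.new_aa not in AMINO_ACIDS:
                raise VariantParseError(
                    f"unknown residue code in {s.label}"
                )
        object.__setattr__(self, "substitutions", subs)

    @property
    def label(self) -> str:
        if not self.substitutions:
            return "WT"
        return "+".join(s.label for s in self.substitutions)

    @property
    def is_wild_type(self) -> bool:
        return not self.substitutions

    @property
    def positions(self) -> Tuple[int, ...]:
        return tuple(s.position for s in self.substitutions)

    def __str__(self) -> str:
        return self.label


def parse_variant(label: str) -> Variant:
    """Parse ``"WT"`` or ``"X<pos>Y[+X<pos>Y...]"`` into a Variant.

    The returned variant's label is canonical (substitutions sorted by
    position), so parse/format round-trips.
    """
    if not isinstance(label, str) or not label.strip():
        raise VariantParseError(f"empty variant label: {label!r}")
    text = label.strip()
    if text.upper() == "WT":
        return Variant()
    subs = []
    for token in text.split("+"):
        token = token.strip()
        m = _TOKEN.match(token)
        if not m:
            raise VariantParseError(
                f"malformed substitution token {token!r} in {label!r}"
            )
        subs.append(Substitution(int(m.group(2)), m.group(1), m.group(3)))
    return Variant(substitutions=tuple(subs))


def alanine_scan_library(
    positions: Sequence[Tuple[int, str]],
    exclusions: Set[int] = frozenset(),
) -> List[Variant]:
    """One X→A variant per non-excluded position.

    Positions whose wild type is already Ala or Gly are skipped (an
    alanine substitution there is a no-op or a backbone change) with a
    :class:`LibraryNotice`; exclusions not present in ``positions`` warn
    rather than fail.
    """
    if not positions:
        raise InvalidInputError("alanine scan needs at least one position")
    known = {p for p, _ in positions}
    for e in exclusions:
        if e not in known:
            warnings.warn(
                f"excluded position {e} not in the position list",
                LibraryNotice,
            )
    out = []
    for pos, wt in sorted(positions):
        if pos in exclusions:
            continue
        if wt in ("A", "G"):
            warnings.warn(
                f"position {pos} ({wt}) skipped: wild type is already "
                "Ala/Gly", LibraryNotice,
            )
            continue
        out.append(Variant(((pos, wt, "A"),)))
    return out


def site_saturation_library(
    position: int,
    wt_aa: str,
    alphabet: Iterable[str] = AMINO_ACIDS,
) -> List[Variant]:
    """One variant per alphabet residue other than the wild type."""
    alphabet = sorted(set(alphabet))
    if not alphabet:
        raise InvalidInputError("empty saturation alphabet")
    if wt_aa not in alphabet:
        raise InvalidInputError(
            f"wild-type {wt_aa!r} not in the saturation alphabet"
        )
    return [Variant(((position, wt_aa, aa),))
            for aa in alphabet if aa != wt_aa]


def combinatorial_library(
    choices: Mapping[int, Tuple[str, Sequence[str]]],
) -> List[Variant]:
    """Cartesian product of per-position residue choices.

    ``choices`` maps position → (wild type, candidate residues).  A wild
    type appearing in its own candidate list is removed with a notice.
    Output order is deterministic: positions ascending, residues in
    alphabet order within each position.
    """
    cleaned = []
    for pos in sorted(choices):
        wt, res = choices[pos]
        res = sorted(set(res))
        if not res:
            raise InvalidInputError(f"empty choice list at position {pos}")
        if wt in res:
            warnings.warn(
                f"position {pos}: wild-type {wt} removed from its own "
                "choice list", LibraryNotice,
            )
            res = [r for r in res if r != wt]
            if not res:
                raise InvalidInputError(
                    f"position {pos}: no choices left after removing wt"
                )
        cleaned.append([(pos, wt, r) for r in res])
    return [Variant(tuple(combo)) for combo in itertools.product(*cleaned)]
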
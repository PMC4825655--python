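"""Restriction-enzyme catalog: IUPAC recognition sites and site scanning.

An enzyme is defined by an IUPAC recognition sequence and the top-strand cut
offset within it (``G^ANTC`` means the top strand is cleaved one base into
the site).  Scanning reports every match start on the forward strand; for
non-palindromic sites the reverse-complement pattern is scanned as well and
the two position lists are merged.  Ambiguity codes in the *genome* (``N``
and friends) never match any pattern position — assembly gaps must not
produce phantom cut sites — whereas ambiguity codes in the *pattern* expand
to their usual base sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator

# IUPAC nucleotide codes -> the set of plain bases each stands for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class CatalogError(ValueError):
    """Raised for malformed enzyme definitions or catalog files."""


def _validate_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    if not pattern:
        raise CatalogError("recognition sequence must be non-empty")
    bad = sorted(set(pattern) - set(IUPAC_CODES))
    if bad:
        raise CatalogError(
            f"invalid IUPAC letter(s) {','.join(bad)} in recognition sequence {pattern!r}"
        )
    return pattern


def expand_iupac(pattern: str) -> set[str]:
    """Expand an IUPAC pattern into the full set of plain ACGT strings.

    The size of the result is the product of the per-position degeneracies
    (e.g. ``GANTC`` -> 4 strings, ``GCWGC`` -> 2).
    """
    pattern = _validate_pattern(pattern)
    return {"".join(p) for p in product(*(IUPAC_CODES[c] for c in pattern))}


def reverse_complement_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (degenerate codes included)."""
    pattern = _validate_pattern(pattern)
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern))


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition site plus top-strand cut offset.

    ``cut_offset`` is measured from the site start, so CviAII (C^ATG) has
    offset 1 and PstI (CTGCA^G) has offset 5.  ``methylation_sensitive`` and
    ``incubation_temp_c`` are metadata only; cutting is never conditioned on
    them.
    """

    name: str
    recognition: str
    cut_offset: int
    methylation_sensitive: bool = False
    incubation_temp_c: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise CatalogError("enzyme name must be non-empty")
        object.__setattr__(self, "recognition", _validate_pattern(self.recognition))
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise CatalogError(
                f"{self.name}: cut_offset {self.cut_offset} outside "
                f"[0, {len(self.recognition)}]"
            )

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        """True when the site reads the same on both strands (as IUPAC)."""
        return reverse_complement_iupac(self.recognition) == self.recognition


def _compile(pattern: str) -> re.Pattern[str]:
    # Lookahead makes overlapping matches visible; classes contain plain
    # bases only, so genome N (or any ambiguity code) matches nothing.
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]" for c in pattern
    )
    return re.compile(f"(?=({body}))")


def _match_starts(sequence: str, pattern: str) -> list[int]:
    return [m.start() for m in _compile(pattern).finditer(sequence)]


def scan_oriented(sequence: str, enzyme: EnzymeSpec) -> tuple[list[int], list[int]]:
    """Site start positions per orientation: (forward, reverse-complement).

    For palindromic sites the reverse list is empty (the forward scan already
    covers both strands).  The input is uppercased; soft-masked FASTA is
    therefore handled.
    """
    sequence = sequence.upper()
    fwd = _match_starts(sequence, enzyme.recognition)
    if enzyme.is_palindromic:
        return fwd, []
    rc = reverse_complement_iupac(enzyme.recognition)
    rev = [p for p in _match_starts(sequence, rc) if p not in set(fwd)]
    return fwd, rev


def scan_sites(sequence: str, enzyme: EnzymeSpec, strands: str = "both") -> list[int]:
    """All recognition-site start positions on a sequence, sorted ascending.

    Overlapping matches are all reported.  With ``strands="both"`` (default)
    reverse-complement matches of non-palindromic sites are merged in and
    deduplicated; ``strands="forward"`` restricts to the forward pattern.
    """
    if strands not in ("both", "forward"):
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    fwd, rev = scan_oriented(sequence, enzyme)
    if strands == "forward":
        return fwd
    return sorted(set(fwd) | set(rev))


# Standard REBASE definitions (^ marks the top-strand cut) for the enzymes
# used throughout the single-enzyme screen and the pair designs.  Incubation
# temperatures and methylation sensitivity follow supplier catalogs and are
# metadata only.
_BUILTIN: tuple[tuple[str, str, int, bool, float], ...] = (
    # name, recognition, cut_offset, methylation_sensitive, temp C
    ("CviAII", "CATG", 1, False, 25.0),
    ("NlaIII", "CATG", 4, False, 37.0),
    ("MluCI", "AATT", 0, False, 37.0),
    ("MseI", "TTAA", 1, False, 37.0),
    ("HinfI", "GANTC", 1, False, 37.0),
    ("DdeI", "CTNAG", 1, False, 37.0),
    ("BfaI", "CTAG", 1, False, 37.0),
    ("TfiI", "GAWTC", 1, False, 65.0),
    ("HpyCH4IV", "ACGT", 1, True, 37.0),
    ("MspI", "CCGG", 1, False, 37.0),
    ("ApeKI", "GCWGC", 1, True, 75.0),
    ("AvaII", "GGWCC", 1, True, 37.0),
    ("PstI", "CTGCAG", 5, True, 37.0),
    ("TaqI", "TCGA", 1, False, 65.0),
    ("EcoRI", "GAATTC", 1, False, 37.0),
)


def builtin_catalog() -> list[EnzymeSpec]:
    """The built-in enzyme table (standard REBASE definitions)."""
    return [
        EnzymeSpec(name, rec, off, methylation_sensitive=meth, incubation_temp_c=temp)
        for name, rec, off, meth, temp in _BUILTIN
    ]


def _parse_bool(token: str, line_no: int) -> bool:
    t = token.strip().lower()
    if t in ("1", "true", "yes", "y"):
        return True
    if t in ("0", "false", "no", "n"):
        return False
    raise CatalogError(f"line {line_no}: cannot parse boolean {token!r}")


def _iter_tsv_rows(path: Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            yield line_no, line.split()


def load_catalog(source: str | Path | None = None) -> list[EnzymeSpec]:
    """Load the enzyme catalog from a TSV file, or the built-in table.

    The TSV has whitespace/tab-separated columns
    ``name recognition cut_offset [methylation_sensitive] [incubation_temp_c]``
    with ``#`` comments.  Rows are validated; a malformed row raises
    :class:`CatalogError` naming the offending line.
    """
    if source is None:
        return builtin_catalog()
    path = Path(source)
    enzymes: list[EnzymeSpec] = []
    seen: set[str] = set()
    for line_no, fields in _iter_tsv_rows(path):
        if len(fields) < 3:
            raise CatalogError(
                f"{path.name} line {line_no}: expected at least 3 columns "
                f"(name recognition cut_offset), got {len(fields)}"
            )
        name, recognition, offset_s = fields[:3]
        try:
            cut_offset = int(offset_s)
        except ValueError:
            raise CatalogError(
                f"{path.name} line {line_no}: cut_offset {offset_s!r} is not an integer"
            ) from None
        meth = _parse_bool(fields[3], line_no) if len(fields) > 3 else False
        temp = float(fields[4]) if len(fields) > 4 else None
        try:
            enz = EnzymeSpec(name, recognition, cut_offset,
                             methylation_sensitive=meth, incubation_temp_c=temp)
        except CatalogError as exc:
            raise CatalogError(f"{path.name} line {line_no}: {exc}") from None
        if enz.name in seen:
            raise CatalogError(f"{path.name} line {line_no}: duplicate enzyme {enz.name!r}")
        seen.add(enz.name)
        enzymes.append(enz)
    if not enzymes:
        raise CatalogError(f"{path.name}: no enzyme rows found")
    return enzymes


def catalog_index(enzymes: Iterable[EnzymeSpec]) -> dict[str, EnzymeSpec]:
    """Name -> EnzymeSpec lookup for a catalog list."""
    return {e.name: e for e in enzymes}


def get_enzyme(name: str, catalog: Iterable[EnzymeSpec] | None = None) -> EnzymeSpec:
    """Look an enzyme up by name in a catalog (built-in by default)."""
    idx = catalog_index(builtin_catalog() if catalog is None else catalog)
    try:
        return idx[name]
    except KeyError:
        raise CatalogError(
            f"unknown enzyme {name!r}; known: {', '.join(sorted(idx))}"
        ) from None
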
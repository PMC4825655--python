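"""Cut-site arithmetic and fragment enumeration for single and double digests.

A digest of one record is the sorted, deduplicated union of the cut
coordinates of the participating enzymes; fragments are the intervals
between consecutive cuts, each end labeled with the set of enzymes that
produced the cut (or ``CHROM_END`` for a chromosome terminus).  GBS-style
selection then keeps fragments inside an inclusive length window and — for
double digests — only those whose two ends can be assigned two *distinct*
enzymes (the different-ends rule: only such fragments receive both adapters
and get sequenced).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .catalog import EnzymeSpec, scan_oriented

#: End label for the interval bounded by a chromosome terminus rather than a cut.
CHROM_END = "CHROM_END"


@dataclass(frozen=True)
class CutSite:
    """A 0-based inter-base cut coordinate and the enzymes cutting there."""

    position: int
    enzymes: frozenset[str]

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"cut position must be >= 0, got {self.position}")
        if not self.enzymes:
            raise ValueError("a cut site needs at least one responsible enzyme")
        object.__setattr__(self, "enzymes", frozenset(self.enzymes))


@dataclass(frozen=True)
class Fragment:
    """A half-open interval [start, end) with labeled ends.

    ``left_end``/``right_end`` are frozensets of enzyme names; a terminal
    fragment carries ``{CHROM_END}`` on its outer side.  A cut coordinate
    claimed by two enzymes propagates the full label set, since either
    enzyme's adapter could ligate to that end.
    """

    record_id: str
    start: int
    end: int
    left_end: frozenset[str]
    right_end: frozenset[str]

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"fragment length must be >= 1 ({self.start}..{self.end})")
        object.__setattr__(self, "left_end", frozenset(self.left_end))
        object.__setattr__(self, "right_end", frozenset(self.right_end))

    @property
    def length(self) -> int:
        return self.end - self.start

    def has_different_enzyme_ends(self) -> bool:
        """True if two distinct enzymes can be assigned to the two ends.

        ``CHROM_END`` never qualifies as an enzyme.
        """
        left = self.left_end - {CHROM_END}
        right = self.right_end - {CHROM_END}
        if not left or not right:
            return False
        return len(left | right) >= 2


def _as_enzyme_list(enzymes: EnzymeSpec | Iterable[EnzymeSpec]) -> list[EnzymeSpec]:
    enz = [enzymes] if isinstance(enzymes, EnzymeSpec) else list(enzymes)
    if not 1 <= len(enz) <= 2:
        raise ValueError(f"expected one or two enzymes, got {len(enz)}")
    return enz


def cut_positions(
    sequence: str,
    enzymes: EnzymeSpec | Iterable[EnzymeSpec],
    boundary_mode: str = "cut_offset",
    strands: str = "both",
) -> list[CutSite]:
    """Labeled, deduplicated cut coordinates of one or two enzymes.

    In ``cut_offset`` mode a forward-orientation site starting at ``p`` cuts
    the top strand at ``p + cut_offset``; a reverse-orientation site of a
    non-palindromic enzyme cuts at ``p + site_length - cut_offset`` (the
    enzyme sits on the other strand, so its bottom-strand cleavage is what
    crosses the genome's top strand).  ``site_start`` mode places the
    boundary at the site start instead; the two conventions differ by a few
    bp per fragment.  Coordinates shared by both enzymes carry both labels.
    """
    if boundary_mode not in ("cut_offset", "site_start"):
        raise ValueError(
            f"boundary_mode must be 'cut_offset' or 'site_start', got {boundary_mode!r}"
        )
    enz_list = _as_enzyme_list(enzymes)
    length = len(sequence)
    labels: dict[int, set[str]] = {}
    for enz in enz_list:
        fwd, rev = scan_oriented(sequence, enz)
        if strands == "forward":
            rev = []
        elif strands != "both":
            raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
        if boundary_mode == "cut_offset":
            coords = [p + enz.cut_offset for p in fwd]
            coords += [p + enz.site_length - enz.cut_offset for p in rev]
        else:
            coords = list(fwd) + list(rev)
        for c in coords:
            c = min(max(c, 0), length)
            labels.setdefault(c, set()).add(enz.name)
    return [CutSite(pos, frozenset(names)) for pos, names in sorted(labels.items())]


def enumerate_fragments(
    cuts: Sequence[CutSite],
    record_length: int,
    record_id: str = "",
    terminal_policy: str = "include",
) -> list[Fragment]:
    """Fragments between consecutive cuts, tiling the record.

    With ``terminal_policy="include"`` the leading ``[0, first_cut)`` and
    trailing ``[last_cut, L)`` intervals are emitted with ``CHROM_END`` on
    the outer side, so fragment lengths sum to the record length;
    ``"exclude"`` drops both terminals.  Zero-length intervals (a cut at
    coordinate 0 or L) are suppressed.
    """
    if terminal_policy not in ("include", "exclude"):
        raise ValueError(
            f"terminal_policy must be 'include' or 'exclude', got {terminal_policy!r}"
        )
    positions = [c.position for c in cuts]
    if positions != sorted(set(positions)):
        raise ValueError("cuts must be sorted and deduplicated")
    if positions and positions[-1] > record_length:
        raise ValueError(
            f"cut position {positions[-1]} beyond record length {record_length}"
        )
    bounds: list[tuple[int, frozenset[str]]] = [(0, frozenset({CHROM_END}))]
    bounds += [(c.position, c.enzymes) for c in cuts]
    bounds.append((record_length, frozenset({CHROM_END})))

    fragments: list[Fragment] = []
    for (start, left_lab), (end, right_lab) in zip(bounds, bounds[1:]):
        if end - start < 1:
            continue
        if terminal_policy == "exclude" and (CHROM_END in left_lab or CHROM_END in right_lab):
            continue
        fragments.append(Fragment(record_id, start, end, left_lab, right_lab))
    return fragments


def select_fragments(
    fragments: Iterable[Fragment],
    min_len: int = 100,
    max_len: int = 600,
    end_rule: str = "any",
) -> list[Fragment]:
    """GBS size selection (inclusive window) plus the optional different-ends rule.

    ``end_rule="any"`` keeps every fragment in the length window (single
    digests); ``"different_enzymes"`` additionally requires that the two end
    label sets admit two distinct enzymes (double digests; ``CHROM_END``
    never qualifies, so terminal fragments are excluded automatically).
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    if end_rule not in ("any", "different_enzymes"):
        raise ValueError(
            f"end_rule must be 'any' or 'different_enzymes', got {end_rule!r}"
        )
    kept = [f for f in fragments if min_len <= f.length <= max_len]
    if end_rule == "different_enzymes":
        kept = [f for f in kept if f.has_different_enzyme_ends()]
    return kept


def digest_record(
    sequence: str,
    record_id: str,
    enzymes: EnzymeSpec | Iterable[EnzymeSpec],
    boundary_mode: str = "cut_offset",
    terminal_policy: str = "include",
    strands: str = "both",
) -> tuple[list[CutSite], list[Fragment]]:
    """Convenience: cut positions and fragments for one record."""
    cuts = cut_positions(sequence, enzymes, boundary_mode=boundary_mode, strands=strands)
    frags = enumerate_fragments(cuts, len(sequence), record_id, terminal_policy)
    return cuts, frags


def _end_label(labels: frozenset[str]) -> str:
    return "+".join(sorted(labels))


def fragments_to_bed(fragments: Iterable[Fragment]) -> str:
    """BED6 text for a fragment list: name=left|right labels, score=length."""
    lines = []
    for f in fragments:
        name = f"{_end_label(f.left_end)}|{_end_label(f.right_end)}"
        lines.append(f"{f.record_id}\t{f.start}\t{f.end}\t{name}\t{f.length}\t.")
    return "\n".join(lines) + ("\n" if lines else "")
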
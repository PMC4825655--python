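"""The four fragment metrics and the IgC genome-coverage statistic.

For one genome and one enzyme (or enzyme pair) a digest is summarised by
four metrics — the total number of fragments, their total length, the
number of fragments passing selection, and their total length — computed
per chromosome and summed over the genome.  The in-silico genome coverage
is then

    IgC = 100 * len_fragments_selected / genome_length        (percent)

with the reported assembly length (all bases, N included) as the default
denominator.  Single digests select on the length window alone; double
digests additionally apply the different-ends rule, which is what makes a
pair such as HinfI + HpyCH4IV cover far more of a genome than the
six-cutter reference pair PstI + MspI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .catalog import EnzymeSpec
from .digest import Fragment, digest_record, select_fragments
from .genome_io import Genome, genome_length


def igc(selected_length_bp: int | float, genome_length_bp: int | float) -> float:
    """In-silico genome coverage, percent: 100 * selected length / genome length."""
    if genome_length_bp <= 0:
        raise ValueError(f"genome length must be positive, got {genome_length_bp}")
    return 100.0 * selected_length_bp / genome_length_bp


def round1(value: float) -> float:
    """Half-up rounding to 1 decimal, for tabular presentation only."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RecordMetrics:
    """The four fragment metrics for one record."""

    record_id: str
    n_fragments_total: int
    len_fragments_total: int
    n_fragments_selected: int
    len_fragments_selected: int


@dataclass(frozen=True)
class DigestSummary:
    """Genome-wide digest metrics and IgC for one genome x enzyme(-pair)."""

    genome_id: str
    enzymes: tuple[str, ...]
    n_fragments_total: int
    len_fragments_total: int
    n_fragments_selected: int
    len_fragments_selected: int
    genome_length_bp: int
    per_record: tuple[RecordMetrics, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.n_fragments_selected > self.n_fragments_total:
            raise ValueError("selected fragment count exceeds total")
        if self.len_fragments_selected > self.len_fragments_total:
            raise ValueError("selected fragment length exceeds total")

    @property
    def igc_percent(self) -> float:
        return igc(self.len_fragments_selected, self.genome_length_bp)

    def row(self) -> dict[str, object]:
        """Flat dict for tabular (TSV/DataFrame) output; full precision."""
        return {
            "genome_id": self.genome_id,
            "enzymes": "+".join(self.enzymes),
            "n_fragments_total": self.n_fragments_total,
            "len_fragments_total": self.len_fragments_total,
            "n_fragments_selected": self.n_fragments_selected,
            "len_fragments_selected": self.len_fragments_selected,
            "genome_length_bp": self.genome_length_bp,
            "igc_percent": self.igc_percent,
        }


def _metrics(fragments: list[Fragment], selected: list[Fragment], record_id: str) -> RecordMetrics:
    return RecordMetrics(
        record_id=record_id,
        n_fragments_total=len(fragments),
        len_fragments_total=sum(f.length for f in fragments),
        n_fragments_selected=len(selected),
        len_fragments_selected=sum(f.length for f in selected),
    )


def _digest_genome(
    genome: Genome,
    enzymes: list[EnzymeSpec],
    genome_id: str,
    end_rule: str,
    min_len: int,
    max_len: int,
    boundary_mode: str,
    terminal_policy: str,
    denominator_mode: str,
) -> DigestSummary:
    per_record = []
    for rec in genome:
        _, frags = digest_record(
            rec.sequence, rec.id, enzymes,
            boundary_mode=boundary_mode, terminal_policy=terminal_policy,
        )
        selected = select_fragments(frags, min_len=min_len, max_len=max_len, end_rule=end_rule)
        per_record.append(_metrics(frags, selected, rec.id))
    return DigestSummary(
        genome_id=genome_id,
        enzymes=tuple(e.name for e in enzymes),
        n_fragments_total=sum(m.n_fragments_total for m in per_record),
        len_fragments_total=sum(m.len_fragments_total for m in per_record),
        n_fragments_selected=sum(m.n_fragments_selected for m in per_record),
        len_fragments_selected=sum(m.len_fragments_selected for m in per_record),
        genome_length_bp=genome_length(genome, denominator_mode),
        per_record=tuple(per_record),
    )


def digest_genome_single(
    genome: Genome,
    enzyme: EnzymeSpec,
    min_len: int = 100,
    max_len: int = 600,
    genome_id: str = "genome",
    boundary_mode: str = "cut_offset",
    terminal_policy: str = "include",
    denominator_mode: str = "all_bases",
) -> DigestSummary:
    """Single-enzyme digest: metrics summed over records, selection by length only."""
    return _digest_genome(
        genome, [enzyme], genome_id, "any",
        min_len, max_len, boundary_mode, terminal_policy, denominator_mode,
    )


def digest_genome_pair(
    genome: Genome,
    enzyme_a: EnzymeSpec,
    enzyme_b: EnzymeSpec,
    min_len: int = 100,
    max_len: int = 600,
    genome_id: str = "genome",
    boundary_mode: str = "cut_offset",
    terminal_policy: str = "include",
    denominator_mode: str = "all_bases",
) -> DigestSummary:
    """Double digest: selection by length window *and* the different-ends rule.

    Passing the same enzyme twice warns and yields IgC 0 by construction
    (no fragment can have two distinct enzyme ends).
    """
    if enzyme_a.name == enzyme_b.name:
        warnings.warn(
            f"enzyme pair ({enzyme_a.name}, {enzyme_b.name}) is a self-pair; "
            "the different-ends rule selects no fragments, IgC will be 0",
            stacklevel=2,
        )
    return _digest_genome(
        genome, [enzyme_a, enzyme_b], genome_id, "different_enzymes",
        min_len, max_len, boundary_mode, terminal_policy, denominator_mode,
    )
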
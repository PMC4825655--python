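"""Seeded synthetic genomes with planted recognition sites and N-gap runs.

The generator draws i.i.d. bases at a requested GC fraction, guarantees the
background is free of a declared set of recognition motifs (rejection at
generation time, both strands), then overwrites planted motifs at known
coordinates and N-gap runs.  Because every recognition site in the result
is planted, the exact digest outcome can be computed by direct arithmetic
on the planted coordinates (:func:`expected_digest`) — an oracle that never
touches the scanning/digestion code it is used to test.

Determinism: one PRNG stream per record, spawned from the spec seed, so
adding records does not reshuffle earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .catalog import EnzymeSpec, expand_iupac, reverse_complement_iupac
from .coverage import DigestSummary, RecordMetrics
from .digest import CHROM_END
from .genome_io import Genome, GenomeRecord

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SynthesisSpec:
    """Recipe for a synthetic genome.

    ``planted_motifs`` is a list of ``(record_index, position, motif)``;
    ``gap_runs`` a list of ``(record_index, start, length)`` N runs;
    ``forbidden_motifs`` the IUPAC patterns the background must not contain
    (in either orientation) — list the recognition sequences of every
    enzyme the fixture will be digested with.
    """

    n_records: int
    record_length: int
    gc_fraction: float = 0.5
    planted_motifs: tuple[tuple[int, int, str], ...] = ()
    gap_runs: tuple[tuple[int, int, int], ...] = ()
    forbidden_motifs: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.record_length < 1:
            raise ValueError("need at least one record of positive length")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gc_fraction must be in [0,1], got {self.gc_fraction}")
        object.__setattr__(self, "planted_motifs", tuple(
            (int(r), int(p), str(m).upper()) for r, p, m in self.planted_motifs))
        object.__setattr__(self, "gap_runs", tuple(
            (int(r), int(s), int(l)) for r, s, l in self.gap_runs))
        object.__setattr__(self, "forbidden_motifs", tuple(
            str(m).upper() for m in self.forbidden_motifs))
        self._validate_intervals()

    def _validate_intervals(self) -> None:
        per_record: dict[int, list[tuple[int, int, str]]] = {}
        for rec, pos, motif in self.planted_motifs:
            if set(motif) - set("ACGT"):
                raise ValueError(f"planted motif {motif!r} must be plain ACGT")
            per_record.setdefault(rec, []).append((pos, pos + len(motif), "plant"))
        for rec, start, length in self.gap_runs:
            if length < 1:
                raise ValueError("gap run length must be >= 1")
            per_record.setdefault(rec, []).append((start, start + length, "gap"))
        for rec, intervals in per_record.items():
            if not 0 <= rec < self.n_records:
                raise ValueError(f"record index {rec} out of range")
            intervals.sort()
            for (s, e, _) in intervals:
                if s < 0 or e > self.record_length:
                    raise ValueError(
                        f"interval [{s},{e}) outside record of length {self.record_length}")
            for (s1, e1, k1), (s2, e2, k2) in zip(intervals, intervals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping {k1}/{k2} intervals [{s1},{e1}) and [{s2},{e2}) "
                        f"in record {rec}")

    def record_ids(self) -> list[str]:
        return [f"synth{i + 1}" for i in range(self.n_records)]

    def protected_intervals(self, record: int) -> list[tuple[int, int]]:
        """Plant+gap intervals of one record (sorted, non-overlapping)."""
        out = [(p, p + len(m)) for r, p, m in self.planted_motifs if r == record]
        out += [(s, s + l) for r, s, l in self.gap_runs if r == record]
        return sorted(out)


def _forbidden_windows(seq: np.ndarray, patterns: Sequence[str]) -> list[tuple[int, int]]:
    """Intervals of every forbidden-motif match (both orientations)."""
    s = "".join(seq)
    hits: list[tuple[int, int]] = []
    for pat in patterns:
        targets = expand_iupac(pat) | expand_iupac(reverse_complement_iupac(pat))
        L = len(pat)
        for concrete in targets:
            start = s.find(concrete)
            while start != -1:
                hits.append((start, start + L))
                start = s.find(concrete, start + 1)
    return hits


def _planted_starts(spec: SynthesisSpec, record: int) -> set[int]:
    return {p for r, p, _ in spec.planted_motifs if r == record}


def _synthesize_record(spec: SynthesisSpec, record: int, rng: np.random.Generator) -> str:
    probs = np.array([
        (1 - spec.gc_fraction) / 2, spec.gc_fraction / 2,
        spec.gc_fraction / 2, (1 - spec.gc_fraction) / 2,
    ])
    seq = rng.choice(_BASES, size=spec.record_length, p=probs)
    protected = np.zeros(spec.record_length, dtype=bool)
    for r, pos, motif in spec.planted_motifs:
        if r == record:
            seq[pos:pos + len(motif)] = list(motif)
            protected[pos:pos + len(motif)] = True
    for r, start, length in spec.gap_runs:
        if r == record:
            seq[start:start + length] = "N"
            protected[start:start + length] = True

    if spec.forbidden_motifs:
        planted = _planted_starts(spec, record)
        for _ in range(200):
            bad = [
                (s, e) for s, e in _forbidden_windows(seq, spec.forbidden_motifs)
                if s not in planted
            ]
            redrawable = False
            for s, e in bad:
                idx = np.arange(s, e)
                idx = idx[~protected[idx]]
                if idx.size:
                    seq[idx] = rng.choice(_BASES, size=idx.size, p=probs)
                    redrawable = True
            if not bad:
                break
            if not redrawable:
                raise ValueError(
                    "planted/gap layout itself contains a forbidden motif outside "
                    "the planted starts; adjust the spec")
        else:
            raise RuntimeError("could not clear forbidden motifs from background")
    return "".join(seq)


def random_genome(spec: SynthesisSpec) -> Genome:
    """Generate the genome a spec describes; identical seed, identical genome."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_records)
    records = []
    for i, (rid, ss) in enumerate(zip(spec.record_ids(), children)):
        rng = np.random.default_rng(ss)
        records.append(GenomeRecord(rid, _synthesize_record(spec, i, rng)))
    return Genome(tuple(records))


def write_plants_tsv(spec: SynthesisSpec, path: str | Path) -> None:
    """Sidecar TSV of planted coordinates: record_id, position, motif."""
    ids = spec.record_ids()
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# record\tposition\tmotif\n")
        for rec, pos, motif in sorted(spec.planted_motifs):
            fh.write(f"{ids[rec]}\t{pos}\t{motif}\n")


def _motif_matches(motif: str, enzyme: EnzymeSpec) -> tuple[bool, bool]:
    """(matches forward pattern, matches reverse-complement pattern)."""
    fwd = motif in expand_iupac(enzyme.recognition)
    if enzyme.is_palindromic:
        return fwd, False
    rev = motif in expand_iupac(reverse_complement_iupac(enzyme.recognition))
    return fwd, rev and not fwd


def expected_digest(
    spec: SynthesisSpec,
    enzymes: EnzymeSpec | Iterable[EnzymeSpec],
    min_len: int = 100,
    max_len: int = 600,
    genome_id: str = "synthetic",
    boundary_mode: str = "cut_offset",
    terminal_policy: str = "include",
    denominator_mode: str = "all_bases",
) -> DigestSummary:
    """Digest outcome computed from planted coordinates alone (the oracle).

    Valid only when the background is guaranteed motif-free for every
    enzyme under test, i.e. each enzyme's recognition pattern appears in
    ``spec.forbidden_motifs``; otherwise refuses.  Pair mode (two enzymes)
    applies the different-ends rule, single mode the length window only.
    The construction is deliberately naive interval arithmetic, independent
    of the scanning/digestion modules.
    """
    enz_list = [enzymes] if isinstance(enzymes, EnzymeSpec) else list(enzymes)
    if not 1 <= len(enz_list) <= 2:
        raise ValueError("expected one or two enzymes")
    for enz in enz_list:
        if enz.recognition not in spec.forbidden_motifs:
            raise ValueError(
                f"background not guaranteed free of {enz.name} sites "
                f"({enz.recognition}); oracle would be invalid")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")

    different_ends = len(enz_list) == 2
    per_record: list[RecordMetrics] = []
    for rec in range(spec.n_records):
        cuts: dict[int, set[str]] = {}
        for r, pos, motif in spec.planted_motifs:
            if r != rec:
                continue
            for enz in enz_list:
                fwd, rev = _motif_matches(motif, enz)
                if fwd:
                    c = pos + (enz.cut_offset if boundary_mode == "cut_offset" else 0)
                elif rev:
                    c = pos + (enz.site_length - enz.cut_offset
                               if boundary_mode == "cut_offset" else 0)
                else:
                    continue
                cuts.setdefault(c, set()).add(enz.name)
        bounds = [(0, {CHROM_END})] + sorted(
            (p, lab) for p, lab in cuts.items()) + [(spec.record_length, {CHROM_END})]
        n_tot = len_tot = n_sel = len_sel = 0
        for (s, left), (e, right) in zip(bounds, bounds[1:]):
            if e - s < 1:
                continue
            terminal = CHROM_END in left or CHROM_END in right
            if terminal and terminal_policy == "exclude":
                continue
            n_tot += 1
            len_tot += e - s
            if not min_len <= e - s <= max_len:
                continue
            if different_ends:
                l_enz, r_enz = left - {CHROM_END}, right - {CHROM_END}
                if not l_enz or not r_enz or len(l_enz | r_enz) < 2:
                    continue
            n_sel += 1
            len_sel += e - s
        per_record.append(RecordMetrics(spec.record_ids()[rec], n_tot, len_tot, n_sel, len_sel))

    gap_bases = sum(l for _, _, l in spec.gap_runs)
    total = spec.n_records * spec.record_length
    denom = total if denominator_mode == "all_bases" else total - gap_bases
    return DigestSummary(
        genome_id=genome_id,
        enzymes=tuple(e.name for e in enz_list),
        n_fragments_total=sum(m.n_fragments_total for m in per_record),
        len_fragments_total=sum(m.len_fragments_total for m in per_record),
        n_fragments_selected=sum(m.n_fragments_selected for m in per_record),
        len_fragments_selected=sum(m.len_fragments_selected for m in per_record),
        genome_length_bp=denom,
        per_record=tuple(per_record),
    )
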
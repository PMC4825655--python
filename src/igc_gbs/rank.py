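"""Batch digestion grids: enzymes/pairs x genomes, summaries, and ratios.

Runs a digest for every cell of an (enzyme or enzyme-pair) x (genome) grid
and assembles the IgC values into a matrix with per-row mean and sample
standard deviation, optional column-group means (e.g. plants only), and
per-column ratios against a reference row such as the GBS standard pair
PstI + MspI.  This reproduces the shape of the screening tables used to
rank candidate enzyme combinations across species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import EnzymeSpec
from .coverage import DigestSummary, digest_genome_pair, digest_genome_single
from .genome_io import Genome, read_genome

logger = logging.getLogger(__name__)

RowSpec = EnzymeSpec | tuple[EnzymeSpec, ...] | tuple[EnzymeSpec, EnzymeSpec]


def row_label(row: RowSpec) -> str:
    if isinstance(row, EnzymeSpec):
        return row.name
    return "+".join(e.name for e in row)


@dataclass
class CoverageMatrix:
    """IgC (and selected-count) values for rows of enzymes/pairs x genome columns.

    ``values`` holds igc_percent, ``counts`` holds n_fragments_selected;
    both are pandas DataFrames indexed by row label x genome id.  Cells for
    genomes that failed to load are NaN.  ``conventions`` records the
    resolved digestion conventions for reproducibility.
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    conventions: dict[str, object] = field(default_factory=dict)

    def to_wide_tsv(self, path: str | Path, groups: Mapping[str, Sequence[str]] | None = None,
                    round_1dp: bool = False) -> None:
        table = self.values.join(summarize_rows(self.values, groups=groups))
        if round_1dp:
            table = table.round(1)
        table.to_csv(path, sep="\t", index_label="enzymes")


@dataclass(frozen=True)
class RatioReport:
    """Per-column ratios of each row to a reference row, plus the row means.

    Columns where the reference is zero are NaN (flagged missing), and
    excluded from the mean.
    """

    ratios: pd.DataFrame
    mean_ratio: pd.Series
    reference_row: str


def _digest_cell(genome: Genome, row: RowSpec, genome_id: str, **conv) -> DigestSummary:
    if isinstance(row, EnzymeSpec):
        return digest_genome_single(genome, row, genome_id=genome_id, **conv)
    enzymes = tuple(row)
    if len(enzymes) == 1:
        return digest_genome_single(genome, enzymes[0], genome_id=genome_id, **conv)
    if len(enzymes) != 2:
        raise ValueError(f"a row must be one enzyme or a pair, got {len(enzymes)}")
    return digest_genome_pair(genome, enzymes[0], enzymes[1], genome_id=genome_id, **conv)


def build_matrix(
    genomes: Mapping[str, Genome | str | Path],
    rows: Sequence[RowSpec],
    min_len: int = 100,
    max_len: int = 600,
    boundary_mode: str = "cut_offset",
    terminal_policy: str = "include",
    denominator_mode: str = "all_bases",
) -> CoverageMatrix:
    """Digest every genome with every row spec and collect IgC values.

    ``genomes`` maps genome id -> Genome or FASTA path.  A genome that fails
    to load marks its column missing (NaN) and is logged; it does not abort
    the grid.  Row/column order follows the input order and the run is
    deterministic.
    """
    if not genomes or not rows:
        raise ValueError("need at least one genome and one row spec")
    conv = dict(
        min_len=min_len, max_len=max_len, boundary_mode=boundary_mode,
        terminal_policy=terminal_policy, denominator_mode=denominator_mode,
    )
    loaded: dict[str, Genome | None] = {}
    for gid, g in genomes.items():
        if isinstance(g, Genome):
            loaded[gid] = g
        else:
            try:
                loaded[gid] = read_genome(g)
            except (OSError, ValueError) as exc:
                logger.warning("genome %s failed to load (%s); column marked missing", gid, exc)
                loaded[gid] = None

    labels = [row_label(r) for r in rows]
    values = pd.DataFrame(np.nan, index=labels, columns=list(genomes), dtype=float)
    counts = pd.DataFrame(np.nan, index=labels, columns=list(genomes), dtype=float)
    for row, label in zip(rows, labels):
        for gid, genome in loaded.items():
            if genome is None:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # self-pairs are a legitimate grid row
                summary = _digest_cell(genome, row, gid, **conv)
            values.loc[label, gid] = summary.igc_percent
            counts.loc[label, gid] = summary.n_fragments_selected
    conventions = dict(conv, sd="sample (n-1)")
    return CoverageMatrix(values=values, counts=counts, conventions=conventions)


def summarize_rows(
    matrix: CoverageMatrix | pd.DataFrame,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Row mean and sample SD (ddof=1), plus optional column-group means.

    Missing cells are excluded, not imputed; an all-missing row yields NaN
    summaries, and a single-value row has an undefined (NaN) SD.
    """
    values = matrix.values if isinstance(matrix, CoverageMatrix) else matrix
    out = pd.DataFrame(index=values.index)
    out["row_mean"] = values.mean(axis=1, skipna=True)
    out["row_sd"] = values.std(axis=1, ddof=1, skipna=True)
    for name, cols in (groups or {}).items():
        missing = [c for c in cols if c not in values.columns]
        if missing:
            raise KeyError(f"group {name!r} names unknown columns: {missing}")
        out[f"mean_{name}"] = values[list(cols)].mean(axis=1, skipna=True)
    return out


def ratio_to_reference(
    matrix: CoverageMatrix | pd.DataFrame,
    reference_row: str,
) -> RatioReport:
    """Per-column value/reference ratios and their row means.

    Raises if the reference row is absent or entirely zero; columns where
    the reference is 0 (or missing) are NaN and excluded from means.
    """
    values = matrix.values if isinstance(matrix, CoverageMatrix) else matrix
    if reference_row not in values.index:
        raise KeyError(f"reference row {reference_row!r} not in matrix")
    ref = values.loc[reference_row]
    if not (ref.fillna(0) != 0).any():
        raise ValueError(f"reference row {reference_row!r} is all zero/missing")
    safe_ref = ref.where(ref != 0)
    ratios = values.div(safe_ref, axis=1)
    return RatioReport(
        ratios=ratios,
        mean_ratio=ratios.mean(axis=1, skipna=True),
        reference_row=reference_row,
    )


def matrix_to_tidy(matrix: CoverageMatrix) -> pd.DataFrame:
    """Long-format view: one row per (enzymes, genome) cell."""
    tidy = (
        matrix.values.reset_index(names="enzymes")
        .melt(id_vars="enzymes", var_name="genome_id", value_name="igc_percent")
    )
    counts = (
        matrix.counts.reset_index(names="enzymes")
        .melt(id_vars="enzymes", var_name="genome_id", value_name="n_fragments_selected")
    )
    return tidy.merge(counts, on=["enzymes", "genome_id"])
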
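"""Bundled reference tables from a published GBS enzyme-screening study.

Three small tables ship with the package so that the ranking and summary
machinery can be exercised against printed values without any downloads:

* ``load_pair_igc()`` — IgC (%) of 22 sequenced genomes (eight plants, 13
  animals, one fungus) for the 21 top-ranked enzyme pairs plus the GBS
  reference pair PstI + MspI;
* ``load_single_enzyme_igc()`` — the single-enzyme screen (60 enzymes x
  four plant genomes): selected-fragment counts and IgC;
* ``load_egc_ratios()`` — empirical genome coverage (from MiSeq contigs)
  for PM/AB/HH in 12 plant species, with per-species ratios to PM.

These are inputs for aggregation (row means, SDs, ratio-to-reference), not
outputs of this package's digestion engine.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Column ids of the eight plant genomes in the 22-species pair table.
PLANT_SPECIES: tuple[str, ...] = (
    "Arabidopsis", "Cottonwood", "Medicago", "Winegrape",
    "Soybean", "Rice", "Sorghum", "Maize",
)

#: Row label of the GBS reference pair in the pair table.
REFERENCE_PAIR = "PstI+MspI"


def _read(name: str, index_col: str) -> pd.DataFrame:
    with resources.files("igc_gbs.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col=index_col)


def load_pair_igc() -> pd.DataFrame:
    """Pairs x 22 species IgC matrix (percent); index = 'A+B' pair labels."""
    return _read("pair_igc_22species.tsv", index_col="pair")


def load_species_info() -> pd.DataFrame:
    """Group (plant/animal/fungus) and genome size (Mb) per assayed species."""
    return _read("species_22.tsv", index_col="species")


def load_single_enzyme_igc() -> pd.DataFrame:
    """Single-enzyme screen: counts and IgC over four plant genomes."""
    return _read("single_enzyme_igc_4plants.tsv", index_col="enzyme")


def load_egc_ratios() -> pd.DataFrame:
    """Empirical coverage (EgC, %) and ratios to PM for 12 plant species."""
    return _read("egc_ratios_12plants.tsv", index_col="species")
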
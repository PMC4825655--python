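import pytest
from hypothesis import settings

from igc_gbs.catalog import builtin_catalog

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture(scope="session")
def enzymes(catalog):
    """Name -> EnzymeSpec lookup for the built-in catalog."""
    return {e.name: e for e in catalog}


# Independent IUPAC table for brute-force oracles; kept separate from the
# package's own so the oracles do not share code with the path under test.
ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}


def oracle_rc(pattern: str) -> str:
    return "".join(_COMP[c] for c in reversed(pattern))


def oracle_scan(sequence: str, pattern: str, both_strands: bool = True) -> list[int]:
    """Position-by-position IUPAC comparison: genome ambiguity never matches."""
    sequence = sequence.upper()
    pats = [pattern]
    if both_strands and oracle_rc(pattern) != pattern:
        pats.append(oracle_rc(pattern))
    hits = set()
    for pat in pats:
        L = len(pat)
        for p in range(len(sequence) - L + 1):
            if all(sequence[p + i] in ORACLE_IUPAC[c] for i, c in enumerate(pat)):
                hits.add(p)
    return sorted(hits)
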
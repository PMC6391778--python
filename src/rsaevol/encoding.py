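"""Pseudo-amino-acid (PAA) encoding of solvent accessibility.

Relative solvent accessibility is discretised on a 5-unit grid from -5
("unknown") to 95.  Encoding each grid value as a letter of a 20-symbol
alphabet lets standard protein phylogenetics machinery -- substitution
matrices, likelihood engines, simulators -- run unchanged on RSA data.
The 20-category map assigns one letter per grid value except that 90 and 95
collapse onto 'V'; a coarser 10-category map and arbitrary user-supplied
alphabet reductions are also supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import (
    AMINO_ACIDS,
    GAP_VALUE,
    RSA_GRID,
    AlignmentError,
    AlphabetError,
    ResidueAlignment,
    RsaProfile,
)

#: 20-category RSA -> PAA map.  -5 ("unknown") -> A; 90 and 95 share 'V'.
RSA20_TABLE: dict[int, str] = {
    -5: "A", 0: "R", 5: "N", 10: "D", 15: "C", 20: "E", 25: "Q",
    30: "G", 35: "H", 40: "I", 45: "L", 50: "K", 55: "M", 60: "F",
    65: "P", 70: "S", 75: "T", 80: "W", 85: "Y", 90: "V", 95: "V",
}

#: 10-category RSA map: pairs of adjacent grid values share a letter and the
#: whole exposed range 80..95 collapses onto 'W'.
RSA10_TABLE: dict[int, str] = {
    -5: "A",
    0: "R", 5: "R",
    10: "D", 15: "D",
    20: "E", 25: "E",
    30: "G", 35: "G",
    40: "I", 45: "I",
    50: "K", 55: "K",
    60: "F", 65: "F",
    70: "S", 75: "S",
    80: "W", 85: "W", 90: "W", 95: "W",
}

PAA20_ALPHABET = AMINO_ACIDS           # A R N D C E Q G H I L K M F P S T W Y V
PAA10_ALPHABET = "ARDEGIKFSW"

#: Representative numeric value of each 20-category letter (inverse map used
#: by the simulator); the collapsed 'V' maps back to 90.
PAA20_REPRESENTATIVE: dict[str, int] = {
    sym: val for val, sym in RSA20_TABLE.items() if not (sym == "V" and val == 95)
}


@dataclass
class AlphabetMap:
    """A named reduction from source symbols/values to a target alphabet.

    ``mapping`` keys may be RSA grid integers (an encoding map) or single
    characters (an alphabet reduction); values are target symbols.  The
    target alphabet is the ordered set of distinct mapped symbols.
    """

    name: str
    mapping: dict
    target_alphabet: str

    def __post_init__(self) -> None:
        mapped = set(self.mapping.values())
        if mapped != set(self.target_alphabet):
            raise ValueError(
                f"target alphabet {self.target_alphabet!r} does not equal the "
                f"set of mapped symbols {sorted(mapped)}"
            )
        int_keys = [k for k in self.mapping if isinstance(k, int)]
        if int_keys and set(int_keys) != set(RSA_GRID):
            missing = sorted(set(RSA_GRID) - set(int_keys))
            raise ValueError(f"grid map does not cover grid values {missing}")

    # -- canned maps ---------------------------------------------------------

    @classmethod
    def rsa20(cls) -> "AlphabetMap":
        return cls("rsa20", dict(RSA20_TABLE), PAA20_ALPHABET)

    @classmethod
    def rsa10(cls) -> "AlphabetMap":
        return cls("rsa10", dict(RSA10_TABLE), PAA10_ALPHABET)

    @classmethod
    def reduction_20_to_10(cls) -> "AlphabetMap":
        """Letter-level map carrying 20-category PAA onto the 10-category set."""
        mapping = {
            RSA20_TABLE[v]: RSA10_TABLE[v] for v in RSA_GRID
        }
        return cls("paa20_to_paa10", mapping, PAA10_ALPHABET)

    @classmethod
    def identity(cls, alphabet: str) -> "AlphabetMap":
        return cls("identity", {c: c for c in alphabet}, alphabet)

    # -- persistence -----------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mapping": {str(k): v for k, v in self.mapping.items()},
            "target_alphabet": self.target_alphabet,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AlphabetMap":
        mapping = {}
        for k, v in d["mapping"].items():
            try:
                key = int(k)
            except ValueError:
                key = k
            mapping[key] = v
        return cls(d["name"], mapping, d["target_alphabet"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_file(cls, path) -> "AlphabetMap":
        """Load from JSON or YAML."""
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text)
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Encoding operations
# ---------------------------------------------------------------------------


def _encode(profile: RsaProfile, table: Mapping[int, str],
            alphabet: str) -> ResidueAlignment:
    rows = []
    for r in range(len(profile.taxon_names)):
        vals = profile.values[r]
        rows.append(
            "".join("-" if v == GAP_VALUE else table[int(v)] for v in vals)
        )
    return ResidueAlignment(
        list(profile.taxon_names), rows, alphabet, missing="-"
    )


def encode_rsa20(profile: RsaProfile) -> ResidueAlignment:
    """Encode a numeric RSA profile as a 20-letter PAA alignment.

    Gap positions stay gaps; unknown RSA (-5) becomes the 'A' category.
    """
    return _encode(profile, RSA20_TABLE, PAA20_ALPHABET)


def encode_rsa10(profile: RsaProfile) -> ResidueAlignment:
    """Encode a numeric RSA profile with the coarser 10-category alphabet."""
    return _encode(profile, RSA10_TABLE, PAA10_ALPHABET)


def decode_paa20(alignment: ResidueAlignment) -> RsaProfile:
    """Invert :func:`encode_rsa20` letter-by-letter.

    Each letter maps to its representative grid value ('V' -> 90), so
    ``encode_rsa20(decode_paa20(a)) == a`` for any 20-letter PAA alignment.
    """
    values = np.full((alignment.n_taxa, alignment.n_sites), GAP_VALUE, dtype=int)
    for r, row in enumerate(alignment.rows):
        for c, ch in enumerate(row):
            if ch not in alignment.missing:
                values[r, c] = PAA20_REPRESENTATIVE[ch]
    return RsaProfile(list(alignment.taxon_names), values)


def reduce_alphabet(alignment: ResidueAlignment,
                    amap: AlphabetMap) -> ResidueAlignment:
    """Apply a symbol-level alphabet reduction; column count is unchanged."""
    table = {k: v for k, v in amap.mapping.items() if isinstance(k, str)}
    uncovered = (
        {c for row in alignment.rows for c in row}
        - set(table) - set(alignment.missing)
    )
    if uncovered:
        raise AlphabetError(
            f"symbols {sorted(uncovered)} are not covered by map {amap.name!r}"
        )
    rows = [
        "".join(ch if ch in alignment.missing else table[ch] for ch in row)
        for row in alignment.rows
    ]
    return ResidueAlignment(
        list(alignment.taxon_names), rows, amap.target_alphabet,
        alignment.missing,
    )


@dataclass
class CategoryUsage:
    """Frequency table over an alignment's declared alphabet."""

    frequencies: pd.Series    # indexed by alphabet symbol, sums to 1
    absent: tuple[str, ...]   # declared symbols never observed
    n_observed: int           # non-missing cells counted


def category_usage(alignment: ResidueAlignment) -> CategoryUsage:
    """Per-symbol frequencies over non-missing cells, plus absent symbols.

    Absent categories matter downstream: a family that never uses a symbol
    gives prior-dominated exchangeability estimates for it, and any reduction
    in the number of used types is tracked as a data-uncertainty signal.
    """
    codes = alignment.codes()
    body = codes[codes >= 0]
    if body.size == 0:
        raise AlignmentError("alignment has no non-missing cells")
    counts = np.bincount(body, minlength=len(alignment.alphabet))
    freqs = pd.Series(
        counts / body.size, index=list(alignment.alphabet), name="frequency"
    )
    absent = tuple(sym for sym, c in zip(alignment.alphabet, counts) if c == 0)
    return CategoryUsage(freqs, absent, int(body.size))
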
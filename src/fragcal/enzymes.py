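"""Restriction enzyme definitions with IUPAC-degenerate recognition sites.

An enzyme is described by its recognition pattern in the IUPAC nucleotide
ambiguity alphabet plus the 0-based offset of the blunt cut within that
pattern (``GAANN^NNTTC`` has offset 5).  Only blunt cutters are supported:
the cut position applies symmetrically to both strands.  Overhang-producing
enzymes are a declared extension point.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# complement map covering every ambiguity code
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


class InvalidEnzymeError(ValueError):
    """A recognition pattern contains a non-IUPAC character or a bad cut offset."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string."""
    try:
        return "".join(IUPAC_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - guarded upstream for enzymes
        raise InvalidEnzymeError(f"non-IUPAC character {exc.args[0]!r} in {seq!r}") from exc


@dataclass(frozen=True)
class RecognitionSite:
    """A restriction enzyme's degenerate recognition pattern and blunt cut offset.

    Parameters
    ----------
    name
        Enzyme name, e.g. ``"XmnI"``.
    pattern
        IUPAC recognition sequence, e.g. ``"GAANNNNTTC"``.
    cut_offset
        0-based position within ``pattern`` after which the top strand is
        cut; ``GAANN^NNTTC`` is offset 5.
    """

    name: str
    pattern: str
    cut_offset: int

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        bad = set(pat) - set(IUPAC_CODES)
        if not pat or bad:
            raise InvalidEnzymeError(
                f"{self.name}: pattern {self.pattern!r} contains non-IUPAC characters {sorted(bad)}"
            )
        object.__setattr__(self, "pattern", pat)
        if not 0 < self.cut_offset < len(pat):
            raise InvalidEnzymeError(
                f"{self.name}: cut offset {self.cut_offset} outside pattern of length {len(pat)}"
            )

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def is_palindromic(self) -> bool:
        """True when the degenerate pattern equals its own reverse complement."""
        return self.pattern == reverse_complement(self.pattern)

    @property
    def caret_pattern(self) -> str:
        return self.pattern[: self.cut_offset] + "^" + self.pattern[self.cut_offset :]

    def regex(self) -> re.Pattern[str]:
        """Lookahead regex matching every (overlapping) pattern occurrence.

        Genome ``N`` bases never match: each position expands only to the
        concrete bases the IUPAC code allows.
        """
        body = "".join(
            c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]" for c in self.pattern
        )
        return re.compile(f"(?=({body}))")


def parse_caret_pattern(name: str, caret_pattern: str) -> RecognitionSite:
    """Build a :class:`RecognitionSite` from ``"GAANN^NNTTC"`` notation."""
    cleaned = caret_pattern.replace(" ", "").upper()
    if cleaned.count("^") != 1:
        raise InvalidEnzymeError(f"{name}: expected exactly one '^' in {caret_pattern!r}")
    offset = cleaned.index("^")
    return RecognitionSite(name=name, pattern=cleaned.replace("^", ""), cut_offset=offset)


#: The four blunt cutters used to build E. coli / lambda length standards.
BUILTIN_ENZYMES: dict[str, RecognitionSite] = {
    e.name: e
    for e in (
        parse_caret_pattern("AleI", "CACNN^NNGTG"),
        parse_caret_pattern("PshAI", "GACNN^NNGTC"),
        parse_caret_pattern("XmnI", "GAANN^NNTTC"),
        parse_caret_pattern("PvuII", "CAG^CTG"),
    )
}


def get_enzyme(name: str) -> RecognitionSite:
    """Look up a built-in enzyme by (case-insensitive) name."""
    for key, enz in BUILTIN_ENZYMES.items():
        if key.lower() == name.lower():
            return enz
    raise KeyError(f"unknown enzyme {name!r}; built-ins: {', '.join(BUILTIN_ENZYMES)}")


def load_enzyme_table(path: str | Path) -> dict[str, RecognitionSite]:
    """Read user enzymes from a TSV of (name, pattern-with-caret) rows."""
    enzymes: dict[str, RecognitionSite] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            name, caret = row[0].strip(), row[1].strip()
            enzymes[name] = parse_caret_pattern(name, caret)
    return enzymes
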
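"""Nucleotide alphabet utilities shared across the package.

The working alphabet is {A,C,G,T,N,-} plus the IUPAC ambiguity codes.
``N`` means "a base was present but could not be read"; it is therefore
never interpreted as a gap.
"""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# inverse lookup: base set -> tightest IUPAC code
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

BASES = frozenset("ACGT")
ALLOWED = frozenset(IUPAC_SETS) | {"-"}


def base_set(symbol: str) -> frozenset[str]:
    """IUPAC base set of a single symbol (gap excluded)."""
    try:
        return IUPAC_SETS[symbol]
    except KeyError:
        raise ValueError(f"illegal nucleotide symbol {symbol!r}") from None


def iupac_code(bases: frozenset[str] | set[str]) -> str:
    return SET_TO_IUPAC[frozenset(bases)]


def reverse_complement(seq: str) -> str:
    """Reverse-complement over the full IUPAC alphabet; N maps to N.

    Raises ValueError on any symbol outside the alphabet.
    """
    try:
        return "".join(COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"illegal nucleotide symbol {exc.args[0]!r}") from None


def clean_sequence(raw: str, *, label: str = "<sequence>") -> str:
    """Uppercase, map U->T and validate against the working alphabet.

    Reports the offending record label and 1-based position on failure.
    """
    out = raw.upper().replace("U", "T")
    for i, c in enumerate(out):
        if c not in ALLOWED:
            raise ValueError(
                f"illegal character {c!r} in record {label!r} at position {i + 1}"
            )
    return out


def compatible(a: str, b: str) -> bool:
    """True when two non-gap symbols could represent the same base."""
    return not base_set(a).isdisjoint(base_set(b))
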
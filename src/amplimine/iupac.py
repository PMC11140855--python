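"""IUPAC degenerate-nucleotide algebra.

Every matching decision in the package reduces to set operations on the
four concrete bases: a degenerate code stands for the set of bases it can
pair-read as, two codes are compatible when those sets intersect, and a
mismatch is a position where they do not.
"""

from __future__ import annotations

IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_EXPANSION)

#: canonical code for every non-empty subset of {A,C,G,T}
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPANSION.items()}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}

# 4-bit masks (A=1, C=2, G=4, T=8) for the vectorised matcher.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASK: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_EXPANSION.items()
}


class InvalidBaseError(ValueError):
    """A character outside the IUPAC nucleotide alphabet (or a gap)."""


def _check(code: str) -> str:
    if code not in IUPAC_ALPHABET:
        raise InvalidBaseError(f"not an IUPAC nucleotide code: {code!r}")
    return code


def expansion(code: str) -> frozenset[str]:
    """Concrete bases {A,C,G,T} a single IUPAC code stands for."""
    return IUPAC_EXPANSION[_check(code)]


def base_matches(primer_base: str, template_base: str) -> bool:
    """True iff the two codes share at least one concrete base.

    This is the pairing rule for degenerate primers: S matches G because
    S = {G,C} intersects {G}; R does not match C because {A,G} ∩ {C} = ∅.
    """
    return bool(expansion(primer_base) & expansion(template_base))


def validate_sequence(seq: str, *, what: str = "sequence") -> str:
    """Raise InvalidBaseError naming the first bad position; return seq."""
    for i, c in enumerate(seq):
        if c not in IUPAC_ALPHABET:
            raise InvalidBaseError(
                f"{what} contains non-IUPAC character {c!r} at position {i + 1}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving degenerate codes (R↔Y, K↔M, ...)."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise InvalidBaseError(f"non-IUPAC character {exc.args[0]!r}") from exc


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate string stands for."""
    n = 1
    for c in seq:
        n *= len(expansion(c))
    return n


def expand_sequence(seq: str, *, cap: int = 1024) -> list[str]:
    """All concrete expansions of a degenerate string (error above cap)."""
    if degeneracy(seq) > cap:
        raise ValueError(
            f"degeneracy {degeneracy(seq)} exceeds the expansion cap of {cap}"
        )
    out = [""]
    for c in seq:
        bases = sorted(expansion(c))
        out = [p + b for p in out for b in bases]
    return out


def code_for_bases(bases: frozenset[str] | set[str]) -> str:
    """Minimal-degeneracy IUPAC code covering a non-empty base set."""
    key = frozenset(bases)
    if key not in CODE_FOR_SET:
        raise InvalidBaseError(f"no IUPAC code for base set {sorted(bases)!r}")
    return CODE_FOR_SET[key]
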
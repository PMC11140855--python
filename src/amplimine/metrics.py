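"""Per-primer physico-chemical statistics and design-rule validation.

GC% uses a strict degenerate convention: a position counts as G+C only
when its IUPAC expansion is a subset of {G,C} — i.e. the codes G, C and
S. This is the only convention that reproduces the published values for
degenerate panel primers (e.g. veneroida forward CSCTGTTATCCCYRCGGTA →
52.63%, where S counts but Y and R do not). Reported percentages are
rounded half-up to two decimals; the unrounded value is kept alongside.

Melting temperatures come in two flavours: the Wallace rule
2(A+T) + 4(G+C), and nearest-neighbor thermodynamics via Biopython's
unified parameter table at 50 mM monovalent salt / 250 nM oligo.
Degenerate primers are averaged over their concrete expansions (capped
at 1024). Published annealing temperatures are deliberately not used as
numeric targets: the formula behind them is not reproducible, so Tm
checks are internal-consistency only.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal

from Bio.SeqUtils import MeltingTemp as _mt

from . import iupac
from .iupac import InvalidBaseError, expand_sequence, validate_sequence

GC_CODES = frozenset("GCS")  # expansion ⊆ {G,C}

Role = Literal["forward", "reverse"]


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str
    role: Role

    def __post_init__(self) -> None:
        if not self.seq:
            raise InvalidBaseError(f"primer {self.name!r} is empty")
        validate_sequence(self.seq, what=f"primer {self.name!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer pair with derived statistics.

    ``expected_product_bp`` is an int, or a (lo, hi) tuple for pairs whose
    published product size is a range.
    """

    name: str
    forward: Primer
    reverse: Primer
    expected_product_bp: int | tuple[int, int] | None = None
    gene: str | None = None
    source: str | None = None
    flags: tuple[str, ...] = ()
    alt_forward: str | None = None

    @property
    def gc_f(self) -> float:
        return gc_content(self.forward.seq)

    @property
    def gc_r(self) -> float:
        return gc_content(self.reverse.seq)

    @property
    def degeneracy_f(self) -> int:
        return iupac.degeneracy(self.forward.seq)

    @property
    def degeneracy_r(self) -> int:
        return iupac.degeneracy(self.reverse.seq)

    def tm_f(self, method: str = "wallace") -> float:
        return melting_temperature(self.forward.seq, method=method)

    def tm_r(self, method: str = "wallace") -> float:
        return melting_temperature(self.reverse.seq, method=method)

    def product_range(self) -> tuple[int, int] | None:
        if self.expected_product_bp is None:
            return None
        if isinstance(self.expected_product_bp, tuple):
            return self.expected_product_bp
        return (self.expected_product_bp, self.expected_product_bp)


@dataclass(frozen=True)
class DesignConstraints:
    """Primer-design bounds: GC 40–60%, Tm 50–60 °C, length 18–27 nt,
    product 100–300 bp."""

    gc_min: float = 40.0
    gc_max: float = 60.0
    tm_min: float = 50.0
    tm_max: float = 60.0
    len_min: int = 18
    len_max: int = 27
    product_min: int = 100
    product_max: int = 300

    def __post_init__(self) -> None:
        for lo, hi, label in (
            (self.gc_min, self.gc_max, "gc"),
            (self.tm_min, self.tm_max, "tm"),
            (self.len_min, self.len_max, "len"),
            (self.product_min, self.product_max, "product"),
        ):
            if lo > hi:
                raise ValueError(f"{label}_min {lo} exceeds {label}_max {hi}")


def gc_content(seq: str, *, rounded: bool = True) -> float:
    """Percent G+C under the strict degenerate convention (G, C, S count)."""
    if not seq:
        raise InvalidBaseError("gc_content of an empty sequence")
    validate_sequence(seq)
    n_gc = sum(1 for c in seq if c in GC_CODES)
    exact = Decimal(100 * n_gc) / Decimal(len(seq))
    if not rounded:
        return float(exact)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def degeneracy(seq: str) -> int:
    validate_sequence(seq)
    return iupac.degeneracy(seq)


def _wallace(concrete: str) -> float:
    at = sum(1 for c in concrete if c in "AT")
    gc = sum(1 for c in concrete if c in "GC")
    return 2.0 * at + 4.0 * gc


def melting_temperature(
    seq: str,
    method: Literal["wallace", "nearest_neighbor"] = "wallace",
    *,
    na_mM: float = 50.0,
    oligo_nM: float = 250.0,
    expansion_cap: int = 1024,
) -> float:
    """Primer Tm in °C; degenerate inputs are averaged over expansions."""
    validate_sequence(seq)
    if method == "nearest_neighbor" and len(seq) < 2:
        raise ValueError("nearest-neighbor Tm needs at least 2 nt")
    variants = expand_sequence(seq, cap=expansion_cap)
    if method == "wallace":
        tms = [_wallace(v) for v in variants]
    elif method == "nearest_neighbor":
        tms = [
            float(_mt.Tm_NN(v, Na=na_mM, dnac1=oligo_nM, dnac2=0.0)) for v in variants
        ]
    else:
        raise ValueError(f"unknown Tm method {method!r}")
    return sum(tms) / len(tms)


def check_primer_pair(
    pair: PrimerPair,
    constraints: DesignConstraints = DesignConstraints(),
    *,
    tm_method: str = "wallace",
    check_tm: bool = False,
) -> list[str]:
    """Labels for every design bound the pair violates (empty = clean).

    Tm bounds are checked only on request: the published panel's annealing
    temperatures are not reproducible numerically, so Tm is advisory.
    """
    v: list[str] = []
    for role, primer in (("forward", pair.forward), ("reverse", pair.reverse)):
        if len(primer) < constraints.len_min:
            v.append(f"{role}_length_below_min")
        elif len(primer) > constraints.len_max:
            v.append(f"{role}_length_above_max")
        gc = gc_content(primer.seq)
        if gc < constraints.gc_min:
            v.append(f"{role}_gc_below_min")
        elif gc > constraints.gc_max:
            v.append(f"{role}_gc_above_max")
        if check_tm:
            tm = melting_temperature(primer.seq, method=tm_method)
            if tm < constraints.tm_min:
                v.append(f"{role}_tm_below_min")
            elif tm > constraints.tm_max:
                v.append(f"{role}_tm_above_max")
    rng = pair.product_range()
    if rng is not None:
        lo, hi = rng
        if lo < constraints.product_min:
            v.append("product_below_min")
        if hi > constraints.product_max:
            v.append("product_above_max")
    return v


def _parse_product(text: str) -> int | tuple[int, int] | None:
    text = text.strip()
    if not text:
        return None
    if "-" in text:
        lo, hi = text.split("-", 1)
        return (int(lo), int(hi))
    return int(text)


def read_primer_pairs(path: str | Path) -> list[PrimerPair]:
    """Read pairs from ``name<TAB>forward<TAB>reverse<TAB>product_bp`` TSV.

    Extra columns (gene, annealing, printed GC%, source, flags,
    alt_forward) are carried through when present; a header row is
    detected and skipped.
    """
    pairs: list[PrimerPair] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return pairs
    header = lines[0].split("\t")
    has_header = header[0].strip().lower() == "name"
    cols = {h.strip().lower(): i for i, h in enumerate(header)} if has_header else {}
    body = lines[1:] if has_header else lines

    def get(parts: list[str], col: str, default_idx: int | None = None) -> str | None:
        idx = cols.get(col, default_idx)
        if idx is None or idx >= len(parts):
            return None
        return parts[idx].strip() or None

    for line in body:
        parts = line.split("\t")
        name = get(parts, "name", 0)
        fwd = get(parts, "forward", 1)
        rev = get(parts, "reverse", 2)
        if name is None or fwd is None or rev is None:
            raise ValueError(f"{path}: malformed primer row {line!r}")
        product = get(parts, "product_bp", 3)
        flags_text = get(parts, "flags")
        pairs.append(
            PrimerPair(
                name=name,
                forward=Primer(f"{name}-F", fwd.upper(), "forward"),
                reverse=Primer(f"{name}-R", rev.upper(), "reverse"),
                expected_product_bp=_parse_product(product) if product else None,
                gene=get(parts, "gene"),
                source=get(parts, "source"),
                flags=tuple(flags_text.split(",")) if flags_text else (),
                alt_forward=get(parts, "alt_forward"),
            )
        )
    return pairs


def write_primer_pairs(pairs: Iterable[PrimerPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tforward\treverse\tproduct_bp\n")
        for p in pairs:
            rng = p.product_range()
            if rng is None:
                product = ""
            elif rng[0] == rng[1]:
                product = str(rng[0])
            else:
                product = f"{rng[0]}-{rng[1]}"
            fh.write(f"{p.name}\t{p.forward.seq}\t{p.reverse.seq}\t{product}\n")


def load_reference_panel() -> list[PrimerPair]:
    """The packaged 15-pair mollusk metabarcoding reference panel.

    Seven newly designed pairs (three COI, three 12S, one 16S) plus eight
    previously published mollusk primers. The unionoida row carries the
    ``ambiguous_forward`` flag: its published 19-nt forward string is
    inconsistent with its published GC% (which matches the 18-nt reading
    stored in ``alt_forward``), so both readings ship and neither is scored.
    """
    ref = importlib.resources.files("amplimine.data") / "reference_primers.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_primer_pairs(path)
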
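"""Degenerate-aware in silico PCR.

The matching model mirrors a Primer-BLAST-style screen: a primer binds a
template wherever it aligns with at most ``max_mismatches`` positions of
disagreement, provided its 3'-terminal ``three_prime_anchor`` bases (the
last two by default) match exactly — a mismatch there blocks polymerase
extension. Disagreement is defined on IUPAC expansions: a position is a
mismatch iff the primer code's base set and the template code's base set
are disjoint, so degenerate primers match every sequence they cover.

Both strands are always scanned. Forward/reverse sites on opposite
strands with 3' ends pointing inward and an outer (primer-inclusive)
span inside the product-size window form an amplicon. Default settings
follow the published screen: product 100–500 bp, ≤3 mismatches per
primer, 2-nt 3' anchor; the optional Tm gate (57–63 °C, ΔTm ≤ 2 °C)
is off by default because it belongs to the database screen, not to the
amplification model itself.

The scanner is vectorised: bases become 4-bit masks (A=1 C=2 G=4 T=8),
windows come from a stride trick, and a mismatch is a zero bitwise-AND.
An intentionally naive per-position oracle in the test suite checks it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd

from .iupac import IUPAC_MASK, reverse_complement
from .metrics import Primer, PrimerPair, melting_temperature
from .seqio import SequenceRecord

Strand = Literal["+", "-"]


@dataclass(frozen=True)
class ISPCRSettings:
    """Screen settings; defaults are the published in silico PCR rules."""

    product_min: int = 100
    product_max: int = 500
    max_mismatches: int = 3
    three_prime_anchor: int = 2
    enforce_tm: bool = False
    tm_min: float = 57.0
    tm_max: float = 63.0
    max_tm_diff: float = 2.0
    tm_method: str = "nearest_neighbor"

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.three_prime_anchor < 0:
            raise ValueError("three_prime_anchor must be >= 0")
        if self.product_min > self.product_max:
            raise ValueError("product_min exceeds product_max")


@dataclass(frozen=True)
class BindingSite:
    """A primer-template match; start/end are 0-based half-open on the
    + strand regardless of which strand the primer anneals to."""

    template_id: str
    strand: Strand
    start: int
    end: int
    mismatches: int
    primer_role: str


@dataclass(frozen=True)
class AmpliconHit:
    """Inward-facing F/R site pairing; product span includes both primers."""

    template_id: str
    fwd: BindingSite
    rev: BindingSite
    product_bp: int

    @property
    def total_mismatches(self) -> int:
        return self.fwd.mismatches + self.rev.mismatches


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((IUPAC_MASK[c] for c in seq), dtype=np.uint8, count=len(seq))


def _scan(primer_seq: str, template_seq: str, max_mm: int, anchor_slice: slice | None,
          anchor_len: int) -> Iterator[tuple[int, int]]:
    """Yield (offset, mismatches) for every admissible window.

    ``anchor_slice`` selects the window positions that must match exactly
    (None disables anchoring).
    """
    m, n = len(primer_seq), len(template_seq)
    if n < m:
        return
    p = _encode(primer_seq)
    t = _encode(template_seq)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mm = (windows & p) == 0  # disjoint expansions = mismatch
    totals = mm.sum(axis=1)
    if anchor_slice is not None and anchor_len > 0:
        anchored = mm[:, anchor_slice].sum(axis=1) == 0
    else:
        anchored = np.ones(len(totals), dtype=bool)
    for off in np.nonzero((totals <= max_mm) & anchored)[0]:
        yield int(off), int(totals[off])


def find_binding_sites(
    primer: Primer,
    template: SequenceRecord,
    settings: ISPCRSettings = ISPCRSettings(),
) -> list[BindingSite]:
    """All binding sites of a primer on both strands of a template.

    A + strand site means the primer reads 5'→3' along the template text
    (3' end at ``end``); a − strand site means it reads along the reverse
    complement (3' end at ``start``). The 3' anchor bases must match
    exactly in either case.
    """
    anchor = min(settings.three_prime_anchor, len(primer.seq))
    sites: list[BindingSite] = []
    # + strand: primer aligned to template text, 3' suffix anchored
    plus_anchor = slice(len(primer.seq) - anchor, len(primer.seq)) if anchor else None
    for off, mm in _scan(primer.seq, template.seq, settings.max_mismatches,
                         plus_anchor, anchor):
        sites.append(BindingSite(template.id, "+", off, off + len(primer.seq),
                                 mm, primer.role))
    # − strand: reverse complement aligned to template text; the primer's
    # 3' end maps to the window's first bases
    rc = reverse_complement(primer.seq)
    minus_anchor = slice(0, anchor) if anchor else None
    for off, mm in _scan(rc, template.seq, settings.max_mismatches,
                         minus_anchor, anchor):
        sites.append(BindingSite(template.id, "-", off, off + len(primer.seq),
                                 mm, primer.role))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify(
    pair: PrimerPair,
    template: SequenceRecord,
    settings: ISPCRSettings = ISPCRSettings(),
) -> list[AmpliconHit]:
    """All amplicons a primer pair predicts on a template.

    Both template orientations are honoured: (forward on +, reverse on −)
    and the mirror (reverse on +, forward on −). Self-overlapping site
    pairs — product shorter than the two primer lengths combined — are
    rejected. Every hit is reported (nested and multiple products
    included), sorted by product size then total mismatches.
    """
    if settings.enforce_tm:
        tm_f = melting_temperature(pair.forward.seq, method=settings.tm_method)
        tm_r = melting_temperature(pair.reverse.seq, method=settings.tm_method)
        if not (settings.tm_min <= tm_f <= settings.tm_max
                and settings.tm_min <= tm_r <= settings.tm_max
                and abs(tm_f - tm_r) <= settings.max_tm_diff):
            return []
    f_sites = find_binding_sites(pair.forward, template, settings)
    r_sites = find_binding_sites(pair.reverse, template, settings)
    min_product = max(settings.product_min, len(pair.forward) + len(pair.reverse))
    hits: list[AmpliconHit] = []
    for outer5, outer3 in (
        # amplicon read off the + strand: F binds +, R binds −, R downstream
        ([s for s in f_sites if s.strand == "+"],
         [s for s in r_sites if s.strand == "-"]),
        # amplicon read off the − strand: R binds +, F binds −, F downstream
        ([s for s in r_sites if s.strand == "+"],
         [s for s in f_sites if s.strand == "-"]),
    ):
        for left in outer5:
            for right in outer3:
                product = right.end - left.start
                if min_product <= product <= settings.product_max:
                    fwd, rev = ((left, right) if left.primer_role == "forward"
                                else (right, left))
                    hits.append(AmpliconHit(template.id, fwd, rev, product))
    hits.sort(key=lambda h: (h.product_bp, h.total_mismatches,
                             min(h.fwd.start, h.rev.start), h.fwd.strand))
    return hits


def batch_ispcr(
    pairs: Iterable[PrimerPair],
    db: Iterable[SequenceRecord],
    settings: ISPCRSettings = ISPCRSettings(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every pair against every template.

    Returns ``(hits, summary)``: one hits row per amplicon (pair order,
    then template input order), and one summary row per pair × template
    with the amplified flag (≥1 hit).
    """
    db = list(db)
    hit_rows: list[dict] = []
    summary_rows: list[dict] = []
    for pair in pairs:
        for template in db:
            hits = amplify(pair, template, settings)
            for h in hits:
                hit_rows.append({
                    "pair": pair.name,
                    "template_id": template.id,
                    "strand": "+" if h.fwd.strand == "+" else "-",
                    "start": min(h.fwd.start, h.rev.start),
                    "end": max(h.fwd.end, h.rev.end),
                    "product_bp": h.product_bp,
                    "mismatches_f": h.fwd.mismatches,
                    "mismatches_r": h.rev.mismatches,
                })
            summary_rows.append({
                "pair": pair.name,
                "template_id": template.id,
                "amplified": bool(hits),
                "n_hits": len(hits),
                "best_product_bp": hits[0].product_bp if hits else pd.NA,
            })
    hits_df = pd.DataFrame(
        hit_rows,
        columns=["pair", "template_id", "strand", "start", "end",
                 "product_bp", "mismatches_f", "mismatches_r"],
    )
    summary_df = pd.DataFrame(
        summary_rows,
        columns=["pair", "template_id", "amplified", "n_hits", "best_product_bp"],
    )
    return hits_df, summary_df


def write_hits_tsv(hits_df: pd.DataFrame, path: str | Path) -> None:
    """Hit table with 1-based inclusive coordinates, as reported to users."""
    out = hits_df.copy()
    out["start"] = out["start"] + 1  # 1-based inclusive for reporting
    out.to_csv(path, sep="\t", index=False)


def hit_count_summary(summary_df: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Per-pair template/hit counts for the JSON summary."""
    out: dict[str, dict[str, int]] = {}
    for pair_name, grp in summary_df.groupby("pair", sort=False):
        out[str(pair_name)] = {
            "templates_scanned": int(len(grp)),
            "templates_amplified": int(grp["amplified"].sum()),
            "total_hits": int(grp["n_hits"].sum()),
        }
    return out
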
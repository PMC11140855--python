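"""End-to-end primer enumeration from an alignment, and panel statistics.

``run_design`` chains the conservation scan with candidate enumeration:
for every amplifiable region, forward candidates are substrings of the
left-flank consensus, reverse candidates are reverse complements of
substrings of the right-flank consensus, products are measured on the
ungapped consensus between the forward start and reverse end, and pairs
surviving the design constraints are ranked by combined degeneracy, Tm
balance and closeness to the mid-range product size.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .conserved import (
    AmplifiableRegion,
    column_conservation,
    find_amplifiable_regions,
    find_conserved_regions,
    ungapped_span_length,
)
from .iupac import reverse_complement
from .metrics import (
    DesignConstraints,
    Primer,
    PrimerPair,
    check_primer_pair,
    degeneracy,
    gc_content,
    melting_temperature,
)
from .seqio import Alignment


@dataclass(frozen=True)
class ScanThresholds:
    min_flank_len: int = 18
    min_score: float = 0.90
    max_gap_fraction: float = 0.10
    inclusion_floor: float = 0.05
    gap_policy: str = "count_as_mismatch"


def _substrings(s: str, len_min: int, len_max: int):
    for length in range(len_min, min(len_max, len(s)) + 1):
        for a in range(len(s) - length + 1):
            yield a, a + length


def run_design(
    aln: Alignment,
    constraints: DesignConstraints = DesignConstraints(),
    scan: ScanThresholds = ScanThresholds(),
    *,
    tm_method: str = "wallace",
    max_degeneracy: int = 64,
) -> list[PrimerPair]:
    """Enumerate constraint-passing primer pairs from an alignment.

    Deterministic: candidates are generated in coordinate order and
    ranked by (combined degeneracy, |ΔTm|, |product − midrange|, name).
    Degeneracy above ``max_degeneracy`` per pair is discarded outright.
    Returns an empty list (not an error) when nothing qualifies.
    """
    if aln.n_rows < 2:
        raise ValueError("design needs an alignment with at least 2 rows")
    profile = column_conservation(aln, scan.gap_policy)  # type: ignore[arg-type]
    regions = find_conserved_regions(
        aln,
        min_len=scan.min_flank_len,
        min_score=scan.min_score,
        max_gap_fraction=scan.max_gap_fraction,
        gap_policy=scan.gap_policy,  # type: ignore[arg-type]
        inclusion_floor=scan.inclusion_floor,
        profile=profile,
    )
    amp_regions = find_amplifiable_regions(aln, regions, constraints, profile=profile)
    midrange = (constraints.product_min + constraints.product_max) / 2

    candidates: list[tuple[tuple, PrimerPair]] = []
    seen: set[tuple[str, str]] = set()
    for region in amp_regions:
        left, right = region.left_flank, region.right_flank
        for fa, fb in _substrings(left.consensus, constraints.len_min, constraints.len_max):
            fwd_seq = left.consensus[fa:fb]
            for ra, rb in _substrings(right.consensus, constraints.len_min,
                                      constraints.len_max):
                rev_seq = reverse_complement(right.consensus[ra:rb])
                key = (fwd_seq, rev_seq)
                if key in seen:
                    continue
                # product: ungapped consensus span, fwd start col → rev end col
                product = ungapped_span_length(aln, left.start + fa, right.start + rb)
                name = f"cand_{left.start + fa}_{right.start + rb}_{product}"
                pair = PrimerPair(
                    name=name,
                    forward=Primer(f"{name}-F", fwd_seq, "forward"),
                    reverse=Primer(f"{name}-R", rev_seq, "reverse"),
                    expected_product_bp=product,
                )
                if pair.degeneracy_f * pair.degeneracy_r > max_degeneracy:
                    continue
                if check_primer_pair(pair, constraints, tm_method=tm_method):
                    continue
                seen.add(key)
                tm_gap = abs(
                    melting_temperature(fwd_seq, method=tm_method)
                    - melting_temperature(rev_seq, method=tm_method)
                )
                rank_key = (
                    pair.degeneracy_f * pair.degeneracy_r,
                    tm_gap,
                    abs(product - midrange),
                    name,
                )
                candidates.append((rank_key, pair))
    candidates.sort(key=lambda kp: kp[0])
    return [pair for _, pair in candidates]


def run_gcstats(pairs: list[PrimerPair], *, tm_method_extra: bool = True) -> pd.DataFrame:
    """Per-primer statistics table: length, GC% (2 dp), degeneracy, Tm.

    Primers flagged ``ambiguous_forward`` get no GC value (the published
    sequence and published GC% disagree); both readings are listed.
    """
    rows = []
    for pair in pairs:
        ambiguous = "ambiguous_forward" in pair.flags
        for role, primer in (("forward", pair.forward), ("reverse", pair.reverse)):
            skip_gc = ambiguous and role == "forward"
            row = {
                "pair": pair.name,
                "role": role,
                "seq": primer.seq,
                "length": len(primer),
                "gc_pct": None if skip_gc else gc_content(primer.seq),
                "degeneracy": degeneracy(primer.seq),
                "tm_wallace": melting_temperature(primer.seq, method="wallace"),
                "ambiguous": skip_gc,
            }
            if tm_method_extra:
                row["tm_nn"] = round(
                    melting_temperature(primer.seq, method="nearest_neighbor"), 2)
            rows.append(row)
            if skip_gc and pair.alt_forward:
                alt = dict(row)
                alt["seq"] = pair.alt_forward
                alt["length"] = len(pair.alt_forward)
                alt["gc_pct"] = gc_content(pair.alt_forward)
                alt["degeneracy"] = degeneracy(pair.alt_forward)
                alt["tm_wallace"] = melting_temperature(pair.alt_forward, method="wallace")
                if tm_method_extra:
                    alt["tm_nn"] = round(
                        melting_temperature(pair.alt_forward, method="nearest_neighbor"), 2)
                alt["role"] = "forward_alt_reading"
                rows.append(alt)
    cols = ["pair", "role", "seq", "length", "gc_pct", "degeneracy",
            "tm_wallace"] + (["tm_nn"] if tm_method_extra else []) + ["ambiguous"]
    return pd.DataFrame(rows, columns=cols)
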
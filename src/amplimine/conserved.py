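"""Conserved-region detection in multiple alignments.

Primer mining needs three things from an alignment: conserved windows of
at least 18 columns to bind primers, a hypervariable core between two
such windows to discriminate species, and a total span whose ungapped
consensus length fits the product-size bounds (100–300 bp by default).

Conservation is scored per column as the frequency of the modal non-gap
residue; the ``gap_policy`` decides whether gapped rows dilute that
frequency (``count_as_mismatch``) or are excluded from the denominator
(``ignore``). There is no field-standard numeric cutoff for
"conserved", so min_score (default 0.90) and max_gap_fraction (default
0.10) are explicit, mandatory knobs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .iupac import IUPAC_EXPANSION, code_for_bases
from .metrics import DesignConstraints
from .seqio import Alignment

GapPolicy = Literal["count_as_mismatch", "ignore"]


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation score and gap fraction (length = width)."""

    score: np.ndarray
    gap_fraction: np.ndarray

    def __len__(self) -> int:
        return len(self.score)


@dataclass(frozen=True)
class ConservedRegion:
    """Alignment-column span [start, end) of conserved residues.

    ``consensus`` is the gap-free minimal-degeneracy IUPAC consensus over
    residues whose column frequency reaches the inclusion floor.
    """

    start: int
    end: int
    mean_score: float
    consensus: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AmplifiableRegion:
    """Two conserved flanks around a variable core, product-size feasible."""

    left_flank: ConservedRegion
    right_flank: ConservedRegion
    product_span_bp: int
    core_variability: float

    @property
    def core_start(self) -> int:
        return self.left_flank.end

    @property
    def core_end(self) -> int:
        return self.right_flank.start


def _column_matrix(aln: Alignment) -> np.ndarray:
    return np.array([list(row) for row in aln.rows()], dtype="U1")


def column_conservation(
    aln: Alignment, gap_policy: GapPolicy = "count_as_mismatch"
) -> ConservationProfile:
    """Score every column by the frequency of its modal non-gap residue.

    All-gap columns score 0 under either policy.
    """
    mat = _column_matrix(aln)
    n_rows, width = mat.shape
    score = np.zeros(width)
    gap_fraction = np.zeros(width)
    for j in range(width):
        col = mat[:, j]
        gaps = int(np.sum(col == "-"))
        gap_fraction[j] = gaps / n_rows
        non_gap = n_rows - gaps
        if non_gap == 0:
            score[j] = 0.0
            continue
        counts = Counter(col[col != "-"])
        modal = counts.most_common(1)[0][1]
        denom = n_rows if gap_policy == "count_as_mismatch" else non_gap
        score[j] = modal / denom
    return ConservationProfile(score=score, gap_fraction=gap_fraction)


def consensus_sequence(
    aln: Alignment,
    start: int,
    end: int,
    *,
    inclusion_floor: float = 0.05,
) -> str:
    """Minimal-degeneracy IUPAC consensus of columns [start, end).

    Residues at frequency ≥ inclusion_floor among non-gap rows contribute
    their expansions to the column's code; majority-gap columns are
    dropped so the consensus is always gap-free.
    """
    mat = _column_matrix(aln)
    out = []
    for j in range(start, end):
        col = mat[:, j]
        residues = col[col != "-"]
        if len(residues) <= len(col) / 2:
            continue  # majority-gap column contributes no consensus base
        counts = Counter(residues)
        total = len(residues)
        bases: set[str] = set()
        for res, n in counts.items():
            if n / total >= inclusion_floor:
                bases |= IUPAC_EXPANSION[res]
        if not bases:  # every residue below the floor: fall back to modal
            bases = set(IUPAC_EXPANSION[counts.most_common(1)[0][0]])
        out.append(code_for_bases(frozenset(bases)))
    return "".join(out)


def find_conserved_regions(
    aln: Alignment,
    *,
    min_len: int = 18,
    min_score: float = 0.90,
    max_gap_fraction: float = 0.10,
    gap_policy: GapPolicy = "count_as_mismatch",
    inclusion_floor: float = 0.05,
    profile: ConservationProfile | None = None,
) -> list[ConservedRegion]:
    """Maximal runs of columns meeting the conservation thresholds.

    A run qualifies when every column has score ≥ min_score and
    gap_fraction ≤ max_gap_fraction and the run is at least min_len
    columns long.
    """
    if not 0.0 <= min_score <= 1.0 or not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    if profile is None:
        profile = column_conservation(aln, gap_policy)
    ok = (profile.score >= min_score) & (profile.gap_fraction <= max_gap_fraction)
    regions: list[ConservedRegion] = []
    width = len(ok)
    j = 0
    while j < width:
        if not ok[j]:
            j += 1
            continue
        start = j
        while j < width and ok[j]:
            j += 1
        if j - start >= min_len:
            regions.append(
                ConservedRegion(
                    start=start,
                    end=j,
                    mean_score=float(np.mean(profile.score[start:j])),
                    consensus=consensus_sequence(
                        aln, start, j, inclusion_floor=inclusion_floor
                    ),
                )
            )
    return regions


def ungapped_span_length(aln: Alignment, start: int, end: int) -> int:
    """Consensus length of columns [start, end) after dropping
    majority-gap columns — the product size an amplicon spanning these
    columns would actually have."""
    mat = _column_matrix(aln)
    n = 0
    for j in range(start, end):
        col = mat[:, j]
        if int(np.sum(col != "-")) > len(col) / 2:
            n += 1
    return n


def find_amplifiable_regions(
    aln: Alignment,
    regions: list[ConservedRegion],
    constraints: DesignConstraints = DesignConstraints(),
    *,
    profile: ConservationProfile | None = None,
    gap_policy: GapPolicy = "count_as_mismatch",
) -> list[AmplifiableRegion]:
    """All ordered flank pairs whose ungapped span fits the product bounds.

    Returned sorted by descending core variability (mean 1−score over the
    core columns) so the most species-discriminating candidates lead; no
    hard variability cutoff is applied.
    """
    if profile is None:
        profile = column_conservation(aln, gap_policy)
    regions = sorted(regions, key=lambda r: r.start)
    out: list[AmplifiableRegion] = []
    for i, left in enumerate(regions):
        for right in regions[i + 1:]:
            if right.start < left.end:
                continue
            span = ungapped_span_length(aln, left.start, right.end)
            if not constraints.product_min <= span <= constraints.product_max:
                continue
            core = profile.score[left.end:right.start]
            variability = float(np.mean(1.0 - core)) if len(core) else 0.0
            out.append(
                AmplifiableRegion(
                    left_flank=left,
                    right_flank=right,
                    product_span_bp=span,
                    core_variability=variability,
                )
            )
    out.sort(key=lambda a: (-a.core_variability, a.left_flank.start, a.right_flank.start))
    return out


def write_regions_bed(
    regions: Iterable[ConservedRegion], path: str | Path, *, track_name: str = "conserved"
) -> None:
    """BED export in alignment-coordinate space (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for i, r in enumerate(regions, start=1):
            fh.write(f"alignment\t{r.start}\t{r.end}\t{track_name}_{i}\t"
                     f"{int(round(1000 * r.mean_score))}\t+\n")


def write_regions_tsv(regions: Iterable[ConservedRegion], path: str | Path) -> None:
    """TSV export; coordinates 1-based inclusive for human consumption."""
    with open(path, "w") as fh:
        fh.write("start\tend\tlength\tmean_score\tconsensus\n")
        for r in regions:
            fh.write(f"{r.start + 1}\t{r.end}\t{len(r)}\t{r.mean_score:.4f}\t{r.consensus}\n")
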
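"""Primer-pair scoring: specificity, universality, robustness, faults.

The three criteria follow the standard metabarcoding usage: specificity
is the number (and fraction) of non-target species amplified,
universality the number of target species amplified, robustness the
amplification success rate. Robustness is template-denominated
(amplified sequences / sequences screened) as its primary reading —
universality already carries the species view — with the
species-denominated rate reported alongside.

Fault labels summarise failure modes the way a comparison table would:

* ``cross_amplification`` — too many of the amplified species are
  non-target (default: more than 5% of amplified species).
* ``limited_coverage``  — amplification confined to a single target
  class although several classes are present.
* ``partial_amplification`` — more than one but not all target classes
  amplified.
* ``poor_coverage`` — universality in the lowest quartile of a compared
  panel (only assigned in :func:`compare_pairs`, or per-pair when an
  explicit species-count threshold is supplied).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ispcr import ISPCRSettings, amplify
from .metrics import PrimerPair
from .seqio import SequenceRecord, TaxonomyTable, UnknownSequenceIdError

FAULT_LABELS = (
    "cross_amplification",
    "limited_coverage",
    "partial_amplification",
    "poor_coverage",
)


@dataclass(frozen=True)
class FaultThresholds:
    cross_amplification_min_fraction: float = 5.0  # percent of amplified species
    poor_coverage_max_species: int | None = None  # None → quartile rule in compare

    def __post_init__(self) -> None:
        if not 0.0 <= self.cross_amplification_min_fraction <= 100.0:
            raise ValueError("cross_amplification_min_fraction must be a percentage")


@dataclass
class EvaluationResult:
    pair_name: str
    n_templates: int
    n_target_species: int
    n_nontarget_species: int
    n_templates_amplified: int
    universality_count: int
    nontarget_count: int
    per_class: dict[str, tuple[int, int]]  # class → (amplified, present), targets only
    fault_labels: tuple[str, ...] = ()

    @property
    def robustness(self) -> float:
        """Amplification success rate over templates (sequences)."""
        return self.n_templates_amplified / self.n_templates if self.n_templates else 0.0

    @property
    def species_robustness(self) -> float:
        """Secondary, species-denominated success rate (targets only)."""
        return (self.universality_count / self.n_target_species
                if self.n_target_species else 0.0)

    @property
    def total_species_amplified(self) -> int:
        return self.universality_count + self.nontarget_count

    @property
    def nontarget_fraction(self) -> float:
        """Percent of amplified species that are non-target."""
        total = self.total_species_amplified
        return 100.0 * self.nontarget_count / total if total else 0.0


def _assign_faults(
    universality: int,
    nontarget_fraction: float,
    per_class: dict[str, tuple[int, int]],
    thresholds: FaultThresholds,
) -> tuple[str, ...]:
    faults: list[str] = []
    amplified_any = universality > 0 or nontarget_fraction > 0
    if amplified_any and nontarget_fraction > thresholds.cross_amplification_min_fraction:
        faults.append("cross_amplification")
    classes_present = [c for c, (_, present) in per_class.items() if present > 0]
    classes_amplified = [c for c, (amp, _) in per_class.items() if amp > 0]
    if len(classes_present) >= 2:
        if len(classes_amplified) == 1:
            faults.append("limited_coverage")
        elif 1 < len(classes_amplified) < len(classes_present):
            faults.append("partial_amplification")
    if (thresholds.poor_coverage_max_species is not None
            and universality <= thresholds.poor_coverage_max_species):
        faults.append("poor_coverage")
    return tuple(faults)


def evaluate_pair(
    pair: PrimerPair,
    db: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    settings: ISPCRSettings = ISPCRSettings(),
    thresholds: FaultThresholds = FaultThresholds(),
) -> EvaluationResult:
    """Score one primer pair against a labeled reference database.

    A species counts as amplified when at least one of its templates
    yields at least one amplicon. Every template id must resolve in the
    taxonomy table.
    """
    for record in db:
        if record.id not in taxonomy:
            raise UnknownSequenceIdError(
                f"template {record.id!r} has no taxonomy row"
            )
    amplified_templates = 0
    species_templates: dict[str, list[bool]] = {}
    species_meta: dict[str, tuple[str, bool]] = {}
    order: list[str] = []
    for record in sorted(db, key=lambda r: r.id):  # row-order invariant
        species, class_name, is_target = taxonomy.lookup(record.id)
        hit = bool(amplify(pair, record, settings))
        if hit:
            amplified_templates += 1
        if species not in species_templates:
            species_templates[species] = []
            species_meta[species] = (class_name, is_target)
            order.append(species)
        species_templates[species].append(hit)

    target_species = [s for s in order if species_meta[s][1]]
    nontarget_species = [s for s in order if not species_meta[s][1]]
    amplified = {s for s, hits in species_templates.items() if any(hits)}

    per_class: dict[str, tuple[int, int]] = {}
    for s in target_species:
        cls = species_meta[s][0]
        amp, present = per_class.get(cls, (0, 0))
        per_class[cls] = (amp + (1 if s in amplified else 0), present + 1)

    universality = sum(1 for s in target_species if s in amplified)
    nontarget_count = sum(1 for s in nontarget_species if s in amplified)
    total_amp = universality + nontarget_count
    nontarget_fraction = 100.0 * nontarget_count / total_amp if total_amp else 0.0

    return EvaluationResult(
        pair_name=pair.name,
        n_templates=len(db),
        n_target_species=len(target_species),
        n_nontarget_species=len(nontarget_species),
        n_templates_amplified=amplified_templates,
        universality_count=universality,
        nontarget_count=nontarget_count,
        per_class=dict(sorted(per_class.items())),
        fault_labels=_assign_faults(universality, nontarget_fraction,
                                    per_class, thresholds),
    )


def compare_pairs(
    results: Sequence[EvaluationResult],
    thresholds: FaultThresholds = FaultThresholds(),
) -> pd.DataFrame:
    """Deterministic ranking of evaluated pairs plus a fault matrix.

    Rank order: fewest fault labels, then highest universality, then
    lowest non-target fraction, then highest robustness; ties break
    lexicographically on the pair name. When no explicit poor-coverage
    threshold is set, pairs whose universality falls strictly below the
    panel's lowest quartile receive ``poor_coverage`` here.
    """
    if not results:
        raise ValueError("compare_pairs needs at least one result")
    results = list(results)
    if thresholds.poor_coverage_max_species is None and len(results) > 1:
        cutoff = float(np.percentile([r.universality_count for r in results], 25))
        for r in results:
            if (r.universality_count < cutoff
                    and "poor_coverage" not in r.fault_labels):
                r.fault_labels = tuple(list(r.fault_labels) + ["poor_coverage"])
    rows = []
    for r in results:
        rows.append({
            "pair": r.pair_name,
            "n_faults": len(r.fault_labels),
            "faults": ",".join(r.fault_labels),
            "universality": r.universality_count,
            "nontarget_species": r.nontarget_count,
            "nontarget_fraction_pct": round(r.nontarget_fraction, 2),
            "robustness": round(r.robustness, 4),
            "species_robustness": round(r.species_robustness, 4),
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["n_faults", "universality", "nontarget_fraction_pct", "robustness", "pair"],
        ascending=[True, False, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def fault_matrix_markdown(results: Sequence[EvaluationResult]) -> str:
    """Markdown fault matrix: one row per pair, one column per category."""
    lines = ["| Primer | " + " | ".join(FAULT_LABELS) + " |",
             "|" + "---|" * (len(FAULT_LABELS) + 1)]
    for r in results:
        cells = ["x" if f in r.fault_labels else "" for f in FAULT_LABELS]
        lines.append("| " + r.pair_name + " | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def write_evaluation_tsv(results: Sequence[EvaluationResult], path: str | Path) -> None:
    rows = []
    for r in results:
        row = {
            "pair": r.pair_name,
            "n_templates": r.n_templates,
            "templates_amplified": r.n_templates_amplified,
            "robustness": round(r.robustness, 4),
            "universality": r.universality_count,
            "n_target_species": r.n_target_species,
            "nontarget_species_amplified": r.nontarget_count,
            "nontarget_fraction_pct": round(r.nontarget_fraction, 2),
            "faults": ",".join(r.fault_labels),
        }
        for cls, (amp, present) in r.per_class.items():
            row[f"class_{cls}"] = f"{amp}/{present}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def result_to_json(result: EvaluationResult) -> dict:
    return {
        "pair": result.pair_name,
        "n_templates": result.n_templates,
        "templates_amplified": result.n_templates_amplified,
        "robustness": result.robustness,
        "species_robustness": result.species_robustness,
        "universality_count": result.universality_count,
        "n_target_species": result.n_target_species,
        "nontarget_count": result.nontarget_count,
        "nontarget_fraction_pct": result.nontarget_fraction,
        "per_class": {c: {"amplified": a, "present": p}
                      for c, (a, p) in result.per_class.items()},
        "fault_labels": list(result.fault_labels),
    }


def write_evaluation_json(results: Sequence[EvaluationResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([result_to_json(r) for r in results], fh, indent=2)
        fh.write("\n")
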
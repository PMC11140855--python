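"""Seeded synthetic reference sets with planted primer-binding sites.

Each simulated target-species sequence has the anatomy the primer-mining
model assumes::

    pad | forward binding site | hypervariable core | revcomp(reverse site) | pad

The binding sites start from the planted primer pair (any degenerate
positions resolved uniformly per template, so a degenerate primer still
matches its own site with zero mismatches) and then take independent
per-base substitutions at rate ``theta_flank``; the core diverges from a
single shared consensus at rate ``theta_core``. Decoys are random
sequences of matched length and GC labeled as Decapoda non-targets.

Defaults mirror the reference-panel study structure: 213 target species
split 125 Bivalvia / 61 Gastropoda / 27 Cephalopoda with 2 decapod
decoys, MollCOI253 planted (20 + 215 + 18 → a 253 bp product).

Ground truth is recorded per template — site coordinates, raw mutation
counts and effective mismatch counts against the (degenerate) primer —
so expected amplification under any screen settings is recomputable
without running the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .iupac import base_matches, expansion, reverse_complement
from .ispcr import ISPCRSettings
from .metrics import PrimerPair, load_reference_panel
from .seqio import Alignment, SequenceRecord, TaxonomyTable

_BASES = np.array(list("ACGT"))

#: target-class composition of the reference study (species per class)
DEFAULT_CLASSES: dict[str, int] = {"Bivalvia": 125, "Gastropoda": 61, "Cephalopoda": 27}


def default_planted_pair() -> PrimerPair:
    """MollCOI253 from the packaged panel (non-degenerate, 253 bp product)."""
    panel = {p.name: p for p in load_reference_panel()}
    return panel["MollCOI253"]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    classes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES))
    n_decoys: int = 2
    flank_len: int = 20
    core_len: int = 215
    theta_flank: float = 0.02
    theta_core: float = 0.2
    genome_pad: int = 50
    planted_pair: PrimerPair | None = None  # None → MollCOI253

    def __post_init__(self) -> None:
        for theta in (self.theta_flank, self.theta_core):
            if not 0.0 <= theta <= 1.0:
                raise ValueError("substitution probabilities must lie in [0,1]")
        if self.flank_len < 18:
            raise ValueError("flank_len must be at least 18 bp")
        if self.core_len <= 0 or self.genome_pad < 0:
            raise ValueError("lengths must be positive")

    @property
    def n_target_species(self) -> int:
        return sum(self.classes.values())

    def pair(self) -> PrimerPair:
        return self.planted_pair if self.planted_pair is not None else default_planted_pair()


@dataclass(frozen=True)
class PlantedSite:
    """One planted binding site: coordinates on the template's + strand,
    raw substitution count and effective mismatches vs the primer."""

    start: int
    end: int
    n_mutations: int
    effective_mismatches: int
    anchor_mismatches: int  # effective mismatches within the 2-nt 3' anchor


@dataclass(frozen=True)
class TemplateTruth:
    template_id: str
    is_decoy: bool
    fwd: PlantedSite | None
    rev: PlantedSite | None
    product_bp: int | None

    def expected_amplifiable(self, settings: ISPCRSettings = ISPCRSettings()) -> bool:
        """Recompute amplifiability from the planted facts alone."""
        if self.is_decoy or self.fwd is None or self.rev is None:
            return False
        anchor = settings.three_prime_anchor
        for site in (self.fwd, self.rev):
            if site.effective_mismatches > settings.max_mismatches:
                return False
            if anchor > 0 and site.anchor_mismatches > 0:
                return False
        assert self.product_bp is not None
        return settings.product_min <= self.product_bp <= settings.product_max


@dataclass(frozen=True)
class PlantedTruth:
    templates: tuple[TemplateTruth, ...]

    def fraction_amplifiable(
        self, settings: ISPCRSettings = ISPCRSettings()
    ) -> float:
        flags = [t.expected_amplifiable(settings) for t in self.templates]
        return sum(flags) / len(flags) if flags else 0.0

    def lookup(self, template_id: str) -> TemplateTruth:
        for t in self.templates:
            if t.template_id == template_id:
                return t
        raise KeyError(template_id)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n else ""


def _resolve(rng: np.random.Generator, degenerate: str) -> str:
    """Resolve degenerate codes uniformly to concrete bases."""
    return "".join(
        c if len(expansion(c)) == 1 else rng.choice(sorted(expansion(c)))
        for c in degenerate
    )


def _mutate(rng: np.random.Generator, seq: str, theta: float) -> tuple[str, np.ndarray]:
    """Independent per-base substitution to one of the 3 alternatives."""
    bases = np.array(list(seq))
    hit = rng.random(len(bases)) < theta
    for i in np.nonzero(hit)[0]:
        alternatives = [b for b in "ACGT" if b != bases[i]]
        bases[i] = alternatives[rng.integers(3)]
    return "".join(bases), hit


def _planted_site(
    rng: np.random.Generator, primer_seq: str, theta: float, offset: int
) -> tuple[str, PlantedSite]:
    """Build one binding site and its truth record.

    Effective mismatches are scored against the degenerate primer with
    IUPAC semantics: a substitution landing inside the primer code's own
    expansion is not a mismatch. The anchor is the primer's 3'-terminal
    two positions (sequence end for either role before strand placement).
    """
    resolved = _resolve(rng, primer_seq)
    mutated, hit = _mutate(rng, resolved, theta)
    eff = [not base_matches(p, t) for p, t in zip(primer_seq, mutated)]
    site = PlantedSite(
        start=offset,
        end=offset + len(primer_seq),
        n_mutations=int(hit.sum()),
        effective_mismatches=int(sum(eff)),
        anchor_mismatches=int(sum(eff[-2:])),
    )
    return mutated, site


def _core_consensus(rng: np.random.Generator, n: int) -> str:
    return _random_seq(rng, n)


def simulate_reference_set(
    cfg: SimulationConfig,
) -> tuple[list[SequenceRecord], TaxonomyTable, PlantedTruth]:
    """Generate the labeled reference set, taxonomy and planted truth.

    Deterministic per seed: the same config yields byte-identical
    sequences. Decoys match the targets' length and GC composition but
    carry no planted sites.
    """
    pair = cfg.pair()
    if len(pair.forward) > cfg.flank_len or len(pair.reverse) > cfg.flank_len:
        raise ValueError(
            f"planted primers ({len(pair.forward)}/{len(pair.reverse)} nt) "
            f"exceed flank_len {cfg.flank_len}"
        )
    rng = np.random.default_rng(cfg.seed)
    core_consensus = _core_consensus(rng, cfg.core_len)

    records: list[SequenceRecord] = []
    taxonomy = TaxonomyTable()
    truths: list[TemplateTruth] = []

    idx = 0
    for class_name, n_species in cfg.classes.items():
        for k in range(n_species):
            idx += 1
            tid = f"tgt{idx:04d}"
            species = f"{class_name}_sp{k + 1}"
            pad5 = _random_seq(rng, cfg.genome_pad)
            fwd_seq, fwd_site = _planted_site(
                rng, pair.forward.seq, cfg.theta_flank, cfg.genome_pad)
            core, _ = _mutate(rng, core_consensus, cfg.theta_core)
            rev_offset = cfg.genome_pad + len(pair.forward) + cfg.core_len
            rev_seq, rev_site = _planted_site(
                rng, pair.reverse.seq, cfg.theta_flank, rev_offset)
            pad3 = _random_seq(rng, cfg.genome_pad)
            seq = pad5 + fwd_seq + core + reverse_complement(rev_seq) + pad3
            records.append(SequenceRecord(tid, seq, species, class_name, True))
            taxonomy.add(tid, species, class_name, True)
            truths.append(TemplateTruth(
                template_id=tid,
                is_decoy=False,
                fwd=fwd_site,
                rev=rev_site,
                product_bp=len(pair.forward) + cfg.core_len + len(pair.reverse),
            ))

    if records:
        gc = np.mean([
            sum(1 for c in r.seq if c in "GC") / len(r.seq) for r in records])
    else:
        gc = 0.5
    total_len = 2 * cfg.genome_pad + len(pair.forward) + cfg.core_len + len(pair.reverse)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for k in range(cfg.n_decoys):
        tid = f"decoy{k + 1:03d}"
        seq = "".join(rng.choice(_BASES, size=total_len, p=probs))
        species = f"Decapoda_sp{k + 1}"
        records.append(SequenceRecord(tid, seq, species, "Decapoda", False))
        taxonomy.add(tid, species, "Decapoda", False)
        truths.append(TemplateTruth(tid, True, None, None, None))

    return records, taxonomy, PlantedTruth(tuple(truths))


def simulate_alignment(cfg: SimulationConfig) -> tuple[Alignment, list[tuple[int, int]]]:
    """Gap-free alignment of the target species (pads excluded).

    Rows are flank + core + flank, so columns line up by construction;
    returns the alignment and the two planted flank column spans.
    """
    pad_free = SimulationConfig(
        seed=cfg.seed,
        classes=dict(cfg.classes),
        n_decoys=0,
        flank_len=cfg.flank_len,
        core_len=cfg.core_len,
        theta_flank=cfg.theta_flank,
        theta_core=cfg.theta_core,
        genome_pad=0,
        planted_pair=cfg.planted_pair,
    )
    records, _, _ = simulate_reference_set(pad_free)
    pair = cfg.pair()
    n_f, n_r = len(pair.forward), len(pair.reverse)
    spans = [(0, n_f), (n_f + cfg.core_len, n_f + cfg.core_len + n_r)]
    return Alignment(tuple((r.id, r.seq) for r in records)), spans


def truth_to_json(truth: PlantedTruth, settings: ISPCRSettings = ISPCRSettings()) -> dict:
    return {
        "templates": [
            {
                "template_id": t.template_id,
                "is_decoy": t.is_decoy,
                "fwd": None if t.fwd is None else vars(t.fwd).copy(),
                "rev": None if t.rev is None else vars(t.rev).copy(),
                "product_bp": t.product_bp,
                "expected_amplifiable": t.expected_amplifiable(settings),
            }
            for t in truth.templates
        ],
        "fraction_amplifiable": truth.fraction_amplifiable(settings),
    }
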
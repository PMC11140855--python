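# Methods

## Matching model

A primer base matches a template base iff their IUPAC expansions
intersect; a mismatch is a position where the two base sets are
disjoint. This makes degenerate primers (e.g. veneroida's S/Y/R/D
positions) match every sequence they cover with zero mismatches, and it
extends symmetrically to degenerate template residues: an N in the
template matches anything. The engine applies the rule identically to
degenerate×degenerate positions (disjoint expansions = mismatch), a
case real chemistry never presents but reference databases do.

A binding site requires

* total mismatches ≤ `max_mismatches` (default 3), and
* zero mismatches in the primer's 3′-terminal `three_prime_anchor`
  bases (default 2), modeling extension failure at a 3′ mismatch.

The anchor rule is applied per primer, to both primers of a pair. No
positional weighting beyond the binary anchor is used, and no
thermodynamic 3′ ΔG model: the screen the defaults emulate specifies
only the two-base rule. With `max_mismatches = 0` the anchor is
vacuous by construction.

Both strands are always scanned. Site pairing accepts any
forward/reverse sites on opposite strands with 3′ ends facing inward
and an outer, primer-inclusive span in `[product_min, product_max]`
(default 100–500 bp). Pairings whose span is shorter than the two
primer lengths combined (physically overlapping sites) are rejected.
All hits are reported — nested and multiple amplicons included — and
downstream counting uses only the "≥ 1 hit" flag, so the absence of a
shortest-amplicon heuristic cannot bias the metrics. The optional Tm
gate (57–63 °C, ΔTm ≤ 2 °C) is off by default: it belongs to the
database screening protocol, not to the amplification model.

The production scanner encodes bases as 4-bit masks and slides the
primer with a vectorised bitwise-AND; an independent, deliberately
naive per-position scanner lives in the test suite and the two are
compared on several hundred randomized instances per run.

## Primer statistics

GC% counts a position iff its expansion ⊆ {G,C} (codes G, C, S). This
strict convention is the only one consistent with the published values
of the packaged panel's degenerate primers (veneroida F/R → 52.63 /
42.86). Percentages are rounded half-up to two decimals for reporting;
the unrounded value is retained. One published primer (unionoida
forward, printed as a 19-mer ending in R with GC 61.11%) is internally
inconsistent: no convention reproduces its printed GC from the 19-mer,
while the 18-mer reading without the trailing R does. The packaged
fixture stores both readings, flags the row ambiguous, and scores
neither.

Tm: Wallace rule 2(A+T) + 4(G+C), or nearest-neighbor via Biopython's
unified parameter table at 50 mM monovalent salt and 250 nM oligo.
Degenerate primers are averaged over their concrete expansions, capped
at 1024 expansions (error above). Published annealing temperatures are
deliberately not treated as numeric targets — the software that
produced them does not disclose its formula — so Tm participates only
in internal consistency checks and optional gating.

## Conservation scan and design

Per-column score = frequency of the modal non-gap residue; under the
default `count_as_mismatch` gap policy the denominator is all rows,
under `ignore` only non-gap rows (all-gap columns score 0 either way).
"Conserved" has no published numeric threshold, so `min_score` (0.90)
and `max_gap_fraction` (0.10) are explicit parameters; the defaults
recover planted flanks in simulation at realistic noise. Conserved
regions are maximal qualifying runs ≥ 18 columns. The consensus uses
minimal-degeneracy IUPAC codes over residues at frequency ≥ 0.05
(bounding primer degeneracy while tolerating rare variants); product
spans are measured on the ungapped consensus (majority-gap columns
dropped) because raw column counts inflate with alignment gaps.
Core variability (mean 1 − score over the inter-flank columns) is
reported and used for ranking but carries no hard cutoff: how much
inter-specific variation is "sufficient" is left to the user.

Candidate enumeration takes every flank-consensus substring of length
18–27 as a forward primer (reverse complements on the right flank),
keeps pairs passing GC 40–60%, length, and product 100–300 bp, and
ranks by (combined degeneracy, |ΔTm|, distance from the mid-range
product size, name) — a deterministic order with no hash dependence.
Pairs with combined degeneracy above 64 are dropped outright.

Coordinates are 0-based half-open internally and in BED exports,
1-based inclusive in human-readable TSVs.

## Synthetic data

Each simulated target sequence is
`pad | forward site | core | revcomp(reverse site) | pad`.
Degenerate planted-primer positions are resolved uniformly per template
*before* mutation, so a degenerate primer matches its own clean site
exactly. Flank sites then take independent per-base substitutions at
`theta_flank`, drawn uniformly from the three alternative bases (no
indels: the matching model is substitution-only, and simulating indels
would test a rule the engine does not implement). The core diverges at
`theta_core` from a single consensus shared by all target species;
a single consensus (rather than per-class consensi) keeps the
zero-divergence limit fully conserved, which is the regime the scan's
correctness tests need. Class labels are therefore pure metadata for
the evaluation bookkeeping. Decoys are i.i.d. sequences matched to the
targets' length and GC with no planted sites, labeled Decapoda
non-targets after the decapod negative controls such panels use.

Defaults mirror the reference study's structure: 213 target species
(125 Bivalvia, 61 Gastropoda, 27 Cephalopoda), 2 decoys, MollCOI253
planted (20 + 215 + 18 → 253 bp), 50 bp pads, `theta_flank` 0.02 and
`theta_core` 0.2. Tests and examples use smaller class maps (10–40
species) — the generator is O(n) and the choice is about keeping
fixtures legible, not about fidelity; every structural property holds
at any n.

Ground truth records, per template, the site coordinates, raw mutation
counts, and *effective* mismatches against the degenerate primer (a
substitution landing inside the primer code's own expansion is not a
mismatch), plus anchor hits. Expected amplifiability under any settings
is recomputed from these facts alone, never by calling the engine, so
truth-vs-engine agreement is a genuine two-route check. A decoy's
expected amplifiability is False; a spurious decoy amplification
(two compatible ≤3-mismatch anchored sites at a legal spacing arising
by chance) is possible in principle but has negligible probability at
the simulated lengths, and the agreement tests would surface it.

What the simulator does **not** emulate: phylogenetic correlation
between species, indels and alignment gaps, sequencing error, chimeras,
and database taxonomy errors. Passing tests therefore demonstrate the
pipeline's internal correctness under the stated noise model, not
field performance on real reference databases.

## Evaluation

A species counts as amplified when any of its templates yields ≥ 1
amplicon. Robustness is template-denominated (amplified sequences /
sequences screened, whole database): "amplification success rate" reads
most naturally over attempts, and universality already carries the
species view; the species-denominated rate is computed and reported
secondary. Fault labels, in the vocabulary comparison tables use:

* `cross_amplification` — > 5% of amplified species are non-target
  (configurable; published commentary treats ~12.6% as notable but
  names no cutoff).
* `limited_coverage` — amplified target species confined to one class
  with ≥ 2 classes present.
* `partial_amplification` — more than one but not all target classes
  amplified (distinguishing "missed the cephalopods" from "only
  bivalves").
* `poor_coverage` — universality strictly below the compared panel's
  lowest quartile (assigned during comparison; per-pair only with an
  explicit count threshold).

Ranking is deterministic: fewest faults, highest universality, lowest
non-target fraction, highest robustness, then name.

## Numerical and degenerate-input choices

* GC rounding uses decimal half-up (not banker's rounding), matching
  how the published values were evidently produced.
* Thresholds are closed bounds (≥ / ≤) throughout.
* Empty FASTA, ragged alignments, gaps outside alignments, non-IUPAC
  characters and unknown taxonomy ids raise typed errors naming the
  offender; an empty design result is a warning, not an error.
* Tie-breaks everywhere fall back to lexicographic names or input
  order; no operation depends on set/dict iteration order.

## Known limitations

* The matcher is O(n·m) per primer-template pair (vectorised); it is
  meant for reference panels of thousands of sequences, not for
  nr-scale BLAST-seeded search.
* No hairpin/dimer thermodynamics and no penalty-based primer
  optimisation; candidates are filtered and ranked, not optimised.
* Product sizes for candidate pairs are consensus-based; per-template
  indel variation in real data can shift true product sizes.
* The quartile rule for `poor_coverage` depends on the panel being
  compared; a pair's fault set is only meaningful relative to that
  panel.
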
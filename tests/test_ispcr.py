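"""In silico PCR engine: binding sites, anchoring, amplification, batch.

The vectorised scanner is checked against the naive per-position oracle
in ``oracle.py`` on randomized instances with degenerate codes and every
mismatch-budget/anchor combination the screen supports.
"""

import numpy as np
import pytest

import amplimine as am
from amplimine.ispcr import ISPCRSettings, batch_ispcr, find_binding_sites
from amplimine.metrics import Primer, PrimerPair

from oracle import naive_products, naive_sites

BASES = "ACGT"
DEGENERATE = "ACGTRYSWKMBDHVN"


def random_seq(rng, n, alphabet=BASES):
    return "".join(rng.choice(list(alphabet), size=n))


def make_pair(name, fwd, rev, product=None):
    return PrimerPair(
        name=name,
        forward=Primer(f"{name}-F", fwd, "forward"),
        reverse=Primer(f"{name}-R", rev, "reverse"),
        expected_product_bp=product,
    )


class TestFindBindingSites:
    def test_self_match_single_plus_site(self, mollcoi253):
        primer = mollcoi253.forward
        template = am.SequenceRecord("self", primer.seq)
        sites = find_binding_sites(primer, template)
        assert len(sites) == 1
        s = sites[0]
        assert (s.strand, s.start, s.end, s.mismatches) == ("+", 0, 20, 0)

    def test_internal_mismatch_counted_but_tolerated(self):
        primer = Primer("p", "ACGTACGTACGTACGTAA", "forward")
        template_seq = list(primer.seq)
        template_seq[5] = "G"  # position 6 (was C), far from the 3' end
        sites = find_binding_sites(
            primer, am.SequenceRecord("t", "".join(template_seq)))
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1 and plus[0].mismatches == 1

    @pytest.mark.parametrize("mutated_from_end", [1, 2])
    def test_three_prime_anchor_abolishes_site(self, mutated_from_end):
        primer = Primer("p", "ACGTACGTACGTACGTAA", "forward")
        template_seq = list(primer.seq)
        template_seq[-mutated_from_end] = "C"
        sites = find_binding_sites(
            primer, am.SequenceRecord("t", "".join(template_seq)))
        assert [s for s in sites if s.strand == "+"] == []

    def test_substitution_three_bases_in_is_one_mismatch(self):
        primer = Primer("p", "ACGTACGTACGTACGTAA", "forward")
        template_seq = list(primer.seq)
        template_seq[-3] = "C"  # 3 bases from the 3' end: outside the anchor
        sites = find_binding_sites(
            primer, am.SequenceRecord("t", "".join(template_seq)))
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1 and plus[0].mismatches == 1

    def test_template_shorter_than_primer_empty(self):
        primer = Primer("p", "ACGTACGTACGTACGTAA", "forward")
        assert find_binding_sites(primer, am.SequenceRecord("t", "ACGT")) == []

    def test_degenerate_primer_matches_every_expansion(self):
        primer = Primer("p", "CSCTGTTATCCCYRCGGTA", "forward")
        for concrete in ("CGCTGTTATCCCCACGGTA", "CCCTGTTATCCCTGCGGTA"):
            sites = find_binding_sites(primer, am.SequenceRecord("t", concrete))
            plus = [s for s in sites if s.strand == "+"]
            assert plus and plus[0].mismatches == 0

    def test_minus_strand_site_found(self):
        primer = Primer("p", "GGAGTAGGAACTGGTTGGAC", "forward")
        template = am.SequenceRecord("t", "TT" + am.reverse_complement(primer.seq) + "TT")
        sites = find_binding_sites(primer, template)
        minus = [s for s in sites if s.strand == "-"]
        assert len(minus) == 1
        assert (minus[0].start, minus[0].end) == (2, 22)


class TestOracleEquivalence:
    @pytest.mark.parametrize("max_mm,anchor", [(0, 0), (0, 2), (1, 1), (2, 2), (3, 2), (3, 0)])
    def test_sites_match_naive_scanner(self, max_mm, anchor):
        rng = np.random.default_rng(1000 + 10 * max_mm + anchor)
        for case in range(40):
            alphabet = DEGENERATE if case % 3 == 0 else BASES
            primer_seq = random_seq(rng, int(rng.integers(16, 25)), alphabet)
            template_seq = random_seq(rng, int(rng.integers(40, 500)), BASES)
            # plant a corrupted copy so non-trivial sites actually occur
            insert_at = int(rng.integers(0, len(template_seq) - len(primer_seq)))
            planted = list(primer_seq.replace("N", "A"))
            for pos in rng.choice(len(planted), size=min(max_mm, 2), replace=False):
                planted[pos] = rng.choice(list(BASES))
            concrete = "".join(
                c if c in BASES else "ACGT"[int(rng.integers(4))] for c in planted)
            template_seq = (template_seq[:insert_at] + concrete
                            + template_seq[insert_at + len(concrete):])
            settings = ISPCRSettings(max_mismatches=max_mm, three_prime_anchor=anchor)
            primer = Primer("p", primer_seq, "forward")
            got = sorted(
                (s.strand, s.start, s.mismatches)
                for s in find_binding_sites(
                    primer, am.SequenceRecord("t", template_seq), settings))
            expected = naive_sites(primer_seq, template_seq, max_mm, anchor)
            assert got == expected

    def test_products_match_naive_pairing(self):
        rng = np.random.default_rng(77)
        pair = make_pair("x", "GGAGTAGGAACTGGTTGGAC", "CAGCTGCTAACACAGGCA")
        settings = ISPCRSettings()
        for _ in range(30):
            template_seq = random_seq(rng, 460)
            at = int(rng.integers(0, 120))
            template_seq = (template_seq[:at] + pair.forward.seq
                            + template_seq[at + 20:at + 220]
                            + am.reverse_complement(pair.reverse.seq)
                            + template_seq[at + 238:])
            got = sorted(h.product_bp for h in am.amplify(
                pair, am.SequenceRecord("t", template_seq), settings))
            expected = naive_products(
                pair.forward.seq, pair.reverse.seq, template_seq,
                settings.max_mismatches, settings.three_prime_anchor,
                settings.product_min, settings.product_max)
            assert got == expected


class TestAmplify:
    def test_published_product_geometry(self, panel):
        for name, pad, product in (("MollCOI253", 215, 253), ("MollCOI154", 115, 154)):
            pair = panel[name]
            template = am.SequenceRecord(
                "t", pair.forward.seq + "A" * pad
                + am.reverse_complement(pair.reverse.seq))
            hits = am.amplify(pair, template)
            assert [h.product_bp for h in hits] == [product]
            assert hits[0].total_mismatches == 0

    def test_product_beyond_max_rejected(self, mollcoi253):
        template = am.SequenceRecord(
            "t", mollcoi253.forward.seq + "A" * 500
            + am.reverse_complement(mollcoi253.reverse.seq))
        assert am.amplify(mollcoi253, template) == []

    def test_two_forward_sites_one_reverse_two_hits(self, mollcoi253):
        # exact matching so the two planted F sites and one R site are the
        # only sites; amplicons from each F to the shared R: 118 and 218 bp
        f = mollcoi253.forward.seq
        rc_r = am.reverse_complement(mollcoi253.reverse.seq)
        template = am.SequenceRecord("t", f + "T" * 80 + f + "T" * 80 + rc_r)
        hits = am.amplify(mollcoi253, template, ISPCRSettings(max_mismatches=0))
        assert sorted(h.product_bp for h in hits) == [118, 218]

    def test_self_overlapping_sites_rejected(self, mollcoi253):
        # truncated F next to a full R site: product would be shorter than
        # the two primer lengths combined, so no amplicon
        template = am.SequenceRecord(
            "t", mollcoi253.forward.seq[:10]
            + am.reverse_complement(mollcoi253.reverse.seq))
        assert am.amplify(mollcoi253, template,
                          ISPCRSettings(product_min=10, max_mismatches=0)) == []

    def test_strand_symmetry(self, mollcoi253):
        rng = np.random.default_rng(9)
        for _ in range(10):
            template_seq = (random_seq(rng, 30) + mollcoi253.forward.seq
                            + random_seq(rng, 180)
                            + am.reverse_complement(mollcoi253.reverse.seq)
                            + random_seq(rng, 30))
            fwd_products = sorted(h.product_bp for h in am.amplify(
                mollcoi253, am.SequenceRecord("t", template_seq)))
            rc_products = sorted(h.product_bp for h in am.amplify(
                mollcoi253,
                am.SequenceRecord("t", am.reverse_complement(template_seq))))
            assert fwd_products == rc_products

    def test_anchor_vacuous_at_zero_mismatches(self, mollcoi253):
        rng = np.random.default_rng(21)
        for _ in range(10):
            template = am.SequenceRecord("t", random_seq(rng, 400))
            hits0 = am.amplify(mollcoi253, template,
                               ISPCRSettings(max_mismatches=0, three_prime_anchor=0))
            hits2 = am.amplify(mollcoi253, template,
                               ISPCRSettings(max_mismatches=0, three_prime_anchor=2))
            assert [h.product_bp for h in hits0] == [h.product_bp for h in hits2]

    @pytest.mark.parametrize("seed", [4, 44])
    def test_monotone_in_mismatch_budget_and_product_window(self, seed, mollcoi253):
        rng = np.random.default_rng(seed)
        template_seq = list(
            mollcoi253.forward.seq + random_seq(rng, 215)
            + am.reverse_complement(mollcoi253.reverse.seq))
        for pos in (3, 7):  # corrupt the forward site away from its 3' end
            template_seq[pos] = "ACGT"[int(rng.integers(4))]
        template = am.SequenceRecord("t", "".join(template_seq))
        n_hits = [len(am.amplify(mollcoi253, template,
                                 ISPCRSettings(max_mismatches=mm)))
                  for mm in range(4)]
        assert n_hits == sorted(n_hits)
        narrow = len(am.amplify(mollcoi253, template,
                                ISPCRSettings(product_min=200, product_max=300)))
        wide = len(am.amplify(mollcoi253, template,
                              ISPCRSettings(product_min=100, product_max=500)))
        assert wide >= narrow

    def test_tm_gate_filters_when_enforced(self, panel):
        # Wallace-style gate: pick a pair and a window excluding its Tm
        pair = panel["MollCOI253"]
        template = am.SequenceRecord(
            "t", pair.forward.seq + "A" * 215
            + am.reverse_complement(pair.reverse.seq))
        blocked = am.amplify(pair, template, ISPCRSettings(
            enforce_tm=True, tm_min=95.0, tm_max=99.0, tm_method="wallace"))
        assert blocked == []
        open_gate = am.amplify(pair, template, ISPCRSettings(
            enforce_tm=True, tm_min=40.0, tm_max=80.0, max_tm_diff=20.0,
            tm_method="wallace"))
        assert [h.product_bp for h in open_gate] == [253]


class TestBatch:
    def test_planted_db_counts(self, small_sim_cfg, mollcoi253):
        records, _, truth = am.simulate_reference_set(small_sim_cfg)
        hits_df, summary = batch_ispcr([mollcoi253], records)
        # theta_flank=0: every target amplifies, no decoy does
        by_id = summary.set_index("template_id")["amplified"]
        for t in truth.templates:
            assert by_id[t.template_id] == (not t.is_decoy)
        assert set(hits_df["product_bp"]) == {253}

    def test_no_match_db_all_false(self, mollcoi253):
        db = [am.SequenceRecord(f"r{i}", "AT" * 150) for i in range(3)]
        hits_df, summary = batch_ispcr([mollcoi253], db)
        assert hits_df.empty
        assert not summary["amplified"].any()

    def test_row_order_deterministic(self, small_sim_cfg, panel):
        records, _, _ = am.simulate_reference_set(small_sim_cfg)
        pairs = [panel["MollCOI253"], panel["MollCOI154"]]
        _, s1 = batch_ispcr(pairs, records)
        _, s2 = batch_ispcr(pairs, records)
        assert s1.equals(s2)
        assert list(s1["pair"].unique()) == ["MollCOI253", "MollCOI154"]

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            ISPCRSettings(max_mismatches=-1)
        with pytest.raises(ValueError):
            ISPCRSettings(product_min=500, product_max=100)
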
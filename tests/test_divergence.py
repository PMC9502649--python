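"""Alignment, NG86 Ka/Ks, strata permutation test, K2P dating and SDR gene
classification."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdrkit.divergence import (
    CODON_AA,
    call_pseudogene,
    classify_sdr_genes,
    codon_align,
    date_ltr_elements,
    global_align,
    jukes_cantor,
    kimura2p,
    ltr_insertion_age,
    ng86_ka_ks,
    reciprocal_best_hits,
    strata_test,
    tandem_duplicates,
)
from sdrkit.io import SequenceRecord
from sdrkit.simulate import simulate_gametolog_pairs, simulate_ltr_elements

dna = st.text(alphabet="ACGT", min_size=1, max_size=25)


def _rec(rid, seq):
    return SequenceRecord(id=rid, residues=seq)


class TestGlobalAlign:
    def test_identical_sequences(self):
        pair = global_align("ACGTACGT", "ACGTACGT")
        assert pair.identity == 1.0 and pair.coverage == 1.0
        assert "-" not in pair.aligned_a + pair.aligned_b

    def test_single_gap_example(self):
        pair = global_align("ACGT", "ACT", match=1, mismatch=-1, gap=-1)
        assert pair.score == 2.0
        assert sum(1 for c in pair.aligned_b if c == "-") == 1

    @given(dna, dna)
    @settings(max_examples=60, deadline=None)
    def test_score_symmetry(self, a, b):
        assert global_align(a, b).score == global_align(b, a).score

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")


class TestReciprocalBestHits:
    def test_identical_sets_give_identity_mapping(self):
        recs = [_rec(f"g{i}", s) for i, s in
                enumerate(["ACGTACGTAC", "TTTTGGGGCC", "ACACACACAC"])]
        other = [_rec(f"h{i}", r.residues) for i, r in enumerate(recs)]
        rbh = reciprocal_best_hits(recs, other)
        assert rbh == {"g0": "h0", "g1": "h1", "g2": "h2"}

    def test_non_reciprocal_pair_dropped(self):
        # a1's best hit is b1, but b1 prefers a2
        a1 = _rec("a1", "AACCGGTTAA")
        a2 = _rec("a2", "AACCGGTTAC")
        b1 = _rec("b1", "AACCGGTTAC")
        rbh = reciprocal_best_hits([a1, a2], [b1])
        assert "a1" not in rbh and rbh == {"a2": "b1"}

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        set_a = [_rec(f"a{i}", "".join(rng.choice(list("ACGT"), 30)))
                 for i in range(5)]
        set_b = [_rec(f"b{i}", "".join(rng.choice(list("ACGT"), 30)))
                 for i in range(5)]
        scores = {
            (ra.id, rb.id): global_align(ra, rb).score
            for ra in set_a for rb in set_b
        }
        expected = {}
        for ra in set_a:
            best_b = min(sorted(s.id for s in set_b),
                         key=lambda j: (-scores[(ra.id, j)], j))
            back = min(sorted(s.id for s in set_a),
                       key=lambda i: (-scores[(i, best_b)], i))
            if back == ra.id:
                expected[ra.id] = best_b
        assert reciprocal_best_hits(set_a, set_b,
                                    min_score=-1e9) == expected


def ng86_pathway_oracle(c1, c2):
    """Independent pathway enumeration of synonymous/nonsynonymous
    differences for one codon pair, skipping stop-passing paths."""
    from Bio.Seq import Seq

    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, syn, non, ok = c1, 0, 0, True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if str(Seq(nxt).translate()) == "*":
                ok = False
                break
            if str(Seq(nxt).translate()) == str(Seq(cur).translate()):
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            paths.append((syn, non))
    if not paths:
        return None
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


class TestNG86:
    def test_identical_pair_is_zero(self):
        pair = ng86_ka_ks("ATGGCTGCT", "ATGGCTGCT")
        assert pair.Ka == 0.0 and pair.Ks == 0.0

    def test_lysine_codon_worked_example(self):
        # ten AAA codons vs nine AAA + one AAG: one synonymous difference,
        # S = 10/3 under the stop-excluded convention, pS = 0.3
        x = "AAA" * 10
        y = "AAA" * 9 + "AAG"
        pair = ng86_ka_ks(x, y)
        assert pair.Sd == 1.0 and pair.Nd == 0.0
        assert pair.S == pytest.approx(10 / 3)
        assert pair.Ks == pytest.approx(-0.75 * math.log(0.6), abs=1e-9)
        assert pair.Ka == 0.0

    def test_two_difference_codons_match_pathway_oracle(self):
        sense = [c for c in CODON_AA if CODON_AA[c] != "*"]
        rng = np.random.default_rng(0)
        checked = 0
        for c1 in rng.choice(sense, size=12, replace=False):
            for c2 in sense:
                if sum(a != b for a, b in zip(c1, c2)) != 2:
                    continue
                oracle = ng86_pathway_oracle(c1, c2)
                pair = ng86_ka_ks(c1, c2)
                if oracle is None:
                    continue
                assert pair.Sd == pytest.approx(oracle[0], abs=1e-12)
                assert pair.Nd == pytest.approx(oracle[1], abs=1e-12)
                checked += 1
        assert checked > 50

    def test_saturation_flagged(self):
        # every third position differs -> pS far beyond the JC limit
        x = "GGT" * 200
        y = "GGA" * 200
        pair = ng86_ka_ks(x, y)
        assert pair.Ks is None or pair.Ks > 0  # saturated or finite
        assert jukes_cantor(0.8) is None

    def test_gapped_codons_excluded(self):
        pair = ng86_ka_ks("ATG---GCT", "ATGAAAGCT")
        assert pair.n_codons == 2

    def test_recovers_planted_ks(self):
        pairs = simulate_gametolog_pairs(60, 999, 0.033, seed=3)
        ks = [ng86_ka_ks(x.residues, y.residues).Ks for x, y in pairs]
        assert np.mean(ks) == pytest.approx(0.033, rel=0.1)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ng86_ka_ks("ATGGCT", "ATG")


class TestCodonAlign:
    def test_threads_codons_through_protein_alignment(self):
        x = "ATG" + "GCT" + "TGG" + "GAA" + "TAA"
        y = "ATG" + "TGG" + "GAA" + "TAA"  # one codon deleted
        ax, ay = codon_align(x, y)
        assert len(ax) == len(ay) and len(ax) % 3 == 0
        assert "-" not in ax + ay
        pair = ng86_ka_ks(ax, ay)
        assert pair.Nd == 0 and pair.Sd == 0  # identical after threading


class TestStrata:
    def test_constant_ks_is_null(self):
        pairs = [(i * 1000, 0.03) for i in range(20)]
        res = strata_test(pairs, n_perm=500, seed=1)
        assert res.p_value > 0.05 and res.breakpoints == []

    def test_planted_step_detected_near_true_breakpoint(self):
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(20):
            ks = np.concatenate([
                rng.normal(0.02, 0.01, 10), rng.normal(0.10, 0.01, 10)])
            pairs = [(i * 1000, max(k, 0.0)) for i, k in enumerate(ks)]
            res = strata_test(pairs, n_perm=500, seed=seed)
            if res.p_value < 0.05 and res.breakpoints and \
                    abs(res.breakpoints[0] // 1000 - 10) <= 2:
                hits += 1
        assert hits >= 18

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # 8 points: enumerate all 8! orderings exactly
        pairs = [(i, k) for i, k in
                 enumerate([0.01, 0.02, 0.03, 0.02, 0.09, 0.10, 0.11, 0.12])]
        ks = np.array([k for _, k in pairs])

        def stat(v):
            best = -1
            c = np.cumsum(v)
            for i in range(4, 5):  # min_segment 4 on 8 points: one breakpoint
                d = abs(c[i - 1] / i - (c[-1] - c[i - 1]) / (8 - i))
                best = max(best, d)
            return best

        obs = stat(ks)
        hits = total = 0
        for perm in itertools.permutations(ks):
            total += 1
            if stat(np.array(perm)) >= obs:
                hits += 1
        exact = hits / total
        res = strata_test(pairs, n_perm=20_000, seed=5)
        se = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(res.p_value - exact) <= 3 * se + 1e-4

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            strata_test([(0, 0.1)] * 7)


class TestKimura2P:
    def test_identical_arms(self):
        assert kimura2p("ACGT" * 10, "ACGT" * 10) == (0.0, 0.0, 0.0)

    def test_closed_form_value(self):
        # 1000 sites: 100 transitions (A->G), 50 transversions (A->C)
        a = "A" * 1000
        b = "G" * 100 + "C" * 50 + "A" * 850
        P, Q, K = kimura2p(a, b)
        assert (P, Q) == (0.1, 0.05)
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.9)
        assert K == pytest.approx(expected, abs=1e-9)
        assert round(expected, 5) == 0.17018

    def test_simulated_divergence_recovered(self):
        elems = simulate_ltr_elements([10e6], 2.5e-9, 5000, 2.0, seed=9)
        _, a5, a3, _ = elems[0]
        _, _, K = kimura2p(a5.residues, a3.residues)
        d = 0.05
        se = math.sqrt(d * (1 - d) / 5000)
        assert abs(K - d) < 3 * se + 0.003

    def test_k_at_least_raw_difference(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 300))
            b = "".join(
                c if rng.random() > 0.1
                else rng.choice([x for x in "ACGT" if x != c])
                for c in a
            )
            P, Q, K = kimura2p(a, b)
            if K is not None:
                assert K >= P + Q - 1e-12

    def test_saturation_flagged(self):
        P, Q, K = kimura2p("A" * 100, "G" * 60 + "C" * 40)
        assert K is None

    def test_n_sites_excluded(self):
        P, Q, K = kimura2p("ANGT", "AAGT")
        assert (P, Q, K) == (0.0, 0.0, 0.0)


class TestLTRDating:
    def test_zero_divergence_zero_age(self):
        assert ltr_insertion_age(0.0, 2.5e-9) == 0.0

    def test_arithmetic_example(self):
        # K=0.05 at 2.5e-9 per year: 10 Mya
        assert ltr_insertion_age(0.05, 2.5e-9) == pytest.approx(1.0e7)

    def test_invalid_mu(self):
        with pytest.raises(ValueError):
            ltr_insertion_age(0.05, 0.0)

    @pytest.mark.parametrize("age", [1e6, 5e6, 10e6, 20e6])
    def test_round_trip_within_ten_percent(self, age):
        elems = simulate_ltr_elements([age] * 30, 2.5e-9, 5000, 2.0,
                                      seed=int(age // 1e6))
        ages = [e.age_years for e in date_ltr_elements(elems, mu=2.5e-9)]
        assert np.mean(ages) == pytest.approx(age, rel=0.1)


class TestTandemsAndPseudogenes:
    def test_tandem_window(self):
        g1 = _rec("g1", "ACGTACGTACGTACGTACGT")
        g2 = _rec("g2", "ACGTACGTACGTACGTACGT")
        near = [(g1, 100_000), (g2, 500_000)]  # 400 kb apart
        far = [(g1, 100_000), (g2, 700_000)]  # 600 kb apart
        assert tandem_duplicates(near, min_score=10) == [("g1", "g2")]
        assert tandem_duplicates(far, min_score=10) == []

    def test_self_pairing_excluded(self):
        g1 = _rec("g1", "ACGTACGTACGT")
        assert tandem_duplicates([(g1, 0)], min_score=0) == []

    def _parent(self):
        rng = np.random.default_rng(8)
        codons = ["ATG"] + [
            p + t for p, t in zip(
                rng.choice(["GCT", "ACT", "CCT", "GGT", "TCT"], 49),
                [""] * 49)
        ]
        return "".join(codons)

    def test_degraded_copy_with_stop_called(self):
        parent = self._parent()
        # ~25% of codons mutated at position 2 -> identity ~0.92, one stop
        cand = list(parent)
        rng = np.random.default_rng(1)
        for ci in rng.choice(range(1, 50), size=12, replace=False):
            cand[3 * ci + 1] = "A"
        cand[3 * 25: 3 * 25 + 3] = "TAA"  # premature stop
        call = call_pseudogene(_rec("cand", "".join(cand)),
                               _rec("parent", parent))
        assert call is not None and "premature_stop" in call.disruptions

    def test_frameshift_called(self):
        parent = self._parent()
        cand = parent[:60] + parent[61:]  # 1-bp deletion
        call = call_pseudogene(_rec("cand", cand), _rec("parent", parent))
        assert call is not None and "frameshift" in call.disruptions

    def test_low_identity_not_called(self):
        # a copy diverged at ~35% of positions sits below the 70% identity
        # threshold even when it carries a stop
        rng = np.random.default_rng(3)
        parent = self._parent()
        cand = list(parent)
        for i in rng.choice(len(parent), size=int(0.35 * len(parent)),
                            replace=False):
            cand[i] = rng.choice([b for b in "ACGT" if b != cand[i]])
        cand[75:78] = "TAA"
        assert call_pseudogene(_rec("c", "".join(cand)),
                               _rec("p", parent)) is None

    def test_intact_copy_not_called(self):
        parent = self._parent()
        assert call_pseudogene(_rec("c", parent), _rec("p", parent)) is None


class TestClassification:
    def _sets(self):
        rng = np.random.default_rng(6)

        def seq(n=60):
            return "".join(rng.choice(list("ACGT"), n))

        shared = seq()
        transposed = seq()
        x = [_rec("x_shared", shared), _rec("x_widow", seq())]
        y = [_rec("y_shared", shared), _rec("y_transposed", transposed),
             _rec("y_specific", seq())]
        autosomal = [_rec("aut_partner", transposed), _rec("aut_other", seq())]
        return x, y, autosomal

    def test_shared_transposed_specific(self):
        x, y, autosomal = self._sets()
        calls = {c.gene_id: c for c in classify_sdr_genes(
            x, y, autosomal_genes=autosomal, min_score=40)}
        assert "X_Y_SHARED" in calls["x_shared"].labels
        assert "X_Y_SHARED" in calls["y_shared"].labels
        assert "AUTOSOMAL_TRANSPOSITION" in calls["y_transposed"].labels
        assert "SPECIFIC" in calls["y_specific"].labels

    def test_pseudogene_relic_marks_loss_on_other_haplotype(self):
        from sdrkit.divergence import PseudogeneCall

        x, y, autosomal = self._sets()
        pseudo = {"x_widow": PseudogeneCall("relic", "x_widow", 0.8, 0.9,
                                            ["premature_stop"])}
        calls = {c.gene_id: c for c in classify_sdr_genes(
            x, y, pseudogene_calls=pseudo, min_score=40)}
        assert "LOST" in calls["x_widow"].labels
        assert calls["x_widow"].evidence["lost_haplotype"] == "Y"

    def test_duplicate_gene_across_sets_rejected(self):
        x, y, _ = self._sets()
        with pytest.raises(ValueError, match="present in both"):
            classify_sdr_genes(x, x, min_score=0)

    def test_stable_under_input_order(self):
        x, y, autosomal = self._sets()
        a = classify_sdr_genes(x, y, autosomal_genes=autosomal, min_score=40)
        b = classify_sdr_genes(x[::-1], y[::-1],
                               autosomal_genes=autosomal[::-1], min_score=40)
        assert [(c.gene_id, sorted(c.labels)) for c in a] == \
            [(c.gene_id, sorted(c.labels)) for c in b]
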
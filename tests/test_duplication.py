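"""Nei-Gojobori estimator, duplication classification, dating, selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genefam._codons import SENSE_CODONS
from genefam.duplication import (
    classify_pair,
    date_pair,
    nei_gojobori,
    selection_mode,
)

from oracles import jc_correct, ng86_brute_force


def random_codon_pair(rng, n_codons):
    """Random codon-aligned pair: shared backbone with scattered mutations."""
    codons_a = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    codons_b = list(codons_a)
    for i in range(n_codons):
        if rng.random() < 0.15:
            codons_b[i] = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
    return "".join(codons_a), "".join(codons_b)


class TestNeiGojobori:
    def test_identical_sequences_have_zero_rates(self):
        r = nei_gojobori("GCTTTTAAA", "GCTTTTAAA")
        assert r.ka == 0.0 and r.ks == 0.0

    def test_worked_example_single_synonymous_difference(self):
        # Ala GCT->GCC is synonymous; S = 1 + 1/3 + 1/3 per sequence
        r = nei_gojobori("GCTTTTAAA", "GCCTTTAAA")
        assert r.s_sites == pytest.approx(5.0 / 3.0)
        assert r.ps == pytest.approx(0.6)
        assert r.ks == pytest.approx(-0.75 * math.log(0.2))
        assert r.ks == pytest.approx(1.2069, abs=2e-4)
        assert r.ka == 0.0

    def test_saturated_synonymous_proportion_is_flagged(self):
        r = nei_gojobori("GCT", "GCC")
        assert r.s_sites == pytest.approx(1.0)
        assert r.ps == pytest.approx(1.0)
        assert r.saturated_ks and math.isnan(r.ks)

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(0)
        a, b = random_codon_pair(rng, 50)
        r = nei_gojobori(a, b)
        assert r.n_sites + r.s_sites == pytest.approx(3 * r.codons_compared)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = random_codon_pair(rng, 30)
            r1, r2 = nei_gojobori(a, b), nei_gojobori(b, a)
            assert r1.ps == pytest.approx(r2.ps, abs=1e-12)
            assert r1.pn == pytest.approx(r2.pn, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b = random_codon_pair(rng, int(rng.integers(10, 60)))
            r = nei_gojobori(a, b)
            pn, ps, n, s, nd, sd = ng86_brute_force(a, b)
            assert r.s_sites == pytest.approx(s, abs=1e-9)
            assert r.n_sites == pytest.approx(n, abs=1e-9)
            assert r.sd == pytest.approx(sd, abs=1e-9)
            assert r.nd == pytest.approx(nd, abs=1e-9)
            if not math.isnan(r.ks):
                assert r.ks == pytest.approx(jc_correct(ps), abs=1e-9)
            if not math.isnan(r.ka):
                assert r.ka == pytest.approx(jc_correct(pn), abs=1e-9)

    def test_gap_codons_skipped_pairwise(self):
        full = nei_gojobori("GCTTTTAAA", "GCCTTTAAA")
        gapped = nei_gojobori("GCTTTT---AAA", "GCCTTTCCCAAA")
        assert gapped.s_sites == pytest.approx(full.s_sites)
        assert gapped.sd == pytest.approx(full.sd)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            nei_gojobori("TAAGCT", "TGAGCT")

    def test_raw_proportions_without_correction(self):
        r = nei_gojobori("GCTTTTAAA", "GCCTTTAAA", correction="none")
        assert r.ks == pytest.approx(0.6)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            nei_gojobori("GCTGCT", "GCT")


class TestDating:
    def test_clock_formula_worked_values(self):
        assert date_pair(0.0) == 0.0
        assert date_pair(0.122) == pytest.approx(10.0)
        assert date_pair(0.0122) == pytest.approx(1.0)

    def test_linearity_over_ks_grid(self):
        grid = np.linspace(0.0, 1.0, 21)
        dates = [date_pair(k) for k in grid]
        assert np.allclose(np.diff(dates), dates[1] - dates[0])
        assert all(x < y for x, y in zip(dates, dates[1:]))

    def test_saturated_ks_gives_undetermined_date(self):
        assert math.isnan(date_pair(math.nan))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            date_pair(-0.1)
        with pytest.raises(ValueError):
            date_pair(0.1, lambda_rate=0.0)


class TestSelectionMode:
    @pytest.mark.parametrize(
        "ka,ks,expected",
        [
            (0.034, 0.1, "purifying"),  # ratio 0.34 as in duplicate-pair averages
            (0.213, 0.1, "positive"),  # ratio 2.13, the positive-selection extreme
            (0.0, 0.0, "undetermined"),
            (0.05, 0.0, "positive"),
            (0.1, 0.1, "neutral"),
        ],
    )
    def test_ratio_thresholds(self, ka, ks, expected):
        assert selection_mode(ka, ks) == expected

    def test_neutral_band(self):
        assert selection_mode(0.105, 0.1, neutral_band=0.1) == "neutral"
        assert selection_mode(0.2, 0.1, neutral_band=0.1) == "positive"

    @given(
        ka=st.floats(0, 5, allow_nan=False),
        ks=st.floats(0, 5, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True)
    def test_total_function(self, ka, ks):
        assert selection_mode(ka, ks) in {"purifying", "neutral", "positive", "undetermined"}


def _loci(rows):
    return pd.DataFrame(rows, columns=["gene", "chromosome", "locus_rank"]).set_index("gene")


class TestClassifyPair:
    def test_same_chromosome_within_window_is_tandem(self):
        loci = _loci([("a", "Chr03", 5), ("b", "Chr03", 12)])
        assert classify_pair("a", "b", loci) == "tandem"

    def test_different_chromosomes_is_segmental(self):
        loci = _loci([("a", "Chr03", 5), ("b", "Chr17", 5)])
        assert classify_pair("a", "b", loci) == "segmental"

    def test_same_chromosome_beyond_window_is_dispersed(self):
        loci = _loci([("a", "Chr03", 10), ("b", "Chr03", 200)])
        assert classify_pair("a", "b", loci) == "dispersed"

    def test_order_invariant(self):
        loci = _loci([("a", "Chr03", 5), ("b", "Chr03", 12)])
        assert classify_pair("a", "b", loci) == classify_pair("b", "a", loci)

    def test_window_boundary_inclusive(self):
        loci = _loci([("a", "Chr01", 1), ("b", "Chr01", 21)])
        assert classify_pair("a", "b", loci) == "tandem"
        loci2 = _loci([("a", "Chr01", 1), ("b", "Chr01", 22)])
        assert classify_pair("a", "b", loci2) == "dispersed"

    def test_scaffold_gene_undetermined(self):
        loci = _loci([("a", "scaffold_123", 1), ("b", "Chr01", 2)])
        assert classify_pair("a", "b", loci) == "undetermined"

    def test_missing_gene_rejected(self):
        loci = _loci([("a", "Chr01", 1)])
        with pytest.raises(KeyError, match="b"):
            classify_pair("a", "b", loci)


class TestDetectPairs:
    @staticmethod
    def _tree(newick):
        from genefam.phylo import read_newick

        return read_newick(newick)

    def test_perfect_cherry_kept(self):
        tree = self._tree("((A:0.01,B:0.01)100:0.2,(C:0.3,D:0.4)95:0.2,E:0.5);")
        prots = {k: "MKLVWACDEF" * 8 for k in "ABE"}
        prots["C"] = "MKLVWACDEF" * 4 + "WWYYFFPPGG" * 4
        prots["D"] = "PPGGWWYYFF" * 8
        from genefam.duplication import detect_pairs

        pairs, rejected = detect_pairs(tree, prots)
        kept = {(p.gene_a, p.gene_b) for p in pairs}
        assert ("A", "B") in kept
        pair = next(p for p in pairs if p.gene_a == "A")
        assert pair.identity == pytest.approx(1.0)
        assert pair.coverage == pytest.approx(1.0)

    def test_low_support_cherry_rejected(self):
        tree = self._tree("((A:0.01,B:0.01)85:0.2,C:0.3,D:0.4);")
        prots = {k: "MKLVWACDEF" * 8 for k in "ABCD"}
        from genefam.duplication import detect_pairs

        pairs, rejected = detect_pairs(tree, prots)
        assert pairs == []
        assert rejected[0].bootstrap == 85

    def test_low_identity_cherry_rejected(self):
        tree = self._tree("((A:0.3,B:0.3)100:0.2,C:0.3,D:0.4);")
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        prots = {
            "A": "".join(rng.choice(aas, 80)),
            "B": "".join(rng.choice(aas, 80)),
            "C": "".join(rng.choice(aas, 80)),
            "D": "".join(rng.choice(aas, 80)),
        }
        from genefam.duplication import detect_pairs

        pairs, rejected = detect_pairs(tree, prots)
        assert pairs == []
        assert rejected and rejected[0].identity < 0.70

    def test_missing_leaf_sequence_named(self):
        tree = self._tree("((A:0.1,B:0.1)100:0.2,C:0.3,D:0.4);")
        from genefam.duplication import detect_pairs

        with pytest.raises(KeyError, match="B"):
            detect_pairs(tree, {"A": "MKLVW", "C": "MKLVW", "D": "MKLVW"})

    def test_genes_appear_in_at_most_one_pair(self, study_sim):
        import numpy as np

        from genefam.duplication import detect_pairs
        from genefam.phylo import bootstrap

        aln = {
            g: study_sim.proteins[g][p : p + study_sim.motif_model.length]
            for g, p in study_sim.truth.motif_positions.items()
        }
        tree, _ = bootstrap(aln, 100, rng=np.random.default_rng(1))
        pairs, _ = detect_pairs(tree, study_sim.proteins)
        seen = [g for p in pairs for g in (p.gene_a, p.gene_b)]
        assert len(seen) == len(set(seen))


class TestParameterRecovery:
    def test_mean_ka_ks_tracks_omega_and_dates_recover_truth(self):
        from genefam.duplication import date_pair, nei_gojobori
        from genefam.simulate import evolve_codon_pair, reverse_translate

        rng = np.random.default_rng(55)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for omega in (0.2, 1.0, 2.0):
            ka_list, ks_list = [], []
            for _ in range(60):
                anc = reverse_translate("".join(rng.choice(aas, 300)), rng)
                a, b = evolve_codon_pair(anc, 10.0, omega, rng=rng)
                r = nei_gojobori(a, b)
                ka_list.append(r.ka)
                ks_list.append(r.ks)
            ratio = np.mean(ka_list) / np.mean(ks_list)
            assert ratio == pytest.approx(omega, rel=0.2)
            t = np.mean([date_pair(k) for k in ks_list])
            assert t == pytest.approx(10.0, rel=0.15)
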
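import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rguc import (
    AnalysisConfig,
    RegionPartition,
    apportion,
    assign_psa,
    capture_R,
    loss_probabilities,
    populations_needed,
    prioritize,
)
from rguc.diversity import RareAllele
from rguc.io import PopulationProfile
from rguc.selection import AlleleLoss, LossProbabilities
from conftest import make_attributes


def rare(marker, p, carriers, overall=0.01):
    return RareAllele(marker, p, frozenset(carriers), overall)


class TestPopulationsNeeded:
    def test_high_target_with_strong_structure(self):
        req = populations_needed(0.999, 0.289)
        assert req.n_required == 6
        assert req.n_real == pytest.approx(5.5648, abs=1e-4)

    def test_exact_closed_form(self):
        req = populations_needed(0.75, 0.5)
        assert req.n_required == 2  # 1 - 0.5^2 = 0.75 exactly
        assert req.n_real == pytest.approx(2.0)

    def test_diagnostic_fst_reconciles_printed_real_value(self):
        # an F_ST of 0.297 puts the real-valued requirement near 5.69
        assert populations_needed(0.999, 0.297).n_real == pytest.approx(5.69, abs=0.005)

    def test_zero_fst_needs_one_population(self):
        assert populations_needed(0.999, 0.0).n_required == 1

    def test_fst_one_unreachable(self):
        with pytest.raises(ValueError):
            populations_needed(0.999, 1.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        p1=st.floats(0.5, 0.998), p2=st.floats(0.5, 0.998),
        f1=st.floats(0.05, 0.95), f2=st.floats(0.05, 0.95),
    )
    def test_monotone_in_target_and_fst(self, p1, p2, f1, f2):
        lo_p, hi_p = sorted((p1, p2))
        lo_f, hi_f = sorted((f1, f2))
        assert populations_needed(lo_p, lo_f).n_required <= populations_needed(hi_p, lo_f).n_required
        assert populations_needed(lo_p, lo_f).n_required <= populations_needed(lo_p, hi_f).n_required

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(p=st.floats(0.5, 0.999), f=st.floats(0.05, 0.95))
    def test_minimality_invariant(self, p, f):
        n = populations_needed(p, f).n_required
        assert 1.0 - f**n >= p
        if n > 1:
            assert 1.0 - f ** (n - 1) < p


class TestLossProbabilities:
    def test_direct_substitution(self):
        loss = loss_probabilities([rare("a", 0.5, ["P1"]), rare("b", 0.1, ["P1", "P2", "P3"])])
        a, b = loss.alleles
        assert (a.lo, a.le) == (pytest.approx(0.25), pytest.approx(0.25))
        assert b.lo == pytest.approx(0.9**6)
        assert b.le == pytest.approx(0.81)

    def test_multi_population_alleles_lose_less(self):
        loss = loss_probabilities([rare(f"m{n}", 0.07, [f"P{i}" for i in range(n)]) for n in (2, 3, 5)])
        for a in loss:
            assert a.lo < a.le

    def test_degenerate_frequency_rejected(self):
        bad = AlleleLoss("x", 0.0, 1, 1.0, 1.0)  # constructed directly
        with pytest.raises(ValueError):
            loss_probabilities([rare("x", 1.0, ["P1"])])


class TestCaptureR:
    def test_all_private_alleles_give_r_one(self):
        loss = loss_probabilities([rare(f"m{i}", p, ["P1"]) for i, p in enumerate((0.02, 0.05, 0.08))])
        assert capture_R(loss).R == pytest.approx(1.0)

    def test_two_carrier_alleles_at_small_p_give_half(self):
        # -log L = -2N log(1-p) ~ 2Np, so slopes scale with N
        ps = np.linspace(0.001, 0.01, 8)
        loss = loss_probabilities([rare(f"m{i}", float(p), ["P1", "P2"]) for i, p in enumerate(ps)])
        assert capture_R(loss).R == pytest.approx(0.5, abs=0.01)

    def test_matches_ols_oracle(self):
        rng = np.random.default_rng(4)
        alleles = [
            rare(f"m{i}", float(rng.uniform(0.02, 0.09)), [f"P{j}" for j in range(int(rng.integers(1, 4)))])
            for i in range(12)
        ]
        loss = loss_probabilities(alleles)
        reg = capture_R(loss)
        p = np.array([a.p for a in loss])
        for y, slope in (
            (np.array([a.neg_log_lo for a in loss]), reg.slope_obs),
            (np.array([a.neg_log_le for a in loss]), reg.slope_exp),
        ):
            X = np.c_[np.ones_like(p), p]
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            assert slope == pytest.approx(beta[1])

    def test_r_invariant_to_log_base(self):
        loss = loss_probabilities(
            [rare("a", 0.03, ["P1"]), rare("b", 0.06, ["P1", "P2"]), rare("c", 0.09, ["P1", "P2", "P3"])]
        )
        reg = capture_R(loss)
        p = np.array([a.p for a in loss])
        base10_obs = np.polyfit(p, [-math.log10(a.lo) for a in loss], 1)[0]
        base10_exp = np.polyfit(p, [-math.log10(a.le) for a in loss], 1)[0]
        assert base10_exp / base10_obs == pytest.approx(reg.R)

    def test_equal_frequencies_rejected(self):
        loss = loss_probabilities([rare("a", 0.05, ["P1"]), rare("b", 0.05, ["P2"])])
        with pytest.raises(ValueError, match="slope undefined"):
            capture_R(loss)

    def test_through_origin_variant(self):
        loss = loss_probabilities(
            [rare("a", 0.03, ["P1"]), rare("b", 0.06, ["P1", "P2"]), rare("c", 0.09, ["P1"])]
        )
        cfg = AnalysisConfig(regression_through_origin=True)
        reg = capture_R(loss, cfg)
        assert reg.intercept_obs == 0.0
        assert 0 < reg.R <= 1


class TestAssignPsa:
    def _freq_table(self, pops, markers, entries):
        df = pd.DataFrame(0.0, index=pops, columns=markers)
        for (pop, marker), f in entries.items():
            df.at[pop, marker] = f
        return df

    def test_private_allele_goes_to_its_region(self):
        part = RegionPartition({"P1": "A", "P2": "A", "P3": "B"})
        freq = self._freq_table(["P1", "P2", "P3"], ["m"], {("P3", "m"): 0.1})
        psa = assign_psa([rare("m", 0.1, ["P3"])], part, freq, {"P1": 10, "P2": 10, "P3": 10})
        assert psa.region_of_allele["m"] == "B"
        assert psa.counts == {"A": 0, "B": 1}

    def test_smaller_region_wins_at_equal_frequency(self):
        pops = ["I1", "I2", "M1", "M2", "M3", "M4"]
        part = RegionPartition({p: ("IP" if p.startswith("I") else "M") for p in pops})
        freq = self._freq_table(pops, ["m"], {("I1", "m"): 0.08, ("M1", "m"): 0.08})
        sizes = {p: 20 for p in pops}
        psa = assign_psa([rare("m", 0.08, ["I1", "M1"])], part, freq, sizes)
        assert psa.region_of_allele["m"] == "IP"  # divided by 2 beats divided by 4

    def test_matches_brute_force_capture_probability(self):
        rng = np.random.default_rng(17)
        pops = [f"P{i}" for i in range(8)]
        part = RegionPartition({p: f"R{i % 3}" for i, p in enumerate(pops)})
        sizes = {p: int(rng.integers(8, 25)) for p in pops}
        markers = [f"m{i}" for i in range(10)]
        freq = pd.DataFrame(
            rng.random((8, 10)) * (rng.random((8, 10)) < 0.3), index=pops, columns=markers
        )
        alleles = []
        for m in markers:
            carriers = [p for p in pops if freq.at[p, m] > 0]
            if carriers:
                alleles.append(rare(m, float(np.mean([freq.at[p, m] for p in carriers])), carriers))
        psa = assign_psa(alleles, part, freq, sizes)
        for ra in alleles:
            best_region, best_p = None, -1.0
            for g in part.regions:
                pg = part.populations_in(g)
                capture = [1 - (1 - freq.at[p, ra.marker_id]) ** (2 * sizes[p]) for p in pg]
                val = sum(capture) / len(pg)
                if val > best_p:
                    best_region, best_p = g, val
            assert psa.region_of_allele[ra.marker_id] == best_region
        assert sum(psa.counts.values()) == len(alleles)

    def test_carrier_fraction_variant(self):
        part = RegionPartition({"P1": "A", "P2": "A", "P3": "B"})
        freq = self._freq_table(["P1", "P2", "P3"], ["m"], {("P1", "m"): 0.01, ("P3", "m"): 0.09})
        cfg = AnalysisConfig(psa_use_carrier_fractions=True)
        psa = assign_psa([rare("m", 0.05, ["P1", "P3"])], part, freq,
                         {"P1": 10, "P2": 10, "P3": 10}, cfg)
        # carrier fractions: A = 1/2, B = 1/1 -> B despite A's head start in pops
        assert psa.region_of_allele["m"] == "B"


class TestApportion:
    def test_six_slots_with_regional_shares(self):
        assert apportion(6, {"IP": 0.45, "M": 0.34, "CI": 0.21}) == {"IP": 3, "M": 2, "CI": 1}

    def test_tie_broken_by_label_order(self):
        assert apportion(5, {"A": 0.5, "B": 0.5}) == {"A": 3, "B": 2}

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            apportion(4, {"A": 0.0, "B": 0.0})

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        n=st.integers(1, 10),
        w=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=4),
    )
    def test_matches_exhaustive_l1_minimizer(self, n, w):
        labels = [f"g{i}" for i in range(len(w))]
        props = {g: wi / sum(w) for g, wi in zip(labels, w)}
        alloc = apportion(n, props)
        assert sum(alloc.values()) == n
        best = min(
            (c for c in itertools.product(range(n + 1), repeat=len(w)) if sum(c) == n),
            key=lambda c: sum(abs(ci - n * props[g]) for ci, g in zip(c, labels)),
        )
        got_err = sum(abs(alloc[g] - n * props[g]) for g in labels)
        opt_err = sum(abs(bi - n * props[g]) for bi, g in zip(best, labels))
        assert got_err == pytest.approx(opt_err)


class TestPrioritize:
    def _profiles(self, spec):
        return [
            PopulationProfile(p, h, d, r, 20) for p, (h, d, r) in spec.items()
        ]

    def test_dominant_population_ranks_first(self):
        part = RegionPartition({"P1": "A", "P2": "A", "P3": "A"})
        profiles = self._profiles({"P1": (0.15, 5.0, 40), "P2": (0.10, 3.0, 20), "P3": (0.08, 2.0, 10)})
        attrs = make_attributes(["P1", "P2", "P3"], P1={"legal_status": "unprotected"})
        sel = prioritize(profiles, attrs, {"A": 1}, part)
        assert sel.selected("A") == ["P1"]

    def test_endemic_haplotype_in_low_ranked_population_is_flagged(self):
        part = RegionPartition({"P1": "A", "P2": "A", "P3": "A"})
        profiles = self._profiles({"P1": (0.15, 5.0, 40), "P2": (0.10, 3.0, 20), "P3": (0.05, 1.0, 2)})
        attrs = make_attributes(["P1", "P2", "P3"])
        from rguc.io import PopulationAttributes
        attrs["P3"] = PopulationAttributes(
            "small", "reduced", "critical", "unprotected",
            haplotypes=frozenset({"VI"}), endemic_haplotypes=frozenset({"VI"}),
        )
        sel = prioritize(profiles, attrs, {"A": 2}, part)
        assert sel.selected("A") == ["P1", "P2"]
        assert sel.also_recommended("A") == ["P3"]
        flagged = [rp for rp in sel.ranked_populations["A"] if rp.population == "P3"][0]
        assert flagged.also_recommended_for == ("VI",)

    def test_selection_sizes_match_allocation_across_regions(self):
        part = RegionPartition({f"P{i}": ("A" if i < 3 else "B") for i in range(6)})
        rng = np.random.default_rng(0)
        profiles = self._profiles(
            {f"P{i}": (float(rng.uniform(0.05, 0.2)), float(rng.uniform(1, 6)), int(rng.integers(0, 50)))
             for i in range(6)}
        )
        attrs = make_attributes([f"P{i}" for i in range(6)])
        alloc = {"A": 2, "B": 1}
        sel = prioritize(profiles, attrs, alloc, part)
        for region, k in alloc.items():
            assert len(sel.selected(region)) == k

    def test_missing_attributes_rank_on_genetics_with_warning(self, caplog):
        part = RegionPartition({"P1": "A", "P2": "A"})
        profiles = self._profiles({"P1": (0.1, 2.0, 5), "P2": (0.12, 3.0, 9)})
        with caplog.at_level("WARNING", logger="rguc"):
            sel = prioritize(profiles, {}, {"A": 1}, part)
        assert sel.selected("A") == ["P2"]
        assert any("lacks attributes" in r.message for r in caplog.records)
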
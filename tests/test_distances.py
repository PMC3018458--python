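"""Genetic distance statistics against independent oracles and closed forms."""

import itertools
import math

import numpy as np
import pytest

from crenadelim.distances import (
    corrected_distance,
    distance_matrix,
    divergence_to_rate,
    fixed_differences,
    group_divergence_summary,
    nei_unbiased_distance,
    p_distance,
    rogers_distance,
)
from crenadelim.io_model import AlleleFreqProfile, ValidationError
from crenadelim.report import load_published_matrix
from crenadelim.synthetic_data import ScenarioSpec, simulate_sequences

from conftest import random_profile


def profile(group, locus_freqs, two_n=20):
    return AlleleFreqProfile(
        group,
        {l: dict(f) for l, f in locus_freqs.items()},
        {l: two_n for l in locus_freqs},
    )


# ---------------------------------------------------------------------------
# Rogers


class TestRogers:
    def test_fixed_difference_is_maximal(self):
        a = profile("A", {"L1": {"a": 1.0}})
        b = profile("B", {"L1": {"b": 1.0}})
        assert rogers_distance(a, b) == pytest.approx(1.0)

    def test_identity_is_zero(self):
        a = profile("A", {"L1": {"a": 0.3, "b": 0.7}, "L2": {"a": 1.0}})
        b = profile("B", {"L1": {"a": 0.3, "b": 0.7}, "L2": {"a": 1.0}})
        assert rogers_distance(a, b) == pytest.approx(0.0)

    def test_half_fixed_case(self):
        # sqrt(0.5*(0.25+0.25)) = 0.5
        a = profile("A", {"L1": {"a": 1.0}})
        b = profile("B", {"L1": {"a": 0.5, "b": 0.5}})
        assert rogers_distance(a, b) == pytest.approx(0.5)

    def test_symmetry_range_triangle_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            a = random_profile(rng, "A")
            b = random_profile(rng, "B")
            c = random_profile(rng, "C")
            dab, dba = rogers_distance(a, b), rogers_distance(b, a)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert 0.0 <= dab <= 1.0 + 1e-12
            dac, dcb = rogers_distance(a, c), rogers_distance(c, b)
            assert dab <= dac + dcb + 1e-9

    def test_no_joint_loci_errors(self):
        a = AlleleFreqProfile("A", {"L1": {"a": 1.0}}, {"L1": 4, "L2": 0})
        b = AlleleFreqProfile("B", {"L2": {"a": 1.0}}, {"L1": 0, "L2": 4})
        with pytest.raises(ValidationError, match="no comparable loci"):
            rogers_distance(a, b)


# ---------------------------------------------------------------------------
# Nei's unbiased D


def nei_1978_oracle(pa, pb, na, nb):
    """Straight-line Nei (1978) for one locus with gene-copy counts na/nb."""
    jab = sum(pa.get(al, 0) * pb.get(al, 0) for al in set(pa) | set(pb))
    ja = (na * sum(p * p for p in pa.values()) - 1) / (na - 1)
    jb = (nb * sum(p * p for p in pb.values()) - 1) / (nb - 1)
    return -math.log(jab / math.sqrt(ja * jb))


class TestNeiUnbiased:
    def test_identity_limit_large_n(self):
        f = {"L1": {"a": 0.5, "b": 0.5}, "L2": {"a": 1.0}}
        a = profile("A", f, two_n=10**7)
        b = profile("B", f, two_n=10**7)
        assert nei_unbiased_distance(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_alleles_give_infinity(self):
        a = profile("A", {"L1": {"a": 1.0}})
        b = profile("B", {"L1": {"b": 1.0}})
        with pytest.warns(UserWarning, match="no alleles"):
            assert math.isinf(nei_unbiased_distance(a, b))

    def test_against_straight_line_oracle(self):
        a = profile("A", {"L1": {"a": 0.9, "b": 0.1}})
        b = profile("B", {"L1": {"a": 0.1, "b": 0.9}})
        expected = nei_1978_oracle({"a": 0.9, "b": 0.1}, {"a": 0.1, "b": 0.9}, 20, 20)
        assert expected == pytest.approx(1.5047269583450698)  # frozen oracle value
        assert nei_unbiased_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_small_negative_clamped_to_zero(self):
        # identical moderately diverse profiles at small n: correction overshoots
        f = {"L1": {"a": 0.5, "b": 0.5}}
        a = profile("A", f, two_n=4)
        b = profile("B", f, two_n=4)
        with pytest.warns(UserWarning, match="clamped"):
            assert nei_unbiased_distance(a, b) == 0.0


# ---------------------------------------------------------------------------
# fixed differences


def brute_force_strict_fd(a, b):
    """Oracle: loci typed in both whose observed allele sets are disjoint."""
    count = 0
    for locus in a.typed_loci:
        if b.gene_copies.get(locus, 0) == 0:
            continue
        sa = {al for al, p in a.freqs[locus].items() if p > 0}
        sb = {al for al, p in b.freqs[locus].items() if p > 0}
        if not (sa & sb):
            count += 1
    return count


class TestFixedDifferences:
    def test_strict_percent_display(self):
        # 4 FD loci among 40 jointly scorable -> "4 (10%)"
        loci = {f"L{i}": {"a": 1.0} for i in range(1, 37)}
        loci_b = {f"L{i}": {"a": 1.0} for i in range(1, 37)}
        for i in range(37, 41):
            loci[f"L{i}"] = {"x": 1.0}
            loci_b[f"L{i}"] = {"y": 1.0}
        res = fixed_differences(profile("A", loci), profile("B", loci_b), tolerance=0.0)
        assert (res.count, res.denominator) == (4, 40)
        assert res.percent_display == 10

    def test_low_shared_mass_counts_within_tolerance(self):
        a = profile("A", {"L1": {"x": 0.94, "s": 0.06}})
        b = profile("B", {"L1": {"y": 0.94, "s": 0.06}})
        res = fixed_differences(a, b, tolerance=0.10)
        assert res.count == 1
        assert res.shared_mass["L1"] == pytest.approx(0.06)

    def test_higher_shared_mass_does_not_count(self):
        a = profile("A", {"L1": {"x": 0.8, "s": 0.2}})
        b = profile("B", {"L1": {"y": 0.8, "s": 0.2}})
        assert fixed_differences(a, b, tolerance=0.10).count == 0

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = random_profile(rng, "A", n_loci=8)
            b = random_profile(rng, "B", n_loci=8)
            assert fixed_differences(a, b, tolerance=0.0).count == brute_force_strict_fd(a, b)

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = random_profile(rng, "A", n_loci=8)
            b = random_profile(rng, "B", n_loci=8)
            counts = [fixed_differences(a, b, t).count for t in (0.0, 0.05, 0.1, 0.2, 0.4)]
            assert counts == sorted(counts)

    def test_tolerance_domain_checked(self):
        a = profile("A", {"L1": {"a": 1.0}})
        with pytest.raises(ValidationError, match="tolerance"):
            fixed_differences(a, a, tolerance=0.6)


# ---------------------------------------------------------------------------
# sequence distances


class TestPDistance:
    def test_identical_and_single_mismatch(self):
        assert p_distance("ACGT", "ACGT") == 0.0
        assert p_distance("ACGT", "ACGA") == 0.25

    def test_pairwise_deletion(self):
        assert p_distance("AC-T", "ACGT") == 0.0
        assert p_distance("ACNT", "ACGA") == pytest.approx(1 / 3)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        alphabet = np.array(list("ACGT-N"))
        for _ in range(100):
            x = "".join(rng.choice(alphabet, size=60, p=[0.22] * 4 + [0.06, 0.06]))
            y = "".join(rng.choice(alphabet, size=60, p=[0.22] * 4 + [0.06, 0.06]))
            good = [(a, b) for a, b in zip(x, y) if a in "ACGT" and b in "ACGT"]
            if not good:
                continue
            naive = sum(a != b for a, b in good) / len(good)
            assert p_distance(x, y) == pytest.approx(naive, abs=1e-12)

    def test_all_missing_errors(self):
        with pytest.raises(ValidationError, match="no comparable sites"):
            p_distance("NN--", "ACGT")


# reference distances for a fixed 40-bp 4-sequence alignment, computed with
# an independent implementation (R ape::dist.dna for raw/JC69/K80; the TN93
# closed form evaluated step by step in R)
_S = {
    "s1": "ACGTACGTACGTTTGCAGCATCGATCGAAATTCCGGAACT",
    "s4": "ATGAACCAACGATTCCAGGATGGATAGTAATTACGCAATT",
}
_REFERENCE = {
    "p": 0.325,
    "jc69": 0.4259880282045,
    "k2p": 0.434628738677,
    "tn93": 0.447407640580,
}


class TestCorrectedDistance:
    def test_zero_at_identity_for_all_models(self):
        for model in ("jc69", "k2p", "tn93", "gtr_g"):
            assert corrected_distance("ACGTAC", "ACGTAC", model) == pytest.approx(0.0, abs=1e-6)

    def test_jc69_closed_form_at_quarter(self):
        # 4 sites, 1 mismatch: d = -3/4 ln(1 - 4*0.25/3)
        expected = -0.75 * math.log(1.0 - 4.0 * 0.25 / 3.0)
        assert expected == pytest.approx(0.30409883108112323, abs=1e-12)
        assert corrected_distance("ACGT", "ACGA", "jc69") == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("model", ["p", "jc69", "k2p", "tn93"])
    def test_against_independent_reference(self, model):
        got = (
            p_distance(_S["s1"], _S["s4"])
            if model == "p"
            else corrected_distance(_S["s1"], _S["s4"], model)
        )
        assert got == pytest.approx(_REFERENCE[model], abs=1e-9)

    def test_saturation_returns_infinity(self):
        with pytest.warns(UserWarning, match="JC69"):
            assert math.isinf(corrected_distance("AAAA", "CCCC", "jc69"))

    def test_jc69_recovers_simulated_divergence(self):
        spec = ScenarioSpec(
            group_names=["X", "Y"],
            group_sizes={"X": 1, "Y": 1},
            n_loci=1,
            seed=1,
            tree_newick="(X_01:0.25,Y_01:0.25);",
            seq_length=100_000,
        )
        aln, _ = simulate_sequences(spec)
        est = corrected_distance(aln.seqs[0], aln.seqs[1], "jc69")
        assert est == pytest.approx(0.5, abs=0.02)

    def test_jc69_mean_estimate_unbiased(self):
        # 50 replicate 10-kb pairs at true d = 0.3
        ests = []
        for seed in range(50):
            spec = ScenarioSpec(
                group_names=["X", "Y"],
                group_sizes={"X": 1, "Y": 1},
                n_loci=1,
                seed=seed,
                tree_newick="(X_01:0.15,Y_01:0.15);",
                seq_length=10_000,
            )
            aln, _ = simulate_sequences(spec)
            ests.append(corrected_distance(aln.seqs[0], aln.seqs[1], "jc69"))
        assert np.mean(ests) == pytest.approx(0.3, abs=0.01)

    def test_gtr_g_close_to_jc69_under_uniform_model(self):
        est_gtr = corrected_distance(_S["s1"], _S["s4"], "gtr_g", gamma_shape=1e6)
        assert est_gtr == pytest.approx(_REFERENCE["jc69"], abs=0.02)


# ---------------------------------------------------------------------------
# matrix summaries and rate conversion


class TestGroupDivergenceSummary:
    def test_published_corrected_extremes(self):
        m = load_published_matrix("mt_corrected")
        summary = group_divergence_summary(m, {l: l for l in m.labels})
        assert summary.min_between == pytest.approx(0.221)
        assert summary.max_between == pytest.approx(1.059)

    def test_singleton_groups_have_no_within(self):
        m = load_published_matrix("mt_corrected")
        summary = group_divergence_summary(m, {l: l for l in m.labels})
        assert all(v is None for v in summary.within.values())
        assert summary.max_within is None

    def test_duplicated_group_between_zero(self):
        rng = np.random.default_rng(5)
        a = random_profile(rng, "A")
        profiles = {"A1": a, "A2": AlleleFreqProfile("A2", a.freqs, a.gene_copies)}
        m = distance_matrix(profiles, "rogers")
        summary = group_divergence_summary(m, {"A1": "g1", "A2": "g2"})
        assert summary.min_between == pytest.approx(0.0)


class TestDivergenceToRate:
    @pytest.mark.parametrize(
        "d,age,expected", [(0.4, 20.0, 1.0), (0.0, 5.0, 0.0), (0.41, 10.25, 2.0)]
    )
    def test_conversion(self, d, age, expected):
        assert divergence_to_rate(d, age) == pytest.approx(expected)

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValidationError):
            divergence_to_rate(0.1, 0.0)
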
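"""Strand bias, densities, stop codons, age strata, presence matrix."""

import math

import numpy as np
import pytest
from scipy import stats

from spacerhost.annotation import Feature
from spacerhost.biasstats import (AgeStratum, binomial_tail, identity_by_age,
                                  presence_marginals, presence_matrix,
                                  stop_codon_profile, strand_bias_test,
                                  target_density)
from spacerhost.glocal import SpacerMatch


def mk_match(sp, genome, strand="+", start=0, end=36, ident=1.0, score=30,
             ev=1e-6, mode="glocal"):
    idx = int(sp[2:]) if sp[2:].isdigit() else None
    return SpacerMatch(sp, genome, strand, start, end, score, ev, ident,
                       0, 0, "", "", mode=mode, spacer_index=idx)


class TestStrandBias:
    def test_fifteen_of_twentythree(self):
        r = strand_bias_test(23, 15)
        assert round(r.one_sided_p, 3) == 0.105
        assert r.complementary_percent == 35

    def test_eighteen_of_twentyseven(self):
        # the split after adding the four local-only matches
        assert round(strand_bias_test(27, 18).one_sided_p, 3) == 0.061

    def test_tiny_case_exact(self):
        assert strand_bias_test(2, 1).one_sided_p == pytest.approx(0.75)

    def test_agrees_with_enumeration_for_small_n(self):
        """Exhaustive enumeration of all 2^n strand outcomes."""
        for n in range(1, 13):
            for k in range(n + 1):
                count = sum(1 for outcome in range(2 ** n)
                            if bin(outcome).count("1") >= k)
                assert binomial_tail(n, k) == pytest.approx(count / 2 ** n)

    def test_agrees_with_scipy_binomtest(self):
        for n, k in [(23, 15), (27, 18), (50, 31), (10, 2)]:
            expected = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
            assert strand_bias_test(n, k).one_sided_p == pytest.approx(expected)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            strand_bias_test(10, 11)

    def test_type_one_error_calibrated_quick(self):
        """Rejection rate under the null tracks the achievable level.

        n = 37 makes the discrete achievable one-sided level (0.0494)
        nearly nominal; a 2000-replicate check stays within a wide band
        (the full 10k-replicate calibration runs with the acceptance
        properties).
        """
        n, alpha = 37, 0.05
        crit = next(k for k in range(n + 1) if binomial_tail(n, k) <= alpha)
        rng = np.random.default_rng(12)
        draws = rng.binomial(n, 0.5, size=2000)
        rate = np.mean(draws >= crit)
        assert abs(rate - 0.0494) < 0.02


class TestTargetDensity:
    def _ann(self):
        return [Feature("rep", 0, 900, "+", "gene"),
                Feature("intergenic", 900, 1100, "+", "intergenic"),
                Feature("cap", 1100, 2270, "+", "gene"),
                Feature("intergenic2", 2270, 2500, "+", "intergenic")]

    def test_planted_counts_recovered(self):
        matches = ([mk_match(f"sp{i}", "g", start=i * 80, end=i * 80 + 36)
                    for i in range(1, 11)]                  # 10 in rep
                   + [mk_match(f"sp{i}", "g", start=1100 + (i - 11) * 90,
                               end=1136 + (i - 11) * 90)
                      for i in range(11, 20)])              # 9 in cap
        dens, split = target_density(matches, self._ann())
        by = {d.region: d for d in dens}
        assert by["rep"].n_targets == 10
        assert by["cap"].n_targets == 9
        assert by["rep"].per_kb > by["cap"].per_kb  # cap is 30% larger

    def test_intergenic_only(self):
        matches = [mk_match("sp1", "g", start=950, end=986)]
        dens, _ = target_density(matches, self._ann())
        regions = {d.region for d in dens}
        assert "rep" not in regions and "cap" not in regions

    def test_coding_vs_template_split(self):
        matches = [mk_match("sp1", "g", "+", 10, 46),
                   mk_match("sp2", "g", "-", 100, 136),
                   mk_match("sp3", "g", "-", 200, 236)]
        _, split = target_density(matches, self._ann())
        assert split == {"coding": 1, "template": 2}

    def test_unannotated_genome_counts_unknown(self):
        dens, _ = target_density([mk_match("sp1", "g", start=10, end=46)], {})
        assert dens[0].region == "unknown"


class TestStopCodons:
    def test_all_ochre(self):
        p = stop_codon_profile(["ATGAAATAA"] * 10, "x")
        assert p.percentages["ochre"] == 100.0
        assert p.percentages["amber"] == 0.0

    def test_amber_fraction_of_188(self):
        cds = (["ATGTAG"] * 8 + ["ATGTGA"] * 90 + ["ATGTAA"] * 90)
        p = stop_codon_profile(cds, "smacovirus-like")
        assert p.n_cds == 188
        assert p.percentages["amber"] == pytest.approx(100 * 8 / 188)
        assert abs(p.percentages["amber"] - 4.2553) < 0.001

    def test_non_stop_ending_excluded(self):
        p = stop_codon_profile(["ATGTAA", "ATGTGC"], "x")
        assert p.n_cds == 1 and p.n_excluded == 1

    def test_percentages_sum_and_permutation_invariance(self):
        rng = np.random.default_rng(13)
        cds = (["AAATAG"] * 5 + ["AAATGA"] * 25 + ["AAATAA"] * 70)
        p1 = stop_codon_profile(cds, "x")
        shuffled = list(cds)
        rng.shuffle(shuffled)
        p2 = stop_codon_profile(shuffled, "x")
        assert p1.percentages == p2.percentages
        assert sum(p1.percentages.values()) == pytest.approx(100.0)

    def test_rna_alphabet_accepted(self):
        p = stop_codon_profile(["AUGUAG"], "x")
        assert p.counts["amber"] == 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            stop_codon_profile([], "x")


class TestAgeStrata:
    def test_decay_flag_on_decreasing_identity(self):
        matches = [mk_match(f"sp{i}", "g", ident=1.0 - 0.004 * i)
                   for i in range(1, 73)]
        summaries, decay = identity_by_age(matches)
        assert decay is True
        by = {s.stratum: s for s in summaries}
        assert by["modern"].mean_identity > by["ancient"].mean_identity

    def test_boundaries_are_inclusive(self):
        matches = [mk_match("sp9", "g"), mk_match("sp12", "g"),
                   mk_match("sp10", "g")]
        summaries, _ = identity_by_age(matches)
        by = {s.stratum: s for s in summaries}
        assert by["modern"].n_spacers == 1   # sp9
        assert by["middle"].n_spacers == 1   # sp12; sp10 falls between strata

    def test_single_match_stratum(self):
        summaries, _ = identity_by_age([mk_match("sp3", "g", ident=1.0)])
        assert summaries[0].min_identity == summaries[0].mean_identity == 1.0

    def test_overlapping_strata_rejected(self):
        with pytest.raises(ValueError):
            identity_by_age([mk_match("sp1", "g")],
                            [AgeStratum("a", 1, 10), AgeStratum("b", 5, 20)])


class TestPresenceMatrix:
    def test_column_marginal_counts_targets_per_genome(self):
        matches = [mk_match(f"sp{i}", "gA") for i in range(1, 15)] + \
                  [mk_match(f"sp{i}", "gB") for i in range(1, 10)]
        mat = presence_matrix(matches)
        per_spacer, per_genome = presence_marginals(mat)
        assert per_genome["gA"] == 14
        assert per_genome["gB"] == 9

    def test_matchless_spacer_gets_empty_row(self):
        mat = presence_matrix([mk_match("sp1", "gA")], spacers=["sp1", "sp2"])
        assert mat.loc["sp2"].isna().all()

    def test_duplicate_hits_keep_best_identity(self):
        matches = [mk_match("sp1", "gA", ident=0.8),
                   mk_match("sp1", "gA", ident=0.95, start=500, end=536)]
        mat = presence_matrix(matches)
        assert mat.loc["sp1", "gA"] == 0.95
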
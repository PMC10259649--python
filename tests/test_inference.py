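import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from moldscore import (
    anova_tukey,
    compact_letter_display,
    holm_bonferroni,
    species_comparison_battery,
    student_t,
    wilcoxon_rank_sum,
)
from moldscore.panel import ConcentrationMatrix


def ranksum_enumeration_oracle(x, y):
    """Independent brute-force two-sided rank-sum p: enumerate every
    assignment of the observed (mid-ranked) values with itertools."""
    combined = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(combined)).astype(int)  # doubled: integer
    n1, n = len(x), len(combined)
    w2_obs = int(ranks2[:n1].sum())
    mean2 = n1 * (n + 1)  # doubled-scale null mean
    dev = abs(w2_obs - mean2)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(int(ranks2[list(idx)].sum()) - mean2) >= dev:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_fully_separated_triples(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.statistic == 6.0
        assert res.p_raw == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([2, 2, 5], [2, 2, 5]).p_raw == 1.0

    def test_exact_matches_oracle_on_ties(self, rng):
        for _ in range(40):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            x = rng.integers(0, 4, size=n1).astype(float)  # heavy ties
            y = rng.integers(0, 4, size=n2).astype(float)
            got = wilcoxon_rank_sum(x, y, mode="exact").p_raw
            assert got == pytest.approx(ranksum_enumeration_oracle(x, y), abs=1e-12)

    def test_normal_close_to_exact(self, rng):
        """The continuity-corrected normal approximation tracks the exact
        p within 0.05 at n=5+5 on continuous (tie-free) samples."""
        for _ in range(200):
            x = rng.uniform(0, 1, size=5)
            y = rng.uniform(0, 1, size=5)
            p_exact = wilcoxon_rank_sum(x, y, mode="exact").p_raw
            p_norm = wilcoxon_rank_sum(x, y, mode="normal").p_raw
            assert abs(p_exact - p_norm) < 0.05

    def test_auto_mode_switches(self):
        small = wilcoxon_rank_sum([1, 2], [3, 4], mode="auto")
        assert small.method == "wilcoxon_exact"
        big = wilcoxon_rank_sum(list(range(10)), list(range(10, 20)), mode="auto")
        assert big.method == "wilcoxon_normal"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestHolm:
    def test_worked_two_value_example(self):
        assert holm_bonferroni([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.3]) == pytest.approx([0.3])

    def test_caps_at_one(self):
        assert holm_bonferroni([0.5, 0.5, 0.5]) == pytest.approx([1.0, 1.0, 1.0])

    def test_never_below_raw_and_monotone(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 15)))
            adj = np.asarray(holm_bonferroni(p))
            assert (adj >= p - 1e-15).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])


class TestStudentT:
    def test_equal_samples(self):
        res = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_separation_limit(self):
        res = student_t([1, 2, 3, 4], [101, 102, 103, 104])
        assert res.p_raw < 1e-6

    def test_hand_computed_pooled(self):
        # pooled sd = 1, se = sqrt(2/3), df = 4
        res = student_t([1, 2, 3], [2, 3, 4], variant="pooled")
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.p_raw == pytest.approx(0.2878, abs=1e-3)

    def test_zero_variance_conventions(self):
        same = student_t([5.0, 5.0], [5.0, 5.0])
        assert same.p_raw == 1.0 and same.degenerate
        apart = student_t([5.0, 5.0], [6.0, 6.0])
        assert apart.p_raw == 0.0 and apart.degenerate

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            student_t([1.0], [2.0, 3.0])


class TestTukey:
    def test_identical_groups_share_letter(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = anova_tukey(g)
        assert (res.pairwise["p_adjusted"] == 1.0).all()
        assert set(res.letters.values()) == {"a"}

    def test_two_group_limit_equals_pooled_t(self, rng):
        """With k=2 the studentized range collapses to q = |t|*sqrt(2)."""
        for _ in range(10):
            x = rng.normal(0, 1, size=int(rng.integers(3, 12)))
            y = rng.normal(0.5, 1, size=int(rng.integers(3, 12)))
            tk = anova_tukey({"x": x, "y": y})
            t = student_t(x, y, variant="pooled")
            q = tk.pairwise["q"].iloc[0]
            assert q == pytest.approx(abs(t.statistic) * np.sqrt(2), rel=1e-9)
            assert tk.pairwise["p_adjusted"].iloc[0] == pytest.approx(
                t.p_raw, abs=1e-6
            )

    def test_middle_group_separated_letter_pattern(self):
        """Means 0 / +2 / 0 at sd 0.5, n=10: letters a, b, a in >= 19/20 seeds."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            groups = {
                "g1": r.normal(0.0, 0.5, 10),
                "g2": r.normal(2.0, 0.5, 10),
                "g3": r.normal(0.0, 0.5, 10),
            }
            res = anova_tukey(groups)
            if (res.letters["g1"], res.letters["g2"], res.letters["g3"]) == (
                "a",
                "b",
                "a",
            ):
                hits += 1
        assert hits >= 19

    def test_degenerate_zero_mse(self):
        res = anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.degenerate
        assert res.pairwise["significant"].all()

    def test_small_group_rejected_and_flagged(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})
        res = anova_tukey({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0, 4.0]})
        assert res.small_groups == ("a",)

    def test_letters_biconditional_audit(self, rng):
        """Sharing a letter <=> the pair is non-significant, on random
        significance graphs."""
        for _ in range(50):
            k = int(rng.integers(2, 8))
            labels = [f"g{i}" for i in range(k)]
            pairs = list(itertools.combinations(labels, 2))
            sig = [p for p in pairs if rng.random() < 0.4]
            letters = compact_letter_display(labels, sig)
            sig_set = {frozenset(p) for p in sig}
            for a, b in pairs:
                share = bool(set(letters[a]) & set(letters[b]))
                assert share != (frozenset((a, b)) in sig_set)


class TestBattery:
    @staticmethod
    def _matrices(panel, rng, n=8, tweak=None):
        species = list(panel.species_names)

        def build(year):
            rows = {}
            for i in range(n):
                vals = 10 ** rng.uniform(0, 3, size=36)
                rows[(f"h{i}", year)] = dict(zip(species, vals))
            return rows

        rows_a, rows_b = build(2018), build(2019)
        if tweak:
            tweak(rows_a, rows_b)
        m_a = ConcentrationMatrix.from_rows(rows_a, species)
        m_b = ConcentrationMatrix.from_rows(rows_b, species)
        return m_a, m_b

    def test_constant_species_marked_nm(self, panel, rng):
        def pin(rows_a, rows_b):
            for rows in (rows_a, rows_b):
                for key in rows:
                    rows[key]["Penicillium corylophilum"] = 1.0

        m_a, m_b = self._matrices(panel, rng, tweak=pin)
        report = species_comparison_battery(m_a, m_b, panel)
        row = report.species.set_index("species").loc["Penicillium corylophilum"]
        assert row["method"] == "NM"
        assert np.isnan(row["p_raw"]) and np.isnan(row["p_adjusted"])
        assert report.holm_family_size == 35

    def test_group_tests_present_and_unadjusted(self, panel, rng):
        m_a, m_b = self._matrices(panel, rng)
        report = species_comparison_battery(m_a, m_b, panel)
        assert set(report.group_tests) == {"sum_logs_g1", "sum_logs_g2", "ermi"}
        for res in report.group_tests.values():
            assert res.method == "t_pooled"
            assert res.p_adjusted is None

    def test_home_order_invariance(self, panel, rng):
        m_a, m_b = self._matrices(panel, rng)
        shuffled = ConcentrationMatrix(
            m_a.values.iloc[::-1], m_a.detected.iloc[::-1]
        )
        r1 = species_comparison_battery(m_a, m_b, panel)
        r2 = species_comparison_battery(shuffled, m_b, panel)
        pd.testing.assert_frame_equal(r1.species, r2.species)

    def test_too_few_homes_rejected(self, panel, rng):
        m_a, m_b = self._matrices(panel, rng, n=1)
        with pytest.raises(ValueError, match="2 homes"):
            species_comparison_battery(m_a, m_b, panel)

    def test_per_group_family_option(self, panel, rng):
        m_a, m_b = self._matrices(panel, rng)
        r_all = species_comparison_battery(m_a, m_b, panel, holm_family="all")
        r_grp = species_comparison_battery(m_a, m_b, panel, holm_family="per_group")
        # per-group families are smaller, so adjustment is never harsher
        merged = r_all.species.merge(
            r_grp.species, on="species", suffixes=("_all", "_grp")
        )
        ok = merged["p_adjusted_all"] >= merged["p_adjusted_grp"] - 1e-12
        assert ok[merged["p_adjusted_all"].notna()].all()

    def test_paired_mode_runs(self, panel, rng):
        m_a, m_b = self._matrices(panel, rng)
        report = species_comparison_battery(m_a, m_b, panel, paired=True)
        assert (report.species["method"] != "NM").sum() > 0
        assert report.species["method"].isin(["wilcoxon_signed_rank", "NM"]).all()
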
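"""Haplotype calling, group statistics, Duncan letters, combinations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haplopheno.datatypes import HaploPhenoError
from haplopheno.haplotypes import (
    analyze_groups,
    call_haplotypes,
    combine_haplotypes,
    duncan_letters,
    filter_rare_haplotypes,
    superior_haplotype,
    two_group_test,
    variance_explained,
)

from conftest import make_matrix


# ----------------------------------------------------------------------
# Independent Duncan oracle: explicit recursive step-down over spans
# ----------------------------------------------------------------------

def duncan_significant_pairs_oracle(groups, alpha=0.05):
    """Recursive multiple-range test: returns the set of significantly
    different (label, label) pairs, enumerating every span decision."""
    labels = list(groups)
    vals = {l: np.asarray(groups[l], float) for l in labels}
    allv = np.concatenate(list(vals.values()))
    k = len(labels)
    n_tot = len(allv)
    ss_w = sum(((v - v.mean()) ** 2).sum() for v in vals.values())
    df_w = n_tot - k
    mse = ss_w / df_w
    n_h = k / sum(1.0 / len(v) for v in vals.values())
    order = sorted(labels, key=lambda l: -vals[l].mean())

    sig = set()

    def crit(p):
        a_p = 1 - (1 - alpha) ** (p - 1)
        return stats.studentized_range.ppf(1 - a_p, p, df_w) * np.sqrt(mse / n_h)

    def test_span(i, j):
        p = j - i + 1
        if p < 2:
            return
        rng_val = vals[order[i]].mean() - vals[order[j]].mean()
        if rng_val > crit(p):
            sig.add(frozenset((order[i], order[j])))
            test_span(i + 1, j)
            test_span(i, j - 1)

    test_span(0, k - 1)
    return sig


def letters_to_pairs(letters):
    """Significant pairs implied by a compact letter display."""
    sig = set()
    for a, b in itertools.combinations(letters, 2):
        if not set(letters[a]) & set(letters[b]):
            sig.add(frozenset((a, b)))
    return sig


class TestCallHaplotypes:
    def test_frequency_labels_and_determinism(self):
        # one site, 90/10 split: H1 carries the common allele
        dosage = np.array([[0.0]] * 9 + [[2.0]])
        m = make_matrix(dosage)
        a = call_haplotypes(m, "g", m.variant_ids)
        assert a.counts == {"H1": 9, "H2": 1}
        assert a.alleles["H1"] == ("A",)
        assert a.alleles["H2"] == ("G",)

    def test_identical_rows_share_label(self):
        dosage = np.array([[0, 2, 0], [0, 2, 0], [2, 0, 2]], dtype=float)
        m = make_matrix(dosage)
        a = call_haplotypes(m, "g", m.variant_ids)
        assert a.labels["a0"] == a.labels["a1"] != a.labels["a2"]

    def test_matches_bruteforce_string_equality(self):
        rng = np.random.default_rng(0)
        dosage = 2.0 * rng.integers(0, 2, (6, 3))
        m = make_matrix(dosage)
        a = call_haplotypes(m, "g", m.variant_ids)
        for i in range(6):
            for j in range(6):
                same = np.array_equal(dosage[i], dosage[j])
                assert (a.labels[f"a{i}"] == a.labels[f"a{j}"]) == same

    def test_missing_or_het_is_missing(self):
        dosage = np.array([[0, 2], [0, np.nan], [1, 2], [0, 2]], dtype=float)
        m = make_matrix(dosage)
        a = call_haplotypes(m, "g", m.variant_ids)
        assert a.labels["a1"] is None
        assert a.labels["a2"] is None
        assert a.labels["a0"] == a.labels["a3"] == "H1"

    def test_empty_variant_list_errors(self):
        m = make_matrix(np.zeros((3, 1)))
        with pytest.raises(HaploPhenoError):
            call_haplotypes(m, "g", [])


class TestRareFilter:
    def _assignment(self, counts):
        rows = []
        for k, c in enumerate(counts):
            hap = [2.0 * int(b) for b in np.binary_repr(k, 3)[-3:]]
            rows.extend([hap] * c)
        m = make_matrix(np.array(rows, dtype=float))
        return call_haplotypes(m, "g", m.variant_ids)

    def test_count_threshold_is_more_than_three(self):
        a = self._assignment([10, 4, 3])
        retained = filter_rare_haplotypes(a)
        counts = a.counts
        assert sorted(counts[l] for l in retained) == [4, 10]

    def test_large_panel_small_group_retained(self):
        a = self._assignment([171, 9])
        assert len(filter_rare_haplotypes(a)) == 2

    def test_all_rare_errors(self):
        a = self._assignment([2, 2])
        with pytest.raises(HaploPhenoError, match="no analyzable"):
            filter_rare_haplotypes(a)

    def test_percent_mode(self):
        a = self._assignment([96, 3, 1])
        # "fewer than 1%" excluded: 1/100 is exactly 1% and survives,
        # 3/100 = 3% passes too although it fails the count rule
        assert len(filter_rare_haplotypes(a, min_percent=1.0)) == 3
        assert len(filter_rare_haplotypes(a, min_percent=2.0)) == 2
        assert len(filter_rare_haplotypes(a)) == 1


class TestTwoGroupTest:
    def test_closed_form_oracle(self):
        g1 = np.array([5.1, 4.8, 5.6, 5.0, 4.9])
        g2 = np.array([6.0, 6.3, 5.8, 6.1, 6.4])
        p = two_group_test(g1, g2)
        n1, n2 = len(g1), len(g2)
        sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
        t = (g1.mean() - g2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_oracle = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_symmetry_and_identity(self):
        g1 = np.array([1.0, 2.0, 3.0])
        g2 = np.array([2.5, 3.5, 1.5])
        assert two_group_test(g1, g2) == two_group_test(g2, g1)
        assert two_group_test(g1, g1.copy()) == 1.0

    def test_zero_variance_cases(self):
        same = np.array([2.0, 2.0, 2.0])
        assert two_group_test(same, same.copy()) == 1.0
        assert two_group_test(same, np.array([3.0, 3.0, 3.0])) == 0.0


class TestDuncan:
    def test_identical_means_single_letter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 8)
        groups = {f"H{i}": base + 0.0 for i in range(1, 4)}
        letters = duncan_letters(groups)
        assert len({l for l in letters.values()}) == 1

    def test_extreme_separation_distinct_letters(self):
        rng = np.random.default_rng(1)
        groups = {
            "H1": 0.0 + 0.01 * rng.normal(size=6),
            "H2": 0.1 + 0.01 * rng.normal(size=6),
            "H3": 50.0 + 0.01 * rng.normal(size=6),
        }
        letters = duncan_letters(groups)
        assert len(set(letters.values())) == 3

    def test_two_groups_refused(self):
        with pytest.raises(HaploPhenoError):
            duncan_letters({"a": np.ones(3), "b": np.zeros(3)})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_span_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        groups = {
            f"H{i}": rng.normal(rng.uniform(0, 3), 1.0, int(rng.integers(4, 12)))
            for i in range(1, k + 1)
        }
        letters = duncan_letters(groups, alpha=0.05)
        assert letters_to_pairs(letters) == duncan_significant_pairs_oracle(groups, 0.05)


class TestVarianceExplained:
    def test_equal_means_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        r2, p = variance_explained([g, g + 0.0])
        assert r2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_within_hundred(self):
        r2, p = variance_explained([np.full(5, 1.0), np.full(5, 2.0)])
        assert r2 == 100.0
        assert p == 0.0

    def test_closed_form_limit_two_equal_groups(self):
        """Standardized gap d between two equal groups: R2 -> d^2/(d^2+4)."""
        rng = np.random.default_rng(2)
        n = 10_000
        d = 1.3
        g1 = rng.normal(0, 1, n)
        g2 = rng.normal(d, 1, n)
        r2, _ = variance_explained([g1, g2])
        assert r2 == pytest.approx(100 * d**2 / (d**2 + 4), abs=1.0)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        gs = [rng.normal(i * 0.5, 1, 9) for i in range(3)]
        _, p = variance_explained(gs)
        assert p == pytest.approx(stats.f_oneway(*gs).pvalue, rel=1e-10)

    def test_t_squared_equals_f_for_two_groups(self):
        rng = np.random.default_rng(4)
        g1, g2 = rng.normal(0, 1, 8), rng.normal(1, 1, 11)
        _, p_f = variance_explained([g1, g2])
        p_t = two_group_test(g1, g2)
        assert p_f == pytest.approx(p_t, rel=1e-9)


class TestSuperior:
    def test_reported_group_mean_examples(self):
        # grain length: H1 9.01 vs H2 8.34, maximize -> H1
        assert superior_haplotype({"H1": 9.01, "H2": 8.34}, {"H1": 171, "H2": 9}) == "H1"
        # thousand-grain weight: H1 24.17 vs H2 28.06, maximize -> H2
        assert superior_haplotype({"H1": 24.17, "H2": 28.06}, {"H1": 100, "H2": 50}) == "H2"

    def test_minimize_direction(self):
        assert (
            superior_haplotype({"H1": 2.9, "H2": 2.4}, {"H1": 5, "H2": 5}, "minimize") == "H2"
        )

    def test_tie_prefers_larger_group(self):
        assert superior_haplotype({"H1": 5.0, "H2": 5.0}, {"H1": 3, "H2": 9}) == "H2"

    def test_single_group(self):
        assert superior_haplotype({"H1": 5.0}, {"H1": 10}) == "H1"


class TestCombinations:
    def _two_gene_panel(self):
        rng = np.random.default_rng(6)
        d1 = 2.0 * rng.integers(0, 2, (30, 2))
        d2 = 2.0 * rng.integers(0, 2, (30, 2))
        m1 = make_matrix(d1, positions=[100, 101])
        m2 = make_matrix(d2, positions=[500, 501], chrom="chr2")
        a1 = call_haplotypes(m1, "gA", m1.variant_ids)
        a2 = call_haplotypes(m2, "gB", m2.variant_ids)
        return a1, a2

    def test_counts_and_bounds(self):
        a1, a2 = self._two_gene_panel()
        combo = combine_haplotypes([a1, a2])
        assert sum(combo.counts.values()) <= 30
        assert len(combo.counts) <= len(a1.counts) * len(a2.counts)
        # frequencies non-increasing in label order
        counts = [combo.counts[f"HC{i + 1}"] for i in range(len(combo.counts))]
        assert counts == sorted(counts, reverse=True)

    def test_single_gene_degenerates(self):
        a1, _ = self._two_gene_panel()
        combo = combine_haplotypes([a1])
        # identical partition, relabelled HC*
        groups1 = {frozenset(a1.members(l)) for l in a1.counts}
        groups2 = {frozenset(combo.members(l)) for l in combo.counts}
        assert groups1 == groups2

    def test_missing_propagates(self):
        a1, a2 = self._two_gene_panel()
        acc = next(iter(a1.labels))
        a1.labels[acc] = None
        combo = combine_haplotypes([a1, a2])
        assert combo.labels[acc] is None

    def test_disjoint_accessions_error(self):
        a1, a2 = self._two_gene_panel()
        a2.labels = {f"x{i}": l for i, l in enumerate(a2.labels.values())}
        with pytest.raises(HaploPhenoError):
            combine_haplotypes([a1, a2])


class TestAnalyzeGroups:
    def _values(self, assignment, shift):
        rng = np.random.default_rng(9)
        vals = {}
        for acc, lab in assignment.labels.items():
            base = shift.get(lab, 0.0)
            vals[acc] = base + rng.normal(0, 0.3)
        return pd.Series(vals)

    def test_percent_accounting(self):
        rng = np.random.default_rng(10)
        dosage = 2.0 * rng.integers(0, 2, (40, 2))
        dosage[0, 0] = np.nan  # one missing assignment
        m = make_matrix(dosage)
        a = call_haplotypes(m, "g", m.variant_ids)
        res = analyze_groups(a, self._values(a, {}), "T")
        assert sum(g.percent for g in res.groups) <= 100.0 + 1e-9

    def test_superior_and_r2_on_planted_shift(self):
        rng = np.random.default_rng(12)
        dosage = 2.0 * np.repeat([0, 1], [20, 20])[:, None]
        m = make_matrix(dosage)
        a = call_haplotypes(m, "g", m.variant_ids)
        values = self._values(a, {"H1": 0.0, "H2": 2.0})
        res = analyze_groups(a, values, "T", direction="maximize")
        assert res.superior == "H2"
        assert res.r2 > 50
        assert res.pairwise_p < 1e-6
        assert res.letters == {}  # two groups: t-test, no letter display

    def test_refinement_monotonicity(self):
        """Combining a causal with a non-causal gene cannot reduce the
        between-group sum of squares share."""
        a1, a2 = TestCombinations()._two_gene_panel()
        values = self._values(a1, {"H1": 0.0, "H2": 1.5, "H3": 0.7, "H4": 2.0})
        combo = combine_haplotypes([a1, a2])
        r_causal = analyze_groups(a1, values, "T", min_count=1)
        r_null = analyze_groups(a2, values, "T", min_count=1)
        r_combo = analyze_groups(combo, values, "T", min_count=1)
        assert r_combo.r2 >= r_null.r2 - 1e-9
        assert r_combo.r2 >= r_causal.r2 - 1e-9
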
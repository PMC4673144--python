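"""Fisher exact test, BH correction, signature cutoff and relative risk."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
import scipy.stats

from camlkit.association import (
    LocusAssociation,
    LocusClass,
    bh_adjust,
    classify_loci,
    fisher_exact_two_sided,
    relative_risk,
    run_association,
    signature_cutoff,
)
from camlkit.cohort import CohortTable
from camlkit.errors import InputError
from camlkit.genotyping import CallStatus, SampleGenotype


def fisher_oracle(a, b, c, d):
    """Exact-rational enumeration of the two-sided point-probability rule."""
    n, row, col = a + b + c + d, a + b, a + c
    denom = comb(n, row)
    support = range(max(0, row - (n - col)), min(row, col) + 1)
    probs = {x: Fraction(comb(col, x) * comb(n - col, row - x), denom)
             for x in support}
    threshold = probs[a] * (Fraction(10**7 + 1, 10**7))
    return float(sum(p for p in probs.values() if p <= threshold))


def random_tables(rng, count, max_margin=60):
    for _ in range(count):
        a = int(rng.integers(0, max_margin))
        b = int(rng.integers(0, max_margin))
        c = int(rng.integers(0, max_margin))
        d = int(rng.integers(0, max_margin))
        if a + b + c + d == 0:
            a = 1
        yield a, b, c, d


def cohort_from_pairs(pairs_per_sample, label):
    calls = []
    for i, pair in enumerate(pairs_per_sample):
        calls.append(
            SampleGenotype("L1", f"{label}{i}", pair, 20, CallStatus.CALLED)
        )
    return CohortTable.from_genotypes(calls, label)


class TestFisher:
    def test_no_variants_anywhere(self):
        assert fisher_exact_two_sided(0, 100, 0, 100) == 1.0

    def test_balanced_table(self):
        assert fisher_exact_two_sided(5, 5, 5, 5) == pytest.approx(1.0)

    def test_derived_example_matches_enumeration(self):
        expected = fisher_oracle(10, 90, 40, 60)
        got = fisher_exact_two_sided(10, 90, 40, 60)
        assert got == pytest.approx(expected, rel=1e-7)

    def test_against_scipy_on_random_tables(self):
        rng = np.random.default_rng(3)
        for a, b, c, d in random_tables(rng, 50):
            ours = fisher_exact_two_sided(a, b, c, d)
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_two_sided(0, 0, 0, 0)

    def test_negative_cell_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_two_sided(-1, 5, 5, 5)


class TestBHAdjust:
    def bh_reference(self, p):
        """Naive sorted reference: running minimum of p(k)*n/k from the back."""
        n = len(p)
        order = sorted(range(n), key=lambda i: p[i])
        adjusted = [0.0] * n
        running = math.inf
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adjusted[i] = min(1.0, running)
        return adjusted

    def test_single_p_identity(self):
        assert bh_adjust([0.01]).tolist() == [0.01]

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == [0.04] * 4

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2] * 7).tolist() == [0.2] * 7

    def test_matches_reference_exactly_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for size in (1, 2, 10, 357, 10_000):
            p = rng.random(size)
            assert bh_adjust(p).tolist() == self.bh_reference(p.tolist())

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.random(400)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])


class TestSignatureCutoff:
    def test_threshold_is_one_over_x(self):
        p = [0.001] * 5 + [0.5] * 95  # X = 100 -> cutoff 0.01
        decisions = signature_cutoff(p)
        adj = bh_adjust(p)
        assert decisions.tolist() == (adj < 0.01).tolist()

    def test_all_p_one_gives_empty_signature(self):
        assert not signature_cutoff([1.0] * 20).any()

    def test_small_adjusted_p_passes_large_x(self):
        p = [0.9999] * 999 + [1e-7]
        decisions = signature_cutoff(p)
        # X = 1000 -> cutoff 1e-3; adjusted p of the hit is 1e-4
        assert decisions[-1] and decisions[:-1].sum() == 0


class TestClassify:
    def make(self, p, adj):
        return LocusAssociation("L", 1, 9, 1, 9, p, adj)

    def test_partition(self):
        assocs = [self.make(0.005, 0.002), self.make(0.005, 0.2),
                  self.make(0.5, 0.9)]
        classify_loci(assocs, 0.01, [True, False, False])
        assert [a.klass for a in assocs] == [
            LocusClass.SIGNATURE,
            LocusClass.NON_SIGNATURE,
            LocusClass.NON_SIGNIFICANT,
        ]

    def test_partition_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(2)
        p = rng.random(200)
        assocs = [self.make(x, x) for x in p]
        classify_loci(assocs, 0.01, signature_cutoff(p))
        assert all(a.klass is not None for a in assocs)
        counts = {k: sum(1 for a in assocs if a.klass is k) for k in LocusClass}
        assert sum(counts.values()) == 200


class TestRelativeRisk:
    @pytest.mark.parametrize(
        "table,expected",
        [((20, 80, 10, 90), 2.0), ((10, 90, 10, 90), 1.0)],
    )
    def test_finite(self, table, expected):
        assert relative_risk(*table) == pytest.approx(expected)

    def test_case_only_variants_infinite(self):
        assert math.isinf(relative_risk(5, 95, 0, 100))

    def test_no_variants_undefined(self):
        assert math.isnan(relative_risk(0, 100, 0, 100))

    def test_empty_margin_rejected(self):
        with pytest.raises(InputError):
            relative_risk(0, 0, 5, 5)


class TestRunAssociation:
    def test_identical_cohorts_all_p_one(self):
        pairs = [(20, 20)] * 45 + [(18, 20)] * 15
        cancer = cohort_from_pairs(pairs, "case")
        control = cohort_from_pairs(pairs, "ctrl")
        result = run_association(cancer, control)
        assert all(x.p_value == 1.0 for x in result.associations)
        assert len(result.signature) == 0

    def test_planted_difference_detected(self):
        control = cohort_from_pairs([(20, 20)] * 95 + [(18, 20)] * 5, "ctrl")
        cancer = cohort_from_pairs([(20, 20)] * 60 + [(18, 20)] * 40, "case")
        result = run_association(cancer, control)
        (assoc,) = result.associations
        assert assoc.a == 40 and assoc.c == 5
        assert assoc.p_value < 1e-8
        assert result.signature.loci == {"L1"}
        assert assoc.rr == pytest.approx((40 / 100) / (5 / 100))

    def test_no_evaluable_locus_is_error(self):
        cancer = cohort_from_pairs([(20, 20)] * 5, "case")
        control = cohort_from_pairs([(20, 20)] * 5, "ctrl")
        with pytest.raises(InputError, match="evaluable"):
            run_association(cancer, control)

    def test_summary_counts_consistent(self):
        rng = np.random.default_rng(4)
        calls = []
        for locus in range(30):
            for i in range(40):
                pair = (20, 20) if rng.random() > 0.1 else (18, 20)
                calls.append(
                    SampleGenotype(f"L{locus:02d}", f"c{i}", pair, 20,
                                   CallStatus.CALLED)
                )
        control = CohortTable.from_genotypes(calls, "ctrl")
        cancer = CohortTable.from_genotypes(
            [SampleGenotype(g.locus_id, "x" + g.sample_id, g.alleles, g.depth,
                            g.status) for g in calls],
            "case",
        )
        result = run_association(cancer, control)
        s = result.summary
        assert s["n_tested"] == 30
        klasses = [x.klass for x in result.associations]
        assert (
            klasses.count(LocusClass.SIGNATURE)
            + klasses.count(LocusClass.NON_SIGNATURE)
            + klasses.count(LocusClass.NON_SIGNIFICANT)
        ) == s["n_tested"]
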
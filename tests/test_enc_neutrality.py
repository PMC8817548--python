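"""ENc observed/expected, the deviation histogram and the neutrality fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonusage as cu
from codonusage.composition import CodonCountTable, count_codons
from codonusage.enc_neutrality import (
    DEVIATION_BIN_EDGES,
    deviation_histogram,
    enc_expected,
    enc_observed,
    enc_table,
    neutrality_fit,
)


def _table(**counts) -> CodonCountTable:
    t = CodonCountTable()
    for c, n in counts.items():
        t.counts[c] = n
    return t


class TestEncObserved:
    def test_one_codon_per_family_is_20(self, one_codon_per_family_gene):
        """Using a single synonymous codon per amino acid gives the
        theoretical minimum of 20 effective codons."""
        enc = enc_observed(count_codons(one_codon_per_family_gene))
        assert enc == pytest.approx(20.0, abs=1e-12)

    def test_equal_usage_caps_at_61(self, uniform_usage_counts):
        assert enc_observed(uniform_usage_counts) == 61.0

    def test_wright_f_hat_derived(self, code):
        """2-fold family with counts {3,1}: F_hat = (4*(9+1)/16 - 1)/3 = 0.5."""
        # isolate via a gene carrying every class but with Lys counts 3:1
        t = _table(AAA=3, AAG=1)
        n = 4
        p = np.array([3, 1]) / n
        f_hat = (n * (p**2).sum() - 1) / (n - 1)
        assert f_hat == pytest.approx(0.5)
        # full-gene check: all other classes saturated (F=1), Lys drags F2
        body = {}
        for aa in sorted(code.degeneracy_classes[2]):
            body[code.families[aa][0]] = 2
        for aa in sorted(
            code.degeneracy_classes[3]
            | code.degeneracy_classes[4]
            | code.degeneracy_classes[6]
        ):
            body[code.families[aa][0]] = 2
        body["AAA"], body["AAG"] = 3, 1
        enc = enc_observed(_table(**body))
        # F2 = (8*1 + 0.5)/9, others 1
        assert enc == pytest.approx(2 + 9 / (8.5 / 9) + 1 + 5 + 3)

    def test_relabeling_within_family_invariant(self, code):
        a = _table(GAT=7, GAC=3, GGA=2, GGT=2, ATT=2, ATC=1, TTA=4, TTG=1, CTA=1)
        b = _table(GAC=7, GAT=3, GGT=2, GGC=2, ATC=2, ATA=1, TTG=4, TTA=1, CTC=1)
        assert enc_observed(a) == pytest.approx(enc_observed(b))

    def test_missing_class_undefined(self):
        # only a 2-fold family present: F4/F6 undefined -> ENc undefined
        assert enc_observed(_table(AAA=5, AAG=5)) is None

    def test_ile_imputation(self, code):
        """A gene lacking Ile still gets an ENc via F3 = (F2+F4)/2."""
        body = {}
        for aa in sorted(code.degeneracy_classes[2] | code.degeneracy_classes[4]
                         | code.degeneracy_classes[6]):
            body[code.families[aa][0]] = 2
        enc = enc_observed(_table(**body))
        assert enc == pytest.approx(20.0)  # all F = 1, imputed F3 = 1


class TestEncExpected:
    @pytest.mark.parametrize(
        "f,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)]
    )
    def test_closed_form(self, f, expected):
        assert enc_expected(f) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_symmetry_up_to_linear_term(self, f):
        """enc_expected(F) - F == enc_expected(1-F) - (1-F); max at 0.5."""
        assert enc_expected(f) - f == pytest.approx(
            enc_expected(1 - f) - (1 - f), abs=1e-9
        )
        assert enc_expected(f) <= enc_expected(0.5) + 1e-12


class TestDeviationHistogram:
    def test_zero_deviation_lands_in_first_positive_bin(self):
        hist = deviation_histogram([0.0])
        idx = DEVIATION_BIN_EDGES.index(0.0)
        assert hist.percentages[idx] == 100.0

    def test_percentages_sum_to_100_with_out_of_range(self):
        vals = [-0.5, -0.15, 0.05, 0.05, 0.25, 0.49, 0.5, 0.7]
        hist = deviation_histogram(vals)
        total = sum(hist.percentages) + hist.out_of_range_pct
        assert total == pytest.approx(100.0, abs=1e-9)
        assert hist.out_of_range_pct == pytest.approx(100 * 3 / 8)

    def test_half_open_edges(self):
        hist = deviation_histogram([-0.1, 0.1])
        assert hist.percentages[DEVIATION_BIN_EDGES.index(-0.1)] == 50.0
        assert hist.percentages[DEVIATION_BIN_EDGES.index(0.1)] == 50.0


class TestMutationOnlyNull:
    def test_null_genes_sit_on_expected_curve(self, mutation_only_records):
        """Mutation-only genes scatter tightly around the expected ENc
        curve: mean deviation near 0 and >= 90% within |0.1|."""
        records, hist = enc_table(mutation_only_records)
        dev = np.array([r.deviation for r in records])
        assert abs(dev.mean()) <= 0.05
        assert (np.abs(dev) <= 0.1).mean() >= 0.90
        assert sum(hist.percentages) + hist.out_of_range_pct == pytest.approx(100)

    def test_records_internally_consistent(self, mutation_only_records):
        records, _ = enc_table(mutation_only_records[:50])
        for r in records:
            assert r.enc_exp == pytest.approx(enc_expected(r.gc3s), abs=1e-12)
            assert r.deviation == pytest.approx(
                (r.enc_exp - r.enc_obs) / r.enc_exp, abs=1e-12
            )
            assert 20.0 <= r.enc_obs <= 61.0


class TestNeutralityFit:
    def test_identity_line(self):
        x = np.linspace(30, 60, 20)
        fit = neutrality_fit(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(fit.r**2)

    def test_constant_gc12_zero_slope(self):
        fit = neutrality_fit([45.0] * 10, np.linspace(30, 60, 10))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_gc3_variance_errors(self):
        with pytest.raises(ValueError):
            neutrality_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            neutrality_fit([1.0, 2.0], [1.0, 2.0])

    def test_slope_recovery_from_coupled_model(self):
        """Genes generated with GC12 = 0.45 + 0.37*(GC3-0.42) + noise
        recover the 0.37 slope within +/-0.03, significantly (p < 0.05)."""
        spec = cu.SyntheticSpec(
            n_genes=2000,
            codon_length_range=(600, 600),
            model=cu.Coupled(slope=0.37, intercept=0.45, sigma=0.01,
                             gc3_center=0.42),
            seed=1,
        )
        recs = cu.generate(spec)
        profs = [cu.gc_profile(count_codons(r)) for r in recs]
        fit = neutrality_fit(
            [(p.gc1 + p.gc2) / 2 for p in profs], [p.gc3 for p in profs]
        )
        assert fit.slope == pytest.approx(0.37, abs=0.03)
        assert fit.p_value < 0.05
        assert fit.n_genes == 2000
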
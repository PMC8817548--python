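"""RSCU and derived statistics, checked against an independent recount."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonusage as cu
from codonusage.composition import CodonCountTable, count_codons, pool_counts
from codonusage.genetic_code import SENSE_CODONS, STOP, standard_code
from codonusage.rscu import (
    MOTIF_PATTERNS,
    high_frequency_codons,
    motif_rscu,
    rscu,
    stop_codon_rscu,
    xcg_xcc_ratio,
)


def _table(**counts) -> CodonCountTable:
    t = CodonCountTable()
    for c, n in counts.items():
        t.counts[c] = n
    return t


def _uniform_table(per_codon: int = 10) -> CodonCountTable:
    t = CodonCountTable()
    for c in t.counts:
        t.counts[c] = per_codon
    return t


def brute_force_rscu(seqs: list[str]) -> dict[str, float]:
    """Independent oracle: recount codons straight from raw sequence and
    apply n_i * x / T per family, terminal stops pooled as one family."""
    code = standard_code()
    counts: Counter = Counter()
    for s in seqs:
        for i in range(0, len(s) - 2, 3):
            counts[s[i : i + 3]] += 1
    out = {}
    for aa, fam in code.families.items():
        total = sum(counts[c] for c in fam)
        if total == 0:
            continue
        for c in fam:
            out[c] = len(fam) * counts[c] / total
    return out


class TestRscu:
    def test_equal_usage_all_ones(self):
        table = rscu(_uniform_table())
        assert all(v == pytest.approx(1.0) for v in table.values.values())

    def test_monopolized_six_fold_family(self):
        table = rscu(_table(AGA=6))
        assert table.values["AGA"] == pytest.approx(6.0)
        assert table.values["CGT"] == 0.0

    def test_two_fold_family_derived(self):
        table = rscu(_table(AAA=3, AAG=1))
        assert table.values["AAA"] == pytest.approx(1.5)
        assert table.values["AAG"] == pytest.approx(0.5)
        assert table.rel_freq["AAA"] == pytest.approx(0.75)

    def test_unobserved_family_is_missing_not_zero(self):
        table = rscu(_table(AAA=3))
        assert table.values["GGG"] is None
        assert table.values["AAG"] == 0.0  # observed family, unused codon

    def test_oracle_recount_on_synthetic_genes(self, small_random_records):
        """Pooled-count RSCU equals brute-force recomputation from the raw
        concatenated sequences of 100 random genes."""
        pooled = pool_counts([count_codons(r) for r in small_random_records])
        table = rscu(pooled)
        oracle = brute_force_rscu([r.seq for r in small_random_records])
        for codon, expected in oracle.items():
            assert table.values[codon] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.dictionaries(
            st.sampled_from(SENSE_CODONS),
            st.integers(min_value=0, max_value=100),
            min_size=3,
        ),
        st.integers(min_value=2, max_value=7),
    )
    def test_family_sums_and_scale_invariance(self, counts, k):
        code = standard_code()
        t = _table(**counts)
        if t.total_sense == 0:
            return
        table = rscu(t)
        scaled = rscu(_table(**{c: n * k for c, n in counts.items()}))
        for aa, fam in code.families.items():
            vals = [table.values[c] for c in fam]
            if any(v is None for v in vals):
                assert all(v is None for v in vals)
                continue
            assert sum(vals) == pytest.approx(len(fam), abs=1e-9)
            rfs = [table.rel_freq[c] for c in fam]
            assert sum(rfs) == pytest.approx(1.0, abs=1e-9)
            for c in fam:
                assert scaled.values[c] == pytest.approx(table.values[c])


class TestHighFrequency:
    def test_uniform_table_has_none(self):
        assert high_frequency_codons(rscu(_uniform_table())) == set()

    def test_dominated_family_included(self):
        # Arg: AGA 62 of 100 -> RSCU 3.72 > 1.5 and rel freq 0.62 > 0.6
        t = _table(AGA=62, AGG=10, CGA=7, CGC=7, CGG=7, CGT=7)
        assert "AGA" in high_frequency_codons(rscu(t))

    def test_threshold_is_strict(self):
        # 6-fold family, RSCU exactly 1.5 (count 25 of 100), rel freq 0.25
        t = _table(AGA=25, AGG=15, CGA=15, CGC=15, CGG=15, CGT=15)
        table = rscu(t)
        assert table.values["AGA"] == pytest.approx(1.5)
        assert "AGA" not in high_frequency_codons(table)

    def test_sixty_percent_rule(self):
        # 2-fold family at rel freq 0.61: RSCU 1.22 < 1.5 but share > 60%
        t = _table(AAA=61, AAG=39)
        table = rscu(t)
        assert table.values["AAA"] == pytest.approx(1.22)
        assert "AAA" in high_frequency_codons(table)

    def test_single_codon_families_never_included(self):
        # ATG/TGG have rel freq 1.0 > 0.6 but 1-fold families are exempt;
        # stops are exempt even when one dominates
        t = _table(ATG=100, TGG=100, AAA=50, AAG=50, TGA=10)
        assert high_frequency_codons(rscu(t)) == set()


class TestStopAndMotifs:
    def test_equal_stops(self):
        vals = stop_codon_rscu(_table(TAA=5, TAG=5, TGA=5))
        assert all(v == pytest.approx(1.0) for v in vals.values())

    def test_all_tga(self):
        vals = stop_codon_rscu(_table(TGA=9))
        assert vals == {"TAA": 0.0, "TAG": 0.0, "TGA": pytest.approx(3.0)}

    def test_derived_stop_mix(self):
        vals = stop_codon_rscu(_table(TGA=44, TAA=30, TAG=26))
        assert vals["TGA"] == pytest.approx(1.32)
        assert vals["TAA"] == pytest.approx(0.90)
        assert vals["TAG"] == pytest.approx(0.78)

    def test_no_stops_errors(self):
        with pytest.raises(ValueError):
            stop_codon_rscu(_table(AAA=3))

    @pytest.mark.parametrize(
        "pattern,codons",
        [
            ("NCG", {"ACG", "CCG", "GCG", "TCG"}),
            ("NTA", {"ATA", "CTA", "GTA", "TTA"}),
            ("XCC", {"ACC", "CCC", "GCC", "TCC"}),
        ],
    )
    def test_motif_expansion(self, pattern, codons):
        table = rscu(_uniform_table())
        got = motif_rscu(table, pattern)
        assert set(got) == codons
        assert all(v == pytest.approx(1.0) for v in got.values())

    def test_unknown_pattern(self):
        with pytest.raises(ValueError):
            motif_rscu(rscu(_uniform_table()), "NGG")


class TestXcgXcc:
    def test_uniform_ratio_one(self):
        assert xcg_xcc_ratio(rscu(_uniform_table())) == pytest.approx(1.0)

    def test_half_ratio(self):
        t = _uniform_table(8)
        for c in MOTIF_PATTERNS["XCG"]:
            t.counts[c] = 4  # halve the CG-ending codon within each family
        table = rscu(t)
        # each XCG RSCU is now below its XCC partner; ratio < 1
        assert xcg_xcc_ratio(table) < 1.0

    def test_cg_suppressed_generator_ratio_below_one(self):
        """Sampling with the generator's cg_suppression < 1 produces
        genome-wide CG-dinucleotide avoidance at codon positions 2-3."""
        spec = cu.SyntheticSpec(
            n_genes=150,
            codon_length_range=(101, 200),
            model=cu.MutationOnly(0.5),
            cg_suppression=0.5,
            seed=11,
        )
        recs = cu.generate(spec)
        pooled = pool_counts([count_codons(r) for r in recs])
        assert xcg_xcc_ratio(rscu(pooled)) < 1.0
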
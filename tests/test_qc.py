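"""Variant QC: exact HWE test against a full-enumeration oracle and filters."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from metaboqtl.errors import DataError
from metaboqtl.genotypes import GenotypeMatrix
from metaboqtl.qc import QCReport, filter_variants, hwe_exact_test


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational enumeration of the conditional het-count distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return Fraction(
            2**h * factorial(n),
            factorial(hom_minor) * factorial(h) * factorial(hom_major),
        ) * Fraction(
            factorial(n_minor) * factorial(2 * n - n_minor), factorial(2 * n)
        )

    probs = {h: prob(h) for h in range(n_minor % 2, n_minor + 1, 2)}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHWEExactTest:
    def test_most_probable_configuration_has_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_snp_is_never_rejected(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_extreme_het_deficit_is_rejected(self):
        # exact p for (5,0,5) is 1.36e-3: small but above the 1e-4 QC cutoff
        p = hwe_exact_test(5, 0, 5)
        assert p == pytest.approx(hwe_oracle(5, 0, 5), rel=1e-9)
        assert p < 0.01
        # doubling the table pushes it far below the QC cutoff
        assert hwe_exact_test(10, 0, 10) < 1e-4

    def test_agrees_with_enumeration_oracle_small_tables(self):
        for n in range(1, 21):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    expected = hwe_oracle(n_aa, n_ab, n_bb)
                    assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                        expected, rel=1e-9, abs=1e-300
                    ), (n_aa, n_ab, n_bb)

    def test_undefined_for_empty_table(self):
        with pytest.raises(DataError):
            hwe_exact_test(0, 0, 0)

    @settings(max_examples=200, derandomize=True)
    @given(
        n_aa=st.integers(0, 40),
        n_ab=st.integers(0, 40),
        n_bb=st.integers(0, 40),
    )
    def test_random_tables_match_oracle_and_stay_in_unit_interval(
        self, n_aa, n_ab, n_bb
    ):
        assume(n_aa + n_ab + n_bb >= 1)
        p = hwe_exact_test(n_aa, n_ab, n_bb)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_oracle(n_aa, n_ab, n_bb), rel=1e-9)


def _matrix(dosage_cols, accuracy=None, chrom=None):
    dosages = np.array(dosage_cols, dtype=float).T
    m = dosages.shape[1]
    snps = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(m)],
            "chrom": chrom or ["1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": "G",
            "accuracy": accuracy if accuracy is not None else [1.0] * m,
        }
    )
    samples = [f"a{i}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages)


class TestFilterVariants:
    def test_maf_boundary_is_strict(self):
        # 10 animals: dosage sum 1 -> MAF 0.05 retained; sum 0.049 impossible,
        # use 20 animals: 1 alt allele = MAF 0.025 removed, 2 = 0.05 retained
        col_low = [1.0] + [0.0] * 19
        col_edge = [1.0, 1.0] + [0.0] * 18
        geno = _matrix([col_low, col_edge])
        kept, report = filter_variants(geno, hwe_alpha=1e-10)
        assert list(kept.snps["id"]) == ["s1"]
        assert report.n_low_maf == 1

    def test_accuracy_boundary_is_strict(self):
        col = [0.0, 1.0, 2.0, 1.0, 0.0, 1.0, 2.0, 0.0]
        geno = _matrix([col, col, col], accuracy=[0.94, 0.95, 1.0])
        kept, report = filter_variants(geno, min_maf=0.0, hwe_alpha=1e-10)
        assert report.n_low_accuracy == 1
        assert kept.n_snps == 2

    def test_one_snp_failing_each_filter_reconciles(self):
        ok = [0.0, 1.0, 2.0, 1.0, 0.0, 1.0, 2.0, 0.0, 1.0, 1.0] * 2
        low_acc = ok
        low_maf = [0.0] * 20
        hwe_bad = [0.0] * 10 + [2.0] * 10  # no hets: exact p ~ 1.3e-6
        off_autosome = ok
        geno = _matrix(
            [ok, low_acc, low_maf, hwe_bad, off_autosome],
            accuracy=[1.0, 0.5, 1.0, 1.0, 1.0],
            chrom=["1", "1", "1", "1", "X"],
        )
        kept, report = filter_variants(geno, min_maf=0.05)
        assert kept.n_snps == 1
        assert (
            report.n_non_autosome,
            report.n_low_accuracy,
            report.n_low_maf,
            report.n_hwe_fail,
        ) == (1, 1, 1, 1)
        assert report.n_retained + 4 == report.n_input

    def test_filters_are_conjunctive_and_order_free(self, small_genotypes):
        kept_all, _ = filter_variants(small_genotypes)
        # applying MAF first then accuracy (via two passes) gives the same set
        pass1, _ = filter_variants(
            small_genotypes, min_accuracy=0.0, hwe_alpha=1e-300
        )
        pass2, _ = filter_variants(pass1)
        assert list(pass2.snps["id"]) == list(kept_all.snps["id"])

    def test_empty_output_warns_not_raises(self):
        col = [1.0] + [0.0] * 19
        geno = _matrix([col])
        with pytest.warns(UserWarning, match="all SNPs removed"):
            kept, report = filter_variants(geno)
        assert kept.n_snps == 0 and report.n_retained == 0


def test_qc_report_bookkeeping_is_enforced():
    with pytest.raises(AssertionError):
        QCReport(10, 1, 1, 1, 1, 5)
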
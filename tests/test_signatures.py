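"""96-class strand-aware spectra, normalization, catalog correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from mitolineage.reference import CircularReference
from mitolineage import signatures as sig


class TestClassify:
    def test_pyrimidine_center_is_light_strand(self):
        ref = CircularReference("t", "ACGTA")
        cls, strand = sig.classify_substitution(ref, 2, "C", "T")
        assert strand == "L"
        assert sig.CLASS_LABELS[cls] == "A[C>T]G"

    def test_purine_center_complements_to_heavy_strand(self):
        # G>A at pos 3 of ACGTA: complement is C>T, context revcomp(CGT)=ACG
        ref = CircularReference("t", "ACGTA")
        cls, strand = sig.classify_substitution(ref, 3, "G", "A")
        assert strand == "H"
        assert sig.CLASS_LABELS[cls] == "A[C>T]G"

    def test_circular_flank_at_position_one(self):
        ref = CircularReference("t", "CCGTA")
        cls, strand = sig.classify_substitution(ref, 1, "C", "A")
        assert strand == "L"
        assert sig.CLASS_LABELS[cls] == "A[C>A]C"  # 5' flank wraps to last base

    def test_ref_mismatch_and_identity_rejected(self):
        ref = CircularReference("t", "ACGTA")
        with pytest.raises(ValueError):
            sig.classify_substitution(ref, 2, "G", "T")
        with pytest.raises(ValueError):
            sig.classify_substitution(ref, 2, "C", "C")

    @settings(derandomize=True, max_examples=100)
    @given(data=hst.data())
    def test_involution_complementary_substitution_same_class(self, data, mid_ref):
        """Classifying the complementary substitution on the complementary
        genome yields the same 96-class (strand assignment flips)."""
        pos = data.draw(hst.integers(min_value=1, max_value=mid_ref.length))
        ref_base = mid_ref.base(pos)
        alt = data.draw(hst.sampled_from([b for b in "ACGT" if b != ref_base]))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc_ref = CircularReference("rc", sig.revcomp(mid_ref.sequence))
        rc_pos = mid_ref.length - pos + 1
        cls1, strand1 = sig.classify_substitution(mid_ref, pos, ref_base, alt)
        cls2, strand2 = sig.classify_substitution(
            rc_ref, rc_pos, comp[ref_base], comp[alt]
        )
        assert cls1 == cls2
        assert {strand1, strand2} == {"L", "H"}


class TestSpectrum:
    def test_single_variant_is_indicator(self, mid_ref):
        pos = next(
            p for p in range(1, mid_ref.length + 1) if mid_ref.base(p) == "C"
        )
        spec = sig.build_spectrum([(pos, "C", "T")], mid_ref, normalize=False)
        assert spec.total == 1
        assert spec.rates.sum() == pytest.approx(1.0)
        assert (spec.rates > 0).sum() == 1

    def test_matches_brute_force_tally(self, mid_ref, rng):
        """Oracle: hand tally / per-strand divide / renormalize."""
        variants = []
        for pos in rng.choice(mid_ref.length, size=60, replace=False) + 1:
            ref_base = mid_ref.base(int(pos))
            alts = [b for b in "ACGT" if b != ref_base]
            variants.append((int(pos), ref_base, alts[int(rng.integers(3))]))
        spec = sig.build_spectrum(variants, mid_ref, normalize=True)

        freq = {"L": mid_ref.context_frequencies("L"),
                "H": mid_ref.context_frequencies("H")}
        expected = np.zeros(96)
        for pos, ref_base, alt in variants:
            cls, strand = sig.classify_substitution(mid_ref, pos, ref_base, alt)
            expected[cls] += 1.0 / freq[strand][sig.class_context(cls)]
        expected /= expected.sum()
        np.testing.assert_allclose(spec.rates, expected, rtol=1e-12)

    def test_raw_counts_and_strand_split_sum(self, mid_ref, rng):
        variants = []
        for pos in rng.choice(mid_ref.length, size=30, replace=False) + 1:
            ref_base = mid_ref.base(int(pos))
            alt = [b for b in "ACGT" if b != ref_base][0]
            variants.append((int(pos), ref_base, alt))
        spec = sig.build_spectrum(variants, mid_ref)
        assert spec.total == 30
        assert spec.strand_counts.to_numpy().sum() == 30

    def test_rates_sum_to_one(self, mid_ref, rng):
        variants = [(int(p), mid_ref.base(int(p)),
                     [b for b in "ACGT" if b != mid_ref.base(int(p))][0])
                    for p in rng.choice(mid_ref.length, size=20, replace=False) + 1]
        for normalize in (True, False):
            spec = sig.build_spectrum(variants, mid_ref, normalize=normalize)
            assert spec.rates.sum() == pytest.approx(1.0)


class TestCatalog:
    def test_packaged_catalog_is_row_stochastic(self):
        cat = sig.SignatureCatalog.synthetic()
        assert len(cat.names) == 30
        np.testing.assert_allclose(cat.matrix.sum(axis=1), 1.0, atol=1e-6)
        assert (cat.matrix >= 0).all()

    def test_exact_catalog_row_correlates_at_one(self, mid_ref):
        cat = sig.SignatureCatalog.synthetic()
        spec = sig.SubstitutionSpectrum(
            label="row5", rates=cat.matrix[5].copy(),
            raw_counts=np.ones(96, dtype=int),
            strand_counts=None,
        )
        ranked = sig.correlate_catalog(spec, cat)
        assert ranked.iloc[0]["signature"] == cat.names[5]
        assert ranked.iloc[0]["r"] == pytest.approx(1.0)
        assert ranked.iloc[0]["rank"] == 1

    def test_disjoint_indicators_negative_correlation(self):
        a = np.zeros(96); a[0] = 1.0
        b = np.zeros(96); b[50] = 1.0
        sa = sig.SubstitutionSpectrum("a", a, np.array(a, dtype=int), None)
        sb = sig.SubstitutionSpectrum("b", b, np.array(b, dtype=int), None)
        r = sig.spectrum_similarity(sa, sb)
        assert r == pytest.approx(-1 / 95)

    def test_similarity_symmetric_and_reflexive(self, mid_ref, rng):
        variants = [(int(p), mid_ref.base(int(p)),
                     [b for b in "ACGT" if b != mid_ref.base(int(p))][0])
                    for p in rng.choice(mid_ref.length, size=40, replace=False) + 1]
        s1 = sig.build_spectrum(variants[:25], mid_ref)
        s2 = sig.build_spectrum(variants[25:], mid_ref)
        assert sig.spectrum_similarity(s1, s1) == pytest.approx(1.0)
        assert sig.spectrum_similarity(s1, s2) == pytest.approx(
            sig.spectrum_similarity(s2, s1)
        )

    def test_permutation_invariance_of_correlation(self):
        cat = sig.SignatureCatalog.synthetic()
        rng = np.random.default_rng(3)
        perm = rng.permutation(96)
        spec = sig.SubstitutionSpectrum(
            "s", cat.matrix[2].copy(), np.ones(96, dtype=int), None
        )
        permuted_cat = sig.SignatureCatalog(
            names=list(cat.names), matrix=cat.matrix[:, perm]
        )
        spec_p = sig.SubstitutionSpectrum(
            "s", spec.rates[perm], np.ones(96, dtype=int), None
        )
        r1 = sig.correlate_catalog(spec, cat)
        r2 = sig.correlate_catalog(spec_p, permuted_cat)
        np.testing.assert_allclose(
            r1.sort_values("signature")["r"].to_numpy(),
            r2.sort_values("signature")["r"].to_numpy(),
            rtol=1e-12,
        )
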
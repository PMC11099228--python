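import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axismr.instruments import (EstimationError, IVConfig,
                                compute_f_statistic,
                                exclude_outcome_associated,
                                filter_weak_and_rare, harmonize,
                                is_palindromic, ld_clump, select_instruments,
                                threshold_candidates)
from axismr.io import LDMatrix, VariantAssociation

from conftest import make_dataset


class TestThreshold:
    def test_strict_comparison_keeps_only_below(self):
        ds = make_dataset("t", [dict(pvalue=1e-6), dict(pvalue=2e-5),
                                dict(pvalue=1e-4)])
        assert len(threshold_candidates(ds, 1e-5)) == 1

    def test_threshold_one_is_vacuous(self):
        ds = make_dataset("t", [dict(pvalue=p) for p in (0.1, 0.5, 0.999)])
        assert len(threshold_candidates(ds, 1.0)) == 3

    def test_genomewide_threshold_on_null_pvalues_keeps_none(self, rng):
        # 1,000 uniform p-values at 5e-8: expected count 5e-5
        ds = make_dataset("t", [dict(pvalue=float(p))
                                for p in rng.uniform(size=1000)])
        assert len(threshold_candidates(ds, 5e-8)) == 0


class TestClump:
    def _three_snp(self):
        ds = make_dataset("t", [
            dict(snp_id="A", pvalue=1e-8, pos=1_000_000),
            dict(snp_id="B", pvalue=1e-7, pos=2_000_000),
            dict(snp_id="C", pvalue=1e-6, pos=3_000_000)])
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.5
        m[0, 2] = m[2, 0] = 0.0005
        m[1, 2] = m[2, 1] = 0.0005
        return ds, LDMatrix(["A", "B", "C"], m)

    def test_greedy_selection_by_ascending_p(self):
        ds, ld = self._three_snp()
        kept = ld_clump(ds, ld, 0.001, 10_000)
        assert list(kept.table["snp_id"]) == ["A", "C"]

    def test_identity_ld_keeps_everything(self):
        ds, _ = self._three_snp()
        kept = ld_clump(ds, LDMatrix(["A", "B", "C"], np.eye(3)), 0.001, 10_000)
        assert len(kept) == 3

    def test_pairs_outside_window_ignored(self):
        ds = make_dataset("t", [dict(snp_id="A", pvalue=1e-8, pos=1_000_000),
                                dict(snp_id="B", pvalue=1e-7,
                                     pos=1_000_000 + 20_000_000)])
        m = np.array([[1.0, 0.9], [0.9, 1.0]])
        kept = ld_clump(ds, LDMatrix(["A", "B"], m), 0.001, 10_000)
        assert len(kept) == 2

    def test_absent_snps_assumed_independent(self):
        ds, _ = self._three_snp()
        kept = ld_clump(ds, LDMatrix(["A"], np.eye(1)), 0.001, 10_000)
        assert len(kept) == 3

    def test_greedy_output_is_maximal(self, rng):
        """No removed SNP can rejoin without violating the r² threshold."""
        k = 12
        ids = [f"s{i}" for i in range(k)]
        ds = make_dataset("t", [dict(snp_id=ids[i], pvalue=float(p), pos=1000 + i)
                                for i, p in enumerate(rng.uniform(size=k))])
        half = rng.uniform(size=(k, k))
        m = np.where(half + half.T > 1.0, 0.5, 0.0)
        np.fill_diagonal(m, 1.0)
        ld = LDMatrix(ids, m)
        kept = set(ld_clump(ds, ld, 0.001, 10_000).table["snp_id"])
        for snp in set(ids) - kept:
            assert any(ld.get(snp, other) >= 0.001 for other in kept)


class TestOutcomeExclusion:
    def test_below_cut_removed_above_retained_unmatched_dropped(self):
        inst = make_dataset("x", [dict(snp_id=f"s{i}") for i in range(10)])
        out_rows = []
        for i in range(8):  # s8, s9 unmatched
            p = 1e-6 if i < 3 else 1e-4
            out_rows.append(dict(snp_id=f"s{i}", pvalue=p))
        outcome = make_dataset("y", out_rows)
        kept = exclude_outcome_associated(inst, outcome, 5e-5)
        assert len(kept) == 5
        assert kept.validation.reasons == {"outcome_associated": 3,
                                           "unmatched": 2}


@pytest.mark.parametrize("a1,a2,expected", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("A", "C", False), ("G", "T", False),
])
def test_palindromic_detection(a1, a2, expected):
    assert is_palindromic(a1, a2) is expected


class TestStrengthFilter:
    def test_f_statistic_is_squared_wald_z(self):
        v = VariantAssociation("rs1", "1", 1, "A", "G", 0.3, 0.05, 0.01,
                               1e-6, 1000)
        assert compute_f_statistic(v) == pytest.approx(25.0)
        v0 = VariantAssociation("rs1", "1", 1, "A", "G", 0.3, 0.0, 0.01,
                                1.0, 1000)
        assert compute_f_statistic(v0) == 0.0
        vneg = VariantAssociation("rs1", "1", 1, "A", "G", 0.3, -0.03, 0.01,
                                  1e-2, 1000)
        assert compute_f_statistic(vneg) == pytest.approx(9.0)

    def test_rare_variant_removed(self):
        ds = make_dataset("t", [dict(eaf=0.995), dict(eaf=0.5)])
        kept = filter_weak_and_rare(ds, 10, 0.01)
        assert list(kept.table["eaf"]) == [0.5]

    def test_f_exactly_at_threshold_removed(self):
        # F must be strictly greater than the cutoff; 0.5/0.25 = 2 exactly,
        # so F = 4 is exactly representable
        ds = make_dataset("t", [dict(beta=0.5, se=0.25),
                                dict(beta=0.4, se=0.02)])
        kept = filter_weak_and_rare(ds, f_min=4.0, maf_min=0.01)
        assert list(kept.table["beta"]) == [0.4]


class TestHarmonize:
    def test_swapped_alleles_negate_outcome_beta(self):
        exp = make_dataset("x", [dict(effect_allele="A", other_allele="G",
                                      beta=0.1)])
        out = make_dataset("y", [dict(effect_allele="G", other_allele="A",
                                      beta=-0.05)])
        h = harmonize(exp, out)
        assert h.Gamma[0] == pytest.approx(0.05)

    def test_strand_complement_resolved(self):
        exp = make_dataset("x", [dict(effect_allele="A", other_allele="G")])
        out = make_dataset("y", [dict(effect_allele="T", other_allele="C",
                                      beta=0.07)])
        h = harmonize(exp, out)
        assert h.Gamma[0] == pytest.approx(0.07)

    def test_strand_complement_swapped_resolved_with_flip(self):
        exp = make_dataset("x", [dict(effect_allele="A", other_allele="G")])
        out = make_dataset("y", [dict(effect_allele="C", other_allele="T",
                                      beta=0.07)])
        h = harmonize(exp, out)
        assert h.Gamma[0] == pytest.approx(-0.07)

    def test_palindromic_snp_dropped(self):
        exp = make_dataset("x", [dict(snp_id="pal", effect_allele="A",
                                      other_allele="T"),
                                 dict(snp_id="ok")])
        out = make_dataset("y", [dict(snp_id="pal", effect_allele="A",
                                      other_allele="T"),
                                 dict(snp_id="ok")])
        h = harmonize(exp, out, drop_palindromic=True)
        assert h.snp_ids == ["ok"]

    def test_irreconcilable_alleles_dropped(self):
        exp = make_dataset("x", [dict(snp_id="bad", effect_allele="A",
                                      other_allele="G"),
                                 dict(snp_id="ok")])
        out = make_dataset("y", [dict(snp_id="bad", effect_allele="A",
                                      other_allele="C"),
                                 dict(snp_id="ok")])
        h = harmonize(exp, out)
        assert h.snp_ids == ["ok"]

    def test_no_overlap_raises_estimation_error(self):
        exp = make_dataset("x", [dict(snp_id="a")])
        out = make_dataset("y", [dict(snp_id="b")])
        with pytest.raises(EstimationError, match="no overlapping"):
            harmonize(exp, out)

    def test_idempotent_on_aligned_pair(self):
        exp = make_dataset("x", [dict(beta=0.1), dict(snp_id="z", beta=-0.2)])
        out = make_dataset("y", [dict(beta=0.04), dict(snp_id="z", beta=0.06)])
        h1 = harmonize(exp, out)
        h2 = harmonize(exp, out)
        np.testing.assert_array_equal(h1.Gamma, h2.Gamma)
        np.testing.assert_array_equal(h1.Gamma, out.table["beta"].to_numpy())


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_selection_cascade_is_deterministic(seed):
    from axismr.simulate import SimConfig, generate_study
    e, _, o, _ = generate_study(SimConfig(seed=seed, n_snp_exposure=20,
                                          n_snp_mediator=5))
    try:
        h1 = select_instruments(e, o)
        h2 = select_instruments(e, o)
    except EstimationError:
        return
    assert h1.snp_ids == h2.snp_ids
    np.testing.assert_array_equal(h1.Gamma, h2.Gamma)


def test_cascade_filters_decoys_and_enforces_strength():
    """Palindromic and sub-1%-MAF decoys never survive the cascade and every
    surviving instrument has F > 10 on the exposure side."""
    from axismr.simulate import SimConfig, generate_study
    e, _, o, _ = generate_study(SimConfig(seed=42, n_snp_exposure=60,
                                          palindromic_rate=0.3,
                                          low_maf_rate=0.3))
    h = select_instruments(e, o)
    tab = e.table.set_index("snp_id").loc[h.snp_ids]
    assert ((tab["beta"] / tab["se"]) ** 2 > 10).all()
    maf = np.minimum(tab["eaf"], 1 - tab["eaf"])
    assert (maf >= 0.01).all()
    for ea, oa in zip(tab["effect_allele"], tab["other_allele"]):
        assert not is_palindromic(ea, oa)
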
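"""Summary statistics: rounding, mean/SEM, Student's t, cohort grids."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mitolineage import (
    annotate_variant,
    classify_all,
    is_functional,
    mean_sem,
    percent_rounded,
    summarize_cohort,
    two_sample_t,
)
from mitolineage.pipeline import _Var
from conftest import animal_meta, make_matrix


@pytest.mark.parametrize(
    "num, den, expected",
    [(11, 13, 85), (12, 18, 67), (11, 17, 65), (12, 15, 80),
     (0, 10, 0), (1, 8, 13), (592, 705, 84), (113, 705, 16)],
)
def test_percent_rounded(num, den, expected):
    assert percent_rounded(num, den) == expected


def test_percent_rounded_half_away_from_zero_and_zero_denominator():
    assert percent_rounded(1, 200) == 1          # 0.5 -> 1
    assert percent_rounded(-1, 200) == -1        # -0.5 -> -1
    with pytest.raises(ZeroDivisionError):
        percent_rounded(1, 0)


class TestMeanSem:
    def test_constant_list(self):
        assert mean_sem([2, 2, 2]) == (2.0, 0.0)

    def test_two_values_hand_computed(self):
        mean, sem = mean_sem([0, 1])
        assert mean == pytest.approx(0.5)
        assert sem == pytest.approx(0.5)  # sd = sqrt(0.5), sem = sd/sqrt(2)

    def test_single_value_flagged_undefined(self):
        mean, sem = mean_sem([5])
        assert mean == 5.0 and math.isnan(sem)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mean_sem([])


class TestStudentT:
    def test_identical_groups(self):
        r = two_sample_t([1, 2, 3], [1, 2, 3])
        assert r.t == pytest.approx(0.0) and r.p == pytest.approx(1.0)
        assert not r.significant

    def test_degenerate_zero_variance_equal_means(self):
        r = two_sample_t([2, 2], [2, 2])
        assert (r.t, r.p) == (0.0, 1.0)

    def test_clear_separation_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1e-3, 4)
        b = 1 + rng.normal(0, 1e-3, 4)
        r = two_sample_t(a, b)
        assert r.p < 0.05 and r.significant

    def test_hand_computed_example(self):
        # pooled sd = 1, se = sqrt(2/3), t = -1/0.8165
        r = two_sample_t([1, 2, 3], [2, 3, 4])
        assert r.t == pytest.approx(-1.224745, abs=1e-6)
        assert r.df == 4
        assert r.p == pytest.approx(0.2878641, abs=1e-6)

    def test_insufficient_n(self):
        with pytest.raises(ValueError):
            two_sample_t([1], [1, 2])

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
    )
    @settings(deadline=None, max_examples=80)
    def test_agrees_with_reference_implementation(self, a, b):
        r = two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        if math.isinf(r.t) or (r.t == 0 and math.isnan(ref.statistic)):
            return  # scipy returns nan for zero pooled variance
        assert r.t == pytest.approx(ref.statistic, abs=1e-9)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_welch_option(self):
        r = two_sample_t([1, 2, 3, 9], [2, 2, 2, 2], welch=True)
        ref = sps.ttest_ind([1, 2, 3, 9], [2, 2, 2, 2], equal_var=False)
        assert r.t == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)


class TestIsFunctional:
    def _ann(self, mouse, pos, alt_len=1):
        ref = mouse.sequence[pos - 1 : pos - 1 + alt_len] if alt_len > 1 \
            else mouse.base_at(pos)
        alt = ref[0] if alt_len > 1 else ("A" if ref != "A" else "G")
        return annotate_variant(_Var(pos, ref, alt), mouse)

    def test_rna_variant_functional(self, mouse):
        assert is_functional(self._ann(mouse, 2080))

    def test_protein_indel_functional(self, mouse):
        ann = self._ann(mouse, 13053, alt_len=2)
        assert ann.substitution_class == "indel" and is_functional(ann)

    def test_ncr_variant_not_functional(self, mouse):
        ann = self._ann(mouse, 15800)
        assert ann.effect == "NCR" and not is_functional(ann)

    def test_synonymous_vs_nonsynonymous(self, mouse):
        # scan a protein gene until both effect kinds are seen
        feat = mouse.feature_by_name("mt-Nd1")
        seen = {}
        for pos in range(feat.start, feat.end + 1):
            ref = mouse.base_at(pos)
            for alt in sorted(set("ACGT") - {ref}):
                ann = annotate_variant(_Var(pos, ref, alt), mouse)
                seen.setdefault(ann.effect, ann)
            if {"synonymous", "non_synonymous"} <= set(seen):
                break
        assert is_functional(seen["non_synonymous"])
        assert not is_functional(seen["synonymous"])


class TestSummarizeCohort:
    def _cohort(self, mouse):
        """One old-wt animal: 3 germline variants in all 7 tissues, one
        embryonic in liver, no somatic; plus a clean young-wt animal."""
        meta_old = animal_meta("old1", n_clones=3, age_group="old")
        meta_young = animal_meta("y1", n_clones=3, age_group="young")
        tissues = [s for s, m in meta_old.items() if m.level == "bulk"]
        germ_positions = (3366, 13029, 2080)
        dets = {}
        for i, p in enumerate(germ_positions):
            ref = mouse.base_at(p)
            dets[(p, ref, "A" if ref != "A" else "G")] = {
                s: 20.0 + i for s in tissues
            }
        ref = mouse.base_at(9056)
        dets[(9056, ref, "A" if ref != "A" else "G")] = {"old1_liver": 7.0}
        m_old = make_matrix(dets, meta_old, "old1")
        m_young = make_matrix({}, meta_young, "y1")
        manifest = {**meta_old, **meta_young}
        matrices = {"old1": m_old, "y1": m_young}
        origin_calls = classify_all(m_old)
        annotations = {
            k: annotate_variant(_Var(*k), mouse) for k in dets
        }
        return matrices, origin_calls, annotations, manifest

    def test_germline_mean_matches_brute_force_recount(self, mouse):
        matrices, oc, ann, manifest = self._cohort(mouse)
        s = summarize_cohort(matrices, oc, ann, manifest)
        row = s.counts[(s.counts.age_group == "old")
                       & (s.counts.origin == "germline")].iloc[0]
        # brute force: every old bulk tissue carries exactly the 3 germline
        # variants, young tissues carry none
        assert row["mean"] == pytest.approx(3.0)
        assert row["n"] == 7
        assert row["sem"] == pytest.approx(0.0)

    def test_wt_cohort_reports_zero_somatic(self, mouse):
        matrices, oc, ann, manifest = self._cohort(mouse)
        s = summarize_cohort(matrices, oc, ann, manifest)
        som = s.counts[s.counts.origin == "somatic"]
        assert (som["mean"] == 0).all()

    def test_spectrum_fractions_sum_to_one(self, mouse):
        matrices, oc, ann, manifest = self._cohort(mouse)
        s = summarize_cohort(matrices, oc, ann, manifest)
        for _, sub in s.spectrum.groupby(["genotype", "age_group"]):
            assert sub["fraction"].sum() == pytest.approx(1.0)
        for _, sub in s.complex_dist.groupby(["genotype", "age_group"]):
            assert sub["fraction"].sum() == pytest.approx(1.0)

    def test_young_vs_old_germline_contrast_present(self, mouse):
        matrices, oc, ann, manifest = self._cohort(mouse)
        s = summarize_cohort(matrices, oc, ann, manifest)
        r = s.tests["wt_germline_young_vs_old"]
        assert r.p < 0.05  # 0 per tissue young vs 3 per tissue old
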
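"""The quartile filter: group quantiles, rule evaluation, full runs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylmine.core import (
    CALL_CLASSES,
    FilterConfig,
    classify_probe,
    group_quartiles,
    run_filter,
    tally_calls,
)
from methylmine.synthetic import SimulationConfig, simulate_cohort

from _oracles import classify_literal

CODES = ["X", "Y"]


def _manifest(codes, n_t=4, n_n=4):
    rows = []
    for code in codes:
        rows += [(f"{code}_T{i}", code, "primary_tumor") for i in range(n_t)]
        rows += [(f"{code}_N{i}", code, "normal_tissue") for i in range(n_n)]
    return pd.DataFrame(rows, columns=["sample_id", "cancer_code", "tissue_type"]).set_index("sample_id")


def _profile(vals: dict) -> dict:
    """(cancer, tissue) -> constant value, as a (q1, q3) profile."""
    return {k: (v, v) if np.isscalar(v) else v for k, v in vals.items()}


class TestGroupQuartiles:
    def test_constant_group(self):
        mf = _manifest(CODES)
        m = pd.DataFrame([[0.4] * 16], index=pd.Index(["cg1"], name="probe_id"),
                         columns=mf.index)
        q = group_quartiles(m, mf)
        assert (q["q1"] == 0.4).all() and (q["q3"] == 0.4).all()

    def test_linear_interpolation_values(self):
        # {0.1, 0.2, 0.3, 0.4}: hand interpolation gives Q1=0.175, Q3=0.325
        mf = _manifest(["X", "Y"], n_t=4, n_n=4)
        row = [0.1, 0.2, 0.3, 0.4] * 4
        m = pd.DataFrame([row], index=pd.Index(["cg1"], name="probe_id"), columns=mf.index)
        q = group_quartiles(m, mf).set_index(["cancer_code", "tissue_type"])
        assert q.loc[("X", "primary_tumor"), "q1"] == pytest.approx(0.175)
        assert q.loc[("X", "primary_tumor"), "q3"] == pytest.approx(0.325)

    def test_missing_values_excluded(self):
        mf = _manifest(["X", "Y"], n_t=5, n_n=4)
        row = [0.1, 0.2, 0.3, 0.4, np.nan] + [0.5] * 4 + [0.5] * 9
        m = pd.DataFrame([row], index=pd.Index(["cg1"], name="probe_id"), columns=mf.index)
        q = group_quartiles(m, mf).set_index(["cancer_code", "tissue_type"])
        assert q.loc[("X", "primary_tumor"), "q1"] == pytest.approx(0.175)
        assert q.loc[("X", "primary_tumor"), "n"] == 4

    def test_small_group_flagged_uncallable(self):
        mf = _manifest(["X", "Y"], n_t=3, n_n=3)
        row = [np.nan, np.nan, 0.5] + [0.5] * 9
        m = pd.DataFrame([row], index=pd.Index(["cg1"], name="probe_id"), columns=mf.index)
        q = group_quartiles(m, mf, FilterConfig(min_group_size=2))
        sub = q.set_index(["cancer_code", "tissue_type"])
        assert np.isnan(sub.loc[("X", "primary_tumor"), "q1"])

    def test_missing_tissue_type_errors(self):
        mf = _manifest(["X", "Y"]).query("not (cancer_code == 'X' and tissue_type == 'normal_tissue')")
        m = pd.DataFrame([[0.5] * len(mf)], index=pd.Index(["cg1"], name="probe_id"),
                         columns=mf.index)
        with pytest.raises(ValueError, match="normal_tissue"):
            group_quartiles(m, mf)


class TestClassifyProbe:
    def test_forced_cancer_hyper(self):
        prof = _profile({("X", "primary_tumor"): 0.8, ("X", "normal_tissue"): 0.1,
                         ("Y", "primary_tumor"): 0.1, ("Y", "normal_tissue"): 0.1})
        assert classify_probe(prof, "X", CODES) == "cancer_hyper"

    def test_forced_tissue_hypo(self):
        prof = _profile({("X", "primary_tumor"): 0.05, ("X", "normal_tissue"): 0.05,
                         ("Y", "primary_tumor"): 0.9, ("Y", "normal_tissue"): 0.9})
        assert classify_probe(prof, "X", CODES) == "tissue_hypo"

    def test_boundary_q1_exactly_at_threshold_is_none(self):
        # strict inequality: Q1 == 0.6 does not fire the hyper rule
        prof = _profile({("X", "primary_tumor"): 0.6, ("X", "normal_tissue"): 0.1,
                         ("Y", "primary_tumor"): 0.1, ("Y", "normal_tissue"): 0.1})
        assert classify_probe(prof, "X", CODES) == "none"

    def test_missing_group_is_uncallable(self):
        prof = _profile({("X", "primary_tumor"): 0.8, ("X", "normal_tissue"): 0.1,
                         ("Y", "primary_tumor"): 0.1,
                         ("Y", "normal_tissue"): (np.nan, np.nan)})
        assert classify_probe(prof, "X", CODES) == "none"

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=32, max_size=32))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_literal_oracle(self, flat):
        """classify_probe matches a literal sorted-values rule evaluation."""
        groups = {}
        it = iter(flat)
        for code in CODES:
            for tissue in ("primary_tumor", "normal_tissue"):
                groups[(code, tissue)] = [next(it) for _ in range(8)]
        from _oracles import hand_quantile
        prof = {k: (hand_quantile(v, 0.25), hand_quantile(v, 0.75))
                for k, v in groups.items()}
        for target in CODES:
            assert classify_probe(prof, target, CODES) == classify_literal(
                groups, target, CODES)


class TestRunFilter:
    def test_midrange_background_gets_no_calls(self, two_cancer_manifest):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(0.45 + 0.1 * rng.random((5, 16)),
                         index=pd.Index([f"cg{i}" for i in range(5)], name="probe_id"),
                         columns=two_cancer_manifest.index)
        table = run_filter(m, two_cancer_manifest)
        assert all(c.call_class == "none" for c in table.calls)

    def test_single_cancer_errors(self):
        mf = _manifest(["X"])
        m = pd.DataFrame([[0.5] * 8], index=pd.Index(["cg1"], name="probe_id"),
                         columns=mf.index)
        with pytest.raises(ValueError, match="2 cancer"):
            run_filter(m, mf)

    def test_planted_probes_recovered(self, standard_cohort):
        table = run_filter(standard_cohort.beta, standard_cohort.manifest)
        called = {(c.probe_id, c.call_class, c.target_cancer)
                  for c in table.calls if c.call_class != "none"}
        truth = set(map(tuple, standard_cohort.truth.values))
        assert called == truth

    def test_column_permutation_invariance(self, standard_cohort):
        beta = standard_cohort.beta.iloc[:60]
        rng = np.random.default_rng(7)
        perm = list(rng.permutation(beta.columns))
        a = run_filter(beta, standard_cohort.manifest).to_frame()
        b = run_filter(beta[perm], standard_cohort.manifest).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_threshold_monotonicity(self, standard_cohort):
        loose = run_filter(standard_cohort.beta, standard_cohort.manifest,
                           FilterConfig(0.6, 0.3)).called()
        tight = run_filter(standard_cohort.beta, standard_cohort.manifest,
                           FilterConfig(0.7, 0.2)).called()
        assert tight <= loose

    def test_at_most_one_class_per_target(self, standard_cohort):
        """A probe cannot satisfy two classes for the same target when
        hypo < hyper; long-format output must respect that."""
        table = run_filter(standard_cohort.beta, standard_cohort.manifest)
        seen = set()
        for c in table.all_calls:
            key = (c.probe_id, c.target_cancer)
            assert key not in seen
            seen.add(key)


class TestTally:
    def test_empty_calls_all_zero(self):
        grid = tally_calls([], ["X", "Y"])
        assert (grid.to_numpy() == 0).all()
        assert grid.shape == (4, 2)

    def test_counts_and_total(self, standard_cohort):
        table = run_filter(standard_cohort.beta, standard_cohort.manifest)
        grid = table.tally
        n_called = sum(1 for c in table.calls if c.call_class != "none")
        assert grid.to_numpy().sum() == n_called
        assert grid.loc["Cancer-specific hypermethylation", "BRCA"] == 10
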
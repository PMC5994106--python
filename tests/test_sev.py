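import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sevscan import sev
from sevscan.errors import ValidationError

from conftest import fivenum_oracle


def _ref(values_by_probe: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(values_by_probe, orient="index").astype(float)


def _brute_force_calls(reference: np.ndarray, subject: np.ndarray, multiplier=3.0):
    """Independent oracle: sort, five-number summary, strict fence compare."""
    calls = []
    for i in range(len(subject)):
        q1, q3 = fivenum_oracle(reference[i])
        iqr = q3 - q1
        lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
        if subject[i] < lo:
            calls.append((i, "low"))
        elif subject[i] > hi:
            calls.append((i, "high"))
    return set(calls)


# ---------------------------------------------------------------------------
# fences
# ---------------------------------------------------------------------------

def test_constant_locus_collapsed_fences():
    ref = _ref({"cg1": [0.5] * 12})
    f = sev.compute_fences(ref, min_n=10)
    row = f.loc["cg1"]
    assert row["q1"] == row["q3"] == 0.5
    assert row["iqr"] == 0.0
    assert (row["lower"], row["upper"]) == (0.5, 0.5)


def test_fence_formula_three_iqr():
    # hinges (0.2, 0.4) -> fences (0.2 - 0.6, 0.4 + 0.6) = (-0.4, 1.0)
    ref = _ref({"cg1": [0.10, 0.20, 0.30, 0.40, 0.50]})
    f = sev.compute_fences(ref, min_n=5)
    row = f.loc["cg1"]
    assert row["q1"] == pytest.approx(0.2)
    assert row["q3"] == pytest.approx(0.4)
    assert row["lower"] == pytest.approx(-0.4)
    assert row["upper"] == pytest.approx(1.0)
    lo, hi = fivenum_oracle(np.array([0.1, 0.2, 0.3, 0.4, 0.5]))
    assert (row["q1"], row["q3"]) == (lo, hi)


def test_fences_not_clipped_to_unit_interval():
    ref = _ref({"cg1": [0.05, 0.1, 0.1, 0.15, 0.9, 0.92, 0.95]})
    f = sev.compute_fences(ref, min_n=5)
    assert f.loc["cg1", "lower"] < 0 and f.loc["cg1", "upper"] > 1


def test_min_n_marks_probes_unusable():
    vals = [0.1] * 12
    sparse = [0.1, 0.2, np.nan, np.nan, np.nan, np.nan, np.nan] + [np.nan] * 5
    ref = _ref({"dense": vals, "sparse": sparse})
    f = sev.compute_fences(ref, min_n=10)
    assert f.loc["dense", "usable"]
    assert not f.loc["sparse", "usable"]
    subject = pd.Series({"dense": 0.1, "sparse": 0.99}, name="s")
    cs = sev.call_sevs(subject, f)
    assert cs.n_sev == 0 and cs.n_skipped == 1


def test_too_small_reference_errors():
    ref = _ref({"cg1": [0.1, 0.2, 0.3]})
    with pytest.raises(ValidationError, match="min_n"):
        sev.compute_fences(ref, min_n=10)


def test_linear_quantile_option_matches_numpy():
    rng = np.random.default_rng(4)
    ref = pd.DataFrame(rng.random((20, 15)), index=[f"cg{i}" for i in range(20)])
    f = sev.compute_fences(ref, min_n=10, quantile_method="linear")
    np.testing.assert_allclose(
        f["q1"].to_numpy(), np.quantile(ref.to_numpy(), 0.25, axis=1), rtol=1e-12
    )
    np.testing.assert_allclose(
        f["q3"].to_numpy(), np.quantile(ref.to_numpy(), 0.75, axis=1), rtol=1e-12
    )


def test_hinges_match_oracle_with_missing_values():
    rng = np.random.default_rng(5)
    vals = rng.random(14)
    row = np.concatenate([vals, [np.nan, np.nan]])
    ref = _ref({"cg1": list(row)})
    f = sev.compute_fences(ref, min_n=10)
    lo, hi = fivenum_oracle(vals)
    assert f.loc["cg1", "q1"] == pytest.approx(lo, abs=1e-12)
    assert f.loc["cg1", "q3"] == pytest.approx(hi, abs=1e-12)
    assert f.loc["cg1", "n_reference"] == 14


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def test_central_subject_has_no_sevs():
    rng = np.random.default_rng(6)
    ref = pd.DataFrame(rng.random((30, 15)), index=[f"cg{i}" for i in range(30)])
    f = sev.compute_fences(ref, min_n=10)
    median = ref.median(axis=1)
    cs = sev.call_sevs(median.rename("med"), f)
    assert cs.n_sev == 0
    assert cs.log_offset_used and cs.log_sev == 0.0


def test_strict_inequality_at_fence():
    ref = _ref({"cg1": [0.10, 0.20, 0.30, 0.40, 0.50]})  # fences (-0.4, 1.0)
    f = sev.compute_fences(ref, min_n=5)
    at_fence = sev.call_sevs(pd.Series({"cg1": 1.0}, name="a"), f)
    assert at_fence.n_sev == 0  # exactly on the fence is not an outlier
    near = sev.call_sevs(pd.Series({"cg1": 0.95}, name="b"), f)
    assert near.n_sev == 0  # 0.95 < 1.0
    ref2 = _ref({"cg1": [0.40, 0.45, 0.50, 0.55, 0.60]})  # fences (0.15, 0.85)
    f2 = sev.compute_fences(ref2, min_n=5)
    beyond = sev.call_sevs(pd.Series({"cg1": 0.86}, name="c"), f2)
    assert beyond.probes == {("cg1", "high")}


def test_missing_subject_values_never_flagged():
    ref = _ref({"cg1": [0.40, 0.45, 0.50, 0.55, 0.60]})
    f = sev.compute_fences(ref, min_n=5)
    cs = sev.call_sevs(pd.Series({"cg1": np.nan}, name="s"), f)
    assert cs.n_sev == 0


def test_zero_iqr_probe_called_and_tallied():
    ref = _ref({"cg1": [0.5] * 12})
    f = sev.compute_fences(ref, min_n=10)
    cs = sev.call_sevs(pd.Series({"cg1": 0.5001}, name="s"), f)
    assert cs.probes == {("cg1", "high")}
    assert cs.n_zero_iqr == 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n_probes=st.integers(2, 20),
    n_samples=st.integers(10, 15),
    seed=st.integers(0, 10_000),
)
def test_calls_match_brute_force_oracle(n_probes, n_samples, seed):
    """Fence + call composition equals an independent sort/fivenum oracle."""
    rng = np.random.default_rng(seed)
    reference = rng.random((n_probes, n_samples))
    subject = rng.random(n_probes)
    ref = pd.DataFrame(reference, index=[f"cg{i}" for i in range(n_probes)])
    f = sev.compute_fences(ref, min_n=n_samples)
    cs = sev.call_sevs(pd.Series(subject, index=ref.index, name="s"), f)
    expected = {
        (f"cg{i}", d) for i, d in _brute_force_calls(reference, subject)
    }
    assert cs.probes == expected


def test_monotone_in_fence_multiplier(small_cohort):
    _, _, beta, _, _ = small_cohort
    ref = beta.iloc[:, :20]
    subject = beta.iloc[:, -1]
    narrow = sev.call_sevs(subject, sev.compute_fences(ref, multiplier=3.0))
    wide = sev.call_sevs(subject, sev.compute_fences(ref, multiplier=4.5))
    assert wide.n_sev <= narrow.n_sev
    assert wide.probes <= narrow.probes


def test_permutation_invariance(small_cohort):
    _, _, beta, _, _ = small_cohort
    rng = np.random.default_rng(3)
    ref = beta.iloc[:, :20]
    subject = beta.iloc[:, -1]
    base = sev.call_sevs(subject, sev.compute_fences(ref))
    probe_perm = rng.permutation(len(beta))
    sample_perm = rng.permutation(20)
    ref_p = ref.iloc[probe_perm, sample_perm]
    shuffled = sev.call_sevs(subject.iloc[probe_perm], sev.compute_fences(ref_p))
    assert shuffled.probes == base.probes


# ---------------------------------------------------------------------------
# profiles over reference modes
# ---------------------------------------------------------------------------

def test_profile_composition_matches_manual_calls():
    rng = np.random.default_rng(9)
    probes = [f"cg{i}" for i in range(40)]
    ref = pd.DataFrame(rng.random((40, 12)), index=probes,
                       columns=[f"r{i}" for i in range(12)])
    cohort = pd.DataFrame(rng.random((40, 5)), index=probes,
                          columns=[f"s{i}" for i in range(5)])
    profile = sev.sev_profile(cohort, {"m": ref})
    fences = sev.compute_fences(ref)
    for s in cohort.columns:
        manual = sev.call_sevs(cohort[s], fences, sample_id=s)
        assert profile.call_sets[(s, "m")].probes == manual.probes
        row = profile.summary.query("sample_id == @s")
        assert int(row["n_sev"].iloc[0]) == manual.n_sev
        assert row["log_sev"].iloc[0] == pytest.approx(manual.log_sev)


def test_profile_mode_labels_do_not_matter():
    rng = np.random.default_rng(10)
    probes = [f"cg{i}" for i in range(30)]
    ref = pd.DataFrame(rng.random((30, 11)), index=probes,
                       columns=[f"r{i}" for i in range(11)])
    cohort = pd.DataFrame(rng.random((30, 4)), index=probes,
                          columns=[f"s{i}" for i in range(4)])
    profile = sev.sev_profile(cohort, {"alpha": ref, "omega": ref.copy()})
    pivot = profile.summary.pivot(index="sample_id", columns="mode", values="n_sev")
    assert (pivot["alpha"] == pivot["omega"]).all()


def test_loo_counts_at_least_pooled(small_cohort):
    """A member's own extremes widen pooled fences, so loo >= pooled."""
    _, _, beta, _, _ = small_cohort
    ref = beta.iloc[:, :12]
    cohort = ref  # members only
    pooled = sev.sev_profile(cohort, {"int": ref}, internal_mode="pooled")
    loo = sev.sev_profile(cohort, {"int": ref}, internal_mode="loo")
    p = pooled.summary.set_index("sample_id")["n_sev"]
    l = loo.summary.set_index("sample_id")["n_sev"]
    assert (l >= p).all()


def test_loo_flags_deviant_member_constant_reference():
    # three members constant at 0.5, one deviant member: pooled fences are
    # widened by its own value, loo fences are not
    probes = ["cg1"]
    ref = pd.DataFrame([[0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.9]],
                       index=probes, columns=[f"r{i}" for i in range(10)])
    profile_loo = sev.sev_profile(ref, {"int": ref}, internal_mode="loo", min_n=9)
    profile_pooled = sev.sev_profile(ref, {"int": ref}, internal_mode="pooled", min_n=9)
    n_loo = profile_loo.summary.set_index("sample_id")["n_sev"]
    n_pooled = profile_pooled.summary.set_index("sample_id")["n_sev"]
    assert n_loo["r9"] == 1  # deviant flagged once its value leaves the fences
    assert n_pooled["r9"] == n_loo["r9"]  # hinges at n=10 ignore the extreme here
    assert (n_loo >= n_pooled).all()


def test_empty_probe_intersection_errors():
    a = pd.DataFrame([[0.5]], index=["cg1"], columns=["s1"])
    b = pd.DataFrame([[0.5]], index=["cg2"], columns=["r1"])
    with pytest.raises(ValidationError, match="intersection"):
        sev.sev_profile(a, {"m": b})


def test_log_sev_is_natural_log():
    assert sev.safe_log_count(100) == (math.log(100), False)
    assert sev.safe_log_count(0) == (0.0, True)
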
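import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribometh import (
    SimTruth,
    estimate_bias,
    apply_bias,
    profile_scores,
    score_c,
    simulate_end_counts,
    simulate_reference,
)
from ribometh.end_counting import EndCountProfile
from ribometh.scoring import BiasCorrection, default_weights


def naive_score_c(counts, bond, half_width=6, weights=None):
    """Direct-summation reference implementation (independent of score_c)."""
    counts = [float(c) for c in counts]
    w = list(weights) if weights is not None else [half_width - j for j in range(half_width)]
    i = bond - 1
    lw = lv = rw = rv = 0.0
    for j in range(1, half_width + 1):
        if i - j >= 0:
            lv += w[j - 1] * counts[i - j]
            lw += w[j - 1]
        if i + j < len(counts):
            rv += w[j - 1] * counts[i + j]
            rw += w[j - 1]
    left, right = lv / lw, rv / rw
    mu = (left + right) / 2
    if mu == 0:
        return 0.0, 0.0
    return min(max(1 - counts[i] / mu, 0.0), 1.0), mu


def test_uniform_counts_score_zero():
    score, cov = score_c(np.full(50, 100.0), 25)
    assert score == 0.0 and cov == 100.0


def test_fully_protected_bond_scores_one():
    counts = np.full(50, 80.0)
    counts[24] = 0.0
    score, _ = score_c(counts, 25)
    assert score == 1.0


def test_worked_example_half_width_two():
    counts = np.array([100, 100, 100, 20, 100, 100, 100], dtype=float)
    score, cov = score_c(counts, 4, half_width=2)
    # left = (2*100 + 1*100)/3 = 100 = right, mu = 100, score = 1 - 20/100
    assert score == pytest.approx(0.80)
    assert cov == pytest.approx(100.0)


def test_excess_cleavage_clips_to_zero():
    counts = np.full(30, 100.0)
    counts[14] = 200.0
    score, _ = score_c(counts, 15)
    assert score == 0.0


def test_all_zero_window():
    score, cov = score_c(np.zeros(30), 10)
    assert score == 0.0 and cov == 0.0


def test_edge_bonds_rejected():
    counts = np.ones(30)
    with pytest.raises(IndexError):
        score_c(counts, 0)
    with pytest.raises(IndexError):
        score_c(counts, 31)


def test_window_truncates_at_edges():
    counts = np.arange(1.0, 16.0)
    got = score_c(counts, 2, half_width=6)
    assert got == pytest.approx(naive_score_c(counts, 2, 6))


def test_matches_naive_oracle_on_random_arrays():
    rng = np.random.default_rng(202)
    for _ in range(1000):
        n = int(rng.integers(5, 60))
        counts = rng.integers(0, 500, size=n).astype(float)
        bond = int(rng.integers(2, n))
        hw = int(rng.integers(1, 8))
        s1, c1 = score_c(counts, bond, hw)
        s2, c2 = naive_score_c(counts, bond, hw)
        assert abs(s1 - s2) <= 1e-12 and abs(c1 - c2) <= 1e-9


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(st.integers(0, 1000), min_size=15, max_size=15),
    st.integers(0, 1000),
    st.integers(0, 900),
)
def test_monotone_in_center_count(counts, n_lo, extra):
    """Holding the neighbors fixed, the score never increases with n[i]."""
    counts = np.array(counts, dtype=float)
    bond = 8
    counts[bond - 1] = n_lo
    s_lo, _ = score_c(counts, bond)
    counts[bond - 1] = n_lo + extra
    s_hi, _ = score_c(counts, bond)
    assert s_hi <= s_lo + 1e-12


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(st.integers(0, 1000), min_size=13, max_size=13),
    st.floats(0.01, 100.0, allow_nan=False),
)
def test_scale_invariance(counts, c):
    counts = np.array(counts, dtype=float)
    s1, _ = score_c(counts, 7)
    s2, _ = score_c(counts * c, 7)
    assert s1 == pytest.approx(s2, abs=1e-9)


def test_default_weights_linear_decay():
    assert list(default_weights(6)) == [6, 5, 4, 3, 2, 1]


def _profile(cleavage, sample="s", rep=1, mol="SIM"):
    return EndCountProfile(sample, rep, mol, cleavage=np.asarray(cleavage, float))


class TestProfileScores:
    def test_all_bonds_cardinality(self):
        prof = _profile(np.full(99, 50.0))  # 100-nt molecule, 99 bonds
        rp = profile_scores(prof, "ALL")
        assert len(rp.frame) == 99
        # the two terminal bonds lack a flank and are error records
        assert rp.frame["valid"].sum() == 97

    def test_zero_depth_all_invalid(self, sim_setup):
        refs, sites, _ = sim_setup
        prof = _profile(np.zeros(refs.length("SIM") - 1))
        rp = profile_scores(prof, sites)
        assert not rp.frame["valid"].any()

    def test_site_on_missing_molecule_is_error_record(self, sim_setup):
        refs, sites, _ = sim_setup
        prof = _profile(np.full(refs.length("SIM") - 1, 100.0), mol="OTHER")
        rp = profile_scores(prof, sites[:3])
        assert len(rp.frame) == 3
        assert (~rp.frame["valid"]).all()
        assert rp.frame["error"].str.contains("not in this profile").all()

    def test_recovers_simulated_fraction(self):
        refs, sites = simulate_reference(1500, 10, seed=31)
        truth = SimTruth(sites=sites, f={s.site_id: 0.9 for s in sites},
                         lam=1000.0, seed=32)
        (prof,) = simulate_end_counts(refs, truth)
        rp = profile_scores(prof, sites)
        assert rp.frame["valid"].all()
        assert np.allclose(rp.frame["score"], 0.9, atol=0.05)


class TestBiasCorrection:
    def test_unbiased_counts_give_unit_factors(self, sim_setup):
        refs, sites, truth = sim_setup
        (prof,) = simulate_end_counts(refs, truth, seed=41)
        corr = estimate_bias(prof, refs, exclude_sites=sites)
        for b, fac in corr.factors.items():
            assert abs(fac - 1.0) < 0.05, (b, fac)

    def test_injected_under_ligation_recovered(self, sim_setup):
        refs, sites, truth = sim_setup
        biased = SimTruth(sites=sites, f=truth.f, lam=truth.lam,
                          bias={"G": 0.5}, seed=43)
        (prof,) = simulate_end_counts(refs, biased, seed=43)
        corr = estimate_bias(prof, refs, exclude_sites=sites)
        others = [v for b, v in corr.factors.items() if b != "G"]
        assert corr.factors["G"] / np.mean(others) == pytest.approx(2.0, rel=0.1)

    def test_sparse_class_falls_back_to_one(self, toy_refs):
        prof = EndCountProfile("s", 1, "SSU", cleavage=np.full(119, 10.0))
        corr = estimate_bias(prof, toy_refs, min_bonds_per_class=1000)
        assert all(v == 1.0 for v in corr.factors.values())

    def test_identity_correction_is_noop(self, sim_setup):
        refs, sites, truth = sim_setup
        (prof,) = simulate_end_counts(refs, truth, seed=44)
        out = apply_bias(prof, BiasCorrection({b: 1.0 for b in "ACGU"}), refs)
        assert np.array_equal(out.cleavage, prof.cleavage)

    def test_correction_is_local_to_nucleotide_class(self, sim_setup):
        refs, _, truth = sim_setup
        (prof,) = simulate_end_counts(refs, truth, seed=45)
        corr = BiasCorrection({"A": 1.0, "C": 1.0, "G": 2.0, "U": 1.0})
        out = apply_bias(prof, corr, refs)
        seq = refs["SIM"]
        for k in range(0, prof.length - 1, 97):
            expected = corr.factors["G"] if seq[k].upper() == "G" else corr.factors["A"]
            assert out.cleavage[k] == pytest.approx(prof.cleavage[k] * expected)

    def test_correction_reduces_score_error(self, sim_setup):
        refs, sites, truth = sim_setup
        biased = SimTruth(sites=sites, f=truth.f, lam=truth.lam,
                          bias={"G": 0.5, "A": 1.3}, seed=47)
        (prof,) = simulate_end_counts(refs, biased, seed=47)
        f_true = np.array([truth.f[s.site_id] for s in sites])
        raw = profile_scores(prof, sites).frame["score"].to_numpy()
        corr = estimate_bias(prof, refs, exclude_sites=sites)
        fixed = profile_scores(apply_bias(prof, corr, refs), sites).frame["score"].to_numpy()
        rmse_raw = np.sqrt(np.mean((raw - f_true) ** 2))
        rmse_fix = np.sqrt(np.mean((fixed - f_true) ** 2))
        assert rmse_fix < rmse_raw
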
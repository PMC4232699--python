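"""TFN and FPT normalization procedures."""

import numpy as np
import pytest

from trflpkit import (
    DataError,
    DetectionConfig,
    NormalizationConfig,
    Peak,
    fpt_normalize,
    tfn_normalize,
    total_fluorescence,
)
from trflpkit.normalization import METHOD_CONFIGS

from conftest import make_profile


def test_tfn_hand_trace_single_removal():
    """{2000,120} vs TFmin 1500, threshold 100: the 120 peak scales to 84.9,
    is removed, and the survivor rescales to exactly 1500."""
    p1 = make_profile("P1", [100, 200], [1000, 500])
    p2 = make_profile("P2", [100, 200], [2000, 120])
    out = tfn_normalize([p1, p2], detection=DetectionConfig(pdt=100))
    assert out[0].peaks == p1.peaks  # the TFmin profile is untouched
    assert [(p.size, p.height) for p in out[1].peaks] == [(100, 1500.0)]


def test_tfn_equal_tf_profiles_unchanged():
    ps = [
        make_profile("A", [100, 200], [600, 400]),
        make_profile("B", [110, 210], [700, 300]),
    ]
    out = tfn_normalize(ps, detection=DetectionConfig(pdt=50))
    for before, after in zip(ps, out):
        assert [(p.size, p.height) for p in before.peaks] == [
            (p.size, p.height) for p in after.peaks
        ]


def test_tfn_two_state_cycle_is_averaged():
    """A peak straddling the threshold makes TF alternate around TFmin; the
    output is the peak-wise average of the two states (exact hand trace:
    c = 1000/1055 then c' = 1000/950)."""
    pmin = make_profile("M", [100], [1000])
    posc = make_profile("C", [100, 200], [950, 105])
    out = tfn_normalize([pmin, posc], detection=DetectionConfig(pdt=100))
    heights = {p.size: p.height for p in out[1].peaks}
    c1, c2 = 1000.0 / 1055.0, 1000.0 / 950.0
    assert heights[100] == pytest.approx((950 * c1 + 950 * c2) / 2, abs=1e-9)
    assert heights[200] == pytest.approx((0 + 105 * c2) / 2, abs=1e-9)
    # the averaged sub-threshold peak is retained
    assert heights[200] < 100


def test_tfn_contract_final_tf_equals_tfmin(rng):
    """After TFN every non-cycle profile's TF is TFmin to 1e-9 relative;
    cycle-averaged profiles are within half the contested peak's signal."""
    profiles = []
    for i in range(8):
        n = int(rng.integers(3, 12))
        heights = rng.uniform(60, 3000, n)
        sizes = np.sort(rng.uniform(50, 1000, n))
        sizes += np.arange(n) * 1e-3
        profiles.append(make_profile(f"P{i}", sizes, heights))
    out = tfn_normalize(profiles, detection=DetectionConfig(pdt=50))
    tfmin = min(total_fluorescence(p) for p in profiles)
    for prof in out:
        tf = total_fluorescence(prof)
        if prof.provenance and "cycle-averaged" in prof.provenance[-1]:
            contested = min(p.height for p in prof.peaks)
            assert abs(tf - tfmin) <= contested / 2 + 1e-6
        else:
            assert abs(tf - tfmin) / tfmin <= 1e-9


def test_tfn_idempotent_and_never_grows(rng):
    profiles = [
        make_profile("A", [100, 200, 300], [900, 500, 70]),
        make_profile("B", [100, 200, 300], [2000, 800, 90]),
    ]
    out = tfn_normalize(profiles, detection=DetectionConfig(pdt=50))
    assert all(len(a) <= len(b) for a, b in zip(out, profiles))
    again = tfn_normalize(out, detection=DetectionConfig(pdt=50))
    for a, b in zip(out, again):
        assert len(a) == len(b)
        assert np.allclose(
            [(p.size, p.height) for p in a.peaks],
            [(p.size, p.height) for p in b.peaks],
            rtol=1e-9,
        )


def test_tfn_area_rules_resolve_thresholds():
    a = make_profile("A", [100, 200], [500, 100], areas=[5000, 900])
    b = make_profile("B", [100, 200], [800, 300], areas=[9000, 2500])
    out = tfn_normalize(
        [a, b], METHOD_CONFIGS["TFN-areas-LT"], DetectionConfig(pdt=50)
    )
    # threshold is the local minimum area (900): B's small peak scales to
    # 2500 * (5900/11500) = 1282.6 >= 900, so B keeps both peaks
    assert len(out[1]) == 2
    tf = total_fluorescence(out[1], "area")
    assert tf == pytest.approx(5900.0, rel=1e-9)


def test_tfn_requires_area_data_for_area_basis():
    a = make_profile("A", [100], [500])  # no areas
    b = make_profile("B", [100], [800])
    with pytest.raises(DataError, match="area"):
        tfn_normalize([a, b], METHOD_CONFIGS["TFN-areas"], DetectionConfig())


def test_tfn_degenerate_empty_anchor():
    a = make_profile("A", [], [])
    b = make_profile("B", [100], [800])
    with pytest.raises(DataError, match="TFmin"):
        tfn_normalize([a, b], detection=DetectionConfig())


def test_tfn_reduces_count_tf_dependence(rng):
    """Before TFN-heights the number of retained T-RFs grows with TF;
    afterwards the dependence is gone (loading-duplicate structure)."""
    true_ab = rng.dirichlet(np.ones(30) * 0.4)
    sizes = np.sort(rng.uniform(60, 1000, 30)) + np.arange(30) * 1e-3
    profiles, tf0 = [], []
    for i in range(40):
        mult = rng.uniform(0.7, 1.3)
        heights = true_ab * 8000 * mult
        keep = heights >= 50
        profiles.append(make_profile(f"L{i}", sizes[keep], heights[keep]))
        tf0.append(heights[keep].sum())
    counts_before = np.array([len(p) for p in profiles])
    r_before = np.corrcoef(counts_before, tf0)[0, 1]
    out = tfn_normalize(profiles, detection=DetectionConfig(pdt=50))
    counts_after = np.array([len(p) for p in out])
    if counts_after.std() == 0:
        r_after = 0.0
    else:
        r_after = np.corrcoef(counts_after, tf0)[0, 1]
    assert r_before > 0.5
    assert abs(r_after) < 0.3


def test_fpt_removes_below_threshold_only():
    prof = make_profile("P", [100, 200, 300], [970, 25, 5])
    out = fpt_normalize(prof)
    assert [p.height for p in out.peaks] == [970, 25]
    # signals are not rescaled and survivors stay above the original-profile
    # abundance threshold
    total = 1000.0
    assert all(p.height / total >= 0.01 for p in out.peaks)


def test_fpt_boundary_and_identity():
    prof = make_profile("P", [100, 200], [990, 10])  # 10/1000 is exactly 1%
    out = fpt_normalize(prof)
    assert len(out) == 2
    tiny = NormalizationConfig(method="FPT", fpt_fraction=1e-12)
    assert fpt_normalize(prof, tiny).peaks == prof.peaks


def test_fpt_all_removed_warns():
    prof = make_profile("P", [100, 200], [50, 50])
    cfg = NormalizationConfig(method="FPT", fpt_fraction=0.9)
    with pytest.warns(UserWarning, match="removed"):
        out = fpt_normalize(prof, cfg)
    assert len(out) == 0


def test_config_validation():
    with pytest.raises(DataError, match="fpt_fraction"):
        NormalizationConfig(method="FPT", fpt_fraction=1.5)
    with pytest.raises(DataError, match="PDT"):
        NormalizationConfig(method="TFN", basis="height", threshold_rule="global_min_area")
    with pytest.raises(DataError, match="area threshold"):
        NormalizationConfig(method="TFN", basis="area", threshold_rule="pdt")
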
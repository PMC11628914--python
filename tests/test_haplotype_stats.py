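"""EHH/EHHS profiles, gap-capped integration, Rsb/xpEHH standardization.

The independent oracle for the decay curves is a brute-force pairwise
counter: for every pair of haplotypes, check identity over the closed
interval by direct comparison, no partition refinement involved.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan.haplotype_stats import (
    DegenerateScanError,
    EHHProfile,
    ehh_profile,
    ehhs_profile,
    integrate_profile,
    null_diagnostic,
    rsb,
    scan_hh,
    xpehh,
)

from conftest import make_panel, random_panel


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_ehh(H, focal, core_allele, t):
    """Pairwise identical-fraction among core-allele carriers over [focal, t]."""
    lo, hi = min(focal, t), max(focal, t)
    carriers = np.flatnonzero(H[:, focal] == core_allele)
    n = carriers.size
    if n < 2:
        return float("nan")
    same = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.array_equal(H[carriers[i], lo : hi + 1], H[carriers[j], lo : hi + 1]):
                same += 1
    return same / (n * (n - 1) / 2)


def brute_ehhs(H, focal, t):
    """Pairwise identical-fraction among all haplotypes over [focal, t]."""
    lo, hi = min(focal, t), max(focal, t)
    n = H.shape[0]
    same = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.array_equal(H[i, lo : hi + 1], H[j, lo : hi + 1]):
                same += 1
    return same / (n * (n - 1) / 2)


class TestEHHProfile:
    def test_identical_carriers_give_unit_profile(self):
        panel = make_panel([[0, 1, 0, 1]] * 4 + [[1, 0, 1, 0]])
        left, right = ehh_profile(panel, 1, 1)
        assert np.all(left.values == 1.0) and np.all(right.values == 1.0)

    def test_four_carrier_worked_example(self):
        # carriers extend as AB, AB, AC, AD: one identical pair out of six
        panel = make_panel(
            [
                [0, 0, 0],  # A B
                [0, 0, 0],  # A B
                [0, 1, 0],  # A C
                [0, 0, 1],  # A D
            ]
        )
        left, right = ehh_profile(panel, 0, 0)
        assert right.values[0] == 1.0
        assert right.values[2] == pytest.approx(1 / 6)  # only the AB pair survives

    def test_single_carrier_is_undefined(self):
        panel = make_panel([[1, 0], [0, 0], [0, 1]])
        assert ehh_profile(panel, 0, 1) == (None, None)

    def test_matches_brute_force_on_random_panels(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 31))
            m = int(rng.integers(5, 61))
            panel = random_panel(rng, n, m)
            H = panel.alleles
            focal = int(rng.integers(m))
            for allele in (0, 1):
                if (H[:, focal] == allele).sum() < 2:
                    continue
                left, right = ehh_profile(panel, focal, allele)
                for prof, step in ((left, -1), (right, 1)):
                    for k in range(prof.values.size):
                        t = focal + step * k
                        assert prof.values[k] == pytest.approx(
                            brute_ehh(H, focal, allele, t), abs=1e-12
                        )


class TestEHHSProfile:
    def test_focal_values_two_two_split(self):
        panel = make_panel([[0, 0], [0, 1], [1, 0], [1, 1]])
        left_u, _ = ehhs_profile(panel, 0, normalized=False)
        left_n, _ = ehhs_profile(panel, 0, normalized=True)
        assert left_u.values[0] == pytest.approx(1 / 3)  # (1+1)/6
        assert left_n.values[0] == pytest.approx(1.0)

    def test_all_identical_haplotypes_monomorphic_focal_missing(self):
        panel = make_panel([[0, 1, 0]] * 5)
        assert ehhs_profile(panel, 1) == (None, None)

    def test_all_distinct_at_next_marker_zero_beyond(self):
        panel = make_panel([[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]])
        _, right = ehhs_profile(panel, 0)
        assert right.values[1] == 0.0
        assert right.values.size == 2  # refinement never coarsens: stays 0

    def test_matches_brute_force_on_random_panels(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 31))
            m = int(rng.integers(5, 61))
            panel = random_panel(rng, n, m)
            H = panel.alleles
            focal = int(rng.integers(m))
            result = ehhs_profile(panel, focal, normalized=False)
            col = H[:, focal]
            if np.all(col == col[0]):
                assert result == (None, None)
                continue
            left, right = result
            for prof, step in ((left, -1), (right, 1)):
                for k in range(prof.values.size):
                    assert prof.values[k] == pytest.approx(
                        brute_ehhs(H, focal, focal + step * k), abs=1e-12
                    )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_profiles_monotone_non_increasing_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, int(rng.integers(3, 20)), int(rng.integers(4, 40)))
        focal = int(rng.integers(panel.n_markers))
        result = ehhs_profile(panel, focal)
        if result == (None, None):
            return
        for prof in result:
            assert np.all(prof.values >= 0) and np.all(prof.values <= 1)
            assert np.all(np.diff(prof.values) <= 1e-12)


class TestIntegrateProfile:
    def _flat(self, positions_left, positions_right, value=1.0):
        left = EHHProfile(
            0, "left", np.full(len(positions_left), value),
            np.array(positions_left, dtype=np.int64),
        )
        right = EHHProfile(
            0, "right", np.full(len(positions_right), value),
            np.array(positions_right, dtype=np.int64),
        )
        return left, right

    def test_unit_profile_gives_span(self):
        left, right = self._flat([50_000, 20_000, 0], [50_000, 80_000, 100_000])
        assert integrate_profile(left, right) == pytest.approx(100_000)

    def test_large_gap_capped_at_scalegap(self):
        left, right = self._flat([0], [0, 10_000_000])
        area = integrate_profile(left, right, scalegap_bp=2_500_000)
        assert area == pytest.approx(2_500_000)

    def test_truncation_stops_at_first_subthreshold_marker(self):
        right = EHHProfile(
            0, "right", np.array([1.0, 0.5, 0.04, 0.5]),
            np.array([0, 1000, 2000, 3000], dtype=np.int64),
        )
        left = EHHProfile(0, "left", np.array([1.0]), np.array([0], dtype=np.int64))
        area = integrate_profile(left, right, trunc=0.05)
        assert area == pytest.approx(0.75 * 1000)  # only the first segment

    def test_everywhere_below_trunc_gives_zero(self):
        left, right = self._flat([0, 1000], [0, 1000], value=0.01)
        assert integrate_profile(left, right, trunc=0.05) == 0.0


class TestScanHH:
    def test_monomorphic_panel_all_missing(self):
        panel = make_panel([[0, 0, 0]] * 4)
        scan = scan_hh(panel)
        assert scan["iES"].isna().all() and scan["iNES"].isna().all()

    def test_planted_long_haplotype_raises_focal_ies(self, rng):
        H = (rng.random((40, 41)) < 0.5).astype(np.int8)
        # give 30 of 40 haplotypes an identical 21-marker core segment
        H[:30, 10:31] = H[0, 10:31]
        panel = make_panel(H)
        scan = scan_hh(panel)
        focal_ies = scan["iES"].iloc[20]
        assert focal_ies > np.nanmedian(scan["iES"].to_numpy())

    def test_areas_non_negative_and_bounded_by_capped_span(self, rng):
        panel = random_panel(rng, 15, 30)
        span = panel.map.position_bp[-1] - panel.map.position_bp[0]
        scan = scan_hh(panel)
        ok = scan["iES"].notna()
        assert (scan.loc[ok, "iES"] >= 0).all()
        assert (scan.loc[ok, "iES"] <= span).all()
        assert (scan.loc[ok, "iNES"] >= scan.loc[ok, "iES"] - 1e-9).all()


class TestCrossPopStats:
    def _scan_frames(self, ies_t, ies_r):
        import pandas as pd

        markers = [f"m{i}" for i in range(len(ies_t))]
        t = pd.DataFrame({"marker": markers, "iES": ies_t, "iNES": ies_t})
        r = pd.DataFrame({"marker": markers, "iES": ies_r, "iNES": ies_r})
        return t, r

    def test_equal_scans_are_degenerate(self):
        t, r = self._scan_frames([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateScanError):
            rsb(t, r)

    def test_single_e_fold_ratio_gives_raw_one(self):
        t, r = self._scan_frames([np.e * 2.0, 1.0, 1.0], [2.0, 1.0, 1.0])
        out = rsb(t, r)
        assert out["raw_log_ratio"].iloc[0] == pytest.approx(1.0)
        assert out["raw_log_ratio"].iloc[1] == pytest.approx(0.0)

    def test_rsb_median_zero_xpehh_mean_zero_sd_one(self, rng):
        vals_t = rng.lognormal(14, 0.3, size=500)
        vals_r = rng.lognormal(14, 0.3, size=500)
        t, r = self._scan_frames(vals_t, vals_r)
        out_rsb, out_xp = rsb(t, r), xpehh(t, r)
        assert np.nanmedian(out_rsb["standardized"]) == pytest.approx(0.0, abs=1e-12)
        assert np.nanmean(out_xp["standardized"]) == pytest.approx(0.0, abs=1e-12)
        for out in (out_rsb, out_xp):
            assert np.nanstd(out["standardized"], ddof=1) == pytest.approx(1.0)

    def test_swapping_populations_negates_raw(self, rng):
        vals_t = rng.lognormal(14, 0.3, size=100)
        vals_r = rng.lognormal(14, 0.3, size=100)
        t, r = self._scan_frames(vals_t, vals_r)
        fwd = xpehh(t, r)["raw_log_ratio"].to_numpy()
        rev = xpehh(r, t)["raw_log_ratio"].to_numpy()
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_missing_integrals_propagate(self):
        t, r = self._scan_frames([1.0, np.nan, 3.0, 1.0], [1.0, 2.0, 0.0, 2.0])
        out = xpehh(t, r)
        assert np.isnan(out["raw_log_ratio"].iloc[1])
        assert np.isnan(out["raw_log_ratio"].iloc[2])  # zero integral


class TestNullDiagnostic:
    def test_standard_normal_draws_match_closed_form(self, rng):
        x = rng.standard_normal(10_000)
        out = null_diagnostic(x)
        assert out["frac_beyond_2"] == pytest.approx(0.0455, abs=0.01)
        assert out["normal_discrepancy"] < 0.03
        assert out["mean"] == pytest.approx(0.0, abs=0.05)

    def test_constant_values_flagged_degenerate(self):
        out = null_diagnostic(np.zeros(200))
        assert out["degenerate"]

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match="non-missing"):
            null_diagnostic(np.zeros(10))
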
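from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locusscan.assoc import (
    ContingencyTable,
    UndefinedLDError,
    fisher_exact_2x2,
    ld_r2,
    odds_ratio_ci,
    qt_scan,
    region_wide_permutation,
    segregation_check,
    single_variant_scan,
)
from locusscan.pedigree import Pedigree, PedigreeMember

from _oracles import fisher_two_sided_oracle
from conftest import make_matrix, make_sheet


class TestFisher:
    def test_exchangeable_table(self):
        assert fisher_exact_2x2(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_enumerated_example(self):
        assert fisher_exact_2x2(ContingencyTable(3, 7, 1, 9)) == pytest.approx(
            0.582043, abs=1e-6
        )

    def test_zero_margin_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2(ContingencyTable(0, 5, 0, 5)) == 1.0

    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        """Point-probability two-sided p equals full hypergeometric
        enumeration for tables with margins <= 30."""
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        assert fisher_exact_2x2(ContingencyTable(a, b, c, d)) == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), abs=1e-12
        )


class TestOddsRatio:
    def test_symmetry(self):
        res = odds_ratio_ci(ContingencyTable(10, 10, 10, 10))
        assert res.or_hat == pytest.approx(1.0)

    def test_woolf_example(self):
        res = odds_ratio_ci(ContingencyTable(20, 80, 10, 90))
        assert res.or_hat == pytest.approx(2.25)
        assert res.ci_low == pytest.approx(0.994, abs=1e-3)
        assert res.ci_high == pytest.approx(5.092, abs=1e-3)

    def test_zero_cell_haldane(self):
        res = odds_ratio_ci(ContingencyTable(5, 5, 0, 10))
        assert res.haldane_corrected
        assert np.isfinite(res.or_hat) and res.or_hat > 1

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 40), st.integers(1, 40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_transposition_inverts(self, a, b, c, d):
        """Swapping case/control rows maps OR to 1/OR and swaps the CI
        bounds reciprocally."""
        r1 = odds_ratio_ci(ContingencyTable(a, b, c, d))
        r2 = odds_ratio_ci(ContingencyTable(c, d, a, b))
        assert r2.or_hat == pytest.approx(1 / r1.or_hat)
        assert r2.ci_low == pytest.approx(1 / r1.ci_high)
        assert r2.ci_high == pytest.approx(1 / r1.ci_low)


class TestScan:
    def test_identical_groups_p_one(self):
        calls = np.array([[0], [1], [2], [0], [1], [2]])
        m = make_matrix(calls)
        sheet = make_sheet(["BD"] * 3 + ["control"] * 3)
        res = single_variant_scan(m, sheet, "BD")
        assert res[0].p_raw == pytest.approx(1.0)

    def test_monomorphic_flagged(self):
        m = make_matrix(np.array([[0], [0], [0], [1]]))
        m.variants[0].maf = 0.0
        m.calls[3, 0] = 0
        m.recompute_maf()
        sheet = make_sheet(["SZ", "SZ", "control", "control"])
        res = single_variant_scan(m, sheet, "SZ")
        assert res[0].monomorphic and res[0].p_raw == 1.0 and np.isnan(res[0].or_hat)

    def test_counts_exclude_missing(self):
        calls = np.array([[1], [-1], [0], [2]])
        m = make_matrix(calls)
        sheet = make_sheet(["rMDD", "rMDD", "control", "control"])
        res = single_variant_scan(m, sheet, "rMDD")
        t = res[0].table
        assert (t.a, t.b, t.c, t.d) == (1, 1, 2, 2)


class TestRegionWidePermutation:
    def _null_dataset(self, seed, n=60, v=20):
        rng = np.random.default_rng(seed)
        calls = rng.binomial(2, 0.25, size=(n, v)).astype(np.int8)
        m = make_matrix(calls)
        sheet = make_sheet(["SZ"] * (n // 2) + ["control"] * (n - n // 2))
        return m, sheet

    def test_requires_r_at_least_100(self):
        m, sheet = self._null_dataset(0)
        with pytest.raises(ValueError):
            region_wide_permutation(m, sheet, "SZ", R=50, seed=1)

    def test_single_variant_panel_p_regionwide_tracks_raw(self):
        """With one variant there is no multiplicity: the region-wide
        empirical p approximates the raw p."""
        rng = np.random.default_rng(5)
        calls = rng.binomial(2, 0.4, size=(120, 1)).astype(np.int8)
        calls[:30, 0] = np.minimum(calls[:30, 0] + 1, 2)  # some signal
        m = make_matrix(calls)
        sheet = make_sheet(["SZ"] * 60 + ["control"] * 60)
        res, _ = region_wide_permutation(m, sheet, "SZ", R=2000, seed=2)
        p_raw = res[0].p_raw
        mc_sd = np.sqrt(p_raw * (1 - p_raw) / 2000)
        assert abs(res[0].p_regionwide - p_raw) < 2 * mc_sd + 1 / 2001

    def test_plus_one_lower_bound(self):
        m, sheet = self._null_dataset(3)
        res, _ = region_wide_permutation(m, sheet, "SZ", R=100, seed=4)
        assert min(r.p_regionwide for r in res) >= 1 / 101

    def test_raw_p_matches_scan(self):
        """The cached-hypergeometric permutation machinery reproduces the
        per-variant Fisher p of the plain scan exactly."""
        m, sheet = self._null_dataset(9)
        miss = np.random.default_rng(10).random(m.calls.shape) < 0.05
        m.calls[miss] = -1
        m.recompute_maf()
        scan = single_variant_scan(m, sheet, "SZ")
        res, _ = region_wide_permutation(m, sheet, "SZ", R=100, seed=1)
        for r_scan, r_perm in zip(scan, res):
            assert r_perm.p_raw == pytest.approx(r_scan.p_raw, abs=1e-9)

    def test_thresholds_ordered(self):
        m, sheet = self._null_dataset(12, n=80, v=40)
        _, thr = region_wide_permutation(m, sheet, "SZ", R=300, seed=5)
        assert thr[0.01] <= thr[0.05] <= 1.0


class TestQtScan:
    def _dataset(self, seed, n=80, v=5, beta=0.0):
        rng = np.random.default_rng(seed)
        calls = rng.binomial(2, 0.3, size=(n, v)).astype(np.int8)
        trait = rng.normal(size=n) + beta * calls[:, 0]
        m = make_matrix(calls)
        sheet = make_sheet(["control"] * n, traits={"memory": trait})
        return m, sheet

    def test_perfect_linear_signal_floors_p(self):
        """A residual exactly linear in dosage attains the maximal
        statistic, so the empirical p hits the 1/(R+1) floor."""
        n = 40
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.4, size=(n, 1)).astype(np.int8)
        trait = 2.0 * calls[:, 0]
        m = make_matrix(calls)
        sheet = make_sheet(["control"] * n, traits={"memory": trait})
        res = qt_scan(m, sheet, "memory", R=199, seed=3)
        assert res[0].p_empirical == pytest.approx(1 / 200)

    def test_affine_invariance_two_sided(self):
        m, sheet = self._dataset(7, beta=0.5)
        p1 = [r.p_empirical for r in qt_scan(m, sheet, "memory", R=300, seed=11)]
        sheet2 = make_sheet(
            ["control"] * len(sheet),
            traits={"memory": -3.0 * sheet.trait("memory") + 10.0},
        )
        p2 = [r.p_empirical for r in qt_scan(m, sheet2, "memory", R=300, seed=11)]
        assert p1 == p2

    def test_monomorphic_is_na(self):
        m, sheet = self._dataset(8)
        m.calls[:, 1] = 1
        m.recompute_maf()
        res = qt_scan(m, sheet, "memory", R=150, seed=0)
        assert np.isnan(res[1].p_empirical) and res[1].note

    def test_slope_recovers_planted_effect(self):
        """Across replicates the stage-2 slope estimate is centred on the
        planted per-allele effect."""
        beta = 0.6
        slopes = []
        for rep in range(40):
            m, sheet = self._dataset(100 + rep, n=150, beta=beta)
            res = qt_scan(m, sheet, "memory", R=100, seed=rep)
            slopes.append(res[0].slope)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - beta) < 3 * se

    def test_type_one_error_calibrated(self):
        """Null dosage-trait pairs reject at ~5% at alpha = 0.05."""
        hits = 0
        reps, v = 120, 5
        for rep in range(reps):
            m, sheet = self._dataset(2000 + rep, n=60, v=v)
            res = qt_scan(m, sheet, "memory", R=199, seed=rep)
            hits += sum(r.p_empirical <= 0.05 for r in res if not np.isnan(r.p_empirical))
        rate = hits / (reps * v)
        assert abs(rate - 0.05) < 0.02


class TestLD:
    def test_identical_vectors(self):
        assert ld_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        g = np.array([0, 1, 2, 0])
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_partial_ld_example(self):
        assert ld_r2([0, 1, 2, 0], [0, 0, 2, 2]) == pytest.approx(1 / 11, abs=1e-9)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedLDError):
            ld_r2([1, 1, 1], [0, 1, 2])

    def test_missing_excluded(self):
        assert ld_r2([0, 1, 2, 0, -1], [0, 0, 2, 2, 2]) == pytest.approx(1 / 11, abs=1e-9)


def _family(status_by_member):
    members = [
        PedigreeMember("father", None, None, "M", *status_by_member["father"]),
        PedigreeMember("mother", None, None, "F", *status_by_member["mother"]),
    ]
    for mid, (diag, carrier) in status_by_member.items():
        if mid in ("father", "mother"):
            continue
        members.append(PedigreeMember(mid, "father", "mother", "F", diag, carrier))
    return Pedigree(members)


class TestSegregation:
    def test_perfect_segregation(self):
        ped = _family(
            {
                "father": ("rMDD", "carrier"),
                "mother": ("unaffected", "non-carrier"),
                "c1": ("rMDD", "carrier"),
                "c2": ("unaffected", "non-carrier"),
            }
        )
        res = segregation_check(ped, {"rMDD"})
        assert res.perfect and res.consistency == 1.0

    def test_one_affected_noncarrier_breaks_perfection(self):
        ped = _family(
            {
                "father": ("rMDD", "carrier"),
                "mother": ("unaffected", "non-carrier"),
                "c1": ("rMDD", "non-carrier"),
            }
        )
        res = segregation_check(ped, {"rMDD"})
        assert not res.perfect and res.consistency == pytest.approx(2 / 3)

    def test_diagnosis_spectrum_family(self):
        """A family where the allele tracks recurrent depression and
        generalised anxiety but not bipolar II: perfect under the
        {rMDD, GAD} affected set, imperfect once BP2 counts as
        affected."""
        ped = _family(
            {
                "father": ("rMDD", "carrier"),
                "mother": ("unaffected", "non-carrier"),
                "c1": ("rMDD", "carrier"),
                "c2": ("GAD", "carrier"),
                "c3": ("BP2", "non-carrier"),
                "c4": ("unaffected", "non-carrier"),
            }
        )
        assert segregation_check(ped, {"rMDD", "GAD"}).perfect
        assert not segregation_check(ped, {"rMDD", "GAD", "BP2"}).perfect

    def test_unknowns_excluded_and_empty_errors(self):
        ped = _family({"father": (None, "carrier"), "mother": ("rMDD", "unknown")})
        with pytest.raises(ValueError):
            segregation_check(ped, {"rMDD"})
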
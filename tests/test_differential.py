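"""Size factors, dispersion, the QL Wald test, BH, DEG calling and FC bins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from nulliseq.genome_model import CountMatrix
from nulliseq.differential import (
    ALPHA_FLOOR,
    bh_adjust,
    call_degs,
    estimate_dispersion,
    fc_bin_table,
    nb_wald_test,
    size_factors,
)


def _cm(cols: dict) -> CountMatrix:
    n = len(next(iter(cols.values())))
    return CountMatrix(
        pd.DataFrame(cols, index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"))
    )


def _nb(rng, mu, alpha):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


class TestSizeFactors:
    def test_identical_columns_get_unit_factors(self):
        cm = _cm({"A_1": [5, 10], "A_2": [5, 10], "B_1": [5, 10], "B_2": [5, 10]})
        np.testing.assert_allclose(size_factors(cm), 1.0)

    def test_doubled_column_gets_double_factor(self):
        cm = _cm({"A_1": [5, 10], "A_2": [5, 10], "B_1": [10, 20], "B_2": [5, 10]})
        s = size_factors(cm)
        assert s["B_1"] / s["A_1"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(s))) == pytest.approx(1.0)

    def test_recovers_simulated_depths(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(4, 1, 500)
        depths = np.array([1.0, 1.5, 0.7, 1.2, 0.9, 2.0])
        cols = {
            f"{g}_{r + 1}": _nb(rng, mu * depths[i], 0.05)
            for i, (g, r) in enumerate((g, r) for g in ("A", "B") for r in range(3))
        }
        s = size_factors(_cm(cols))
        expected = depths / np.exp(np.mean(np.log(depths)))
        np.testing.assert_allclose(s.to_numpy(), expected, rtol=0.05)

    def test_fallback_to_library_size_when_no_common_gene(self, caplog):
        cm = _cm({"A_1": [4, 0], "A_2": [4, 0], "B_1": [0, 8], "B_2": [0, 8]})
        with caplog.at_level("WARNING"):
            s = size_factors(cm)
        assert "library-size" in caplog.text
        assert s["B_1"] / s["A_1"] == pytest.approx(2.0)


class TestDispersion:
    def test_poisson_gene_hits_floor(self):
        rng = np.random.default_rng(1)
        cols = {f"{g}_{r}": rng.poisson(100, 2000) for g in ("A", "B") for r in (1, 2, 3)}
        alpha = estimate_dispersion(_cm(cols), ("A", "B"))
        assert np.median(alpha) == pytest.approx(ALPHA_FLOOR, abs=1e-3)

    def test_moment_recovery_at_many_replicates(self):
        rng = np.random.default_rng(2)
        true = 0.2
        cols = {f"A_{r + 1}": _nb(rng, np.full(300, 200.0), true) for r in range(200)}
        cols |= {f"B_{r + 1}": _nb(rng, np.full(300, 200.0), true) for r in range(200)}
        alpha = estimate_dispersion(_cm(cols), ("A", "B"))
        assert alpha.mean() == pytest.approx(true, abs=0.05)

    def test_all_zero_gene_floors_and_tests_null(self):
        cm = _cm(
            {"A_1": [0, 5], "A_2": [0, 6], "A_3": [0, 4],
             "B_1": [0, 5], "B_2": [0, 7], "B_3": [0, 4]}
        )
        alpha = estimate_dispersion(cm, ("A", "B"))
        assert alpha["g0"] == ALPHA_FLOOR
        de = nb_wald_test(cm, ("A", "B"))
        assert de.loc["g0", "p_value"] == 1.0
        assert de.loc["g0", "log2fc"] == 0.0


class TestWaldTest:
    def test_null_gives_flat_fold_changes(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(4, 1, 1000)
        cols = {f"{g}_{r}": _nb(rng, mu, 0.05) for g in ("A", "B") for r in (1, 2, 3)}
        de = nb_wald_test(_cm(cols), ("A", "B"))
        assert abs(de["log2fc"].mean()) < 0.05
        assert 0.02 < (de["p_value"] < 0.05).mean() < 0.08

    def test_log2fc_antisymmetric_under_group_swap(self, small_sim):
        _, _, _, counts, _ = small_sim
        fwd = nb_wald_test(counts, ("Ctr", "NC"))
        rev = nb_wald_test(counts, ("NC", "Ctr"))
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-10)

    def test_effect_recovery_with_significance(self):
        rng = np.random.default_rng(4)
        n, n_sig = 2000, 200
        mu = rng.lognormal(3.0, 1.5, n)
        sig = rng.choice(n, n_sig, replace=False)
        mu[sig] = rng.lognormal(6.0, 0.5, n_sig)
        mu2 = mu.copy()
        signs = np.where(np.arange(n_sig) % 2 == 0, 1.0, -1.0)
        mu2[sig] = mu[sig] * 4.0**signs
        cols = {f"Ctr_{r}": _nb(rng, mu, 0.05) for r in (1, 2, 3)}
        cols |= {f"NC_{r}": _nb(rng, mu2, 0.05) for r in (1, 2, 3)}
        degs = call_degs(nb_wald_test(_cm(cols), ("Ctr", "NC")))
        est = degs.iloc[sig]
        assert np.all(np.sign(est["log2fc"]) == signs)
        assert np.abs(est["log2fc"]).mean() == pytest.approx(2.0, abs=0.2)
        assert (est["q_value"] < 0.05).mean() > 0.9

    def test_zero_euploid_gene_gets_finite_positive_lfc(self):
        cm = _cm(
            {"A_1": [0, 50], "A_2": [0, 55], "A_3": [0, 45],
             "B_1": [40, 50], "B_2": [38, 55], "B_3": [42, 45]}
        )
        de = nb_wald_test(cm, ("A", "B"))
        assert np.isfinite(de.loc["g0", "log2fc"])
        assert de.loc["g0", "log2fc"] > 4  # (40 + pc)/pc with pc = 0.5

    def test_power_monotone_in_effect_size(self):
        # effect on a 10% subset so normalization cannot absorb it
        rng = np.random.default_rng(5)
        n = 1500
        mu = rng.lognormal(4.0, 1.0, n)
        sig = rng.choice(n, 150, replace=False)
        powers = []
        for lfc in (0.5, 1.0, 2.0):
            mu2 = mu.copy()
            mu2[sig] = mu[sig] * 2**lfc
            cols = {f"A_{r}": _nb(rng, mu, 0.1) for r in (1, 2, 3)}
            cols |= {f"B_{r}": _nb(rng, mu2, 0.1) for r in (1, 2, 3)}
            de = nb_wald_test(_cm(cols), ("A", "B"))
            powers.append((de["p_value"].iloc[sig] < 0.05).mean())
        assert powers[0] < powers[1] < powers[2]


class TestBH:
    @pytest.mark.parametrize(
        ("p", "expected"),
        [
            ([0.01], [0.01]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_worked_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_adjust([0.1, np.nan])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_step_up(self, p):
        def brute(ps):
            m = len(ps)
            order = sorted(range(m), key=lambda i: ps[i])
            q = [None] * m
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                val = min(prev, ps[i] * m / rank)
                q[i] = val
                prev = val
            return q

        np.testing.assert_allclose(bh_adjust(p), brute(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_statsmodels(self, p):
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestDEGCalling:
    @pytest.mark.parametrize(
        ("p_scale", "log2fc", "expected"),
        [
            (0.001, 0.5, "ns"),     # significant q but fails the lfc threshold
            (0.001, -1.2, "down"),
            (0.001, 1.0, "up"),     # boundary |lfc| = threshold included
            (0.9, 3.0, "ns"),       # big effect but not significant
        ],
    )
    def test_status_rules(self, p_scale, log2fc, expected):
        de = pd.DataFrame(
            {
                "base_mean_eu": [10.0],
                "base_mean_an": [10.0],
                "log2fc": [log2fc],
                "fc": [2.0**log2fc],
                "p_value": [p_scale],
            },
            index=["g1"],
        )
        assert call_degs(de)["status"].iloc[0] == expected

    def test_status_respects_thresholds_in_bulk(self, fitted):
        d = fitted.de_table
        up, down = d[d["status"] == "up"], d[d["status"] == "down"]
        assert (up["log2fc"] >= 1.0).all() and (up["q_value"] < 0.05).all()
        assert (down["log2fc"] <= -1.0).all()

    def test_empty_deg_list_gives_nan_ratios(self):
        de = pd.DataFrame(
            {"log2fc": [0.1], "fc": [1.07], "p_value": [0.9],
             "q_value": [0.9], "status": ["ns"]},
            index=["g1"],
        )
        table = fc_bin_table(de)
        assert (table["total"] == 0).all()
        assert table["up_ratio_pct"].isna().all()
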
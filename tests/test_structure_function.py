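import warnings

import numpy as np
import pytest

from zerolag.connectivity import phase_delay_matrix
from zerolag.phase_delay import penalisation_value
from zerolag.spectral import analytic_signal, bandpass_filter
from zerolag.structure_function import (group_location_test,
                                        mediation_bootstrap,
                                        penalisation_structure_correlation,
                                        structure_function_concordance,
                                        transmission_fc_correlation,
                                        transmission_time_proxy)


def sym(rng, n=10, positive=True):
    m = rng.uniform(0.0 if positive else -1.0, 1.0, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestConcordance:
    def test_monotone_relation_gives_one(self, rng):
        s = sym(rng)
        assert structure_function_concordance(np.sqrt(s), s) == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self, rng):
        s = sym(rng)
        assert structure_function_concordance(-s, s) == pytest.approx(-1.0)

    def test_independent_matrices_small_rho(self, rng):
        vals = [structure_function_concordance(sym(rng, 68), sym(rng, 68))
                for _ in range(10)]
        assert np.abs(np.mean(vals)) < 0.03
        assert np.max(np.abs(vals)) < 0.1

    def test_constant_matrix_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(structure_function_concordance(
                np.ones((5, 5)), np.ones((5, 5))))


class TestGroupLocationTest:
    def test_clear_shift_is_detected(self, rng):
        hits = 0
        for _ in range(20):
            res = group_location_test(rng.normal(1.0, 1.0, 50),
                                      n_comparisons=10)
            hits += res.p_corrected < 0.05
        assert hits == 20

    def test_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        reps = 200
        for _ in range(reps):
            res = group_location_test(rng.normal(0.0, 1.0, 25))
            rejections += res.p_value < 0.05
        assert abs(rejections / reps - 0.05) < 0.05

    def test_skewed_data_selects_wilcoxon(self, rng):
        res = group_location_test(rng.exponential(1.0, 100))
        assert res.test_used == "wilcoxon"

    def test_degenerate_identical_values(self):
        with pytest.warns(UserWarning, match="identical"):
            res = group_location_test(np.full(10, 3.0))
        assert res.test_used == "degenerate"


class TestTransmissionProxy:
    def test_arithmetic(self):
        assert transmission_time_proxy(128.0, 0.05) == pytest.approx(2560.0)

    def test_doubling_hmoa_halves_proxy(self):
        assert transmission_time_proxy(100.0, 0.08) == pytest.approx(
            transmission_time_proxy(100.0, 0.04) / 2)

    def test_nonpositive_hmoa_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            out = transmission_time_proxy(np.array([100.0, 50.0]),
                                          np.array([0.05, 0.0]))
        assert np.isnan(out[1]) and out[0] == pytest.approx(2000.0)


class TestPenalisationStructureCorrelation:
    def test_monotone_in_count_gives_one(self, rng):
        count = np.round(sym(rng, 12) * 100)
        pen = count / (count.max() + 1)
        assert penalisation_structure_correlation(pen, count) \
            == pytest.approx(1.0)

    def test_zero_streamline_pairs_are_masked(self, rng):
        count = np.round(sym(rng, 12) * 100)
        count[count < 30] = 0.0
        pen = count / (count.max() + 1)
        altered = pen.copy()
        altered[count == 0] = 0.99       # junk on masked pairs
        r1 = penalisation_structure_correlation(pen, count)
        r2 = penalisation_structure_correlation(altered, count)
        assert r1 == pytest.approx(r2)


class TestMediation:
    def test_effect_decomposition_identity(self, rng):
        # c = c' + a*b exactly for linear no-interaction point estimates
        x = rng.normal(size=200)
        m = 0.5 * x + rng.normal(size=200)
        y = 0.3 * x + 0.7 * m + rng.normal(size=200)
        res = mediation_bootstrap(x, m, y, n_boot=200, seed=0)
        assert res.c == pytest.approx(res.c_prime + res.indirect, abs=1e-8)

    def test_full_mediation_recovered(self, rng):
        x = rng.normal(size=500)
        m = 1.0 * x + 0.1 * rng.normal(size=500)
        y = 0.8 * m + 0.1 * rng.normal(size=500)
        res = mediation_bootstrap(x, m, y, n_boot=1000, seed=1)
        assert abs(res.c_prime) < 0.05
        assert res.proportion_mediated == pytest.approx(1.0, abs=0.07)
        assert res.ci_low > 0

    def test_null_mediator_ci_covers_zero(self, rng):
        x = rng.normal(size=500)
        m = rng.normal(size=500)                # independent of x
        y = 0.5 * x + rng.normal(size=500)
        res = mediation_bootstrap(x, m, y, n_boot=1000, seed=2)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_planted_partial_mediation_proportion(self, rng):
        # mixture of direct and mediated paths with proportion 0.25
        x = rng.normal(size=500)
        m = 1.0 * x + 0.3 * rng.normal(size=500)
        y = 0.75 * x + 0.25 * m + 0.2 * rng.normal(size=500)
        res = mediation_bootstrap(x, m, y, n_boot=1000, seed=3)
        half_width = (res.ci_high - res.ci_low) / 2
        assert abs(res.proportion_mediated - 0.25) < half_width + 0.05

    def test_matches_pingouin_point_estimates(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        x = rng.normal(size=120)
        m = 0.6 * x + rng.normal(size=120)
        y = 0.4 * x + 0.5 * m + rng.normal(size=120)
        res = mediation_bootstrap(x, m, y, n_boot=500, seed=4)
        df = pd.DataFrame({"X": x, "M": m, "Y": y})
        ref = pingouin.mediation_analysis(data=df, x="X", m="M", y="Y",
                                          seed=4, n_boot=500)
        ref_ind = float(ref.loc[ref["path"] == "Indirect", "coef"].iloc[0])
        ref_tot = float(ref.loc[ref["path"] == "Total", "coef"].iloc[0])
        assert res.indirect == pytest.approx(ref_ind, abs=1e-8)
        assert res.c == pytest.approx(ref_tot, abs=1e-8)

    def test_input_size_guards(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError):
            mediation_bootstrap(x, x, x, n_boot=500)
        x = rng.normal(size=50)
        with pytest.raises(ValueError):
            mediation_bootstrap(x, x, x, n_boot=50)


class TestTransmissionFcCorrelation:
    def test_strictly_decreasing_gives_minus_one(self, rng):
        proxy = sym(rng, 10) * 1000 + 1
        fc = 1.0 / proxy
        np.fill_diagonal(fc, 0.0)
        assert transmission_fc_correlation(proxy, fc) == pytest.approx(-1.0)

    def test_shuffled_proxy_uncorrelated(self, rng):
        proxy = sym(rng, 30) * 1000 + 1
        fc = 1.0 / proxy
        iu = np.triu_indices(30, k=1)
        vals = []
        for _ in range(10):
            shuffled = np.zeros_like(proxy)
            shuffled[iu] = rng.permutation(proxy[iu])
            vals.append(transmission_fc_correlation(shuffled + shuffled.T, fc))
        assert abs(np.mean(vals)) < 0.05


@pytest.fixture(scope="module")
def chain(dk_cohort):
    iu = np.triu_indices(dk_cohort.geometry.n_regions, k=1)
    x, m, y, pen_rhos = [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in range(dk_cohort.n_participants):
            epoch = dk_cohort.epochs[p][0]
            conn = dk_cohort.connectomes[p]
            tau = phase_delay_matrix(analytic_signal(
                bandpass_filter(epoch, "alpha"))).tau
            pen = penalisation_value(tau)
            proxy = transmission_time_proxy(conn.median_length,
                                            conn.median_hmoa)
            sel = conn.connected[iu]
            x.append(conn.norm_log_count[iu][sel])
            m.append(proxy[iu][sel])
            y.append(pen[iu][sel])
            pen_rhos.append(penalisation_structure_correlation(
                pen, conn.streamline_count))
    return (np.concatenate(x), np.concatenate(m), np.concatenate(y),
            np.array(pen_rhos))


class TestCohortChainRecovery:
    """The generative chain count -> transmission time -> |tau| near {0, pi}
    must be recoverable from simulated epochs."""

    def test_penalisation_count_correlation_positive(self, chain):
        *_, pen_rhos = chain
        assert np.mean(pen_rhos) > 0.2
        res = group_location_test(pen_rhos)
        assert res.p_value < 0.01

    def test_positive_indirect_effect_through_transmission_time(self, chain):
        x, m, y, _ = chain
        res = mediation_bootstrap(x, m, y, n_boot=500, seed=0)
        assert res.indirect > 0
        assert res.ci_low > 0
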
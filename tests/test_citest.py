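import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2

from latentgrn.citest import g2_test, pair_delay_score, series_similarity
from latentgrn.dclinde import DclindeParams, stage1
from latentgrn.timeseries import MISSING, TimeSeriesSet


def brute_force_g2(x, y, cond=()):
    """Independent likelihood-ratio computation by explicit loops."""
    rows = [
        (xi, yi, tuple(c[i] for c in cond))
        for i, (xi, yi) in enumerate(zip(x, y))
        if xi != MISSING and yi != MISSING and all(c[i] != MISSING for c in cond)
    ]
    strata = sorted({r[2] for r in rows})
    g2, dof = 0.0, 0
    for s in strata:
        sub = [(xi, yi) for xi, yi, cs in rows if cs == s]
        if not sub:
            continue
        xs = sorted({xi for xi, _ in sub})
        ys = sorted({yi for _, yi in sub})
        n = len(sub)
        for xi in xs:
            for yi in ys:
                o = sum(1 for a, b in sub if a == xi and b == yi)
                rx = sum(1 for a, _ in sub if a == xi)
                cy = sum(1 for _, b in sub if b == yi)
                e = rx * cy / n
                if o > 0:
                    g2 += 2 * o * math.log(o / e)
        rx_nz = sum(1 for xi in xs if any(a == xi for a, _ in sub))
        cy_nz = sum(1 for yi in ys if any(b == yi for _, b in sub))
        dof += max(rx_nz - 1, 0) * max(cy_nz - 1, 0)
    return g2, dof


def vectors_from_table(table):
    x, y = [], []
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            x += [i] * count
            y += [j] * count
    return np.array(x), np.array(y)


class TestG2:
    def test_hand_computed_2x2_table(self):
        # O = ((30,10),(10,30)): all margins 40, E all 20
        x, y = vectors_from_table([[30, 10], [10, 30]])
        res = g2_test(x, y)
        expected = 2 * (2 * 30 * math.log(1.5) + 2 * 10 * math.log(0.5))
        assert res.g2 == pytest.approx(expected, abs=1e-9)
        assert res.dof == 1
        assert res.score == pytest.approx(-math.log10(chi2.sf(expected, 1)))

    def test_score_is_neg_log10_p(self):
        x, y = vectors_from_table([[25, 15], [15, 25]])
        res = g2_test(x, y)
        assert res.score == pytest.approx(-math.log10(res.p_value))

    def test_constant_variable_carries_no_evidence(self):
        x = np.zeros(50, dtype=int)
        y = np.tile([0, 1, 2], 17)[:50]
        res = g2_test(x, y)
        assert res.p_value == 1.0 and res.score == 0.0

    def test_symmetric_in_arguments(self, rng):
        x = rng.integers(0, 3, 200)
        y = rng.integers(0, 3, 200)
        a, b = g2_test(x, y), g2_test(y, x)
        assert a.g2 == pytest.approx(b.g2, abs=1e-12) and a.dof == b.dof

    def test_single_valued_conditioner_changes_nothing(self, rng):
        x = rng.integers(0, 3, 200)
        y = rng.integers(0, 3, 200)
        plain = g2_test(x, y)
        cond = g2_test(x, y, [np.ones(200, dtype=int)])
        assert cond.g2 == pytest.approx(plain.g2) and cond.dof == plain.dof

    def test_missing_rows_dropped_pairwise(self, rng):
        x = rng.integers(0, 3, 300)
        y = rng.integers(0, 3, 300)
        keep = rng.random(300) > 0.3
        x_miss = np.where(keep, x, MISSING)
        assert g2_test(x_miss, y).g2 == pytest.approx(g2_test(x[keep], y[keep]).g2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n_states = int(rng.integers(2, 4))
        n = int(rng.integers(10, 31))
        x = rng.integers(0, n_states, n)
        y = rng.integers(0, n_states, n)
        res = g2_test(x, y)
        g2, dof = brute_force_g2(x, y)
        if dof == 0:
            assert res.score == 0.0
        else:
            assert res.g2 == pytest.approx(g2, abs=1e-9)
            assert res.dof == dof

    @pytest.mark.parametrize("seed", range(8))
    def test_conditional_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 60
        x = rng.integers(0, 3, n)
        z = rng.integers(0, 2, n)
        y = (x + z + rng.integers(0, 2, n)) % 3
        res = g2_test(x, y, [z])
        g2, dof = brute_force_g2(x, y, (z,))
        assert res.g2 == pytest.approx(g2, abs=1e-9)
        assert res.dof == dof

    def test_exhaustive_small_tables_match_oracle(self):
        # every 2-state table with cell counts summing to <= 12
        for a, b, c, d in itertools.product(range(4), repeat=4):
            if a + b + c + d < 4:
                continue
            x, y = vectors_from_table([[a, b], [c, d]])
            res = g2_test(x, y)
            g2, dof = brute_force_g2(x, y)
            if dof == 0:
                assert res.score == 0.0
            else:
                assert res.g2 == pytest.approx(g2, abs=1e-9)


class TestPairDelayScore:
    def test_peaks_at_true_delay(self, single_edge_data):
        scores = {tau: pair_delay_score(single_edge_data, 0, 1, tau).score for tau in (1, 2, 3, 4)}
        assert max(scores, key=scores.get) == 2

    def test_rejects_zero_delay(self, single_edge_data):
        with pytest.raises(ValueError):
            pair_delay_score(single_edge_data, 0, 1, 0)


class TestSeriesSimilarity:
    def test_identical_series_best_at_zero_shift(self, rng):
        mat = rng.integers(0, 3, size=(2, 60))
        mat[1] = mat[0]
        data = TimeSeriesSet([mat], n_states=3)
        score, shift = series_similarity(data, 0, 1, 4)
        assert shift == 0 and score > 10

    def test_delayed_copy_recovers_lag(self, rng):
        base = rng.integers(0, 3, 80)
        mat = np.vstack([base, np.roll(base, 3)])  # gene 1 lags gene 0 by 3
        data = TimeSeriesSet([mat], n_states=3)
        _, shift = series_similarity(data, 0, 1, 4)
        assert shift == 3

    def test_sign_convention_is_antisymmetric(self, rng):
        base = rng.integers(0, 3, 80)
        mat = np.vstack([base, np.roll(base, 3)])
        data = TimeSeriesSet([mat], n_states=3)
        _, fwd = series_similarity(data, 0, 1, 4)
        _, rev = series_similarity(data, 1, 0, 4)
        assert fwd == -rev


class TestTypeOneCalibration:
    def test_stage1_false_positive_rate_near_one_percent(self):
        """On independent data, links survive stage 1 at roughly the nominal
        p = 0.01 of the score-2 threshold."""
        n, T, d = 6, 400, 4
        total_tests = survivors = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            data = TimeSeriesSet([rng.integers(0, 3, size=(n, T))], n_states=3)
            edges = stage1(data, DclindeParams(max_delay=d))
            survivors += len(edges)
            total_tests += n * (n - 1) * d
        rate = survivors / total_tests
        assert 0.002 < rate < 0.025
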
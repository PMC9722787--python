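import math

import numpy as np
import pytest

from brackish.core_io import ValidationError
from brackish.synthetic import ScenarioSpec, simulate_water_panel
from brackish.waterstats import (correlation_matrix, descriptives,
                                 paired_wilcoxon, pca, seasonal_test,
                                 spatial_test)


@pytest.fixture(scope="module")
def default_panel():
    return simulate_water_panel(ScenarioSpec(rng_seed=123))


class TestDescriptives:
    def test_constant_cell_zero_se(self, water_fixture):
        for s in water_fixture:
            s.dsi = 5.0
        table = descriptives(water_fixture, parameters=("dsi",))
        cell = table[(table.station_id == "UE") & (table.season == "dry")]
        assert float(cell["se"].iloc[0]) == 0.0

    def test_median_of_do_style_cell(self):
        values = np.array([8.4, 8.3, 8.2, 8.3, 8.3])
        assert float(np.median(values)) == pytest.approx(8.3)

    def test_zero_spread_panel_equals_medians(self):
        spec = ScenarioSpec(rng_seed=0, n_eff=0.0)
        # n_eff = 0 collapses every spread to zero
        panel = simulate_water_panel(spec)
        table = descriptives(panel, parameters=("salinity",))
        for _, row in table.iterrows():
            loc, _se = spec.water_panel["salinity"][row.season][row.station_id]
            assert row["median"] == pytest.approx(loc)
            assert row["se"] == pytest.approx(0.0)


class TestSeasonalTest:
    def test_identical_vectors_p_one(self):
        stat, p = paired_wilcoxon([1.0, 2.0, 3.0, 4.0, 5.0],
                                  [1.0, 2.0, 3.0, 4.0, 5.0])
        assert p == 1.0

    def test_six_positive_pairs_exact_one_sided(self):
        stat, p = paired_wilcoxon([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6],
                                  alternative="greater")
        assert p == pytest.approx(1 / 64)

    def test_salinity_contrast_significant(self, default_panel):
        res = seasonal_test("salinity", default_panel)
        assert res.test == "wilcoxon_paired"
        assert res.n == 12
        assert res.p_value < 0.01
        assert res.significant_at in (0.01, 0.001)

    def test_needs_min_pairs(self, water_fixture):
        with pytest.raises(ValidationError, match="pairs"):
            seasonal_test("salinity", water_fixture)


class TestSpatialTest:
    def test_null_gives_large_p(self):
        rng = np.random.default_rng(5)
        panel = simulate_water_panel(ScenarioSpec(rng_seed=5))
        # permute one parameter across all records: no station signal remains
        values = [s.do for s in panel]
        rng.shuffle(values)
        for s, v in zip(panel, values):
            s.do = v
        res = spatial_test("do", panel)
        assert res.p_value > 0.05

    def test_dry_salinity_gradient_significant(self, default_panel):
        res = spatial_test("salinity", default_panel, season="dry")
        assert res.p_value < 0.05

    def test_two_groups_matches_rank_oracle(self):
        from scipy import stats as ss
        a, b = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0, 8.0]
        # brute-force H from ranks (no ties)
        ranks = ss.rankdata(a + b)
        n, k = len(ranks), 2
        r_groups = [ranks[:4], ranks[4:]]
        h = 12 / (n * (n + 1)) * sum(
            len(r) * (np.mean(r) - (n + 1) / 2) ** 2 for r in r_groups)
        got = ss.kruskal(a, b)
        assert got.statistic == pytest.approx(h)

    def test_single_group_rejected(self, water_fixture):
        only_ue = [s for s in water_fixture if s.station_id == "UE"]
        with pytest.raises(ValidationError):
            spatial_test("salinity", only_ue)


class TestCorrelation:
    def test_self_correlation(self, default_panel):
        cells = {c.pair: c for c in correlation_matrix(default_panel)}
        diag = cells[("salinity", "salinity")]
        assert diag.r == 1.0 and diag.stars == "***"

    def test_exact_negative(self, water_fixture):
        for s in water_fixture:
            s.dsi = 10.0 - s.temperature  # force y = -x + c
        cells = {c.pair: c for c in
                 correlation_matrix(water_fixture,
                                    parameters=("temperature", "dsi"))}
        assert cells[("temperature", "dsi")].r == pytest.approx(-1.0)

    def test_default_panel_signs(self, default_panel):
        cells = {c.pair: c for c in correlation_matrix(default_panel)}
        assert cells[("temperature", "salinity")].r < 0
        assert cells[("nh4", "din")].r > 0

    def test_symmetric_psd(self, default_panel):
        params = ("temperature", "salinity", "do", "ph", "chla")
        cells = correlation_matrix(default_panel, parameters=params)
        m = np.eye(len(params))
        index = {p: i for i, p in enumerate(params)}
        for c in cells:
            i, j = index[c.pair[0]], index[c.pair[1]]
            m[i, j] = m[j, i] = c.r
        eig = np.linalg.eigvalsh(m)
        assert eig.min() > -1e-8

    def test_constant_parameter_flagged(self, water_fixture):
        for s in water_fixture:
            s.chla = 3.0
        with pytest.warns(UserWarning, match="constant"):
            cells = {c.pair: c for c in
                     correlation_matrix(water_fixture,
                                        parameters=("chla", "do"))}
        assert math.isnan(cells[("chla", "do")].r)


class TestPCA:
    def test_rank_one_pair_explains_everything(self):
        panel = simulate_water_panel(ScenarioSpec(rng_seed=3))
        for s in panel:
            s.dsi = 2.0 * s.temperature + 1.0
        result = pca(panel, parameters=("temperature", "dsi"))
        assert result.percent_variance[0] == pytest.approx(100.0, abs=1e-6)
        assert result.rank_deficient

    def test_independent_parameters_near_unit_eigenvalues(self):
        rng = np.random.default_rng(42)
        panel = simulate_water_panel(ScenarioSpec(rng_seed=4))
        for s in panel:  # overwrite with iid noise
            for p in ("no3_n", "no2_n", "nh4"):
                setattr(s, p, float(rng.uniform(0, 1)))
        result = pca(panel, parameters=("no3_n", "no2_n", "nh4"))
        assert np.all(np.abs(result.eigenvalues - 1.0) < 0.5)
        assert result.percent_variance.sum() == pytest.approx(100.0)

    def test_dim1_separates_seasons(self, default_panel):
        result = pca(default_panel)
        scores = result.scores
        dry = scores[scores.season == "dry"]["dim1"]
        wet = scores[scores.season == "wet"]["dim1"]
        pooled_sd = np.sqrt((dry.var(ddof=1) + wet.var(ddof=1)) / 2)
        assert abs(dry.mean() - wet.mean()) > 2 * pooled_sd

    def test_reconstruction_and_contributions(self, default_panel):
        result = pca(default_panel)
        Z = result.scores.drop(columns=["station_id", "season"]).to_numpy() @ \
            result.loadings.to_numpy().T
        frame_cols = list(result.loadings.index)
        from brackish.core_io import samples_to_frame
        data = samples_to_frame(default_panel)[frame_cols].dropna().to_numpy()
        Zref = (data - data.mean(0)) / data.std(0, ddof=1)
        assert np.max(np.abs(Z - Zref)) < 1e-8
        assert np.allclose(result.contributions.sum(axis=0), 100.0)

    def test_not_enough_samples_rejected(self, water_fixture):
        with pytest.raises(ValidationError):
            pca(water_fixture)
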
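"""Residual-SHR inference: the residual identity, the Monte-Carlo engine,
and the correlated SHR/NPP ratio statistics."""

import math
from dataclasses import replace

import numpy as np
import pytest

from carbonledger import (
    GLOBAL,
    REGIONS,
    SOURCE_NAMES,
    BudgetTable,
    FluxEstimate,
    McConfig,
    RegionalBudget,
    RiverExport,
    StockChange,
    SynthConfig,
    TradeFlux,
    generate_budget_table,
    ratio_statistics,
    regional_ratio_report,
    regional_nee,
    residual_shr,
    run_monte_carlo,
    source_total,
)


def fe(v, s=0.0):
    return FluxEstimate(v, s)


def zero_sources(**named):
    out = {n: fe(0.0) for n in SOURCE_NAMES}
    out.update(named)
    return out


def toy_budget(region, nee_sigma=0.1, npp_products=((-10.0, 2.0), (-12.0, 2.4)),
               src=0.5, src_sigma=0.1):
    """Minimal budget: all NEE variance on delta3, one uncertain source."""
    stock = StockChange(fe(0), fe(0), fe(-0.5, nee_sigma), fe(0), fe(0))
    rivers = RiverExport(fe(0), fe(0), fe(0), fe(0))
    trade = TradeFlux(fe(0), fe(0), fe(0), fe(0))
    return RegionalBudget(
        region=region, stock=stock, rivers=rivers, trade=trade,
        npp_products=tuple(npp_products),
        non_shr_sources=zero_sources(grazing=fe(src, src_sigma)),
    )


@pytest.fixture(scope="module")
def toy_table():
    return BudgetTable(
        regions={
            "Europe": toy_budget("Europe"),
            "Africa": toy_budget("Africa", npp_products=((-8.0, 1.6), (-9.0, 1.8))),
        },
        non_reccap_sink=0.0,
    )


class TestResidualShr:
    def test_printed_global_residual(self):
        sources = {n: 0.0 for n in SOURCE_NAMES}
        sources["crop"] = 8.3
        assert residual_shr(-2.8, -50.0, sources) == pytest.approx(38.9)

    def test_all_zero(self):
        assert residual_shr(0.0, 0.0, {n: 0.0 for n in SOURCE_NAMES}) == 0.0

    def test_npp_fully_respired(self):
        assert residual_shr(0.0, -10.0, {n: 0.0 for n in SOURCE_NAMES}) == 10.0

    def test_missing_operand_named(self):
        sources = {n: 0.0 for n in SOURCE_NAMES if n != "reduced"}
        with pytest.raises(KeyError, match="reduced"):
            residual_shr(0.0, 0.0, sources)


class TestMonteCarloInvariants:
    def test_residual_identity_holds_per_draw(self, mc_result):
        for region, q in mc_result.draws.items():
            lhs = q["shr"] + q["npp"] + sum(q[n] for n in SOURCE_NAMES)
            rhs = q["nee"]
            if region == GLOBAL:
                rhs = rhs  # global nee already includes the non-RECCAP scalar
            assert np.max(np.abs(lhs - rhs)) < 1e-9, region

    def test_extensivity_of_global_draws(self, mc_result):
        g = mc_result.draws[GLOBAL]
        regions = mc_result.region_names
        for name in ("npp", *SOURCE_NAMES):
            total = sum(mc_result.draws[r][name] for r in regions)
            assert np.allclose(g[name], total, atol=1e-10), name
        for name in ("nee", "shr"):
            total = sum(mc_result.draws[r][name] for r in regions)
            assert np.allclose(g[name], total + mc_result.non_reccap_sink, atol=1e-10)

    def test_seed_reproducibility(self, default_table):
        cfg = McConfig(n_draws=3000, seed=99)
        r1 = run_monte_carlo(default_table, cfg)
        r2 = run_monte_carlo(default_table, cfg)
        for region in r1.draws:
            for name in r1.draws[region]:
                assert np.array_equal(r1.draws[region][name], r2.draws[region][name])

    def test_degenerate_table_gives_central_residual(self):
        table = generate_budget_table(SynthConfig(sigma_scale=0.0, n_npp_products=1, collapse_products=True))
        res = run_monte_carlo(table, McConfig(n_draws=1500, seed=3))
        g = res.draws[GLOBAL]
        expected = residual_shr(
            sum(regional_nee(table.regions[r]).value for r in REGIONS)
            + table.non_reccap_sink,
            sum(table.regions[r].npp_central for r in REGIONS),
            {
                n: sum(table.regions[r].non_shr_sources[n].value for r in REGIONS)
                for n in SOURCE_NAMES
            },
        )
        assert np.ptp(g["shr"]) == 0.0
        assert np.median(g["shr"]) == pytest.approx(expected, abs=1e-9)


class TestOracleEquivalence:
    def test_small_instance_against_enumeration(self, toy_table):
        """MC mean/sigma match product enumeration + Gaussian quadrature.

        With coherent sampling the global draw is an equal-weight mixture
        over the two product indices; each mixture component is Gaussian
        with moments available in closed form.
        """
        n = 200_000
        res = run_monte_carlo(toy_table, McConfig(n_draws=n, seed=11))
        g = res.draws[GLOBAL]

        regions = list(toy_table.regions.values())
        nee_mean = sum(regional_nee(b).value for b in regions)
        nee_var = sum(regional_nee(b).sigma ** 2 for b in regions)
        src_mean = sum(source_total(b).value for b in regions)
        src_var = sum(source_total(b).sigma ** 2 for b in regions)

        mix_means, mix_vars = [], []
        for k in range(2):  # enumerate the coherent product index
            npp_k = sum(b.npp_products[k][0] for b in regions)
            npp_var_k = sum(b.npp_products[k][1] ** 2 for b in regions)
            mix_means.append(nee_mean - npp_k - src_mean)
            mix_vars.append(nee_var + npp_var_k + src_var)
        shr_mean = np.mean(mix_means)
        shr_var = np.mean(
            [v + m**2 for v, m in zip(mix_vars, mix_means)]
        ) - shr_mean**2
        shr_sd = math.sqrt(shr_var)

        se_mean = shr_sd / math.sqrt(n)
        se_sd = shr_sd / math.sqrt(2 * n)
        assert np.mean(g["shr"]) == pytest.approx(shr_mean, abs=3 * se_mean)
        assert np.std(g["shr"]) == pytest.approx(shr_sd, abs=3 * se_sd)
        # NEE is a plain Gaussian sum
        assert np.mean(g["nee"]) == pytest.approx(nee_mean, abs=3 * math.sqrt(nee_var / n))
        assert np.std(g["nee"]) == pytest.approx(
            math.sqrt(nee_var), abs=3 * math.sqrt(nee_var) / math.sqrt(2 * n)
        )

    def test_coherent_vs_independent_product_sampling(self, toy_table):
        """Independent per-region choice narrows the global NPP spread."""
        coh = run_monte_carlo(toy_table, McConfig(n_draws=50_000, seed=5))
        ind = run_monte_carlo(
            toy_table, McConfig(n_draws=50_000, seed=5, coherent_products=False)
        )
        iqr = lambda a: np.subtract(*np.percentile(a, [75, 25]))
        assert iqr(ind.draws[GLOBAL]["npp"]) < iqr(coh.draws[GLOBAL]["npp"])


class TestRatioStatistics:
    def test_global_ratio_median(self, mc_result):
        stats = ratio_statistics(mc_result)
        row = stats[(stats.region == GLOBAL) & (stats.quantity == "ratio")].iloc[0]
        assert row["median"] == pytest.approx(0.78, abs=0.01)

    def test_correlation_narrows_the_ratio(self, mc_result):
        """Paired draws make the ratio tighter than NPP itself."""
        stats = ratio_statistics(mc_result)
        g = stats[stats.region == GLOBAL].set_index("quantity")
        assert g.loc["ratio", "rel_iqr"] < g.loc["npp", "rel_iqr"]

    def test_zero_npp_draws_excluded_and_counted(self):
        budget = toy_budget("Europe", npp_products=((0.0, 0.0),))
        table = BudgetTable(regions={"Europe": budget}, non_reccap_sink=0.0)
        res = run_monte_carlo(table, McConfig(n_draws=1000, seed=0))
        assert res.excluded_zero_npp["Europe"] == 1000
        assert res.draws["Europe"]["ratio"].size == 0


class TestRegionalRatioReport:
    def test_south_asia_and_east_asia_lowest(self, mc_result):
        report = regional_ratio_report(mc_result)
        assert list(report["region"][:2]) == ["South Asia", "East Asia"]
        assert report["median"].iloc[0] == pytest.approx(0.38, abs=0.02)
        assert report["median"].iloc[1] == pytest.approx(0.56, abs=0.02)
        others = report["median"].iloc[2:]
        assert (others > 0.6).all() and (others < 0.9).all()

    def test_identical_regions_identical_central_ratios(self):
        t = BudgetTable(
            regions={r: toy_budget(r) for r in ("Europe", "Africa")},
            non_reccap_sink=0.0,
        )
        res = run_monte_carlo(t, McConfig(n_draws=40_000, seed=21))
        report = regional_ratio_report(res).set_index("region")
        assert report.loc["Europe", "median"] == pytest.approx(
            report.loc["Africa", "median"], abs=0.01
        )

    def test_extra_appropriation_lowers_the_ratio(self, default_table, mc_result):
        """Doubling grazing+fires with NPP fixed strictly lowers the ratio."""
        region = "South America"
        b = default_table.regions[region]
        sources = dict(b.non_shr_sources)
        for name in ("grazing", "fires_residue", "fires_other"):
            sources[name] = sources[name].scaled(2.0)
        modified = BudgetTable(
            regions={**default_table.regions, region: replace(b, non_shr_sources=sources)},
            non_reccap_sink=default_table.non_reccap_sink,
        )
        res2 = run_monte_carlo(modified, mc_result.config)
        base = np.median(mc_result.draws[region]["ratio"])
        bumped = np.median(res2.draws[region]["ratio"])
        assert bumped < base
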
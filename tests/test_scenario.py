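"""Constant-land consumption scenarios (the full breed x management grid)."""

import dataclasses

import pytest

import broilerland as bl

# Published scenario table: maximum consumption (MMT/yr), slaughter rate
# (billion/yr) and population (billion) at the land cap. The slow RG-pasture
# slaughter entry is internally inconsistent in the source table
# (recomputes to 8.57 from its own consumption figure) and is not asserted.
TABLE1 = {
    ("Ross308", "cafo"): (20.0, 9.25, 1.19),
    ("Ross308", "outdoor"): (20.0, 9.24, 1.19),
    ("Ross308", "pasture"): (17.3, 7.99, 1.03),
    ("RC", "cafo"): (16.6, 9.12, 1.42),
    ("RC", "outdoor"): (16.6, 9.11, 1.42),
    ("RC", "pasture"): (13.9, 7.67, 1.20),
    ("RG", "cafo"): (16.7, 10.4, 1.63),
    ("RG", "outdoor"): (16.7, 10.4, 1.62),
    ("RG", "pasture"): (13.7, None, 1.34),
    ("RR", "cafo"): (15.3, 9.01, 1.70),
    ("RR", "outdoor"): (15.3, 9.00, 1.70),
    ("RR", "pasture"): (12.5, 7.35, 1.39),
}


def _tol(printed: float, decimals: int) -> float:
    # 0.5% relative or the printed rounding grid, whichever is looser
    return max(0.005 * printed, 0.5 * 10 ** -decimals)


@pytest.fixture(scope="module")
def results(params):
    out = bl.run_parameter_set(params)
    return {(r.breed, r.management.value): r for r in out}


class TestConstantLandScale:
    def test_identity_scenario(self):
        assert bl.constant_land_scale(75577.0, 75577.0) == 1.0

    def test_conventional_breed_on_pasture(self, results):
        r = results[("Ross308", "pasture")]
        assert r.scale_factor == pytest.approx(0.863, abs=1e-3)
        assert r.max_consumption == pytest.approx(17.3, abs=_tol(17.3, 1))

    def test_zero_scenario_land_rejected(self):
        with pytest.raises(ValueError):
            bl.constant_land_scale(0.0, 75577.0)


class TestScenarioGrid:
    def test_identity_scenario_is_exact_fixed_point(self, results, baseline):
        r = results[("Ross308", "cafo")]
        assert r.scale_factor == pytest.approx(1.0, rel=1e-12)
        assert r.consumption_decrease_mmt == pytest.approx(0.0, abs=1e-9)
        assert r.slaughter_rate_at_cap == pytest.approx(baseline.slaughter_rate, rel=1e-12)
        assert round(r.max_consumption, 1) == 20.1  # 20.056 MMT, reported as ~20

    @pytest.mark.parametrize("key", sorted(TABLE1))
    def test_consumption_slaughter_population_at_cap(self, results, key):
        cons, slaughter_b, pop_b = TABLE1[key]
        r = results[key]
        assert r.max_consumption == pytest.approx(cons, abs=_tol(cons, 1))
        if slaughter_b is not None:
            decimals = 1 if slaughter_b >= 10 else 2
            assert r.slaughter_rate_at_cap / 1e9 == pytest.approx(
                slaughter_b, abs=_tol(slaughter_b, decimals)
            )
        assert r.population_at_cap / 1e9 == pytest.approx(pop_b, abs=_tol(pop_b, 2))

    @pytest.mark.parametrize(
        "key, decrease_pct",
        [
            (("RC", "cafo"), 17.3),
            (("RG", "cafo"), 16.7),
            (("RR", "cafo"), 23.4),
            (("Ross308", "pasture"), 13.7),
            (("RC", "pasture"), 30.4),
            (("RG", "pasture"), 31.4),
            (("RR", "pasture"), 37.6),
            (("RC", "outdoor"), 17.4),
            (("RG", "outdoor"), 16.7),
            (("RR", "outdoor"), 23.5),
        ],
    )
    def test_required_consumption_decreases(self, results, key, decrease_pct):
        assert results[key].consumption_decrease_pct == pytest.approx(
            decrease_pct, abs=0.3
        )

    def test_outdoor_access_barely_moves_consumption(self, results):
        # ~17.6 million kg (0.0%) for the conventional breed with outdoor access
        r = results[("Ross308", "outdoor")]
        assert r.consumption_decrease_mmt * 1e3 == pytest.approx(17.6, abs=0.2)
        assert r.consumption_decrease_pct < 0.1

    def test_consumption_ordering_across_managements(self, results, breeds):
        for name in breeds:
            cafo = results[(name, "cafo")].max_consumption
            outdoor = results[(name, "outdoor")].max_consumption
            pasture = results[(name, "pasture")].max_consumption
            assert cafo >= outdoor >= pasture

    def test_capped_scenario_land_returns_to_cap(self, results, params, land_cap):
        """Defining fixed point: rebuilding each scenario at its capped
        consumption must land exactly on the baseline total."""
        feed_model = params.feed_model
        managements = {m.kind: m for m in params.managements}
        for (breed_name, mgmt_name), r in results.items():
            flock = bl.breed_flock(params.baseline, next(
                b for b in params.breeds if b.name == breed_name
            ))
            s = r.scale_factor
            capped = dataclasses.replace(
                flock,
                fattening_population=flock.fattening_population * s,
                breeding_population=flock.breeding_population * s,
                fattening_placement_rate=flock.fattening_placement_rate * s,
                hen_placement_rate=flock.hen_placement_rate * s,
            )
            if breed_name == "Ross308":
                capped_baseline = params.baseline.model_copy(
                    update={
                        "feed_total": params.baseline.feed_total * s,
                        "maize_mass": params.baseline.maize_mass * s,
                        "soy_mass": params.baseline.soy_mass * s,
                    }
                )
                fp = bl.footprint(
                    capped, managements[bl.ManagementKind(mgmt_name)], feed_model,
                    baseline=capped_baseline, baseline_mode=True,
                )
            else:
                fp = bl.footprint(
                    capped, managements[bl.ManagementKind(mgmt_name)], feed_model
                )
            assert fp.total == pytest.approx(land_cap, rel=1e-6)


class TestRunAll:
    def test_default_grid_has_twelve_deterministic_rows(self, params):
        res = bl.run_parameter_set(params)
        assert len(res) == 12
        assert [r.breed for r in res[:3]] == ["Ross308"] * 3
        assert [r.management.value for r in res[:3]] == ["cafo", "outdoor", "pasture"]

    def test_permuted_inputs_give_identical_rows(self, params):
        forward = bl.run_all(
            params.baseline, params.breeds, params.managements, params.feed_model
        )
        backward = bl.run_all(
            params.baseline, params.breeds[::-1], params.managements[::-1],
            params.feed_model,
        )
        assert forward == backward

    def test_single_pair_composes_with_run_scenario(self, params, breeds, land_cap):
        mgmt = params.managements[0]
        single = bl.run_all(params.baseline, [breeds["Ross308"]], [mgmt], params.feed_model)
        direct = bl.run_scenario(
            breeds["Ross308"], mgmt, params.baseline, params.feed_model,
            baseline_land=land_cap,
        )
        assert single == [direct]

    def test_empty_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            bl.run_all(params.baseline, [], params.managements, params.feed_model)

    def test_report_frames_shapes(self, params):
        res = bl.run_parameter_set(params)
        sf = bl.scenarios_frame(res)
        assert len(sf) == 12
        assert "max_consumption_mmt_per_yr" in sf.columns
        from broilerland.scenario import components_long_frame, footprints_frame

        assert len(footprints_frame(res)) == 12
        assert len(components_long_frame(res)) == 36
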
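"""Synthetic database generator: determinism, calibration, reconstruction."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvsignal import (
    ParameterError,
    build_all_contingencies,
    write_icsr_table,
)
from pvsignal.simulate import (
    ClassSpec,
    SimConfig,
    evaluate_operating_characteristics,
    generate_reports,
    generate_tabulated,
    make_class_map,
    null_config,
    power_config,
    simulate_tables,
    tabulate_virtual,
)


def small_cfg(seed=1, n=500, rr=1.0):
    return SimConfig(
        n_reports=n,
        seed=seed,
        background_event_prob=0.05,
        classes=[ClassSpec("HPV", 0.3, rr=rr), ClassSpec("INFLUENZA", 0.2)],
    )


class TestGenerateReports:
    def test_zero_reports_gives_empty_set(self):
        assert len(generate_reports(small_cfg(n=0))) == 0

    def test_determinism_byte_identical_serialization(self):
        rs1 = generate_reports(small_cfg(seed=42))
        rs2 = generate_reports(small_cfg(seed=42))
        assert rs1 == rs2
        b1, b2 = io.StringIO(), io.StringIO()
        write_icsr_table(rs1, b1)
        write_icsr_table(rs2, b2)
        assert b1.getvalue() == b2.getvalue()

    def test_different_seed_differs(self):
        assert generate_reports(small_cfg(seed=1)) != generate_reports(small_cfg(seed=2))

    def test_invalid_config_lists_violations(self):
        cfg = small_cfg()
        cfg.classes[0].exposure_prevalence = 1.5
        cfg.background_event_prob = -0.1
        with pytest.raises(ParameterError) as err:
            generate_reports(cfg)
        assert "exposure_prevalence" in str(err.value)
        assert "background_event_prob" in str(err.value)

    def test_reports_are_structurally_valid(self):
        from pvsignal import validate_report

        rs = generate_reports(small_cfg(seed=3))
        assert all(validate_report(r) == [] for r in rs)

    def test_null_case_count_within_binomial_bounds(self):
        """Null config, n=1e6, background 1e-4: cases within 3*sqrt(np) of 100."""
        cfg = SimConfig(
            n_reports=10**6,
            seed=5,
            background_event_prob=1e-4,
            classes=[ClassSpec("HPV", 0.05)],
        )
        t = simulate_tables(cfg)["HPV"]
        assert abs(t.n_cases - 100) <= 3 * math.sqrt(100)

    def test_counts_only_path_matches_materialized_tally(self):
        """simulate_tables and a brute-force tally over generate_reports
        agree exactly for the same seed."""
        cfg = small_cfg(seed=9, n=2000, rr=3.0)
        cm = make_class_map(cfg)
        fast = simulate_tables(cfg)
        tallied = build_all_contingencies(
            generate_reports(cfg), cfg.target_selector, cm
        )
        for cid in ("HPV", "INFLUENZA"):
            assert fast[cid].cells() == tallied[cid].cells()

    def test_marginal_calibration_within_4_se(self):
        cfg = SimConfig(
            n_reports=200_000,
            seed=13,
            background_event_prob=2e-3,
            classes=[ClassSpec("HPV", 0.01)],
        )
        t = simulate_tables(cfg)["HPV"]
        n = cfg.n_reports
        prev_hat = (t.a + t.b) / n
        se_prev = math.sqrt(0.01 * 0.99 / n)
        assert abs(prev_hat - 0.01) <= 4 * se_prev
        case_hat = t.n_cases / n
        se_case = math.sqrt(2e-3 * (1 - 2e-3) / n)
        assert abs(case_hat - 2e-3) <= 4 * se_case

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_cfg()
        p = tmp_path / "sim.yaml"
        cfg.to_file(p)
        cfg2 = SimConfig.from_file(p)
        assert cfg2 == cfg


class TestGenerateTabulated:
    def test_single_class_all_cases_exposed_no_exposed_noncases(self, target):
        rs = generate_tabulated({"HPV": (5, 0)}, n_cases=5, n_reports=20)
        from pvsignal.reference import reference_class_map

        t = build_all_contingencies(rs, target, reference_class_map())["HPV"]
        assert t.cells() == (5, 0, 0, 15)

    @pytest.mark.parametrize(
        "counts, n_cases, n_reports, msg",
        [
            ({"HPV": (9, 0)}, 8, 100, "exceeds n_cases"),
            ({"HPV": (1, 95)}, 8, 100, "exceeds n_noncases"),
            ({"HPV": (-1, 0)}, 8, 100, "non-negative"),
        ],
    )
    def test_infeasible_counts_rejected(self, counts, n_cases, n_reports, msg):
        with pytest.raises(ParameterError, match=msg):
            generate_tabulated(counts, n_cases, n_reports)

    def test_n_exposed_cases_constraint_bounds(self):
        with pytest.raises(ParameterError, match="infeasible"):
            generate_tabulated({"A": (5, 0), "B": (2, 0)}, 10, 20, n_exposed_cases=4)
        with pytest.raises(ParameterError, match="infeasible"):
            generate_tabulated({"A": (5, 0), "B": (2, 0)}, 10, 20, n_exposed_cases=8)

    @given(
        spec=st.dictionaries(
            st.sampled_from(["A", "B", "C"]),
            st.tuples(st.integers(0, 10), st.integers(0, 30)),
            min_size=1,
            max_size=3,
        ),
        extra_cases=st.integers(0, 5),
        extra_reports=st.integers(0, 50),
    )
    @settings(max_examples=40, deadline=None)
    def test_reconstruction_fidelity_on_feasible_specs(
        self, spec, extra_cases, extra_reports
    ):
        """generate_tabulated then tallying is the identity on counts."""
        from conftest import TARGET as target

        from pvsignal import ClassMap

        n_cases = max(a for a, _ in spec.values()) + extra_cases
        n_reports = n_cases + max(b for _, b in spec.values()) + extra_reports
        rs = generate_tabulated(spec, n_cases, n_reports)
        cm = ClassMap(
            entries={}, labels={c: c for c in [*spec, "OTHER"]},
        )
        tables = build_all_contingencies(rs, target, cm, class_ids=list(spec))
        for cid, (a, b) in spec.items():
            assert (tables[cid].a, tables[cid].b) == (a, b)
        virtual = tabulate_virtual(spec, n_cases, n_reports)
        for cid in spec:
            assert virtual[cid].cells() == tables[cid].cells()


class TestOperatingCharacteristics:
    def test_single_replicate_frequencies_are_zero_or_one(self):
        oc = evaluate_operating_characteristics(small_cfg(seed=2, n=2000), 1)
        assert set(oc.per_class_flag_freq.values()) <= {0.0, 1.0}
        assert set(oc.per_class_eval_freq.values()) <= {0.0, 1.0}

    def test_deterministic_given_seed_and_replicates(self):
        oc1 = evaluate_operating_characteristics(small_cfg(seed=4, n=2000), 5)
        oc2 = evaluate_operating_characteristics(small_cfg(seed=4, n=2000), 5)
        assert oc1 == oc2

    def test_materialized_and_fast_paths_have_same_interface(self):
        oc = evaluate_operating_characteristics(
            small_cfg(seed=6, n=800), 3, materialize=True
        )
        assert oc.replicates == 3

    def test_replicates_must_be_positive(self):
        with pytest.raises(ParameterError):
            evaluate_operating_characteristics(small_cfg(), 0)

    def test_stock_designs_validate(self):
        assert null_config().validate() == []
        assert power_config().validate() == []
        assert null_config().is_null
        assert not power_config().is_null
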
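"""REF statistic: worked examples, invariances, aggregation and calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sipracs import (
    AsvFractionTable,
    CallingParams,
    aggregate_window_abundance,
    call_active_degraders,
    compute_ref,
    soil_gradient_config,
    simulate_gradient_experiment,
)
from sipracs.gradient import DEFAULT_WINDOWS, Fraction, GradientRun

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False, allow_infinity=False)


class TestComputeRef:
    @pytest.mark.parametrize(
        "abundances,expected",
        [
            ((0.309, 0.100, 0.050, 0.050), 3.09),
            ((0.334, 0.100, 0.080, 0.080), 3.34),
        ],
    )
    def test_worked_examples_exact(self, abundances, expected):
        assert compute_ref(*abundances, pseudocount=0.0) == pytest.approx(expected, abs=1e-12)

    def test_null_case_is_one(self):
        assert compute_ref(0.2, 0.2, 0.7, 0.7, pseudocount=0.0) == pytest.approx(1.0)

    @settings(deadline=None)
    @given(a13h=positive, a13l=positive, a12h=positive, a12l=positive, c=positive)
    def test_scale_invariance(self, a13h, a13l, a12h, a12l, c):
        base = compute_ref(a13h, a13l, a12h, a12l, pseudocount=0.0)
        scaled_13 = compute_ref(c * a13h, c * a13l, a12h, a12l, pseudocount=0.0)
        scaled_12 = compute_ref(a13h, a13l, c * a12h, c * a12l, pseudocount=0.0)
        assert scaled_13 == pytest.approx(base, rel=1e-9)
        assert scaled_12 == pytest.approx(base, rel=1e-9)

    @settings(deadline=None)
    @given(a13h=positive, a13l=positive, a12h=positive, a12l=positive)
    def test_antisymmetry_under_treatment_swap(self, a13h, a13l, a12h, a12l):
        ref = compute_ref(a13h, a13l, a12h, a12l, pseudocount=0.0)
        swapped = compute_ref(a12h, a12l, a13h, a13l, pseudocount=0.0)
        assert swapped == pytest.approx(1.0 / ref, rel=1e-9)

    def test_all_zero_with_zero_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            compute_ref(0.0, 0.0, 0.0, 0.0, pseudocount=0.0)

    def test_pseudocount_applied_only_when_needed(self):
        # exact when no zeros, finite when a denominator is zero
        assert compute_ref(0.309, 0.1, 0.05, 0.05) == pytest.approx(3.09, abs=1e-12)
        assert np.isfinite(compute_ref(0.3, 0.0, 0.05, 0.05))

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_ref(-0.1, 0.1, 0.1, 0.1)


def tiny_table(values):
    """Table over 2 fractions per treatment: heavy=1 (BD 1.7375), light=2 (1.7060)."""
    asvs = list(values)
    cols = pd.MultiIndex.from_tuples(
        [(t, k) for t in ("12C", "13C") for k in (1, 2)],
        names=["treatment", "fraction_number"],
    )
    data = pd.DataFrame(
        [[values[a][c] for c in cols] for a in asvs],
        index=pd.Index(asvs, name="asv_id"),
        columns=cols,
    )
    return AsvFractionTable(data, check=False)


def tiny_runs():
    runs = {}
    for t in ("12C", "13C"):
        runs[t] = GradientRun(
            treatment=t,
            fractions=[
                Fraction(treatment=t, fraction_number=1, buoyant_density=1.7375, copies_16s=1.0),
                Fraction(treatment=t, fraction_number=2, buoyant_density=1.7060, copies_16s=1.0),
            ],
        )
    return runs


class TestAggregation:
    def test_single_fraction_mean_is_identity(self):
        table = tiny_table({
            "a": {("12C", 1): 0.3, ("12C", 2): 0.4, ("13C", 1): 0.6, ("13C", 2): 0.1},
            "b": {("12C", 1): 0.7, ("12C", 2): 0.6, ("13C", 1): 0.4, ("13C", 2): 0.9},
        })
        agg = aggregate_window_abundance(table, DEFAULT_WINDOWS, tiny_runs())
        row = agg.frame.loc["a"]
        assert row["a13_heavy"] == pytest.approx(0.6)
        assert row["a13_light"] == pytest.approx(0.1)
        assert row["a12_heavy"] == pytest.approx(0.3)
        assert row["a12_light"] == pytest.approx(0.4)

    def test_two_heavy_fractions_average(self):
        runs = tiny_runs()
        for t in runs:
            runs[t] = GradientRun(
                treatment=t,
                fractions=runs[t].fractions
                + [Fraction(treatment=t, fraction_number=3,
                            buoyant_density=1.7400, copies_16s=1.0)],
            )
        cols = pd.MultiIndex.from_tuples(
            [(t, k) for t in ("12C", "13C") for k in (1, 2, 3)],
            names=["treatment", "fraction_number"],
        )
        data = pd.DataFrame(
            [[0.10, 0.5, 0.20, 0.10, 0.5, 0.20]],
            index=pd.Index(["a"], name="asv_id"),
            columns=cols,
        )
        agg = aggregate_window_abundance(
            AsvFractionTable(data, check=False), DEFAULT_WINDOWS, runs
        )
        assert agg.frame.loc["a", "a13_heavy"] == pytest.approx(0.15)  # mean(0.10, 0.20)

    def test_empty_window_rejected_with_window_name(self):
        runs = tiny_runs()
        light_only = {
            t: GradientRun(treatment=t, fractions=[runs[t].fractions[1]]) for t in runs
        }
        table = tiny_table({
            "a": {("12C", 1): 0.3, ("12C", 2): 0.4, ("13C", 1): 0.6, ("13C", 2): 0.1},
        })
        with pytest.raises(ValueError, match="heavy"):
            aggregate_window_abundance(table, DEFAULT_WINDOWS, light_only)

    def test_matches_explicit_loop_oracle(self, sip_experiment, sip_windows, sip_aggregates):
        from sipracs.gradient import classify_fraction

        _, run12, run13, table = sip_experiment
        runs = {"12C": run12, "13C": run13}
        for asv in table.asv_ids[:25]:
            for treatment, window, col in (
                ("13C", "heavy", "a13_heavy"),
                ("13C", "light", "a13_light"),
                ("12C", "heavy", "a12_heavy"),
                ("12C", "light", "a12_light"),
            ):
                vals = []
                for f in runs[treatment].fractions:
                    if classify_fraction(f.buoyant_density, sip_windows) == window:
                        vals.append(table.column(treatment, f.fraction_number)[asv])
                expected = sum(vals) / len(vals)
                assert sip_aggregates.frame.loc[asv, col] == pytest.approx(expected, rel=1e-12)


class TestCalling:
    def test_all_ref_one_gives_empty_active_set(self):
        table = tiny_table({
            "a": {("12C", 1): 0.3, ("12C", 2): 0.3, ("13C", 1): 0.3, ("13C", 2): 0.3},
            "b": {("12C", 1): 0.7, ("12C", 2): 0.7, ("13C", 1): 0.7, ("13C", 2): 0.7},
        })
        agg = aggregate_window_abundance(table, DEFAULT_WINDOWS, tiny_runs())
        records = call_active_degraders(table, agg, CallingParams(top_n=2))
        assert not any(r.active for r in records)

    def test_threshold_is_strict(self):
        # ASV 'a' engineered to REF == exactly 2.0
        table = tiny_table({
            "a": {("12C", 1): 0.2, ("12C", 2): 0.2, ("13C", 1): 0.4, ("13C", 2): 0.2},
            "b": {("12C", 1): 0.8, ("12C", 2): 0.8, ("13C", 1): 0.6, ("13C", 2): 0.8},
        })
        agg = aggregate_window_abundance(table, DEFAULT_WINDOWS, tiny_runs())
        records = {r.asv_id: r for r in call_active_degraders(table, agg, CallingParams(top_n=2))}
        assert records["a"].ref == pytest.approx(2.0)
        assert not records["a"].active

    def test_recovers_exactly_the_labelled_taxa(
        self, sip_experiment, sip_aggregates
    ):
        cfg, _, _, table = sip_experiment
        records = call_active_degraders(table, sip_aggregates)
        active = {r.asv_id for r in records if r.active}
        assert active == set(cfg.labelled_taxa)

    def test_fewer_asvs_than_top_n_warns_and_uses_all(self):
        table = tiny_table({
            "a": {("12C", 1): 0.3, ("12C", 2): 0.3, ("13C", 1): 0.3, ("13C", 2): 0.3},
            "b": {("12C", 1): 0.7, ("12C", 2): 0.7, ("13C", 1): 0.7, ("13C", 2): 0.7},
        })
        agg = aggregate_window_abundance(table, DEFAULT_WINDOWS, tiny_runs())
        with pytest.warns(UserWarning, match="fewer than top_n"):
            records = call_active_degraders(table, agg, CallingParams(top_n=100))
        assert len(records) == 2

    def test_matches_exhaustive_recomputation_on_small_table(self):
        """Full calling pipeline agrees with a from-scratch loop on ≤20 ASVs."""
        cfg = soil_gradient_config(seed=13, n_taxa=20,
                                          labelled={"ASV_2": 1.0, "ASV_7": 0.8})
        run12, run13, table = simulate_gradient_experiment(cfg)
        from sipracs.gradient import classify_fraction, identify_windows

        windows = identify_windows(run12, run13)
        runs = {"12C": run12, "13C": run13}
        agg = aggregate_window_abundance(table, windows, runs)
        params = CallingParams(top_n=10, threshold=2.0)
        records = {r.asv_id: r for r in call_active_degraders(table, agg, params)}

        # independent oracle: explicit loops, no shared code paths
        window_cols = {}
        for t in ("12C", "13C"):
            for w in ("heavy", "light"):
                window_cols[(t, w)] = [
                    f.fraction_number
                    for f in runs[t].fractions
                    if classify_fraction(f.buoyant_density, windows) == w
                ]
        rank_vals = {}
        for asv in table.asv_ids:
            vals = [
                table.column(t, k)[asv]
                for (t, _w), ks in window_cols.items()
                for k in ks
            ]
            rank_vals[asv] = sum(vals) / len(vals)
        order = sorted(table.asv_ids, key=lambda a: (-rank_vals[a], a))
        for asv in table.asv_ids:
            terms = []
            for t, w in (("13C", "heavy"), ("13C", "light"), ("12C", "heavy"), ("12C", "light")):
                ks = window_cols[(t, w)]
                terms.append(sum(table.column(t, k)[asv] for k in ks) / len(ks))
            if any(x == 0 for x in terms):
                terms = [x + params.pseudocount for x in terms]
            expected_ref = (terms[0] / terms[1]) / (terms[2] / terms[3])
            rank = order.index(asv) + 1
            assert records[asv].ref == pytest.approx(expected_ref, rel=1e-12)
            assert records[asv].rank == rank
            assert records[asv].active == (rank <= 10 and expected_ref > 2.0)
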
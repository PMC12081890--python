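"""Four-filter gating: per-filter behaviour, KDE live gate, composition."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytoferm import simulate
from cytoferm.events import EmptyTableError, EventTable
from cytoferm.gating import (
    GateConfig,
    LiveGateFitError,
    apply_gfp_gate,
    apply_singlet_filter,
    apply_static_filter,
    fit_live_gate,
    gate_sample,
    gate_timeseries,
    summarize_subpopulations,
)
from conftest import true_live_fraction


def table_from(width=None, fl1=None, fl3=None, n=None):
    if n is None:
        n = len(next(v for v in (width, fl1, fl3) if v is not None))
    return EventTable.from_arrays(
        fsc_h=[1e5] * n,
        width=width if width is not None else [50.0] * n,
        fl1_h=fl1 if fl1 is not None else [100.0] * n,
        fl3_h=fl3 if fl3 is not None else [100.0] * n,
    )


class TestStaticFilter:
    def test_excludes_zero_channel_events(self, toy_table):
        mask = apply_static_filter(toy_table)
        assert mask.sum() == 4
        assert not mask[4]  # the fl1_h == 0 event

    def test_identity_when_all_nonzero(self):
        mask = apply_static_filter(table_from(fl1=[1, 2, 3], fl3=[4, 5, 6]))
        assert mask.all()

    def test_all_zero_green_channel_removes_everything(self):
        table = table_from(fl1=[0.0, 0.0, 0.0])
        mask = apply_static_filter(table)
        assert mask.sum() == 0
        subs = summarize_subpopulations(
            {
                "static": mask,
                "single": np.ones(3, bool),
                "gfp_positive": np.ones(3, bool),
                "live": np.ones(3, bool),
            }
        )
        assert (subs["count"] == 0).all()

    def test_empty_table_rejected(self):
        with pytest.raises(EmptyTableError):
            apply_static_filter(table_from(n=0, fl1=[]))


class TestCutoffFilters:
    def test_singlet_cutoff_enumeration(self):
        mask = apply_singlet_filter(table_from(width=[50, 50, 120]), 80)
        assert mask.tolist() == [True, True, False]

    @pytest.mark.parametrize(
        "cutoff,expected", [(120, [True] * 3), (49, [False] * 3)]
    )
    def test_singlet_cutoff_extremes(self, cutoff, expected):
        mask = apply_singlet_filter(table_from(width=[50, 60, 120]), cutoff)
        assert mask.tolist() == expected

    def test_gfp_cutoff_enumeration(self):
        mask = apply_gfp_gate(table_from(fl1=[1000, 10]), 100)
        assert mask.tolist() == [True, False]

    @pytest.mark.parametrize(
        "cutoff,expected", [(10, [True] * 2), (2000, [False] * 2)]
    )
    def test_gfp_cutoff_extremes(self, cutoff, expected):
        mask = apply_gfp_gate(table_from(fl1=[1000, 10]), cutoff)
        assert mask.tolist() == expected

    @pytest.mark.parametrize("op", [apply_singlet_filter, apply_gfp_gate])
    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_cutoffs_rejected(self, op, bad):
        with pytest.raises(ValueError):
            op(table_from(n=2, fl1=[1, 2]), bad)

    @given(
        lo=st.floats(1, 500),
        hi=st.floats(1, 500),
    )
    def test_monotonicity_in_cutoffs(self, lo, hi):
        """Raising the width cut-off never loses singlets; raising the
        FL1 cut-off never gains GFP-positives."""
        lo, hi = min(lo, hi), max(lo, hi)
        table = table_from(
            width=[10, 60, 110, 200, 490], fl1=[5, 50, 120, 300, 499]
        )
        assert (
            apply_singlet_filter(table, lo) <= apply_singlet_filter(table, hi)
        ).all()
        assert (apply_gfp_gate(table, hi) <= apply_gfp_gate(table, lo)).all()


class TestLiveGate:
    def test_recovers_known_live_fraction(self, live_dead_events):
        model = fit_live_gate(live_dead_events)
        assert not model.unimodal_fallback
        recovered = model.live_mask(live_dead_events).mean()
        assert abs(recovered - true_live_fraction(live_dead_events)) <= 0.02
        assert abs(recovered - 0.70) <= 0.02

    def test_threshold_in_mixture_valley(self):
        """Equal live/dead components at log10 2.0 and 4.2: the fitted
        threshold must fall inside the density valley."""
        spec = simulate.live_dead_spec(live_fraction=0.5)
        events = simulate.simulate_events(spec, n=12_000, seed=11)
        model = fit_live_gate(events)
        assert 2.5 < np.log10(model.threshold) < 3.7
        lo, hi = sorted(model.mode_locations)
        assert lo < np.log10(model.threshold) < hi

    def test_single_component_falls_back_unimodal(self):
        spec = simulate.PopulationSpec(
            (simulate._component("live_singlet_gfp_pos", 1.0, 3.5, 2.0),)
        )
        events = simulate.simulate_events(spec, n=2_000, seed=5)
        model = fit_live_gate(events)
        assert model.unimodal_fallback
        assert model.live_mask(events).all()

    def test_constant_channel_falls_back(self):
        events = table_from(n=100, fl3=[500.0] * 100)
        model = fit_live_gate(events)
        assert model.unimodal_fallback
        assert model.live_mask(events).all()

    def test_too_few_events_refused(self):
        events = table_from(n=20, fl3=list(np.linspace(10, 1e4, 20)))
        with pytest.raises(LiveGateFitError):
            fit_live_gate(events)

    def test_fitted_model_is_idempotent(self, live_dead_events):
        model = fit_live_gate(live_dead_events)
        first = model.live_mask(live_dead_events)
        second = model.live_mask(live_dead_events)
        assert np.array_equal(first, second)


class TestSubpopulations:
    def test_toy_fixture_counts(self, toy_masks):
        subs = summarize_subpopulations(toy_masks)
        assert subs.loc["live", "count"] == 3
        assert subs.loc["live_single", "count"] == 2
        assert subs.loc["live_single_gfp_pos", "count"] == 1
        assert subs.loc["live_single_gfp_neg", "count"] == 1
        assert subs.attrs["n_static"] == 4

    def test_gfp_partitions_live_single(self, toy_masks):
        subs = summarize_subpopulations(toy_masks)
        assert (
            subs.loc["live_single_gfp_pos", "count"]
            + subs.loc["live_single_gfp_neg", "count"]
            == subs.loc["live_single", "count"]
        )

    def test_complements_partition_static_set(self, toy_masks):
        subs = summarize_subpopulations(toy_masks)
        n = subs.attrs["n_static"]
        assert subs.loc["live", "count"] + subs.loc["dead", "count"] == n
        assert (
            subs.loc["live_single", "count"]
            + subs.loc["not_live_single", "count"]
            == n
        )

    def test_composed_counts_bounded_by_constituents(self, toy_masks):
        subs = summarize_subpopulations(toy_masks)
        for name, mask_keys in [
            ("live", ["static", "live"]),
            ("live_single", ["static", "live", "single"]),
            ("live_single_gfp_pos", ["static", "live", "single", "gfp_positive"]),
        ]:
            for key in mask_keys:
                assert subs.loc[name, "count"] <= toy_masks[key].sum()
        assert ((subs["fraction"] >= 0) & (subs["fraction"] <= 1)).all()

    def test_empty_live_mask_zeroes_composed_subsets(self, toy_masks):
        masks = dict(toy_masks, live=np.zeros(5, bool))
        subs = summarize_subpopulations(masks)
        assert subs.loc["live", "count"] == 0
        assert subs.loc["live_single", "count"] == 0
        assert subs.loc["live_single_gfp_pos", "count"] == 0

    def test_low_gfp_cutoff_makes_gfp_pos_equal_live_single(self, toy_table):
        masks = {
            "static": apply_static_filter(toy_table),
            "single": apply_singlet_filter(toy_table, 80.0),
            "gfp_positive": apply_gfp_gate(toy_table, 1e-6),
            "live": toy_table.fl3_h < 1000.0,
        }
        subs = summarize_subpopulations(masks)
        assert (
            subs.loc["live_single_gfp_pos", "count"]
            == subs.loc["live_single", "count"]
        )

    def test_misaligned_masks_rejected(self, toy_masks):
        masks = dict(toy_masks, live=np.ones(3, bool))
        with pytest.raises(ValueError, match="aligned"):
            summarize_subpopulations(masks)

    def test_mask_order_is_irrelevant(self, toy_masks):
        """Intersections commute: any permutation of the mask dictionary
        yields the same subpopulation counts."""
        reference = summarize_subpopulations(toy_masks)["count"]
        for perm in itertools.permutations(toy_masks):
            permuted = {k: toy_masks[k] for k in perm}
            assert (
                summarize_subpopulations(permuted)["count"] == reference
            ).all()


class TestTimeseries:
    def test_identical_samples_give_identical_rows(self, live_dead_events):
        config = GateConfig(width_cutoff=200, fl1_cutoff=100)
        table = gate_timeseries([live_dead_events] * 3, config)
        assert len(table) == 3
        body = table.drop(columns="time")
        assert (body.iloc[0] == body.iloc[1]).all()
        assert (body.iloc[0] == body.iloc[2]).all()

    def test_single_sample_matches_gate_sample(self, live_dead_events):
        config = GateConfig(width_cutoff=200, fl1_cutoff=100)
        table = gate_timeseries([live_dead_events], config)
        single = gate_sample(live_dead_events, config)
        assert len(table) == 1
        assert (
            table.loc[0, "frac_live"]
            == single.subpopulations.loc["live", "fraction"]
        )
        assert table.loc[0, "live_gate_threshold"] == single.live_gate.threshold

    def test_recovers_varying_live_fractions(self):
        """A series with live fraction falling over time: per-timepoint
        recovery against generator ground truth within ±0.02."""
        config = GateConfig(width_cutoff=200, fl1_cutoff=100)
        fractions = [0.9, 0.75, 0.55]
        samples = [
            simulate.simulate_events(
                simulate.live_dead_spec(f), n=12_000, seed=100 + i
            )
            for i, f in enumerate(fractions)
        ]
        table = gate_timeseries(samples, config, times=[0.0, 10.0, 20.0])
        for row, sample in zip(table.itertuples(), samples):
            assert not row.unimodal_fallback
            assert abs(row.frac_live - true_live_fraction(sample)) <= 0.02

    def test_fallback_samples_are_flagged_not_dropped(self, live_dead_events):
        config = GateConfig(width_cutoff=200, fl1_cutoff=100)
        unimodal = simulate.simulate_events(
            simulate.PopulationSpec(
                (simulate._component("live_singlet_gfp_pos", 1.0, 3.5, 2.0),)
            ),
            n=2_000,
            seed=9,
        )
        table = gate_timeseries([live_dead_events, unimodal], config)
        assert len(table) == 2
        assert table["unimodal_fallback"].tolist() == [False, True]
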
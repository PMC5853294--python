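import numpy as np
import pandas as pd
import pytest

from tagflux import (
    Edge,
    LabelingProtocol,
    PoolModel,
    TransferFractionSeries,
    TransferSeries,
    assemble_partition,
    conversion_efficiency,
    daily_pl_synthesis,
    de_novo_direct_daily,
    de_novo_via_pl_daily,
    partition_from_dataset,
    pathway_fractions,
    pl_transfer_fractions,
    pooled_source_series,
    preformed_pl_estimate,
    relative_de_novo,
    simulate,
    starch_to_tag_daily,
)
from tagflux.partition import UndefinedEfficiencyError

from conftest import make_timecourse


def series(values, start=1):
    return pd.Series(values, index=pd.RangeIndex(start, start + len(values), name="day"))


# ---------------------------------------------------------------------------
# pooled transfers and conversion efficiency


def test_constant_series_gives_zero_transfers():
    tc = make_timecourse(
        {"starch": {1: 50.0, 2: 50.0, 3: 50.0}, "TAG": {1: 5.0, 2: 5.0, 3: 5.0}}
    )
    ts = pooled_source_series(tc, ["starch"], "TAG")
    assert np.all(ts.source_decrease == 0) and np.all(ts.sink_increase == 0)


def test_toy_chase_totals():
    tc = make_timecourse(
        {
            "starch": {1: 200.0, 2: 150.0, 3: 100.0},
            "soluble": {1: 100.0, 2: 60.0, 3: 20.0},
            "TAG": {1: 20.0, 2: 110.0, 3: 200.0},
        }
    )
    ts = pooled_source_series(tc, ["starch", "soluble"], "TAG")
    assert ts.source_decrease.sum() == pytest.approx(180.0)
    assert ts.sink_increase.sum() == pytest.approx(180.0)
    assert conversion_efficiency(ts) == pytest.approx(1.0)


def test_negative_transfers_are_clamped_but_kept_in_diagnostics():
    tc = make_timecourse({"starch": {1: 100.0, 2: 120.0, 3: 80.0}, "TAG": {1: 0.0, 2: 0.0, 3: 5.0}})
    ts = pooled_source_series(tc, ["starch"], "TAG")
    assert ts.source_decrease[0] == 0.0  # rise clamps to zero
    assert ts.diagnostics["source_diff"][0] == pytest.approx(20.0)


@pytest.mark.parametrize(
    "sink_total, source_total, expected",
    [(180.0, 300.0, 0.60), (9.0, 12.0, 0.75)],
)
def test_conversion_efficiency_reproduces_published_chases(
    sink_total, source_total, expected
):
    ts = TransferSeries(
        intervals=((1.0, 8.0),),
        source_decrease=np.array([source_total]),
        sink_increase=np.array([sink_total]),
    )
    assert conversion_efficiency(ts) == pytest.approx(expected)


def test_conversion_efficiency_edge_cases():
    zero_sink = TransferSeries(
        intervals=((0.0, 1.0),),
        source_decrease=np.array([10.0]),
        sink_increase=np.array([0.0]),
    )
    assert conversion_efficiency(zero_sink) == 0.0
    zero_source = TransferSeries(
        intervals=((0.0, 1.0),),
        source_decrease=np.array([0.0]),
        sink_increase=np.array([5.0]),
    )
    with pytest.raises(UndefinedEfficiencyError):
        conversion_efficiency(zero_source)
    influx = TransferSeries(
        intervals=((0.0, 1.0),),
        source_decrease=np.array([5.0]),
        sink_increase=np.array([10.0]),
    )
    with pytest.warns(UserWarning, match="exceeds 1"):
        assert conversion_efficiency(influx) == pytest.approx(2.0)


def test_closed_chain_chase_has_unit_efficiency():
    model = PoolModel(
        pools=("ext", "A", "B"),
        edges=(Edge("ext", "A", 1.0), Edge("A", "B", 0.4)),
        external_pool="ext",
        external_level=100.0,
    )
    proto = LabelingProtocol(
        tracer="bicarbonate", label_start=0.0, label_end=1.0, chase_end=9.0
    )
    tc = simulate(model, proto, grid=np.arange(1.0, 10.0))
    eff = conversion_efficiency(pooled_source_series(tc, ["A"], "B"))
    assert eff == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# daily pathway series


def test_flat_tag_series_attribute_nothing():
    pulses = [
        make_timecourse(
            {"starch": {p: 50.0, 8: 50.0}, "TAG": {p: 3.0, 8: 3.0}, "polar_lipid": {p: 1.0, 8: 1.0}},
            label_end=float(p),
        )
        for p in range(1, 8)
    ]
    assert starch_to_tag_daily(pulses).sum() == 0.0


def test_direct_series_passes_through_label_end_tag():
    pulses = [
        make_timecourse({"TAG": {1.0: 8.0, 8.0: 30.0}}, label_end=1.0),
        make_timecourse({"TAG": {2.0: 7.5, 8.0: 20.0}}, label_end=2.0),
    ]
    direct = de_novo_direct_daily(pulses)
    assert direct.loc[1] == pytest.approx(8.0)
    assert direct.loc[2] == pytest.approx(7.5)
    assert direct.loc[3:].sum() == 0.0


def test_missing_label_end_sample_is_an_error():
    tc = make_timecourse({"TAG": {2.0: 1.0}}, label_end=1.0)
    with pytest.raises(ValueError, match="label end"):
        de_novo_direct_daily([tc])


def test_starch_to_tag_on_simulated_pulses_matches_truth(noisefree_dataset):
    """Noise-free chase gains equal the simulator's integrated post-pulse flux."""
    from_starch = starch_to_tag_daily(noisefree_dataset.daily_bicarbonate_pulses)
    assert from_starch.loc[1] == 0.0
    # every post-pulse TAG gain is accounted for: per-pulse totals match the
    # TAG difference between day 8 and label end
    total_expected = 0.0
    for tc in noisefree_dataset.daily_bicarbonate_pulses:
        tag = tc.pool_mean("TAG")
        total_expected += tag.loc[8.0] - tag.loc[tc.label_end]
    assert from_starch.sum() == pytest.approx(total_expected, rel=1e-9)


def test_transfer_fractions_from_toy_chase():
    tc = make_timecourse(
        {"polar_lipid": {1: 100.0, 2: 60.0, 3: 30.0}, "TAG": {1: 0.0, 2: 40.0, 3: 70.0}},
        tracer="palmitic_acid",
        label_end=1.0,
    )
    fr = pl_transfer_fractions(tc)
    assert fr(1) == pytest.approx(0.40)
    assert fr(2) == pytest.approx(0.30)
    assert fr.cumulative == pytest.approx(0.70)


def test_transfer_fractions_cumulative_capped_at_one():
    tc = make_timecourse(
        {"polar_lipid": {1: 100.0, 2: 0.0, 3: 0.0}, "TAG": {1: 0.0, 2: 80.0, 3: 160.0}},
        tracer="palmitic_acid",
        label_end=1.0,
    )
    fr = pl_transfer_fractions(tc)
    assert fr.cumulative == pytest.approx(1.0)
    assert fr(2) == pytest.approx(0.2)


def test_transfer_fraction_requires_label_at_label_end():
    tc = make_timecourse(
        {"polar_lipid": {1: 0.0, 2: 0.0}, "TAG": {1: 0.0, 2: 1.0}},
        tracer="palmitic_acid",
        label_end=1.0,
    )
    with pytest.raises(UndefinedEfficiencyError):
        pl_transfer_fractions(tc)


def test_transfer_fractions_match_first_order_kinetics(noisefree_dataset):
    """Cumulative fraction agrees with 1 - exp(-k T) for the true rate."""
    fr = pl_transfer_fractions(noisefree_dataset.day1_pla_chase)
    truth = noisefree_dataset.truth["pl_to_tag_fraction_day1"]
    assert fr.cumulative == pytest.approx(truth, abs=0.05)


def test_via_pl_convolution_single_synthesis_day():
    synth = series([100.0, 0.0, 0.0])
    fr = TransferFractionSeries(fractions=pd.Series([0.4, 0.3], index=[1, 2]))
    out = de_novo_via_pl_daily(synth, fr)
    assert list(out) == pytest.approx([0.0, 40.0, 30.0])


def test_via_pl_zero_fractions_give_zero_output():
    synth = series([10.0] * 8)
    fr = TransferFractionSeries(fractions=pd.Series([0.0] * 7, index=range(1, 8)))
    assert de_novo_via_pl_daily(synth, fr).sum() == 0.0


def test_daily_pl_synthesis_reads_label_end(noisefree_dataset):
    made = daily_pl_synthesis(noisefree_dataset.daily_bicarbonate_pulses)
    assert made.loc[1] > 5 * made.loc[2]  # day-1 burst dominates


# ---------------------------------------------------------------------------
# assembly, fractions, report quantities


def test_assemble_partition_reproduces_published_row_sums(table1):
    p = assemble_partition(
        table1["from_starch"],
        table1["de_novo_direct"],
        table1["de_novo_via_pl"],
        table1["total_measured"],
    )
    assert p.table.loc[2, "total_calculated"] == pytest.approx(61.2)
    assert p.table.loc[5, "total_calculated"] == pytest.approx(51.3)
    assert p.table.loc[3, "de_novo_via_pl"] == pytest.approx(20.2)
    assert p.column_totals["total_measured"] == pytest.approx(358.0)


def test_assemble_partition_rejects_negatives(table1):
    with pytest.raises(ValueError, match="negative"):
        assemble_partition(
            table1["from_starch"] - 50.0,
            table1["de_novo_direct"],
            table1["de_novo_via_pl"],
            table1["total_measured"],
        )


def test_all_zero_partition_is_valid():
    z = series([0.0] * 8)
    p = assemble_partition(z, z, z, z)
    assert (p.table.to_numpy() == 0).all()


def test_row_closure_holds_exactly(noisy_dataset):
    p = partition_from_dataset(noisy_dataset)
    lhs = p.table[["from_starch", "de_novo_direct", "de_novo_via_pl"]].sum(axis=1)
    assert np.array_equal(lhs.to_numpy(), p.table["total_calculated"].to_numpy())


def test_pathway_fractions_on_published_totals(table1):
    p = assemble_partition(
        table1["from_starch"],
        table1["de_novo_direct"],
        table1["de_novo_via_pl"],
        table1["total_measured"],
    )
    fr = pathway_fractions(p)
    # printed column totals give 233.8 / 354.3 ~ 0.66 from starch; the
    # printed daily starch entries sum to 234.5, hence the loose tolerance
    assert fr["from_starch"] == pytest.approx(0.660, abs=0.005)
    assert fr.sum() == pytest.approx(1.0)


def test_pathway_fractions_degenerate_cases():
    z = series([0.0] * 8)
    only = series([1.0] * 8)
    p = assemble_partition(only, z, z, only)
    fr = pathway_fractions(p)
    assert fr["from_starch"] == 1.0 and fr["de_novo_direct"] == 0.0
    thirds = assemble_partition(only, only, only, 3 * only)
    assert pathway_fractions(thirds).to_numpy() == pytest.approx([1 / 3] * 3)


# ---------------------------------------------------------------------------
# pre-formed polar lipids and condition comparison


def preformed_toy(fraction=0.75):
    pl0 = 16.0
    return make_timecourse(
        {
            "polar_lipid": {0: pl0, 8: pl0 * (1 - fraction)},
            "TAG": {0: 0.0, 8: pl0 * fraction},
        },
        tracer="palmitic_acid",
        label_end=0.0,
    )


def test_homogeneous_extrapolation_is_flagged_inconsistent():
    est = preformed_pl_estimate(preformed_toy(), total_pl_carbon=169.0, pl_decrease_cap=55.0)
    assert not est.homogeneous_consistent
    assert est.homogeneous_estimate_nmol_c == pytest.approx(0.75 * 169.0)


def test_preformed_estimate_is_small_under_stated_assumptions():
    est = preformed_pl_estimate(preformed_toy())
    assert est.estimate_nmol_c <= 5.0
    assert est.conversion_fraction == pytest.approx(0.75)


def test_zero_conversion_gives_zero_estimate():
    est = preformed_pl_estimate(preformed_toy(fraction=0.0))
    assert est.estimate_nmol_c == 0.0
    assert est.homogeneous_consistent


def test_relative_de_novo_ratios():
    control = make_timecourse({"FA": {1: 100.0}, "DGDG": {1: 40.0}})
    deprived = make_timecourse({"FA": {1: 5.0}, "DGDG": {1: 10.0}})
    out = relative_de_novo(control, deprived, ["FA", "DGDG"])
    assert out.loc["FA", "suppression"] == pytest.approx(0.95)
    assert out.loc["DGDG", "ratio"] == pytest.approx(0.25)
    same = relative_de_novo(control, control, ["FA"])
    assert same.loc["FA", "ratio"] == pytest.approx(1.0)
    empty = relative_de_novo(control, deprived, [])
    assert empty.empty
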
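"""Pathway partition of daily TAG synthesis from pulse-chase time courses.

The analysis attributes each day's triacylglycerol (TAG) production to
three routes and closes the carbon budget against an independently
measured total:

* **from starch** — label that appears in TAG *after* the end of each
  daily bicarbonate pulse, summed over pulses: carbon fixed on day *p*
  that reaches TAG on a later day must have passed through a storage pool,
  dominated by starch (the water-soluble fraction is pooled with starch
  where both are followed, because soluble label is converted onward into
  starch during the chase).
* **de novo direct** — TAG label already present at the end of each
  24 h bicarbonate pulse: carbon fixed and esterified within the same day.
* **de novo via polar lipids** — newly made polar lipids hand a fraction
  of their acyl chains to TAG on each subsequent day; the per-day transfer
  fractions are estimated from a day-1 acyl-tracer chase and convolved
  with the daily polar-lipid synthesis series.

Day 1 receives no starch or via-PL attribution: conversions of material
made before the first pulse ends are unobservable in these designs, so
the day-1 calculated total is direct synthesis only and is expected to
undershoot the measured total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import TimeCourse

__all__ = [
    "TransferSeries",
    "TransferFractionSeries",
    "PathwayPartition",
    "PreformedPLEstimate",
    "pooled_source_series",
    "conversion_efficiency",
    "starch_to_tag_daily",
    "de_novo_direct_daily",
    "daily_pl_synthesis",
    "pl_transfer_fractions",
    "de_novo_via_pl_daily",
    "assemble_partition",
    "pathway_fractions",
    "preformed_pl_estimate",
    "relative_de_novo",
    "partition_from_dataset",
]

PATHWAYS = ("from_starch", "de_novo_direct", "de_novo_via_pl")


class UndefinedEfficiencyError(ValueError):
    """Raised when a conversion efficiency has a zero denominator."""


# ---------------------------------------------------------------------------
# interval transfers and efficiencies


@dataclass(frozen=True)
class TransferSeries:
    """Per-interval source decrease and sink increase along a chase.

    ``intervals[i] = (d_i, d_{i+1})``; decreases/increases are clamped at
    zero (noise can make a pool rise spuriously); the raw first
    differences are kept in ``diagnostics``.
    """

    intervals: tuple[tuple[float, float], ...]
    source_decrease: np.ndarray
    sink_increase: np.ndarray
    units: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.intervals)
        if len(self.source_decrease) != n or len(self.sink_increase) != n:
            raise ValueError("interval and value lengths disagree")
        for (a, b), (c, _) in zip(self.intervals, self.intervals[1:]):
            if b != c or not a < b:
                raise ValueError("intervals must be contiguous and ordered")
        if (np.asarray(self.source_decrease) < 0).any() or (
            np.asarray(self.sink_increase) < 0
        ).any():
            raise ValueError("clamped transfers must be >= 0")


def pooled_source_series(
    tc: TimeCourse, source_pools: Iterable[str], sink_pool: str
) -> TransferSeries:
    """Interval transfers from a pooled source into a sink pool.

    Replicates are averaged first; the source series is the *sum* of the
    named pools per day (starch is pooled with the water-soluble fraction
    to absorb soluble-to-starch interconversion during the chase), and
    interval changes are first differences with negative transfers clamped
    to zero.
    """
    source_pools = list(source_pools)
    src = tc.pool_mean(source_pools)
    snk = tc.pool_mean(sink_pool)
    if not src.index.equals(snk.index):
        raise ValueError("source and sink pools are not on a shared day grid")
    days = src.index.to_numpy(dtype=float)
    if len(days) < 2:
        raise ValueError("need at least two sampling days")
    d_src = np.diff(src.to_numpy())
    d_snk = np.diff(snk.to_numpy())
    return TransferSeries(
        intervals=tuple(zip(days[:-1], days[1:])),
        source_decrease=np.clip(-d_src, 0.0, None),
        sink_increase=np.clip(d_snk, 0.0, None),
        units=tc.units,
        diagnostics={"source_diff": d_src, "sink_diff": d_snk},
    )


def conversion_efficiency(ts: TransferSeries) -> float:
    """Total sink increase over total source decrease along the chase.

    Values above 1 are possible (label reaching the sink from pools
    outside the source set) and trigger a warning.
    """
    total_src = float(np.sum(ts.source_decrease))
    total_snk = float(np.sum(ts.sink_increase))
    if total_snk == 0.0:
        return 0.0
    if total_src <= 0.0:
        raise UndefinedEfficiencyError(
            "total source decrease is zero; efficiency undefined"
        )
    eff = total_snk / total_src
    if eff > 1.0 + 1e-9:
        warnings.warn(
            f"conversion efficiency {eff:.3f} exceeds 1: label influx from "
            "outside the source pools",
            stacklevel=2,
        )
    return eff


# ---------------------------------------------------------------------------
# daily pathway series from the pulse designs


def _label_end_mean(tc: TimeCourse, pool: str) -> float:
    if tc.label_end is None:
        raise ValueError(f"experiment {tc.experiment!r} has no label_end")
    series = tc.pool_mean(pool)
    if tc.label_end not in series.index:
        raise ValueError(
            f"experiment {tc.experiment!r} has no sample at label end "
            f"day {tc.label_end}"
        )
    return float(series.loc[tc.label_end])


def _pulse_day(tc: TimeCourse) -> int:
    if tc.label_end is None:
        raise ValueError(f"experiment {tc.experiment!r} has no label_end")
    return int(round(tc.label_end))


def starch_to_tag_daily(
    daily_pulse_tcs: Sequence[TimeCourse], last_day: int = 8
) -> pd.Series:
    """Per-day TAG production from storage, from daily bicarbonate pulses.

    For each pulse experiment the TAG-label increases *after* label end
    are attributed to the chase day on which they appear (negative
    increments clamped to zero); the day-*d* output sums those
    appearances over all pulses. Day 1 is zero by construction — transfer
    of material made before the first label end is not observable.
    """
    out = pd.Series(0.0, index=pd.RangeIndex(1, last_day + 1, name="day"))
    for tc in daily_pulse_tcs:
        p = _pulse_day(tc)
        tag = tc.pool_mean("TAG")
        tag = tag[tag.index >= tc.label_end]
        gains = tag.diff().dropna().clip(lower=0.0)
        for day, gain in gains.items():
            d = int(round(day))
            if not np.isclose(day, d) or d > last_day:
                raise ValueError(
                    f"chase day {day} of {tc.experiment!r} is off the "
                    "integer day grid"
                )
            out.loc[d] += float(gain)
    return out


def de_novo_direct_daily(
    daily_pulse_tcs: Sequence[TimeCourse], last_day: int = 8
) -> pd.Series:
    """Direct same-day TAG synthesis: TAG label at each pulse's label end."""
    out = pd.Series(0.0, index=pd.RangeIndex(1, last_day + 1, name="day"))
    for tc in daily_pulse_tcs:
        out.loc[_pulse_day(tc)] = _label_end_mean(tc, "TAG")
    return out


def daily_pl_synthesis(
    daily_pulse_tcs: Sequence[TimeCourse], last_day: int = 8
) -> pd.Series:
    """Polar lipid made each day: PL label at each pulse's label end."""
    out = pd.Series(0.0, index=pd.RangeIndex(1, last_day + 1, name="day"))
    for tc in daily_pulse_tcs:
        out.loc[_pulse_day(tc)] = _label_end_mean(tc, "polar_lipid")
    return out


@dataclass(frozen=True)
class TransferFractionSeries:
    """Fraction of source label transferred to the sink per elapsed day.

    ``fractions`` is indexed by whole days since label end (lag 1, 2, ...);
    each entry lies in [0, 1] and the running sum never exceeds 1.
    """

    fractions: pd.Series

    def __post_init__(self) -> None:
        f = self.fractions
        if ((f < 0) | (f > 1)).any():
            raise ValueError("each transfer fraction must lie in [0, 1]")
        if f.cumsum().iloc[-1] > 1.0 + 1e-12:
            raise ValueError("cumulative transfer fraction exceeds 1")

    @property
    def cumulative(self) -> float:
        return float(self.fractions.sum())

    def __call__(self, lag: int) -> float:
        return float(self.fractions.get(lag, 0.0))


def pl_transfer_fractions(day1_pla_tc: TimeCourse) -> TransferFractionSeries:
    """Per-day fraction of new polar-lipid label handed on to TAG.

    Estimated from a chase of polar lipids labeled during day 1: the TAG
    increase on each chase day divided by the polar-lipid label present at
    label end. Negative increments clamp to zero and the cumulative sum is
    capped at 1.
    """
    pl0 = _label_end_mean(day1_pla_tc, "polar_lipid")
    if pl0 <= 0.0:
        raise UndefinedEfficiencyError("no polar-lipid label at label end")
    tag = day1_pla_tc.pool_mean("TAG")
    tag = tag[tag.index >= day1_pla_tc.label_end]
    gains = tag.diff().dropna().clip(lower=0.0) / pl0
    lags = [int(round(d - day1_pla_tc.label_end)) for d in gains.index]
    # cap the running total at 1 by trimming later fractions
    capped, running = [], 0.0
    for v in gains.to_numpy():
        take = min(float(v), max(0.0, 1.0 - running))
        capped.append(take)
        running += take
    frac = pd.Series(capped, index=pd.Index(lags, name="lag"))
    return TransferFractionSeries(fractions=frac)


def de_novo_via_pl_daily(
    daily_pl_synthesis: pd.Series,
    fractions: TransferFractionSeries,
    last_day: int | None = None,
) -> pd.Series:
    """Daily TAG made through newly formed polar lipids.

    Convolution of the per-day polar-lipid synthesis series with the
    transfer-fraction series: the day-*d* value sums, over synthesis days
    ``s < d``, the lipid made on day *s* times the fraction handed to TAG
    after ``d - s`` days. Day 1 is zero — transfers begin the day after
    synthesis.
    """
    days = daily_pl_synthesis.index.to_numpy()
    if last_day is None:
        last_day = int(days.max())
    out = pd.Series(0.0, index=pd.RangeIndex(1, last_day + 1, name="day"))
    for s, made in daily_pl_synthesis.items():
        for d in out.index:
            if d > s:
                out.loc[d] += float(made) * fractions(d - s)
    return out


# ---------------------------------------------------------------------------
# assembly and reporting quantities


@dataclass(frozen=True)
class PathwayPartition:
    """Per-day TAG synthesis by pathway with calculated and measured totals.

    ``table`` is indexed by day and has columns ``from_starch,
    de_novo_direct, de_novo_via_pl, total_calculated, total_measured``;
    the row identity ``total_calculated = from_starch + de_novo_direct +
    de_novo_via_pl`` holds exactly at full precision.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = [*PATHWAYS, "total_calculated", "total_measured"]
        missing = set(required) - set(self.table.columns)
        if missing:
            raise ValueError(f"partition table missing columns {sorted(missing)}")
        if (self.table[required] < 0).any().any():
            raise ValueError("partition entries must be >= 0")
        calc = self.table[list(PATHWAYS)].sum(axis=1)
        if not np.array_equal(calc.to_numpy(), self.table["total_calculated"].to_numpy()):
            raise ValueError("row closure violated: calculated total != pathway sum")

    @property
    def column_totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def discrepancy(self) -> pd.Series:
        """Measured minus calculated, per day (kept for reporting)."""
        return self.table["total_measured"] - self.table["total_calculated"]


def assemble_partition(
    from_starch: pd.Series,
    de_novo_direct: pd.Series,
    de_novo_via_pl: pd.Series,
    total_measured: pd.Series,
) -> PathwayPartition:
    """Combine the three pathway series and the measured totals."""
    pieces = {
        "from_starch": from_starch,
        "de_novo_direct": de_novo_direct,
        "de_novo_via_pl": de_novo_via_pl,
        "total_measured": total_measured,
    }
    for name, s in pieces.items():
        if (np.asarray(s, dtype=float) < 0).any():
            raise ValueError(f"{name} has negative entries")
    table = pd.DataFrame(pieces)
    if table.isna().any().any():
        raise ValueError("pathway series are not on a shared day grid")
    table.index.name = "day"
    table["total_calculated"] = (
        table["from_starch"] + table["de_novo_direct"] + table["de_novo_via_pl"]
    )
    order = [*PATHWAYS, "total_calculated", "total_measured"]
    return PathwayPartition(table=table[order])


def pathway_fractions(p: PathwayPartition) -> pd.Series:
    """Share of the calculated 8-day total contributed by each pathway."""
    totals = p.table[list(PATHWAYS)].sum(axis=0)
    grand = float(totals.sum())
    if grand <= 0.0:
        raise UndefinedEfficiencyError("calculated total is zero")
    return totals / grand


# ---------------------------------------------------------------------------
# pre-formed polar lipids and condition comparison


@dataclass(frozen=True)
class PreformedPLEstimate:
    """Bounded estimate of TAG carbon derived from pre-formed polar lipids."""

    estimate_nmol_c: float
    conversion_fraction: float
    homogeneous_estimate_nmol_c: float
    pl_decrease_cap_nmol_c: float
    homogeneous_consistent: bool
    notes: tuple[str, ...]


def preformed_pl_estimate(
    prelabel_tc: TimeCourse,
    *,
    total_pl_carbon: float = 169.0,
    pl_decrease_cap: float = 55.0,
    internal_pla_conc_uM: float = 1.0,
    labeled_pl_carbon_per_uM: float = 6.0,
    homogeneous_labeling: bool = False,
) -> PreformedPLEstimate:
    """Estimate TAG carbon made from polar lipids present before N onset.

    The conversion fraction is measured from the pre-labeling chase (TAG
    gain over the chase divided by polar-lipid label at label end). Under
    *homogeneous* labeling the fraction would apply to the whole membrane
    pool (``total_pl_carbon``); that extrapolation is checked against the
    observed total polar-lipid decrease (``pl_decrease_cap``) and flagged
    inconsistent when it exceeds the cap — the realistic reading is that
    only a small turning-over subpool is labeled. The reported estimate
    scales the conversion fraction by that subpool's carbon content,
    parameterized as ``labeled_pl_carbon_per_uM`` (nmol C per 10^6 cells
    per µM of internal free palmitic acid) times ``internal_pla_conc_uM``;
    every assumption is an explicit argument.
    """
    pl0 = _label_end_mean(prelabel_tc, "polar_lipid")
    if pl0 <= 0.0:
        raise UndefinedEfficiencyError("no polar-lipid label at label end")
    tag = prelabel_tc.pool_mean("TAG")
    tag = tag[tag.index >= prelabel_tc.label_end]
    fraction = float(np.clip((tag.iloc[-1] - tag.iloc[0]) / pl0, 0.0, 1.0))

    homogeneous = fraction * total_pl_carbon
    consistent = homogeneous <= pl_decrease_cap
    notes = []
    if not consistent:
        notes.append(
            f"homogeneous-labeling extrapolation ({homogeneous:.0f} nmol C) "
            f"exceeds the observed polar-lipid decrease "
            f"({pl_decrease_cap:.0f} nmol C): labeling cannot be homogeneous"
        )
    if homogeneous_labeling:
        estimate = homogeneous
    else:
        estimate = fraction * labeled_pl_carbon_per_uM * internal_pla_conc_uM
        notes.append(
            "estimate assumes only the turning-over polar-lipid subpool "
            f"({labeled_pl_carbon_per_uM * internal_pla_conc_uM:.1f} nmol C "
            f"at {internal_pla_conc_uM:g} µM internal PlA) is labeled"
        )
    return PreformedPLEstimate(
        estimate_nmol_c=estimate,
        conversion_fraction=fraction,
        homogeneous_estimate_nmol_c=homogeneous,
        pl_decrease_cap_nmol_c=pl_decrease_cap,
        homogeneous_consistent=consistent,
        notes=tuple(notes),
    )


def relative_de_novo(
    control_tc: TimeCourse,
    deprived_tc: TimeCourse,
    lipid_classes: Sequence[str],
) -> pd.DataFrame:
    """Per-lipid-class ratio of label incorporation, deprived over control.

    Both time courses must carry the named classes as pools; values are
    replicate means summed over the sampled days. Returns columns
    ``ratio`` and ``suppression`` (= 1 − ratio, floored at 0 ... ratios
    above 1 mean enhanced incorporation under deprivation).
    """
    rows = {}
    for cls in lipid_classes:
        ctrl = float(control_tc.pool_mean(cls).sum())
        depr = float(deprived_tc.pool_mean(cls).sum())
        if ctrl <= 0.0:
            raise UndefinedEfficiencyError(f"no control incorporation for {cls!r}")
        ratio = depr / ctrl
        rows[cls] = {"ratio": ratio, "suppression": 1.0 - ratio}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# end-to-end convenience


def partition_from_dataset(ds, last_day: int = 8) -> PathwayPartition:
    """Run the full partition on a generated multi-design dataset.

    Uses the daily bicarbonate pulses for the starch and direct series and
    for daily polar-lipid synthesis, the day-1 acyl chase for the transfer
    fractions, and the total-labeling design for the measured totals.
    """
    from_starch = starch_to_tag_daily(ds.daily_bicarbonate_pulses, last_day)
    direct = de_novo_direct_daily(ds.daily_bicarbonate_pulses, last_day)
    pl_made = daily_pl_synthesis(ds.daily_bicarbonate_pulses, last_day)
    fractions = pl_transfer_fractions(ds.day1_pla_chase)
    via_pl = de_novo_via_pl_daily(pl_made, fractions, last_day)
    tag_total = ds.total_labeling.pool_mean("TAG")
    measured = tag_total.diff().dropna().clip(lower=0.0)
    measured.index = [int(round(d)) for d in measured.index]
    measured = measured.reindex(range(1, last_day + 1), fill_value=0.0)
    measured.index.name = "day"
    return assemble_partition(from_starch, direct, via_pl, measured)
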
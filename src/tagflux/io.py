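"""TSV readers/writers, run configuration and the partition report.

Time courses travel as UTF-8 tab-separated text with Unix newlines and
columns ``experiment tracer pool day replicate value units``; the chase
start is carried in a ``# label_end:`` header comment so a file round-trips
to an identical object. Schema violations raise :class:`SchemaError`
naming the offending row and column.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .partition import PATHWAYS, PathwayPartition
from .simulate import TimeCourse
from .units import round_half_away

__all__ = [
    "SchemaError",
    "ConfigError",
    "RunConfig",
    "read_timecourse",
    "write_timecourse",
    "render_partition_report",
    "write_partition",
    "read_partition",
]

log = logging.getLogger("tagflux")

COLUMNS = ["experiment", "tracer", "pool", "day", "replicate", "value", "units"]


class SchemaError(ValueError):
    """A file does not match the declared TSV schema."""


class ConfigError(ValueError):
    """A run configuration is malformed."""


# ---------------------------------------------------------------------------
# time-course files


def write_timecourse(tc: TimeCourse, path) -> None:
    """Write a TimeCourse in canonical ordering (pool, day, replicate)."""
    path = Path(path)
    df = tc.data.sort_values(["pool", "day", "replicate"], kind="mergesort")
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if tc.label_end is not None:
            fh.write(f"# label_end: {tc.label_end!r}\n")
        fh.write("\t".join(COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{tc.experiment}\t{tc.tracer}\t{row.pool}\t{row.day!r}\t"
                f"{int(row.replicate)}\t{row.value!r}\t{tc.units}\n"
            )


def read_timecourse(path) -> TimeCourse:
    """Read one TimeCourse; empty data sections load with a warning."""
    path = Path(path)
    label_end = None
    header_lines = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].partition(":")
            if key.strip() == "label_end":
                label_end = float(value)
    df = pd.read_csv(path, sep="\t", skiprows=header_lines, float_precision="round_trip")
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")
    if df.empty:
        log.warning("%s: empty data section", path.name)
        return TimeCourse(
            experiment=path.stem,
            tracer="bicarbonate",
            units="nmol_C_per_1e6_cells",
            data=pd.DataFrame(columns=["pool", "day", "replicate", "value"]),
            label_end=label_end,
        )
    for col in ("experiment", "tracer", "units"):
        if df[col].nunique() != 1:
            raise SchemaError(f"{path.name}: column {col!r} is not constant")
    bad = df.index[df["value"] < 0]
    if len(bad):
        raise SchemaError(
            f"{path.name}: negative value in row {bad[0] + 2} (column 'value')"
        )
    dup = df.duplicated(["pool", "day", "replicate"])
    if dup.any():
        raise SchemaError(
            f"{path.name}: duplicate (pool, day, replicate) key in row "
            f"{df.index[dup][0] + 2}"
        )
    data = df[["pool", "day", "replicate", "value"]].reset_index(drop=True)
    return TimeCourse(
        experiment=str(df["experiment"].iloc[0]),
        tracer=str(df["tracer"].iloc[0]),
        units=str(df["units"].iloc[0]),
        data=data,
        label_end=label_end,
    )


# ---------------------------------------------------------------------------
# partition table and report

_REPORT_HEADERS = {
    "from_starch": "Starch",
    "de_novo_direct": "De novo direct",
    "de_novo_via_pl": "De novo via PLs",
    "total_calculated": "Total calculated",
    "total_measured": "Total measured",
}


def render_partition_report(p: PathwayPartition) -> str:
    """Human-readable per-day pathway table with a Total row.

    One row per day, one-decimal rounding (half away from zero), the
    calculated and measured totals side by side. Requires a complete
    contiguous day range.
    """
    days = list(p.table.index)
    expected = list(range(int(min(days)), int(max(days)) + 1))
    missing = sorted(set(expected) - set(int(d) for d in days))
    if missing:
        raise SchemaError(f"partition is missing days {missing}")
    cols = list(_REPORT_HEADERS)
    widths = {c: max(len(_REPORT_HEADERS[c]), 8) for c in cols}
    lines = ["\t".join(["Day"] + [_REPORT_HEADERS[c].ljust(widths[c]) for c in cols])]
    for day, row in p.table.iterrows():
        cells = [f"{round_half_away(row[c], 1):.1f}".ljust(widths[c]) for c in cols]
        lines.append("\t".join([str(int(day))] + cells))
    totals = p.column_totals
    cells = [f"{round_half_away(totals[c], 1):.1f}".ljust(widths[c]) for c in cols]
    lines.append("\t".join(["Total"] + cells))
    return "\n".join(lines) + "\n"


def write_partition(p: PathwayPartition, path) -> None:
    p.table.to_csv(path, sep="\t", float_format="%.10g")


def read_partition(path) -> PathwayPartition:
    df = pd.read_csv(path, sep="\t", index_col="day")
    missing = {*PATHWAYS, "total_measured"} - set(df.columns)
    if missing:
        raise SchemaError(f"{Path(path).name}: missing columns {sorted(missing)}")
    # re-derive the calculated total so row closure holds exactly
    df["total_calculated"] = df[list(PATHWAYS)].sum(axis=1)
    return PathwayPartition(table=df)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings; unknown keys are rejected.

    The conversion section mirrors the specific-activity and carbon-mass
    constants; simulation settings control the synthetic-data generator;
    fit settings the optimizer. All seeds are explicit.
    """

    seed: int
    noise_cv: float = 0.10
    n_replicates: int = 3
    outdir: str = "results"
    conversion: Mapping[str, float] = field(default_factory=dict)
    fit: Mapping[str, int] = field(default_factory=dict)

    _CONVERSION_KEYS = {
        "specific_activity",
        "carbon_mass_fraction_starch",
        "carbon_mass_fraction_tag",
        "carbon_atomic_mass",
    }
    _FIT_KEYS = {"n_starts", "n_bootstrap"}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        known = {"seed", "noise_cv", "n_replicates", "outdir", "conversion", "fit"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("config must set an explicit seed")
        conv = raw.get("conversion") or {}
        bad = set(conv) - cls._CONVERSION_KEYS
        if bad:
            raise ConfigError(f"unknown conversion keys {sorted(bad)}")
        fit = raw.get("fit") or {}
        bad = set(fit) - cls._FIT_KEYS
        if bad:
            raise ConfigError(f"unknown fit keys {sorted(bad)}")
        cfg = cls(
            seed=int(raw["seed"]),
            noise_cv=float(raw.get("noise_cv", 0.10)),
            n_replicates=int(raw.get("n_replicates", 3)),
            outdir=str(raw.get("outdir", "results")),
            conversion=dict(conv),
            fit=dict(fit),
        )
        if cfg.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if cfg.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        return cfg

    def digest(self) -> str:
        """Short hash of the canonicalized config, for output provenance."""
        canon = yaml.safe_dump(
            {
                "seed": self.seed,
                "noise_cv": self.noise_cv,
                "n_replicates": self.n_replicates,
                "outdir": self.outdir,
                "conversion": dict(self.conversion),
                "fit": dict(self.fit),
            },
            sort_keys=True,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
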
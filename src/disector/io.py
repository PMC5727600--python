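"""File formats, run configuration and the end-to-end pipeline.

Count tables travel as CSV with the header

    animal_id, region, side, pair_index, q_forward, q_reverse, p_points

(rows in cutting order within each animal/region/side group; a ``q_total``
column may replace the forward/reverse split when only the bidirectional
sum is known, as in published worked examples).  Reports are JSON plus a
human-readable Markdown summary; every numerical output in a report is
reproducible from the report's own recorded inputs and seeds, and display
rounding (N to the nearest integer half away from zero, V and CE at two
decimals) is centralized here so stored values stay full-precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .counting import CountTable
from .design import SamplingDesign
from .estimators import (
    EstimateResult,
    estimate_from_table,
    group_summary,
    round_half_away,
)
from .exceptions import ValidationError
from .precision import mean_ce, variance_decomposition

__all__ = [
    "COUNT_COLUMNS",
    "RunConfig",
    "read_count_table",
    "read_count_tables",
    "write_count_table",
    "run_pipeline",
    "write_report",
]

COUNT_COLUMNS = [
    "animal_id",
    "region",
    "side",
    "pair_index",
    "q_forward",
    "q_reverse",
    "p_points",
]
_GROUP_COLS = ["animal_id", "region", "side"]


def _fail(lines: list[int], message: str) -> None:
    where = ", ".join(str(ln) for ln in lines)
    raise ValidationError(f"{message} (CSV line{'s' if len(lines) > 1 else ''} {where})")


def _check_int_column(df: pd.DataFrame, col: str, allow_na: bool = False) -> None:
    series = df[col]
    na = series.isna()
    if na.any() and not allow_na:
        _fail(list(df.index[na] + 2), f"missing values in column {col!r}")
    vals = pd.to_numeric(series[~na], errors="coerce")
    bad_num = vals.isna()
    if bad_num.any():
        _fail(list(vals.index[bad_num] + 2), f"non-numeric values in column {col!r}")
    nonint = vals[np.mod(vals, 1) != 0]
    if len(nonint):
        _fail(list(nonint.index + 2), f"non-integer counts in column {col!r}")
    neg = vals[vals < 0]
    if len(neg):
        _fail(list(neg.index + 2), f"negative counts in column {col!r}")


def _table_from_group(g: pd.DataFrame) -> CountTable:
    g = g.reset_index(drop=False)  # keep original index for line numbers
    dup = g["pair_index"][g["pair_index"].duplicated()]
    if len(dup):
        _fail(list(g.loc[dup.index, "index"] + 2), "duplicate pair indices")
    order = np.argsort(g["pair_index"].to_numpy(), kind="stable")
    g = g.iloc[order]
    has_split = "q_forward" in g and g["q_forward"].notna().all()
    p = (
        g["p_points"].astype(np.int64).to_numpy()
        if "p_points" in g and g["p_points"].notna().all()
        else None
    )
    if has_split:
        fwd = g["q_forward"].astype(np.int64).to_numpy()
        rev = g["q_reverse"].astype(np.int64).to_numpy()
        return CountTable(
            pair_index=g["pair_index"].astype(np.int64).to_numpy(),
            q=fwd + rev,
            q_forward=fwd,
            q_reverse=rev,
            p=p,
        )
    return CountTable(
        pair_index=g["pair_index"].astype(np.int64).to_numpy(),
        q=g["q_total"].astype(np.int64).to_numpy(),
        p=p,
    )


def read_count_tables(path: str | Path) -> dict[tuple, CountTable]:
    """Read a count CSV into one :class:`CountTable` per (animal, region, side).

    Rows keep their cutting order (sorted by ``pair_index`` within each
    group); malformed rows are rejected with their CSV line numbers.
    """
    df = pd.read_csv(path, dtype={c: str for c in _GROUP_COLS})
    if "pair_index" not in df.columns:
        raise ValidationError("count CSV lacks required column 'pair_index'")
    has_split = {"q_forward", "q_reverse"} <= set(df.columns)
    if not has_split and "q_total" not in df.columns:
        raise ValidationError(
            "count CSV needs q_forward+q_reverse or a q_total column"
        )
    _check_int_column(df, "pair_index")
    for col in ("q_forward", "q_reverse", "q_total", "p_points"):
        if col in df.columns:
            _check_int_column(df, col, allow_na=(col == "p_points"))
    for col in _GROUP_COLS:
        if col not in df.columns:
            df[col] = ""
        else:
            df[col] = df[col].fillna("")
    out: dict[tuple, CountTable] = {}
    for key, g in df.groupby(_GROUP_COLS, sort=True, dropna=False):
        out[tuple(str(k) for k in key)] = _table_from_group(g)
    return out


def read_count_table(path: str | Path) -> CountTable:
    """Read a count CSV holding a single animal/region/side group."""
    tables = read_count_tables(path)
    if len(tables) != 1:
        raise ValidationError(
            f"expected a single-group count CSV, found {len(tables)} groups; "
            "use read_count_tables"
        )
    return next(iter(tables.values()))


def write_count_table(
    table: CountTable,
    path: str | Path,
    animal_id: str = "",
    region: str = "",
    side: str = "",
) -> None:
    """Write a count table to CSV with the declared header."""
    df = table.to_frame()
    if "q_forward" not in df:
        df["q_forward"] = pd.array([pd.NA] * len(df), dtype="Int64")
        df["q_reverse"] = pd.array([pd.NA] * len(df), dtype="Int64")
    if "p_points" not in df:
        df["p_points"] = pd.array([pd.NA] * len(df), dtype="Int64")
    df["animal_id"] = animal_id
    df["region"] = region
    df["side"] = side
    df[COUNT_COLUMNS + ["q_total"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    design: SamplingDesign = field(default_factory=SamplingDesign)
    mode: str = "counts"  # "counts" | "simulate"
    counts_path: str | None = None
    seed: int = 0
    # display/worked-example overrides: printed, rounded inverse fractions
    inv_asf: float | None = None
    inv_ssf: float | None = None
    bidirectional: bool = True
    thickness: float | None = None  # caliper-calculated t, overrides nominal
    # simulate mode
    n_particles: int = 10_000
    report_json: str | None = None
    report_md: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "simulate"):
            raise ValidationError("mode must be 'counts' or 'simulate'")
        if self.mode == "counts" and not self.counts_path:
            raise ValidationError("counts mode requires counts_path")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "design" in d:
            d["design"] = SamplingDesign.from_dict(d["design"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = self.design.to_dict()
        return d


def _estimate_entry(key: tuple, result: EstimateResult, table: CountTable) -> dict:
    prec = result.precision
    entry = {
        "animal_id": key[0],
        "region": key[1],
        "side": key[2],
        "pair_index": [int(i) for i in table.pair_index],
        "q_list": table.q_list,
        "sum_q": table.sum_q,
        "n": result.n,
        "n_reported": result.n_reported,
    }
    if table.p is not None:
        entry["p_list"] = [int(v) for v in table.p]
        entry["sum_p"] = table.sum_p
        entry["v_mm3"] = result.v_mm3
        entry["v_reported"] = result.v_reported
    entry["precision"] = prec.to_dict()
    return entry


def run_pipeline(config: RunConfig) -> dict:
    """Counting (or count ingestion) → estimation → precision → summary.

    Returns the report dict; writes JSON/Markdown when paths are set in
    the config.  Reports carry the seeds, design and package version and
    contain no timestamps, so a rerun with the same config is
    byte-identical.
    """
    design = config.design
    if config.mode == "simulate":
        from .phantom import generate_phantom, simulate_study

        phantom = generate_phantom(config.n_particles, seed=config.seed)
        tables = {
            ("phantom", "roi", ""): simulate_study(
                phantom, design, seed=config.seed + 1
            )
        }
        truth = {"true_n": phantom.true_n, "true_v_mm3": phantom.true_volume_mm3}
    else:
        tables = read_count_tables(config.counts_path)
        truth = None

    estimates = []
    for key, table in sorted(tables.items()):
        result = estimate_from_table(
            table,
            design,
            label="/".join(str(k) for k in key),
            bidirectional=config.bidirectional,
            inv_asf=config.inv_asf,
            inv_ssf=config.inv_ssf,
            thickness=config.thickness,
        )
        estimates.append(_estimate_entry(key, result, table))

    groups = _group_section(estimates)
    config_echo = config.to_dict()
    # report destinations are not inputs; keep the report content
    # independent of where it is written
    config_echo.pop("report_json", None)
    config_echo.pop("report_md", None)
    report = {
        "package": {"name": "disector", "version": _pkg_version},
        "config": config_echo,
        "seed": config.seed,
        "estimates": estimates,
        "groups": groups,
    }
    if truth is not None:
        report["truth"] = truth
    if config.report_json:
        write_report(report, config.report_json, config.report_md)
    return report


def _group_section(estimates: list[dict]) -> list[dict]:
    """Per-region group statistics; paired ipsi/contra summary when present."""
    groups: list[dict] = []
    regions = sorted({e["region"] for e in estimates})
    for region in regions:
        members = [e for e in estimates if e["region"] == region]
        entry: dict = {"region": region, "n": len(members)}
        ns = [e["n"] for e in members]
        ces = [e["precision"]["ce"] for e in members]
        entry["mean_ce"] = mean_ce(ces) if ces else None
        if len(members) >= 2:
            gs = variance_decomposition(ns, ces)
            entry["variance_decomposition"] = {
                "cv_obs": gs.cv_obs,
                "cv_biol": gs.cv_biol,
                "ce_variance_fraction": gs.ce_variance_fraction,
                "acceptable": gs.acceptable,
            }
        sides = {e["side"] for e in members}
        if {"ipsi", "contra"} <= sides:
            by_side = {
                s: {e["animal_id"]: e["n"] for e in members if e["side"] == s}
                for s in ("ipsi", "contra")
            }
            common = sorted(set(by_side["ipsi"]) & set(by_side["contra"]))
            if common:
                gs = group_summary(
                    [by_side["ipsi"][a] for a in common],
                    [by_side["contra"][a] for a in common],
                )
                entry["paired_summary"] = {
                    "n_animals": gs.n,
                    "mean_ipsi": gs.mean_ipsi,
                    "sem_ipsi": gs.sem_ipsi,
                    "mean_contra": gs.mean_contra,
                    "sem_contra": gs.sem_contra,
                    "percent_reduction_per_animal": gs.percent_reduction_per_animal,
                    "percent_reduction_of_means": gs.percent_reduction_of_means,
                }
        groups.append(entry)
    return groups


def _markdown_summary(report: dict) -> str:
    lines = ["# Disector report", ""]
    lines.append(
        "| animal | region | side | ΣQ⁻ | N | ΣP | V (mm³) | CE |"
    )
    lines.append("|---|---|---|---|---|---|---|---|")
    for e in report["estimates"]:
        v = f"{e['v_reported']:.2f}" if "v_reported" in e else "—"
        sp = str(e.get("sum_p", "—"))
        ce = e["precision"]["ce"]
        lines.append(
            f"| {e['animal_id']} | {e['region']} | {e['side']} | {e['sum_q']} "
            f"| {e['n_reported']:,} | {sp} | {v} | {ce:.2f} |"
        )
    for g in report.get("groups", []):
        if "paired_summary" in g:
            ps = g["paired_summary"]
            lines.append("")
            lines.append(
                f"Region {g['region']}: ipsilateral reduced by "
                f"{ps['percent_reduction_per_animal']:.0f}% "
                f"(per-animal paired mean; ratio of means "
                f"{ps['percent_reduction_of_means']:.0f}%)."
            )
    lines.append("")
    return "\n".join(lines)


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(report: dict, json_path: str | Path, md_path: str | Path | None = None) -> None:
    Path(json_path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    if md_path:
        Path(md_path).write_text(_markdown_summary(report))
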
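"""Cohort statistics and report assembly.

One-way ANOVA with Tukey HSD post-hoc comparisons and post-hoc power
(from observed Cohen's f), paired t-tests for cycle-1 vs cycle-8 loop
energies, cell-density arithmetic, and deterministic tabular report
assembly (group mean +/- sd tables per endpoint, energy tables,
morphometry tables).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.power import FTestAnovaPower

__all__ = [
    "GroupTable",
    "AnovaResult",
    "one_way_anova",
    "anova_arrays",
    "paired_t",
    "cell_density",
    "build_report",
]

GROUP_ORDER = ["0mV", "20mV", "40mV", "60mV", "control", "bareGF"]


@dataclass
class GroupTable:
    """Long-format endpoint table: one row per (sample, endpoint)."""

    data: pd.DataFrame  # columns: sample_id, group, endpoint, value, units

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "endpoint", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"GroupTable missing columns {sorted(missing)}")
        dup = self.data.duplicated(subset=["sample_id", "endpoint"])
        if dup.any():
            raise ValueError("duplicate (sample_id, endpoint) rows")

    def groups_for(self, endpoint: str) -> dict[str, np.ndarray]:
        sub = self.data[self.data["endpoint"] == endpoint]
        if sub.empty:
            raise ValueError(f"no rows for endpoint '{endpoint}'")
        order = [g for g in GROUP_ORDER if g in set(sub["group"])]
        order += sorted(set(sub["group"]) - set(order))
        return {g: sub.loc[sub["group"] == g, "value"].to_numpy(dtype=float)
                for g in order}


@dataclass
class AnovaResult:
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    tukey: pd.DataFrame | None
    power: float | None
    effect_size_f: float


def anova_arrays(groups: dict[str, np.ndarray], alpha: float = 0.05,
                 tukey: bool = True, power: bool = True) -> AnovaResult:
    """Classical one-way ANOVA on named group arrays.

    Sums of squares are computed directly (between/within); Tukey HSD uses
    the studentized range distribution; achieved power is the post-hoc
    power of an F test at the observed Cohen's f.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    k = len(arrays)
    if k < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 samples")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        raise ValueError("zero within-group variance; F undefined")
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    f_stat = ms_between / ms_within
    p = float(sps.f.sf(f_stat, df1, df2))
    eta_sq = ss_between / (ss_between + ss_within)
    cohens_f = float(np.sqrt(eta_sq / (1.0 - eta_sq))) if eta_sq < 1 else float("inf")

    tukey_df = None
    if tukey:
        res = sps.tukey_hsd(*arrays)
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                ci = res.confidence_interval(confidence_level=1 - alpha)
                rows.append({
                    "group_a": names[i], "group_b": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                    "ci_low": float(ci.low[i, j]), "ci_high": float(ci.high[i, j]),
                    "significant": bool(res.pvalue[i, j] < alpha),
                })
        tukey_df = pd.DataFrame(rows)

    achieved = None
    if power:
        solver = FTestAnovaPower()
        achieved = float(solver.power(effect_size=cohens_f, nobs=n_total,
                                      alpha=alpha, k_groups=k))
    return AnovaResult(float(f_stat), (df1, df2), p, tukey_df, achieved, cohens_f)


def one_way_anova(table: GroupTable, endpoint: str, alpha: float = 0.05,
                  tukey: bool = True, power: bool = True) -> AnovaResult:
    """One-way ANOVA across groups for one endpoint of a GroupTable."""
    return anova_arrays(table.groups_for(endpoint), alpha=alpha,
                        tukey=tukey, power=power)


def paired_t(first: np.ndarray, second: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    d = a - b
    if np.std(d) == 0:
        if d[0] == 0:  # identical pairs: no effect, maximal p
            return 0.0, int(a.size - 1), 1.0
        raise ValueError("zero-variance non-zero differences; t undefined")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


def cell_density(cell_count: float, fov_area: float, z_thickness: float) -> float:
    """Cells per mm^3: count / (field-of-view area mm^2 * z-thickness mm)."""
    if cell_count < 0:
        raise ValueError("cell_count must be >= 0")
    vol = fov_area * z_thickness
    if vol <= 0:
        raise ValueError("field-of-view volume must be positive")
    return cell_count / vol


def build_report(out_dir: str | Path,
                 endpoints: pd.DataFrame | None = None,
                 energy_pairs: pd.DataFrame | None = None,
                 decay_fits: pd.DataFrame | None = None,
                 morphometry: pd.DataFrame | None = None,
                 transport: dict | None = None,
                 field_estimates: pd.DataFrame | None = None) -> dict:
    """Assemble cohort CSVs plus a JSON summary with deterministic ordering.

    ``endpoints`` is long-format (sample_id, group, endpoint, value);
    the summary holds group mean +/- sd per endpoint.  Returns the summary
    dict; every input given is also written as a CSV next to it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if all(x is None for x in (endpoints, energy_pairs, decay_fits,
                               morphometry, transport, field_estimates)):
        raise ValueError("no analysis products to report")
    summary: dict = {}
    if endpoints is not None:
        if endpoints.duplicated(subset=["sample_id", "endpoint"]).any():
            raise ValueError("conflicting sample ids in endpoint table")
        df = endpoints.sort_values(["endpoint", "group", "sample_id"],
                                   kind="mergesort")
        df.to_csv(out_dir / "endpoints.csv", index=False, float_format="%.10g")
        stats_tbl = (df.groupby(["endpoint", "group"], sort=True)["value"]
                     .agg(["mean", "std", "count"]).reset_index())
        stats_tbl.to_csv(out_dir / "endpoint_group_stats.csv", index=False,
                         float_format="%.10g")
        summary["endpoints"] = {
            f"{row['endpoint']}|{row['group']}": {
                "mean": float(row["mean"]),
                "sd": float(row["std"]) if pd.notna(row["std"]) else None,
                "n": int(row["count"])}
            for _, row in stats_tbl.iterrows()}
    if energy_pairs is not None:
        energy_pairs.sort_values("sample_id", kind="mergesort").to_csv(
            out_dir / "energy_cycle_pairs.csv", index=False, float_format="%.10g")
        summary["energy_pairs_n"] = int(len(energy_pairs))
    if decay_fits is not None:
        decay_fits.to_csv(out_dir / "decay_fits.csv", index=False,
                          float_format="%.10g")
        summary["decay_fits"] = {
            str(row.get("group", row.get("sample_id", i))):
                {"A": float(row["A"]), "tau": float(row["tau"]),
                 "y0": float(row["y0"]), "rmse": float(row["rmse"])}
            for i, row in decay_fits.iterrows()}
    if morphometry is not None:
        morphometry.to_csv(out_dir / "morphometry.csv", index=False,
                           float_format="%.10g")
        summary["morphometry_rows"] = int(len(morphometry))
    if transport is not None:
        summary["transport"] = transport
    if field_estimates is not None:
        field_estimates.to_csv(out_dir / "field_estimates.csv", index=False,
                               float_format="%.10g")
        summary["field_estimates"] = [
            dict(row) for _, row in field_estimates.iterrows()]
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=float))
    return summary
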
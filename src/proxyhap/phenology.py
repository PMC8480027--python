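"""Field-trial reproductive-timing analysis.

Operations for plot-level phenology records from replicated soybean
trials: days-after-planting (DAP) arithmetic, frost censoring of
maturity, per-group means and test-minus-control deltas of days to
flower (DTF = R1 as DAP) and days to maturity (DTM = R8 as DAP),
vegetative/reproductive phase partitioning, and ANOVA + LSD group
comparisons.

Frost censoring follows field practice: a plot that has not reached
full maturity (R8) by first frost is assigned the frost day as its R8
score and flagged censored.  Censored groups' reproductive-phase
lengths understate the true phase, so phase summaries carry a caveat
flag whenever any member plot was censored.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from proxyhap.group_comparison import GroupedValues, LetterAssignment, fisher_lsd_fdr

PLOT_COLUMNS = ["line_id", "group", "rep", "planting_date", "r1_dap", "r8_dap"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (report-table convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _as_date(d) -> _dt.date:
    if isinstance(d, _dt.datetime):
        return d.date()
    if isinstance(d, _dt.date):
        return d
    return _dt.date.fromisoformat(str(d))


def days_after_planting(event_date, planting_date) -> int:
    """Whole calendar days elapsed since planting (planting day = 0)."""
    event, planting = _as_date(event_date), _as_date(planting_date)
    if event < planting:
        raise ValueError(f"event {event} precedes planting {planting}")
    return (event - planting).days


def mean_r1_per_plot(per_plant_r1) -> float:
    """Plot R1 as the unrounded mean of per-plant R1 days."""
    vals = np.asarray(per_plant_r1, dtype=float)
    if vals.size == 0:
        raise ValueError("no per-plant R1 observations")
    return float(vals.mean())


def censor_at_frost(plots: pd.DataFrame, frost_dap: float) -> pd.DataFrame:
    """Apply frost censoring to a plot table.

    Plots with missing ``r8_dap`` get ``r8_dap = frost_dap`` and
    ``censored = True``; plots with recorded ``r8_dap <= frost_dap``
    pass through with ``censored = False``.  A recorded R8 after the
    frost day is inconsistent input and raises.
    """
    out = plots.copy()
    r8 = pd.to_numeric(out["r8_dap"], errors="coerce")
    late = r8.notna() & (r8 > frost_dap)
    if late.any():
        raise ValueError(
            f"recorded r8_dap after frost day {frost_dap} for lines: "
            f"{out.loc[late, 'line_id'].tolist()}"
        )
    already = (
        out["censored"].fillna(False).astype(bool)
        if "censored" in out.columns
        else pd.Series(False, index=out.index)
    )
    out["censored"] = r8.isna() | already  # idempotent on re-application
    out["r8_dap"] = r8.fillna(float(frost_dap))
    return out


def group_summary(plots: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean DTF/DTM with plot counts and censoring fraction."""
    if "censored" not in plots.columns:
        plots = plots.assign(censored=False)
    g = plots.groupby("group", sort=True)
    out = pd.DataFrame(
        {
            "n": g.size(),
            "mean_r1": g["r1_dap"].mean(),
            "mean_r8": g["r8_dap"].mean(),
            "sd_r1": g["r1_dap"].std(ddof=1),
            "sd_r8": g["r8_dap"].std(ddof=1),
            "frac_censored": g["censored"].mean(),
        }
    )
    return out.reset_index()


def group_delta(
    summary: pd.DataFrame, test_group: str, control_group: str
) -> tuple[float, float]:
    """Test-minus-control deltas of mean DTF and DTM, one-decimal.

    `summary` must carry columns ``group, mean_r1, mean_r8`` (as from
    :func:`group_summary` or a transcribed report table).  Returns
    (ΔDTF, ΔDTM) rounded half away from zero to one decimal; raw means
    stay available in the summary.
    """
    idx = summary.set_index("group")
    for grp in (test_group, control_group):
        if grp not in idx.index:
            raise KeyError(f"group {grp!r} not in summary")
    d_dtf = float(idx.at[test_group, "mean_r1"] - idx.at[control_group, "mean_r1"])
    d_dtm = float(idx.at[test_group, "mean_r8"] - idx.at[control_group, "mean_r8"])
    return round_half_away(d_dtf, 1), round_half_away(d_dtm, 1)


@dataclass(frozen=True)
class PhaseSummary:
    """Vegetative/reproductive split of one group's life span."""

    group: str
    vegetative_days: float
    reproductive_days: float
    vegetative_pct: float
    reproductive_pct: float
    censored: bool  # True -> reproductive length truncated at frost


def phase_partition(summary: pd.DataFrame) -> list[PhaseSummary]:
    """Partition each group's mean life span into phases.

    Vegetative = mean R1; reproductive = mean R8 − mean R1; percentages
    are of mean R8 (total life span) and sum to 100 per group.  Groups
    containing censored plots are flagged: their reproductive phase is
    truncated at the frost day and understates the true length.
    """
    out = []
    for row in summary.itertuples():
        r1, r8 = float(row.mean_r1), float(row.mean_r8)
        if r8 <= 0:
            raise ValueError(f"group {row.group!r}: mean R8 must be positive")
        veg, rep = r1, r8 - r1
        out.append(
            PhaseSummary(
                group=row.group,
                vegetative_days=veg,
                reproductive_days=rep,
                vegetative_pct=100.0 * veg / r8,
                reproductive_pct=100.0 * rep / r8,
                censored=bool(getattr(row, "frac_censored", 0.0) > 0),
            )
        )
    return out


def compare_groups(plots: pd.DataFrame, response: str, alpha: float = 0.05) -> LetterAssignment:
    """ANOVA + Fisher's LSD letters on plot-level R1 or R8 values."""
    if response not in ("r1", "r8"):
        raise ValueError("response must be 'r1' or 'r8'")
    col = f"{response}_dap"
    obs = [
        (g, float(v))
        for g, v in zip(plots["group"], plots[col])
        if pd.notna(v)
    ]
    return fisher_lsd_fdr(GroupedValues(obs, alpha=alpha))


def load_maturity_trial_table() -> pd.DataFrame:
    """Packaged 2020 trial report table: group mean DTF/DTM by maturity group.

    Transcribes the published group means for test lines carrying
    e1la:K82E and their reference controls in maturity groups I, II, III
    and V.  Columns: group, maturity_group, e1la_genotype, n, mean_r1
    (DTF), mean_r8 (DTM).
    """
    path = resources.files("proxyhap.data") / "table3.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    df = df.rename(columns={"dtf": "mean_r1", "dtm": "mean_r8"})
    df["group"] = df["maturity_group"] + " " + df["e1la_genotype"]
    return df
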
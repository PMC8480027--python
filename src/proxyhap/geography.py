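"""Geographic summaries of two-locus allele-combination groups.

Groups germplasm by the allele carried at two causal flowering loci
(e.g. *E1* and *E1La*), summarises latitude per group with significance
letters, and prepares plot-ready coordinate tables: groups larger than
a cap are randomly downsampled and coordinates are jittered so
accessions geocoded to the same state/province do not overplot.

Summary statistics are always computed on the full, un-jittered
records; downsampling and jitter affect plotting tables only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from proxyhap.group_comparison import GroupedValues, LetterAssignment, fisher_lsd_fdr

logger = logging.getLogger(__name__)

DEFAULT_PLOT_CAP = 200
DEFAULT_JITTER_DEG = 0.4
UNKNOWN_COUNTRY = "Unknown"


@dataclass(frozen=True)
class LocusNames:
    """Display names for the two alleles at one locus."""

    wt: str
    mut: str

    def label(self, allele: str) -> str:
        if allele == "WT":
            return self.wt
        if allele == "MUT":
            return self.mut
        raise ValueError(f"allele must be 'WT' or 'MUT', got {allele!r}")


E1_NAMES = LocusNames(wt="E1", mut="e1-as")
E1LA_NAMES = LocusNames(wt="E1La", mut="e1la:K82E")


def assign_combinations(
    locus1_alleles: pd.Series,
    locus2_alleles: pd.Series,
    metadata: pd.DataFrame,
    locus1_names: LocusNames = E1_NAMES,
    locus2_names: LocusNames = E1LA_NAMES,
) -> pd.DataFrame:
    """Label each accession with its two-locus allele combination.

    `locus1_alleles` / `locus2_alleles` are "WT"/"MUT" Series indexed by
    accession id (typically from :func:`proxyhap.proxy_selection.impute_causal`
    or direct genotyping).  Accessions unresolved at either locus are
    dropped with a logged reason.  Returns the metadata joined with
    `allele_1`, `allele_2` and a human-readable `combination` label,
    one of the four "wt1 / wt2" style strings.
    """
    meta = metadata.set_index("id", drop=False)
    rows = []
    n_dropped = 0
    for acc in meta.index:
        a1 = locus1_alleles.get(acc)
        a2 = locus2_alleles.get(acc)
        if a1 not in ("WT", "MUT") or a2 not in ("WT", "MUT"):
            n_dropped += 1
            continue
        row = meta.loc[acc].to_dict()
        row["allele_1"] = a1
        row["allele_2"] = a2
        row["combination"] = (
            f"{locus1_names.label(a1)} / {locus2_names.label(a2)}"
        )
        rows.append(row)
    if n_dropped:
        logger.info(
            "assign_combinations: dropped %d accessions unresolved at one "
            "or both loci",
            n_dropped,
        )
    cols = list(metadata.columns) + ["allele_1", "allele_2", "combination"]
    return pd.DataFrame(rows, columns=cols).reset_index(drop=True)


def latitude_summary(records: pd.DataFrame, alpha: float = 0.05):
    """Mean latitude per allele combination with significance letters.

    Records without latitude are excluded.  Returns a
    :class:`~proxyhap.group_comparison.LetterAssignment` whose group
    table has columns (group, n, mean, sd, letters); means are in °N.
    Letter assignment needs at least two groups; a single group is
    summarised with letter "a".
    """
    with_lat = records[records["latitude"].notna()]
    if with_lat.empty:
        raise ValueError("no records with latitude")
    obs = list(zip(with_lat["combination"], with_lat["latitude"].astype(float)))
    groups = sorted({g for g, _ in obs})
    if len(groups) == 1:
        vals = np.array([v for _, v in obs])
        tbl = pd.DataFrame(
            {
                "group": groups,
                "n": [vals.size],
                "mean": [vals.mean()],
                "sd": [vals.std(ddof=1) if vals.size > 1 else 0.0],
                "letters": ["a"],
            }
        )
        return LetterAssignment(groups=tbl, pairwise=pd.DataFrame(), alpha=alpha)
    return fisher_lsd_fdr(GroupedValues(obs, alpha=alpha))


def downsample_for_plot(
    records: pd.DataFrame, cap: int = DEFAULT_PLOT_CAP, seed: int = 0
) -> pd.DataFrame:
    """Cap each combination group at `cap` records for plotting.

    Groups at or under the cap pass through unchanged; larger groups are
    reduced to exactly `cap` rows by seeded uniform sampling without
    replacement.  Original row order is preserved within groups.
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(records), dtype=bool)
    for _, idx in records.groupby("combination", sort=True).indices.items():
        if len(idx) <= cap:
            keep[idx] = True
        else:
            keep[rng.choice(idx, size=cap, replace=False)] = True
    return records.iloc[np.flatnonzero(keep)].reset_index(drop=True)


def jitter_coordinates(
    records: pd.DataFrame,
    magnitude_deg: float = DEFAULT_JITTER_DEG,
    seed: int = 0,
) -> pd.DataFrame:
    """Add uniform jitter in [-magnitude, +magnitude] degrees.

    Adds `lat_jit` / `lon_jit` columns; the original latitude/longitude
    columns are preserved.  Jitter is drawn independently per record and
    axis.
    """
    if magnitude_deg < 0:
        raise ValueError("jitter magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    out = records.copy()
    n = len(out)
    out["lat_jit"] = out["latitude"].astype(float) + rng.uniform(
        -magnitude_deg, magnitude_deg, size=n
    )
    out["lon_jit"] = out["longitude"].astype(float) + rng.uniform(
        -magnitude_deg, magnitude_deg, size=n
    )
    return out


def country_frequency(records: pd.DataFrame, combination: str) -> pd.DataFrame:
    """Country-of-origin counts for one allele combination.

    Records with missing country are reported under "Unknown".
    Percentages are of the combination's total.
    """
    sub = records[records["combination"] == combination]
    if sub.empty:
        return pd.DataFrame(columns=["country", "count", "percent"])
    country = sub["country"].fillna(UNKNOWN_COUNTRY).replace("", UNKNOWN_COUNTRY)
    counts = country.value_counts()
    out = counts.rename_axis("country").reset_index(name="count")
    out["percent"] = 100.0 * out["count"] / out["count"].sum()
    return out
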
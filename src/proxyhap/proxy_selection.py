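"""Proxy-marker selection by combined pessimistic accuracy.

A *proxy SNP* is an array marker in strong haplotype association with a
causal mutation, used to impute the causal genotype into germplasm that
has array data but no sequence data.  The strength of association is
scored with the **combined pessimistic accuracy**: the percentage of
panel accessions whose array call correctly associates with their
causal-site haplotype,

    accuracy = 100 * (n_correct_WT + n_correct_MUT) / n_total

where an accession is *correct* only if both its proxy call and its
causal call are homozygous and non-missing and the proxy allele maps to
the causal allele under the chosen REF/ALT <-> WT/MUT orientation.
Heterozygous or missing calls on either side are never correct but
always count in the denominator — the "pessimistic" rule, which folds
sensitivity, specificity and missing data into one number.

The orientation (REF<->WT or REF<->MUT) is chosen per marker by
maximising accuracy over both mappings; ties go to REF<->WT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from proxyhap.encoding import ALT_HOM, HET, MISSING, MUT_HOM, REF_HOM, WT_HOM, as_call_array
from proxyhap.genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

ORIENT_REF_WT = "REF<->WT"
ORIENT_REF_MUT = "REF<->MUT"

DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class CausalSite:
    """A named causal biallelic variant, e.g. e1-as or e1la:K82E."""

    name: str
    chromosome: str
    position: int
    wt_allele: str
    mut_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if self.wt_allele == self.mut_allele:
            raise ValueError("WT and MUT alleles must differ")


@dataclass(frozen=True)
class ConcordanceCounts:
    """The three terms of the accuracy equation."""

    n_correct_wt: int
    n_correct_mut: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_correct_wt + self.n_correct_mut > self.n_total:
            raise ValueError("correct counts exceed total")


@dataclass(frozen=True)
class ConcordanceResult:
    """Score for one proxy marker against one causal site."""

    marker_id: str
    distance_bp: int
    orientation: str
    counts: ConcordanceCounts
    accuracy: float  # percent in [0, 100]

    @property
    def n_total(self) -> int:
        return self.counts.n_total


def _oriented_accuracy(proxy: np.ndarray, causal: np.ndarray, flipped: bool):
    """Counts under one orientation.

    Under REF<->WT (`flipped=False`) proxy REF_HOM maps to causal
    WT_HOM and ALT_HOM to MUT_HOM; under REF<->MUT the mapping swaps.
    """
    proxy_wt = ALT_HOM if flipped else REF_HOM
    proxy_mut = REF_HOM if flipped else ALT_HOM
    n_wt = int(np.count_nonzero((proxy == proxy_wt) & (causal == WT_HOM)))
    n_mut = int(np.count_nonzero((proxy == proxy_mut) & (causal == MUT_HOM)))
    return n_wt, n_mut


def combined_pessimistic_accuracy(
    proxy_calls,
    causal_calls,
    marker_id: str = "",
    distance_bp: int = 0,
) -> ConcordanceResult:
    """Score one proxy-call vector against the causal-call vector.

    Parameters
    ----------
    proxy_calls, causal_calls:
        Equal-length vectors in the four-state encoding.  The causal
        vector's REF_HOM/ALT_HOM codes are read as WT_HOM/MUT_HOM.

    Returns
    -------
    ConcordanceResult
        With the orientation that maximises accuracy (ties -> REF<->WT)
        and the count breakdown under that orientation.
    """
    proxy = as_call_array(proxy_calls)
    causal = as_call_array(causal_calls)
    if proxy.shape != causal.shape:
        raise ValueError(
            f"call vectors differ in length: {proxy.shape} vs {causal.shape}"
        )
    if proxy.size == 0:
        raise ValueError("empty call vectors")
    n_total = int(proxy.size)
    best = None
    for orientation, flipped in ((ORIENT_REF_WT, False), (ORIENT_REF_MUT, True)):
        n_wt, n_mut = _oriented_accuracy(proxy, causal, flipped)
        acc = 100.0 * (n_wt + n_mut) / n_total
        if best is None or acc > best[0]:
            best = (acc, orientation, n_wt, n_mut)
    acc, orientation, n_wt, n_mut = best
    return ConcordanceResult(
        marker_id=marker_id,
        distance_bp=distance_bp,
        orientation=orientation,
        counts=ConcordanceCounts(n_wt, n_mut, n_total),
        accuracy=acc,
    )


def scan_window(
    array: GenotypeMatrix,
    panel_causal_calls: pd.Series,
    causal: CausalSite,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[ConcordanceResult]:
    """Score every array marker within `window_bp` of the causal site.

    `panel_causal_calls` is a Series of four-state causal calls indexed
    by accession id.  Accessions absent from either the array matrix or
    the causal vector are dropped before scoring (intersection panel).
    Results are ranked by accuracy descending, then distance ascending,
    then position ascending.
    """
    causal_calls = panel_causal_calls
    shared = [a for a in array.accession_ids if a in causal_calls.index]
    if not shared:
        raise ValueError("no accessions shared between array and causal calls")
    row_idx = [array.accession_ids.index(a) for a in shared]
    causal_vec = as_call_array(causal_calls.loc[shared].to_numpy())

    in_window = (array.markers["chrom"] == causal.chromosome) & (
        (array.markers["pos"] - causal.position).abs() <= window_bp
    )
    if not in_window.any():
        logger.warning(
            "no array markers within %d bp of %s (%s:%d)",
            window_bp,
            causal.name,
            causal.chromosome,
            causal.position,
        )
        return []

    results = []
    positions = {}
    for col in np.flatnonzero(in_window.to_numpy()):
        marker = array.markers.iloc[col]
        res = combined_pessimistic_accuracy(
            array.calls[row_idx, col],
            causal_vec,
            marker_id=marker["marker_id"],
            distance_bp=int(abs(marker["pos"] - causal.position)),
        )
        positions[res.marker_id] = int(marker["pos"])
        results.append(res)
    results.sort(
        key=lambda r: (-r.accuracy, r.distance_bp, positions[r.marker_id])
    )
    return results


def select_proxy(ranked: list[ConcordanceResult]) -> ConcordanceResult:
    """Return the top-ranked marker from a `scan_window` result."""
    if not ranked:
        raise ValueError(
            "no candidate proxy markers in the scan window; widen --window "
            "or check the causal chromosome name"
        )
    return ranked[0]


def impute_causal(
    proxy: ConcordanceResult,
    array_calls: pd.Series,
) -> tuple[pd.Series, pd.DataFrame]:
    """Impute causal alleles into array-only accessions via the proxy.

    Only homozygous proxy calls are imputed: REF_HOM/ALT_HOM map to
    "WT"/"MUT" through the proxy's orientation; HET and MISSING calls
    are excluded (the accession is dropped from downstream grouping).

    Parameters
    ----------
    proxy:
        The selected marker with its resolved orientation.
    array_calls:
        Four-state proxy-marker calls indexed by accession id.

    Returns
    -------
    (imputed, excluded)
        `imputed` — Series of "WT"/"MUT" labels for retained accessions;
        `excluded` — DataFrame (id, reason) for dropped ones.
    """
    flipped = proxy.orientation == ORIENT_REF_MUT
    ref_means = "MUT" if flipped else "WT"
    alt_means = "WT" if flipped else "MUT"
    alleles = {}
    excluded = []
    for acc, call in array_calls.items():
        if call == REF_HOM:
            alleles[acc] = ref_means
        elif call == ALT_HOM:
            alleles[acc] = alt_means
        elif call == HET:
            excluded.append((acc, "heterozygous proxy call"))
        else:
            excluded.append((acc, "missing proxy call"))
    if excluded:
        logger.info(
            "impute_causal(%s): excluded %d of %d accessions (non-homozygous)",
            proxy.marker_id,
            len(excluded),
            len(array_calls),
        )
    return (
        pd.Series(alleles, dtype=object),
        pd.DataFrame(excluded, columns=["id", "reason"]),
    )


def results_to_frame(results: list[ConcordanceResult], array: GenotypeMatrix) -> pd.DataFrame:
    """Tabulate ranked results (the `ranked.tsv` layout)."""
    pos = array.markers.set_index("marker_id")
    rows = [
        {
            "marker_id": r.marker_id,
            "chrom": pos.at[r.marker_id, "chrom"],
            "pos": int(pos.at[r.marker_id, "pos"]),
            "distance_bp": r.distance_bp,
            "orientation": r.orientation,
            "n_correct_wt": r.counts.n_correct_wt,
            "n_correct_mut": r.counts.n_correct_mut,
            "n_total": r.counts.n_total,
            "accuracy_pct": r.accuracy,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
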
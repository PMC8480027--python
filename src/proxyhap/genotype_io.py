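"""Readers and writers for the formats the pipeline touches.

Normalises a panel VCF, an array-genotype TSV, and an accession-metadata
TSV into the shared data model (:class:`GenotypeMatrix`,
:class:`AccessionRecord` tables).  Positions are 1-based inclusive
throughout (VCF convention); chromosome names are compared as exact
strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from proxyhap.encoding import (
    ALT_HOM,
    CODE_TO_TOKEN,
    HET,
    MISSING,
    REF_HOM,
    TOKEN_TO_CODE,
    as_call_array,
)

ARRAY_HEADER = ["marker_id", "chrom", "pos", "ref", "alt"]
METADATA_COLUMNS = [
    "id",
    "species",
    "latitude",
    "longitude",
    "country",
    "state_province",
    "maturity_group",
]


@dataclass
class GenotypeMatrix:
    """Accessions x markers of collapsed diploid calls.

    Attributes
    ----------
    accession_ids:
        Row labels, one per accession.
    markers:
        DataFrame with columns ``marker_id, chrom, pos, ref, alt``
        (positions 1-based bp), one row per marker (column of `calls`).
    calls:
        int8 array of shape ``(n_accessions, n_markers)`` in the
        four-state encoding.
    """

    accession_ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = as_call_array(self.calls)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D accessions x markers array")
        n_acc, n_mark = self.calls.shape
        if n_acc != len(self.accession_ids) or n_mark != len(self.markers):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.markers)} markers"
            )
        ids = self.markers["marker_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate marker ids: {dups}")
        if (self.markers["pos"] < 1).any():
            raise ValueError("marker positions must be >= 1 (1-based)")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_calls(self, marker_id: str) -> np.ndarray:
        """Call vector (one per accession) for a single marker."""
        idx = self.markers.index[self.markers["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"marker {marker_id!r} not in matrix")
        return self.calls[:, self.markers.index.get_loc(idx[0])]

    def call_series(self, marker_id: str) -> pd.Series:
        """Marker calls indexed by accession id."""
        return pd.Series(self.marker_calls(marker_id), index=self.accession_ids)


def read_panel_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Diploid GTs are collapsed: ``0/0`` -> REF_HOM, ``1/1`` -> ALT_HOM,
    ``0/1``/``1/0`` -> HET, ``./.`` -> MISSING.  Multi-allelic records
    are rejected.
    """
    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows = []
    columns = []
    seen_ids: set[str] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={rec.ALT}); split or filter to biallelic sites first"
            )
        marker_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if marker_id in seen_ids:
            raise ValueError(f"duplicate marker id {marker_id!r} in VCF")
        seen_ids.add(marker_id)
        rows.append((marker_id, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = rec.gt_types
        col = np.full(len(accessions), MISSING, dtype=np.int8)
        col[gt == 0] = REF_HOM
        col[gt == 1] = HET
        col[gt == 3] = ALT_HOM
        columns.append(col)
    markers = pd.DataFrame(rows, columns=ARRAY_HEADER)
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(accessions), 0), dtype=np.int8)
    )
    return GenotypeMatrix(accessions, markers, calls)


def write_array_tsv(matrix: GenotypeMatrix, path: str) -> None:
    """Write a matrix as an array TSV (AA/BB/AB/-- call tokens)."""
    # calls are stored accessions x markers; the TSV is markers x accessions
    call_cols = pd.DataFrame(
        {
            acc: [CODE_TO_TOKEN[c] for c in matrix.calls[j, :]]
            for j, acc in enumerate(matrix.accession_ids)
        },
        index=matrix.markers.index,
    )
    out = pd.concat([matrix.markers, call_cols], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_array_tsv(path: str) -> GenotypeMatrix:
    """Read an array-genotype TSV.

    Expected header: ``marker_id  chrom  pos  ref  alt`` followed by one
    column per accession.  Call spellings ``AA/BB/AB/--`` and
    ``0/2/1/-1`` are accepted and normalised to the four-state encoding.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in ARRAY_HEADER if c not in df.columns]
    if missing_cols:
        raise ValueError(f"array TSV missing required columns: {missing_cols}")
    accessions = [c for c in df.columns if c not in ARRAY_HEADER]
    markers = df[ARRAY_HEADER].copy()
    markers["pos"] = markers["pos"].astype(int)
    calls = np.empty((len(accessions), len(df)), dtype=np.int8)
    for j, acc in enumerate(accessions):
        for i, tok in enumerate(df[acc]):
            if tok is None or (isinstance(tok, float) and math.isnan(tok)):
                raise ValueError(
                    f"empty call for accession {acc!r} at marker "
                    f"{markers['marker_id'].iloc[i]!r}"
                )
            tok = str(tok).strip()
            if tok not in TOKEN_TO_CODE:
                raise ValueError(
                    f"unknown call token {tok!r} for accession {acc!r} at "
                    f"marker {markers['marker_id'].iloc[i]!r}"
                )
            calls[j, i] = TOKEN_TO_CODE[tok]
    return GenotypeMatrix(accessions, markers.reset_index(drop=True), calls)


@dataclass
class AccessionRecord:
    """Germplasm metadata for one accession."""

    id: str
    species: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    country: str | None = None
    state_province: str | None = None
    maturity_group: str | None = None
    alleles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")


def read_metadata(
    path: str,
    coordinate_lookup: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Read an accession-metadata TSV into a records DataFrame.

    Records lacking coordinates are filled from `coordinate_lookup`
    (state/province -> (lat, lon)) when a key matches, else left
    missing.  Missing country stays missing here; the geography stage
    applies the "Unknown" label at plot time.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df["latitude"] = pd.to_numeric(df["latitude"], errors="coerce")
    df["longitude"] = pd.to_numeric(df["longitude"], errors="coerce")
    if coordinate_lookup:
        needs = df["latitude"].isna() | df["longitude"].isna()
        for i in df.index[needs]:
            key = df.at[i, "state_province"]
            if pd.notna(key) and key in coordinate_lookup:
                lat, lon = coordinate_lookup[key]
                df.at[i, "latitude"] = lat
                df.at[i, "longitude"] = lon
    bad = df["latitude"].notna() & ~df["latitude"].between(-90, 90)
    if bad.any():
        raise ValueError(
            f"latitudes outside [-90, 90] for ids: {df.loc[bad, 'id'].tolist()}"
        )
    return df[METADATA_COLUMNS]


def read_coordinate_lookup(path: str) -> dict[str, tuple[float, float]]:
    """Read a state/province -> (lat, lon) lookup TSV.

    Columns: ``state_province, latitude, longitude``.  This offline
    table replaces network geocoding so runs are reproducible.
    """
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.state_province): (float(r.latitude), float(r.longitude))
        for r in df.itertuples()
    }
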
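"""Synthetic panels, array matrices, metadata, and phenology tables.

Every downstream stage of the pipeline is testable against data with
known ground truth generated here.  Three generators emulate the three
data sources a real analysis draws on:

* :func:`simulate_panel` — a resequenced inbred panel with one causal
  biallelic site and flanking array markers at specified haplotype
  concordance, with controllable missing-call and heterozygote rates
  (emulating a curated resequencing panel plus a SoySNP50k-style
  array).
* :func:`simulate_geography` — accession metadata with a latitudinal
  cline by allele combination and a weighted country distribution
  (emulating GRIN passport data).
* :func:`simulate_phenology` — plot-level replicated field-trial
  records with genotype-group effects, replicate noise, and maturity
  censoring at first frost.

The haplotype model is deliberately minimal: each accession draws a
causal allele (Bernoulli at the causal minor-allele frequency) and each
marker copies the causal state with probability equal to its planted
concordance, flipping otherwise.  No recombination machinery — the
point is a controllable accuracy surface, not realistic LD decay.
Accessions are simulated fully inbred (homozygous) and then corrupted
to HET/MISSING, matching inbred soybean germplasm.  Corruption applies
to the array-marker calls; the causal-site calls emulate curated
resequencing genotypes and stay clean.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from proxyhap.encoding import ALT_HOM, HET, MISSING, REF_HOM
from proxyhap.genotype_io import GenotypeMatrix

_DEF_CHROM = "Gm04"
_DEF_CAUSAL_POS = 28_294_378  # arbitrary interior coordinate; any >= 1 works


def _check_rate(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class PanelSimParams:
    """Parameters for the panel + array simulator."""

    n_accessions: int
    causal_maf: float
    marker_positions: tuple[int, ...]  # bp offsets from the causal site
    marker_concordance: tuple[float, ...]
    missing_rate: float = 0.0
    het_rate: float = 0.0
    seed: int = 0
    chromosome: str = _DEF_CHROM
    causal_position: int = _DEF_CAUSAL_POS

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("n_accessions must be >= 2")
        _check_rate("causal_maf", self.causal_maf)
        _check_rate("missing_rate", self.missing_rate)
        _check_rate("het_rate", self.het_rate)
        if self.missing_rate + self.het_rate > 1.0:
            raise ValueError("missing_rate + het_rate must not exceed 1")
        if len(self.marker_positions) != len(self.marker_concordance):
            raise ValueError("marker position/concordance lists differ in length")
        for c in self.marker_concordance:
            _check_rate("marker_concordance", c)
        if any(o == 0 for o in self.marker_positions):
            raise ValueError("marker offsets must be non-zero (causal site is separate)")


@dataclass(frozen=True)
class PanelTruth:
    """Ground truth recorded alongside a simulated panel."""

    causal_alleles: tuple[str, ...]  # "WT"/"MUT" per accession
    realized_concordance: tuple[float, ...]  # per marker, pre-corruption
    marker_ids: tuple[str, ...]
    causal_marker_id: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _vcf_gt(call: int) -> str:
    return {REF_HOM: "0/0", ALT_HOM: "1/1", HET: "0/1", MISSING: "./."}[call]


def _write_vcf(
    accessions: list[str],
    records: list[tuple[str, int, str, str, str, np.ndarray]],
) -> str:
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    for chrom in sorted({r[0] for r in records}):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(accessions)
        + "\n"
    )
    for chrom, pos, vid, ref, alt, calls in sorted(records, key=lambda r: (r[0], r[1])):
        gts = "\t".join(_vcf_gt(int(c)) for c in calls)
        buf.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
    return buf.getvalue()


def simulate_panel(params: PanelSimParams) -> tuple[str, GenotypeMatrix, PanelTruth]:
    """Simulate a resequenced panel and its array-marker matrix.

    Returns ``(vcf_text, array_matrix, truth)``.  The VCF contains the
    causal site (REF = WT allele) and all array markers; the
    :class:`GenotypeMatrix` holds the array markers only, with
    HET/MISSING corruption applied.  The truth record stores each
    accession's causal allele and each marker's realized concordance —
    the fraction of accessions whose (pre-corruption) marker haplotype
    matches their causal haplotype under the planted REF<->WT
    orientation.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_accessions
    m = len(params.marker_positions)
    width = max(4, len(str(n)))
    accessions = [f"ACC{i + 1:0{width}d}" for i in range(n)]

    causal_mut = rng.random(n) < params.causal_maf  # True -> MUT
    causal_calls = np.where(causal_mut, ALT_HOM, REF_HOM).astype(np.int8)

    marker_states = np.empty((n, m), dtype=np.int8)
    realized = []
    for j, conc in enumerate(params.marker_concordance):
        match = rng.random(n) < conc
        # planted orientation REF<->WT: marker ALT travels with causal MUT
        marker_states[:, j] = np.where(causal_mut == match, ALT_HOM, REF_HOM)
        realized.append(float(np.mean(match)))

    # HET/MISSING corruption of array calls (mutually exclusive draw)
    u = rng.random((n, m))
    corrupted = marker_states.copy()
    corrupted[u < params.missing_rate] = MISSING
    both = params.missing_rate + params.het_rate
    corrupted[(u >= params.missing_rate) & (u < both)] = HET

    positions = [params.causal_position + off for off in params.marker_positions]
    marker_ids = [f"sim{j + 1:03d}" for j in range(m)]
    causal_id = "causal"
    markers = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "chrom": params.chromosome,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    matrix = GenotypeMatrix(accessions, markers, corrupted)

    records = [(params.chromosome, params.causal_position, causal_id, "A", "G", causal_calls)]
    for j in range(m):
        records.append(
            (params.chromosome, positions[j], marker_ids[j], "A", "G", corrupted[:, j])
        )
    vcf_text = _write_vcf(accessions, records)

    truth = PanelTruth(
        causal_alleles=tuple("MUT" if x else "WT" for x in causal_mut),
        realized_concordance=tuple(realized),
        marker_ids=tuple(marker_ids),
        causal_marker_id=causal_id,
    )
    return vcf_text, matrix, truth


@dataclass(frozen=True)
class GeoSimParams:
    """Parameters for the metadata / latitudinal-cline simulator."""

    group_mean_latitudes: dict[str, float]
    latitude_sd: float
    n_per_group: dict[str, int]
    countries: tuple[tuple[str, float], ...] = (("China", 1.0),)
    missing_country_rate: float = 0.0
    group_mean_longitudes: dict[str, float] | None = None
    longitude_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latitude_sd < 0:
            raise ValueError("latitude_sd must be >= 0")
        _check_rate("missing_country_rate", self.missing_country_rate)
        for g, lat in self.group_mean_latitudes.items():
            if not -90 <= lat <= 90:
                raise ValueError(f"group {g!r} mean latitude {lat} outside [-90, 90]")
        unknown = set(self.n_per_group) - set(self.group_mean_latitudes)
        if unknown:
            raise ValueError(f"n_per_group keys without a mean latitude: {sorted(unknown)}")


def simulate_geography(params: GeoSimParams) -> pd.DataFrame:
    """Simulate accession metadata with a latitudinal cline per group.

    Returns a records DataFrame (id, species, latitude, longitude,
    country, combination) with per-group normal latitudes around the
    planted means and a weighted country draw;
    ``missing_country_rate`` of records get a missing country.
    """
    rng = np.random.default_rng(params.seed)
    names = [c for c, _ in params.countries]
    weights = np.array([w for _, w in params.countries], dtype=float)
    weights = weights / weights.sum()
    lon_means = params.group_mean_longitudes or {}
    lon_sd = params.longitude_sd if params.longitude_sd is not None else params.latitude_sd
    rows = []
    i = 0
    for group in sorted(params.n_per_group):
        n = params.n_per_group[group]
        lats = rng.normal(params.group_mean_latitudes[group], params.latitude_sd, n)
        lons = rng.normal(lon_means.get(group, 127.0), lon_sd, n)
        countries = rng.choice(names, size=n, p=weights)
        miss = rng.random(n) < params.missing_country_rate
        for k in range(n):
            i += 1
            rows.append(
                {
                    "id": f"GEO{i:05d}",
                    "species": "G. soja",
                    "latitude": float(np.clip(lats[k], -90, 90)),
                    "longitude": float(lons[k]),
                    "country": None if miss[k] else str(countries[k]),
                    "combination": group,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhenoSimParams:
    """Parameters for the field-trial phenology simulator."""

    group_effects: dict[str, tuple[float, float]]  # group -> (mean R1, mean R8)
    replicate_sd: float
    n_reps: int
    frost_day: float
    n_lines: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        for g, (r1, r8) in self.group_effects.items():
            if not r1 < r8:
                raise ValueError(f"group {g!r}: mean R1 ({r1}) must be < mean R8 ({r8})")


def simulate_phenology(params: PhenoSimParams) -> pd.DataFrame:
    """Simulate plot-level phenology for a replicated trial.

    Each group contributes ``n_lines`` lines x ``n_reps`` replicate
    plots; plot R1/R8 are the group means plus independent normal
    replicate noise.  Plots whose true R8 exceeds ``frost_day`` are
    emitted with R8 missing, to be censored downstream by
    :func:`proxyhap.phenology.censor_at_frost`.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for group in sorted(params.group_effects):
        mean_r1, mean_r8 = params.group_effects[group]
        for line in range(params.n_lines):
            line_id = f"{group}-L{line + 1}"
            for rep in range(1, params.n_reps + 1):
                r1 = mean_r1 + rng.normal(0.0, params.replicate_sd)
                r8 = mean_r8 + rng.normal(0.0, params.replicate_sd)
                r8 = max(r8, r1)  # maturity cannot precede flowering
                rows.append(
                    {
                        "line_id": line_id,
                        "group": group,
                        "rep": rep,
                        "planting_date": "2019-05-31",
                        "r1_dap": float(r1),
                        "r8_dap": float(r8) if r8 <= params.frost_day else None,
                    }
                )
    return pd.DataFrame(rows)
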
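"""Ingestion of ROV transect survey tables and conversion to density matrices.

The analysis starts from long-format count tables produced by video reads of
remotely-operated-vehicle (ROV) surveys: each survey (one site visit) comprises
3-4 orthogonal 25-m transects, and fish counts are recorded per transect and
taxon.  This module reads those tables, sums counts across transects (with a
school-minimum override for actively schooling species prone to double
counting), converts abundances to densities by the surveyed area, aggregates
taxa into trophic guilds, and assigns each survey to a year bin relative to a
disturbance cutoff date.

CSV dialects (UTF-8, header row required)
-----------------------------------------
counts:   ``site,date,transect,taxon,count``  — ``transect`` is ``1``..``4``
          or the literal ``school`` for a school minimum-count estimate.
metadata: ``site,date,depth_m,longitude,n_transects``
registry: ``taxon,guild,schooling,merge_into`` — ``schooling`` is 0/1;
          ``merge_into`` is empty (keep), ``DROP`` (discard at ingestion,
          e.g. records above species level), or the name of another registry
          taxon to merge counts into (e.g. visually indistinguishable species
          pooled into one group).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("reeftrend")

#: Label of the pooled pre-disturbance year bin.
PRE_BIN = "pre-DWH"

#: Transect length in metres (fixed by the survey protocol).
TRANSECT_LENGTH_M = 25.0

#: Default transect field width in metres.  The width enters only as a
#: constant scale on densities, but it is kept explicit so the density unit
#: is well defined.
DEFAULT_FIELD_WIDTH_M = 2.0

#: Default date after which surveys are no longer pooled into the
#: pre-disturbance bin (surface oil reaching the sampling region).
DEFAULT_CUTOFF = dt.date(2010, 6, 1)

#: Area unit used for reported densities (individuals per 100 m^2).
DENSITY_AREA_M2 = 100.0
DENSITY_UNIT = "ind per 100 m2"

#: The nine trophic guilds used for guild-level analyses.
GUILDS = (
    "herbivore",
    "small demersal browser",
    "large demersal browser",
    "small demersal invertivore",
    "large demersal invertivore",
    "generalist carnivore",
    "piscivore",
    "reef planktivore",
    "pelagic planktivore",
)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class SurveyRecord:
    """One ROV deployment: site metadata plus per-transect counts.

    ``transects`` maps taxon -> count separately for each transect;
    ``school_min`` holds optional minimum school-size estimates that
    supersede the transect sum for schooling taxa.
    """

    site: str
    date: dt.date
    depth_m: float
    longitude: float
    transects: list[dict[str, int]]
    school_min: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 3 <= len(self.transects) <= 4:
            logger.warning(
                "survey %s %s has %d transects (protocol is 3-4)",
                self.site, self.date, len(self.transects),
            )
        for t in self.transects:
            for taxon, c in t.items():
                if c < 0 or int(c) != c:
                    raise ValueError(
                        f"negative or non-integer count for {taxon!r} in "
                        f"survey {self.site} {self.date}: {c}"
                    )

    @property
    def year(self) -> int:
        return self.date.year

    @property
    def month(self) -> int:
        return self.date.month

    @property
    def sample_id(self) -> str:
        return f"{self.site}:{self.date.isoformat()}"


@dataclass
class CommunityMatrix:
    """Samples x taxa density table with sample metadata and a taxon registry.

    ``densities`` has one row per survey (sample) and one column per taxon;
    absences are explicit zeros.  ``meta`` is row-aligned and carries site,
    year, month, year_bin, depth_m, longitude and surveyed area; ``registry``
    is indexed by taxon and carries guild and schooling flags.
    """

    densities: pd.DataFrame
    meta: pd.DataFrame
    registry: pd.DataFrame
    density_unit: str = DENSITY_UNIT

    def __post_init__(self) -> None:
        if not self.densities.index.equals(self.meta.index):
            raise ValueError("densities and meta must share the same sample index")
        if self.densities.isna().any().any():
            raise ValueError("density matrix contains missing cells")
        if (self.densities.to_numpy() < 0).any():
            raise ValueError("density matrix contains negative values")
        missing = set(self.densities.columns) - set(self.registry.index)
        if missing:
            raise ValueError(f"taxa absent from registry: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return len(self.densities)

    def copy_with(self, densities: pd.DataFrame, **kw) -> "CommunityMatrix":
        return CommunityMatrix(
            densities=densities,
            meta=self.meta.copy(),
            registry=kw.pop("registry", self.registry.copy()),
            density_unit=kw.pop("density_unit", self.density_unit),
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_registry(path) -> pd.DataFrame:
    """Read the taxon registry CSV (taxon, guild, schooling, merge_into)."""
    reg = pd.read_csv(path, dtype={"taxon": str, "guild": str, "merge_into": str})
    required = {"taxon", "guild", "schooling"}
    if not required <= set(reg.columns):
        raise ValueError(f"registry missing columns {sorted(required - set(reg.columns))}")
    if "merge_into" not in reg.columns:
        reg["merge_into"] = ""
    reg["merge_into"] = reg["merge_into"].fillna("")
    reg["schooling"] = reg["schooling"].astype(int).astype(bool)
    if reg["taxon"].duplicated().any():
        dups = reg.loc[reg["taxon"].duplicated(), "taxon"].tolist()
        raise ValueError(f"duplicate registry taxa: {dups}")
    bad_guilds = set(reg.loc[reg["merge_into"] != "DROP", "guild"]) - set(GUILDS)
    if bad_guilds:
        logger.warning("registry contains unrecognised guild labels: %s", sorted(bad_guilds))
    return reg.set_index("taxon")


def read_surveys(counts_path, metadata_path, registry_path):
    """Read counts + metadata + registry CSVs into ``SurveyRecord`` objects.

    Returns ``(records, registry)``.  Taxa flagged ``merge_into=DROP`` are
    discarded with a logged note; taxa with a merge target are re-labelled
    before counts are assembled.  Every retained input count row ends up in
    exactly one record; dropped rows are counted in the log.
    """
    registry = read_registry(registry_path)
    counts = pd.read_csv(counts_path, dtype={"site": str, "taxon": str, "transect": str})
    meta = pd.read_csv(metadata_path, dtype={"site": str})

    unknown = set(counts["taxon"]) - set(registry.index)
    if unknown:
        raise ValueError(f"unknown taxa in counts table: {sorted(unknown)}")
    if (counts["count"] < 0).any():
        bad = counts.index[counts["count"] < 0][0]
        raise ValueError(f"negative count at counts row {bad}: {counts.loc[bad].to_dict()}")
    dup = counts.duplicated(subset=["site", "date", "transect", "taxon"])
    if dup.any():
        raise ValueError(
            f"duplicate (site,date,transect,taxon) rows in counts: "
            f"{counts.loc[dup, ['site', 'date', 'transect', 'taxon']].head().to_dict('records')}"
        )

    # apply registry merges / drops
    merge_map = registry["merge_into"].to_dict()
    n_in = len(counts)
    drop_mask = counts["taxon"].map(lambda t: merge_map.get(t, "") == "DROP")
    if drop_mask.any():
        logger.info("dropping %d count rows for DROP-flagged taxa", int(drop_mask.sum()))
    counts = counts.loc[~drop_mask].copy()
    counts["taxon"] = counts["taxon"].map(
        lambda t: merge_map[t] if merge_map.get(t, "") not in ("", "DROP") else t
    )
    still_unknown = set(counts["taxon"]) - set(registry.index)
    if still_unknown:
        raise ValueError(f"merge targets absent from registry: {sorted(still_unknown)}")
    logger.info("counts rows: %d read, %d retained", n_in, len(counts))

    meta["date"] = pd.to_datetime(meta["date"]).dt.date
    counts["date"] = pd.to_datetime(counts["date"]).dt.date
    if meta.duplicated(subset=["site", "date"]).any():
        raise ValueError("duplicate (site,date) rows in metadata")

    records = []
    grouped = counts.groupby(["site", "date"], sort=True)
    meta_idx = meta.set_index(["site", "date"])
    for (site, date), grp in grouped:
        try:
            m = meta_idx.loc[(site, date)]
        except KeyError:
            raise ValueError(f"survey {site} {date} present in counts but not metadata")
        n_tr = int(m["n_transects"])
        transects: list[dict[str, int]] = [dict() for _ in range(n_tr)]
        school: dict[str, int] = {}
        for _, row in grp.iterrows():
            if row["transect"] == "school":
                school[row["taxon"]] = school.get(row["taxon"], 0) + int(row["count"])
                continue
            k = int(row["transect"]) - 1
            if not 0 <= k < n_tr:
                raise ValueError(
                    f"transect {row['transect']} out of range for survey {site} {date} "
                    f"(n_transects={n_tr})"
                )
            transects[k][row["taxon"]] = transects[k].get(row["taxon"], 0) + int(row["count"])
        records.append(
            SurveyRecord(
                site=site, date=date, depth_m=float(m["depth_m"]),
                longitude=float(m["longitude"]), transects=transects,
                school_min=school,
            )
        )
    return records, registry


# ---------------------------------------------------------------------------
# abundance / density
# ---------------------------------------------------------------------------

def total_abundance(record: SurveyRecord, registry: pd.DataFrame) -> dict[str, int]:
    """Per-taxon total abundance for one survey.

    Counts are summed across transects; for schooling taxa a school
    minimum-count estimate, when recorded, supersedes the transect sum (the
    transect sum double-counts individuals of mobile schools).  A schooling
    taxon without an estimate falls back to the transect sum with a note.
    """
    totals: dict[str, int] = {}
    for t in record.transects:
        for taxon, c in t.items():
            totals[taxon] = totals.get(taxon, 0) + int(c)
    schooling = registry["schooling"]
    for taxon in list(totals):
        if taxon in registry.index and bool(schooling.get(taxon, False)):
            if taxon in record.school_min:
                totals[taxon] = int(record.school_min[taxon])
            else:
                logger.info(
                    "schooling taxon %r in survey %s has no school estimate; "
                    "using transect sum", taxon, record.sample_id,
                )
    # school estimates for taxa never seen on-transect still count
    for taxon, c in record.school_min.items():
        if taxon not in totals:
            totals[taxon] = int(c)
    return totals


def to_density(record: SurveyRecord, registry: pd.DataFrame,
               field_width_m: float = DEFAULT_FIELD_WIDTH_M):
    """Convert a survey's abundances to densities (per 100 m^2).

    Returns ``(densities, area_m2)`` where ``area_m2`` is
    ``n_transects * 25 m * field_width_m``.
    """
    if field_width_m <= 0:
        raise ValueError(f"field_width_m must be positive, got {field_width_m}")
    n_tr = len(record.transects)
    if n_tr == 0:
        raise ValueError(f"survey {record.sample_id} has no transects")
    area = n_tr * TRANSECT_LENGTH_M * field_width_m
    abund = total_abundance(record, registry)
    dens = {taxon: c / area * DENSITY_AREA_M2 for taxon, c in abund.items()}
    return dens, area


def assign_year_bin(year: int, month: int, cutoff_date: dt.date = DEFAULT_CUTOFF,
                    allow_pre_study: bool = False) -> str:
    """Year-bin label for a survey date.

    2009 surveys and 2010 surveys before the cutoff are pooled into the
    pre-disturbance bin; anything later is labelled by calendar year.
    """
    if year < 2009 and not allow_pre_study:
        raise ValueError(f"survey year {year} predates the study frame (2009-)")
    if year < cutoff_date.year:
        return PRE_BIN
    if year == cutoff_date.year and month < cutoff_date.month:
        return PRE_BIN
    return str(year)


def build_matrix(records: list[SurveyRecord], registry: pd.DataFrame,
                 field_width_m: float = DEFAULT_FIELD_WIDTH_M,
                 cutoff_date: dt.date = DEFAULT_CUTOFF) -> CommunityMatrix:
    """Assemble survey records into a ``CommunityMatrix`` of densities."""
    rows, meta_rows, ids = [], [], []
    for rec in records:
        dens, area = to_density(rec, registry, field_width_m)
        rows.append(dens)
        meta_rows.append({
            "site": rec.site, "year": rec.year, "month": rec.month,
            "year_bin": assign_year_bin(rec.year, rec.month, cutoff_date),
            "depth_m": rec.depth_m, "longitude": rec.longitude,
            "area_m2": area,
        })
        ids.append(rec.sample_id)
    densities = pd.DataFrame(rows, index=ids).fillna(0.0)
    densities = densities.reindex(sorted(densities.columns), axis=1)
    meta = pd.DataFrame(meta_rows, index=ids)
    return CommunityMatrix(densities=densities, meta=meta, registry=registry)


# ---------------------------------------------------------------------------
# guild aggregation & covariates
# ---------------------------------------------------------------------------

def aggregate_guilds(matrix: CommunityMatrix,
                     exclusions: list[str] | None = None) -> CommunityMatrix:
    """Sum densities into trophic guilds, minus excluded taxa.

    ``exclusions`` lists taxa omitted from their guild's sum (e.g. a highly
    variable schooling species that would swamp the guild signal); excluded
    names must be present in the registry.
    """
    exclusions = list(exclusions or [])
    missing = set(exclusions) - set(matrix.registry.index)
    if missing:
        raise ValueError(f"exclusions not in registry: {sorted(missing)}")
    keep = [t for t in matrix.densities.columns if t not in exclusions]
    guild_of = matrix.registry["guild"]
    grouped = matrix.densities[keep].T.groupby(guild_of.loc[keep]).sum().T
    order = [g for g in GUILDS if g in grouped.columns]
    extra = [g for g in grouped.columns if g not in GUILDS]
    grouped = grouped[order + sorted(extra)]
    guild_registry = pd.DataFrame(
        {"guild": grouped.columns, "schooling": False}, index=grouped.columns
    )
    return CommunityMatrix(
        densities=grouped, meta=matrix.meta.copy(),
        registry=guild_registry, density_unit=matrix.density_unit,
    )


def zscored_covariates(meta: pd.DataFrame) -> pd.DataFrame:
    """z-scored depth and longitude covariates over all samples."""
    out = pd.DataFrame(index=meta.index)
    for col, z in (("depth_m", "depth_z"), ("longitude", "lon_z")):
        x = meta[col].astype(float)
        sd = x.std(ddof=1)
        out[z] = 0.0 if sd == 0 else (x - x.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# writing (round-trips the dialect read above)
# ---------------------------------------------------------------------------

def write_survey_csvs(records: list[SurveyRecord], registry: pd.DataFrame,
                      counts_path, metadata_path, registry_path) -> None:
    """Write survey records back to the counts/metadata/registry CSV dialect."""
    crows, mrows = [], []
    for rec in records:
        mrows.append({
            "site": rec.site, "date": rec.date.isoformat(),
            "depth_m": rec.depth_m, "longitude": rec.longitude,
            "n_transects": len(rec.transects),
        })
        for k, t in enumerate(rec.transects, start=1):
            for taxon, c in sorted(t.items()):
                crows.append({"site": rec.site, "date": rec.date.isoformat(),
                              "transect": str(k), "taxon": taxon, "count": int(c)})
        for taxon, c in sorted(rec.school_min.items()):
            crows.append({"site": rec.site, "date": rec.date.isoformat(),
                          "transect": "school", "taxon": taxon, "count": int(c)})
    pd.DataFrame(crows, columns=["site", "date", "transect", "taxon", "count"]).to_csv(
        counts_path, index=False)
    pd.DataFrame(mrows).to_csv(metadata_path, index=False)
    reg = registry.rename_axis("taxon").reset_index()
    reg["schooling"] = reg["schooling"].astype(int)
    reg.to_csv(registry_path, index=False)


def write_matrix_csv(matrix: CommunityMatrix, densities_path, meta_path) -> None:
    matrix.densities.to_csv(densities_path, index_label="sample_id")
    matrix.meta.to_csv(meta_path, index_label="sample_id")
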
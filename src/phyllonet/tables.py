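"""Count-table and environmental-table containers, I/O, filters, transforms.

The two core containers are :class:`CountTable` (OTU x sample integer counts
with taxonomy and sample metadata) and :class:`EnvTable` (site x month table
of environmental factors).  All filters are pure functions: they return new
objects and never mutate their input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "EnvTable",
    "TERRACLIMATE_FACTORS",
    "read_count_table",
    "filter_low_depth_samples",
    "filter_rare_otus",
    "to_relative_abundance",
    "log10p_transform",
    "aggregate_to_genus",
    "network_prevalence_filter",
    "split_strata",
    "zscore_env",
]

#: The 14 monthly TerraClimate variables used as environmental factors.
TERRACLIMATE_FACTORS = (
    "aet",   # actual evapotranspiration
    "def",   # climatic water deficit
    "pdsi",  # Palmer drought severity index
    "pet",   # potential evapotranspiration
    "ppt",   # precipitation
    "q",     # runoff
    "soil",  # soil moisture
    "srad",  # downward shortwave radiation
    "swe",   # snow water equivalent
    "tmax",  # maximum temperature
    "tmin",  # minimum temperature
    "vap",   # vapour pressure
    "vpd",   # vapour pressure deficit
    "ws",    # wind speed
)

METADATA_COLUMNS = ("compartment", "site", "season", "year", "timepoint")

_TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class TableError(ValueError):
    """Raised on malformed tables or filters that empty a table."""


@dataclass(frozen=True)
class CountTable:
    """An OTU x sample table of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with OTU ids as index and sample ids as columns; integer
        dtype, all values >= 0.
    metadata
        DataFrame indexed by sample id covering every sample column.  The
        canonical columns are compartment, site, season, year, timepoint.
    taxonomy
        Optional per-OTU semicolon-separated lineage strings
        ("Kingdom;Phylum;...;Genus"), possibly truncated.
    kingdom
        Optional per-OTU marker-group label (bacteria | fungi | nfeuk).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.Series | None = None
    kingdom: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate OTU ids: {dupes}")
        if c.columns.has_duplicates:
            dupes = c.columns[c.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dupes}")
        values = c.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                bad = np.argwhere(np.mod(values, 1) != 0)[0]
                raise TableError(
                    f"non-integer count at OTU {c.index[bad[0]]!r}, "
                    f"sample {c.columns[bad[1]]!r}"
                )
            object.__setattr__(self, "counts", c.astype(np.int64))
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise TableError("negative counts are not allowed")
        missing = set(c.columns) - set(self.metadata.index)
        if missing:
            raise TableError(f"samples missing from metadata: {sorted(missing)}")
        # metadata restricted to table samples, in column order
        object.__setattr__(self, "metadata", self.metadata.loc[c.columns])
        if self.taxonomy is not None:
            object.__setattr__(
                self, "taxonomy", self.taxonomy.reindex(c.index)
            )
        if self.kingdom is not None:
            object.__setattr__(self, "kingdom", self.kingdom.reindex(c.index))

    # ------------------------------------------------------------------
    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def _subset(self, otus=None, samples=None) -> "CountTable":
        counts = self.counts
        if otus is not None:
            counts = counts.loc[otus]
        if samples is not None:
            counts = counts[samples]
        tax = self.taxonomy.loc[counts.index] if self.taxonomy is not None else None
        kng = self.kingdom.loc[counts.index] if self.kingdom is not None else None
        return CountTable(counts, self.metadata.loc[counts.columns], tax, kng)

    # ------------------------------------------------------------------ I/O
    def write_tsv(self, path, metadata_path=None) -> None:
        out = self.counts.copy()
        out.index.name = "otu_id"
        if self.kingdom is not None:
            out["kingdom"] = self.kingdom
        if self.taxonomy is not None:
            out["taxonomy"] = self.taxonomy
        out.to_csv(path, sep="\t")
        if metadata_path is not None:
            md = self.metadata.copy()
            md.index.name = "sample"
            md.to_csv(metadata_path, sep="\t")

    def merge(self, *others: "CountTable") -> "CountTable":
        """Stack OTU tables sharing the same samples (kingdom merge)."""
        tables = (self, *others)
        common = self.sample_ids
        for t in tables[1:]:
            common = common.intersection(t.sample_ids)
        if len(common) == 0:
            raise TableError("no shared samples across tables to merge")
        counts = pd.concat([t.counts[common] for t in tables])
        tax = pd.concat(
            [
                t.taxonomy
                if t.taxonomy is not None
                else pd.Series(pd.NA, index=t.otu_ids)
                for t in tables
            ]
        )
        kng = pd.concat(
            [
                t.kingdom
                if t.kingdom is not None
                else pd.Series(pd.NA, index=t.otu_ids)
                for t in tables
            ]
        )
        return CountTable(counts, self.metadata.loc[common], tax, kng)


def read_count_table(path, dialect: str = "tsv", metadata=None) -> CountTable:
    """Read an OTU table from ``tsv`` or mothur ``mothur_shared`` format.

    The plain TSV dialect is OTU x sample with an ``otu_id`` first column and
    optional trailing ``kingdom`` / ``taxonomy`` columns.  The mothur
    ``.shared`` dialect is samples x OTUs with the header
    ``label Group numOtus Otu001 ...`` and is transposed on read.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        tax = kng = None
        if "taxonomy" in df.columns:
            tax = df.pop("taxonomy").astype("string")
        if "kingdom" in df.columns:
            kng = df.pop("kingdom").astype("string")
        counts = _coerce_int(df)
    elif dialect == "mothur_shared":
        df = pd.read_csv(path, sep="\t")
        required = {"label", "Group", "numOtus"}
        if not required.issubset(df.columns):
            raise TableError(
                f"not a mothur .shared file: missing columns {sorted(required - set(df.columns))}"
            )
        if df["Group"].duplicated().any():
            raise TableError(
                f"duplicate sample id in .shared: {df['Group'][df['Group'].duplicated()].tolist()}"
            )
        df = df.set_index("Group").drop(columns=["label", "numOtus"])
        counts = _coerce_int(df.T)
        tax = kng = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if metadata is None:
        metadata = pd.DataFrame(index=counts.columns)
    elif not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t", index_col=0)
    return CountTable(counts, metadata, tax, kng)


def _coerce_int(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        frac = np.mod(arr.astype(float), 1)
        if np.any(frac != 0):
            i, j = np.argwhere(frac != 0)[0]
            raise TableError(
                f"non-integer count at row {df.index[i]!r}, column {df.columns[j]!r}"
            )
        df = df.astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# Filters (pure; output rows/columns are subsets of the input's)
# ---------------------------------------------------------------------------


def filter_low_depth_samples(table: CountTable, min_reads: int = 50) -> CountTable:
    """Drop samples whose total read count is strictly below ``min_reads``."""
    depths = table.counts.sum(axis=0)
    keep = depths.index[depths >= min_reads]
    if len(keep) == 0:
        raise TableError(
            f"all {table.n_samples} samples have fewer than {min_reads} reads"
        )
    return table._subset(samples=keep)


def filter_rare_otus(table: CountTable, min_total_reads: int = 50) -> CountTable:
    """Keep OTUs with total reads strictly greater than ``min_total_reads``."""
    totals = table.counts.sum(axis=1)
    keep = totals.index[totals > min_total_reads]
    return table._subset(otus=keep)


def to_relative_abundance(counts: pd.DataFrame | CountTable) -> pd.DataFrame:
    """Column-normalise counts to fractions summing to 1 per sample."""
    df = counts.counts if isinstance(counts, CountTable) else counts
    sums = df.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise TableError(f"samples with zero total reads: {list(zero)}")
    return df / sums


def log10p_transform(table: pd.DataFrame) -> pd.DataFrame:
    """x -> log10(x + 1), applied elementwise (monotone, 0 -> 0)."""
    return np.log10(table + 1.0)


def parse_genus(lineage: str | None) -> str:
    """Genus label from a ranked lineage string, pooling unresolved OTUs.

    OTUs without a resolved genus are pooled under
    ``unclassified_<highest resolved rank label>`` so table totals are
    conserved by aggregation.
    """
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)) or pd.isna(lineage):
        return "unclassified_unknown"
    parts = [p.strip().strip('"') for p in str(lineage).split(";")]
    # strip bootstrap-style confidence suffixes e.g. Genus(100)
    parts = [p.split("(")[0] for p in parts if p and not p.lower().startswith("unclassified")]
    if len(parts) >= len(_TAXONOMY_RANKS):
        return parts[len(_TAXONOMY_RANKS) - 1]
    if parts:
        return f"unclassified_{parts[-1]}"
    return "unclassified_unknown"


def aggregate_to_genus(table: CountTable) -> pd.DataFrame:
    """Sum OTU counts over shared genus labels (genus x sample table)."""
    if table.taxonomy is None:
        raise TableError("count table has no taxonomy; cannot aggregate to genus")
    genera = table.taxonomy.map(parse_genus)
    return table.counts.groupby(genera.to_numpy()).sum()


def split_strata(table: CountTable, keys=("timepoint", "compartment")):
    """Yield ``(stratum, sub-table)`` per (timepoint, compartment) group."""
    md = table.metadata
    for key in keys:
        if key not in md.columns:
            raise TableError(f"metadata lacks column {key!r}")
    for stratum, samples in md.groupby(list(keys), sort=True).groups.items():
        yield stratum, table._subset(samples=pd.Index(samples))


def network_prevalence_filter(
    table: CountTable, min_samples: int = 5, min_reads: int = 10
) -> CountTable:
    """Keep OTUs observed with >= ``min_reads`` reads in >= ``min_samples`` samples.

    Applied within one (time point, compartment) stratum; use
    :func:`split_strata` to obtain strata.  An empty result is returned as an
    empty table, not an error.
    """
    hits = (table.counts >= min_reads).sum(axis=1)
    keep = hits.index[hits >= min_samples]
    return table._subset(otus=keep)


# ---------------------------------------------------------------------------
# Environmental table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnvTable:
    """Site x month table of environmental factors.

    ``values`` is indexed by (site, year, month) with one real-valued column
    per factor; ``z_transformed`` records whether columns have been scaled to
    mean 0, sd 1.
    """

    values: pd.DataFrame
    z_transformed: bool = False

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise TableError(f"missing environmental values in factors {bad}")

    @property
    def factors(self) -> pd.Index:
        return self.values.columns

    def zscore(self) -> "EnvTable":
        return zscore_env(self)

    def align_to_samples(self, metadata: pd.DataFrame, month_map=None) -> pd.DataFrame:
        """Per-sample factor rows matched by the sample's (site, year, month).

        ``month_map`` maps season label -> collection month; defaults to
        spring -> 3, fall -> 11.
        """
        month_map = month_map or {"spring": 3, "fall": 11}
        keys = [
            (row["site"], int(row["year"]), month_map[row["season"]])
            for _, row in metadata.iterrows()
        ]
        out = self.values.loc[keys]
        out.index = metadata.index
        return out

    def per_timepoint_mean(self, timepoint_key: pd.DataFrame) -> pd.DataFrame:
        """Cross-site mean factor values per time point.

        ``timepoint_key`` has columns timepoint, year, month (one row per
        time point).
        """
        rows = []
        for _, row in timepoint_key.iterrows():
            sub = self.values.xs(
                (int(row["year"]), int(row["month"])), level=(1, 2)
            )
            rows.append(sub.mean(axis=0))
        out = pd.DataFrame(rows, index=timepoint_key["timepoint"].to_numpy())
        out.index.name = "timepoint"
        return out

    def write_tsv(self, path) -> None:
        self.values.rename_axis(["site", "year", "month"]).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, z_transformed: bool = False) -> "EnvTable":
        df = pd.read_csv(path, sep="\t", index_col=[0, 1, 2])
        return cls(df, z_transformed=z_transformed)


def zscore_env(env: EnvTable) -> EnvTable:
    """Scale every factor column to mean 0, sd 1 (sample sd, n-1)."""
    sd = env.values.std(axis=0, ddof=1)
    flat = sd.index[(sd == 0) | sd.isna()]
    if len(flat):
        raise TableError(f"constant factor columns cannot be z-scored: {list(flat)}")
    values = (env.values - env.values.mean(axis=0)) / sd
    return EnvTable(values, z_transformed=True)
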
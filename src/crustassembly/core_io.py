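"""Shared data model, file I/O and sample grouping.

The pipeline operates on five tabular/tree inputs that mirror a processed
amplicon study: an OTU abundance table (samples x taxa), a taxonomy table
(taxon -> domain/phylum lineage), a rooted phylogeny with branch lengths,
per-sample metadata (site, coordinates, successional stage, MAP) and a
per-sample environment table.  All readers accept plain TSV; trees are
newick (read through dendropy).

Samples are grouped along four study angles -- successional stage (A/C/M),
longitude, latitude and mean annual precipitation (MAP) -- each split into
three bins ordered from the most severe to the mildest environment.  A value
falling exactly on a shared bin boundary is assigned to the more severe
(earlier-listed) group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "TaxonomyTable",
    "PhyloTree",
    "SampleMetadata",
    "EnvTable",
    "GroupAssignment",
    "FormatError",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "read_metadata",
    "read_env_table",
    "read_tree",
    "to_relative",
    "cumulative_abundance_filter",
    "assign_groups",
    "haversine_km",
    "geographic_distance_matrix",
    "validate_dataset",
    "ANGLES",
]

EARTH_RADIUS_KM = 6371.0

#: Study angles and their three-level bins, ordered severe -> mild.  A value
#: on a shared boundary belongs to the earlier (more severe) group.
ANGLES = ("succession", "longitude", "latitude", "MAP")

_LONGITUDE_BINS = [("W", 87.0, 98.0), ("M", 98.0, 109.0), ("E", 109.0, 120.0)]
_LATITUDE_BINS = [("N", 42.0, 45.5), ("M", 38.5, 42.0), ("S", 35.0, 38.5)]
_MAP_BINS = [("L", 0.0, 150.0), ("M", 150.0, 300.0), ("H", 300.0, 450.0)]

STAGE_LEVELS = ("A", "C", "M")


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OtuTable:
    """Samples x taxa abundance matrix.

    ``data`` is a DataFrame with sample ids as index and taxon ids as
    columns; ``is_relative`` distinguishes counts from row-normalised
    relative abundances.
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise FormatError("duplicate taxon ids")
        values = df.to_numpy(dtype=float)
        if values.size == 0:
            raise FormatError("empty OTU table")
        if not np.isfinite(values).all():
            raise ValueError("non-finite abundance value")
        if (values < 0).any():
            raise ValueError("negative abundance value")
        row_sums = values.sum(axis=1)
        if (row_sums == 0).any():
            bad = list(df.index[row_sums == 0])
            raise ValueError(f"all-zero samples: {bad}")
        if self.is_relative and not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("relative table rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids) -> "OtuTable":
        sub = self.data.loc[list(sample_ids)]
        keep = sub.sum(axis=0) > 0
        return OtuTable(sub.loc[:, keep], is_relative=self.is_relative)

    def select_taxa(self, taxon_ids) -> "OtuTable":
        # a taxon subset of a relative table no longer sums to 1, so the
        # result is always flagged as counts/raw
        return OtuTable(self.data.loc[:, list(taxon_ids)], is_relative=False)


@dataclass(frozen=True)
class TaxonomyTable:
    """taxon_id -> lineage with at least a domain and phylum rank."""

    data: pd.DataFrame  # index taxon_id, columns include domain, phylum

    def __post_init__(self) -> None:
        for col in ("domain", "phylum"):
            if col not in self.data.columns:
                raise FormatError(f"taxonomy table missing column '{col}'")
        bad = ~self.data["domain"].isin(["Bacteria", "Eukaryota"])
        if bad.any():
            raise ValueError(
                f"unknown domains: {sorted(self.data['domain'][bad].unique())}"
            )

    def domain_of(self, taxon_id: str) -> str:
        return str(self.data.at[taxon_id, "domain"])

    def phylum_of(self, taxon_id: str) -> str:
        return str(self.data.at[taxon_id, "phylum"])

    def taxa_of_domain(self, domain: str) -> list[str]:
        return list(self.data.index[self.data["domain"] == domain])


@dataclass
class PhyloTree:
    """Rooted tree whose leaves are taxon ids; source of patristic distances."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True)

    def patristic_matrix(self, taxon_ids: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Dense patristic (branch-length path) distance matrix.

        Returns ``(D, labels)`` where ``D[i, j]`` is the patristic distance
        between ``labels[i]`` and ``labels[j]``.  When ``taxon_ids`` is given
        the matrix is restricted to (and ordered as) those taxa; missing taxa
        raise ``KeyError`` listing them.
        """
        pdm = self.tree.phylogenetic_distance_matrix()
        by_label = {t.label: t for t in self.tree.taxon_namespace}
        if taxon_ids is None:
            labels = self.leaf_labels
        else:
            labels = list(taxon_ids)
            missing = [t for t in labels if t not in by_label]
            if missing:
                raise KeyError(f"taxa missing from tree: {missing}")
        n = len(labels)
        D = np.zeros((n, n))
        taxa = [by_label[t] for t in labels]
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[i], taxa[j])
                D[i, j] = D[j, i] = d
        return D, labels


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample site, coordinates, succession stage, MAP and replicate."""

    data: pd.DataFrame  # index sample_id; columns site_id, lat, lon, stage, map_mm, replicate

    REQUIRED = ("site_id", "lat", "lon", "stage", "map_mm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        bad = ~self.data["stage"].isin(STAGE_LEVELS)
        if bad.any():
            raise ValueError(
                f"stage must be one of {STAGE_LEVELS}; offending samples: "
                f"{list(self.data.index[bad])}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def site_coordinates(self) -> pd.DataFrame:
        """One row per site with its (lat, lon); coordinates must agree within site."""
        return self.data.groupby("site_id")[["lat", "lon"]].first()


@dataclass(frozen=True)
class EnvTable:
    """Per-sample numeric environmental variables (NaN = explicitly missing)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        non_numeric = [
            c for c in self.data.columns
            if not pd.api.types.is_numeric_dtype(self.data[c])
        ]
        if non_numeric:
            raise FormatError(f"non-numeric environment columns: {non_numeric}")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class GroupAssignment:
    """Mapping sample_id -> one of three group levels for a study angle."""

    angle: str
    labels: pd.Series  # index sample_id, values group labels
    levels: tuple[str, ...]

    def level_samples(self, level: str) -> list[str]:
        return list(self.labels.index[self.labels == level])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_otu_table(path, taxa_as_rows: bool = True) -> OtuTable:
    """Read a TSV abundance table.

    By convention taxa are rows and samples are columns (``taxa_as_rows``);
    set the flag to ``False`` for a transposed file.  Integer-valued input is
    flagged as counts, fractional rows summing to one as relative.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = header[1:]
    if len(cols) != len(set(cols)):
        raise FormatError(f"duplicate ids in header of {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty OTU table file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"empty OTU table file: {path}")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"duplicate ids in {path}")
    if taxa_as_rows:
        df = df.T
    values = df.to_numpy(dtype=float)
    is_relative = bool(
        np.allclose(values.sum(axis=1), 1.0, atol=1e-9)
        and not np.allclose(values, np.round(values))
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OtuTable(df, is_relative=is_relative)


def write_otu_table(t: OtuTable, path, taxa_as_rows: bool = True) -> None:
    df = t.data.T if taxa_as_rows else t.data
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyTable(df)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def read_env_table(path) -> EnvTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return EnvTable(df)


def read_tree(path) -> PhyloTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Table operations
# ---------------------------------------------------------------------------


def to_relative(t: OtuTable) -> OtuTable:
    """Row-normalise a counts table to relative abundances (idempotent)."""
    if t.is_relative:
        return t
    values = t.counts
    row_sums = values.sum(axis=1)
    # OtuTable forbids all-zero rows, but guard for tables built elsewhere
    if (row_sums == 0).any():
        bad = [s for s, z in zip(t.sample_ids, row_sums == 0) if z]
        raise ValueError(f"cannot normalise all-zero samples: {bad}")
    rel = pd.DataFrame(
        values / row_sums[:, None], index=t.data.index, columns=t.data.columns
    )
    return OtuTable(rel, is_relative=True)


def cumulative_abundance_filter(t: OtuTable, coverage: float = 0.99) -> OtuTable:
    """Keep the most abundant taxa up to a pooled cumulative-abundance target.

    Taxa are ranked by their total relative abundance pooled across all
    samples; the shortest prefix whose cumulative share reaches ``coverage``
    is retained.  Taxa tied in pooled abundance with the last retained taxon
    are also retained, so the result does not depend on tie order.
    """
    if not 0 < coverage <= 1:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    rel = to_relative(t)
    pooled = rel.counts.sum(axis=0)
    pooled = pooled / pooled.sum()
    order = np.argsort(-pooled, kind="stable")
    cum = np.cumsum(pooled[order])
    n_keep = int(np.searchsorted(cum, coverage - 1e-12) + 1)
    n_keep = min(n_keep, len(order))
    cutoff_abundance = pooled[order[n_keep - 1]]
    keep_mask = pooled >= cutoff_abundance - 1e-15
    keep_cols = [t.data.columns[i] for i in range(t.n_taxa) if keep_mask[i]]
    out = t.data.loc[:, keep_cols]
    emptied = out.sum(axis=1) == 0
    if emptied.any():
        raise ValueError(
            f"coverage {coverage} would leave samples with no taxa: "
            f"{list(out.index[emptied])}; raise the coverage"
        )
    return OtuTable(out, is_relative=False) if not t.is_relative else OtuTable(
        out.div(out.sum(axis=1), axis=0), is_relative=True
    )


def _bin_lookup(value: float, bins, severe_first: bool, what: str, sample: str) -> str:
    """Assign a value to one of three touching intervals.

    Each angle's bins are listed severe-first.  A value equal to a boundary
    shared by two bins goes to the more severe one.
    """
    lo = min(b[1] for b in bins)
    hi = max(b[2] for b in bins)
    if not (lo <= value <= hi):
        raise ValueError(
            f"{what}={value} for sample {sample} outside [{lo}, {hi}]"
        )
    for label, a, b in bins:
        if a <= value <= b:
            return label
    raise AssertionError("unreachable: bins cover the range")


def assign_groups(m: SampleMetadata, angle: str) -> GroupAssignment:
    """Bin samples along a study angle into its three printed groups.

    Angles: ``succession`` (stage A/C/M), ``longitude`` (W 87-98, M 98-109,
    E 109-120 degrees E), ``latitude`` (N 42-45.5, M 38.5-42, S 35-38.5
    degrees N) and ``MAP`` (L 0-150, M 150-300, H 300-450 mm).  Boundary
    values go to the more severe group (e.g. longitude 98 -> W, latitude
    42 -> N, MAP 150 -> L).
    """
    if angle not in ANGLES:
        raise ValueError(f"unknown angle {angle!r}; expected one of {ANGLES}")
    df = m.data
    if angle == "succession":
        labels = df["stage"].astype(str)
        levels = STAGE_LEVELS
    else:
        col, bins = {
            "longitude": ("lon", _LONGITUDE_BINS),
            "latitude": ("lat", _LATITUDE_BINS),
            "MAP": ("map_mm", _MAP_BINS),
        }[angle]
        if df[col].isna().any():
            bad = list(df.index[df[col].isna()])
            raise ValueError(f"missing {col} for samples {bad} (angle={angle})")
        # bins are searched severe-first so a shared boundary value matches
        # the severe bin before the milder one
        labels = pd.Series(
            [_bin_lookup(v, bins, True, col, s) for s, v in df[col].items()],
            index=df.index,
        )
        levels = tuple(b[0] for b in bins)
    return GroupAssignment(angle=angle, labels=labels, levels=tuple(levels))


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (haversine, Earth radius 6371 km)."""
    for v in (lat1, lon1, lat2, lon2):
        if not math.isfinite(v):
            raise ValueError("non-finite coordinate")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def geographic_distance_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    """Pairwise haversine km distances from a (lat, lon) table."""
    ids = list(coords.index)
    n = len(ids)
    out = np.zeros((n, n))
    lat = coords["lat"].to_numpy(float)
    lon = coords["lon"].to_numpy(float)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return pd.DataFrame(out, index=ids, columns=ids)


def validate_dataset(directory) -> dict:
    """Cross-file id consistency check for a dataset directory.

    Expects ``otu.tsv``, ``taxonomy.tsv``, ``tree.nwk``, ``metadata.tsv``
    and ``env.tsv``.  Returns a report dict; raises ``FormatError`` on a
    fatal inconsistency.
    """
    directory = Path(directory)
    otu = read_otu_table(directory / "otu.tsv")
    tax = read_taxonomy(directory / "taxonomy.tsv")
    tree = read_tree(directory / "tree.nwk")
    meta = read_metadata(directory / "metadata.tsv")
    env = read_env_table(directory / "env.tsv")

    problems = []
    missing_tax = set(otu.taxon_ids) - set(tax.data.index)
    if missing_tax:
        problems.append(f"taxa without taxonomy: {sorted(missing_tax)[:5]}...")
    missing_leaf = set(otu.taxon_ids) - set(tree.leaf_labels)
    if missing_leaf:
        problems.append(f"taxa missing from tree: {sorted(missing_leaf)[:5]}...")
    if set(otu.sample_ids) != set(meta.sample_ids):
        problems.append("sample ids differ between OTU table and metadata")
    if set(otu.sample_ids) != set(env.data.index):
        problems.append("sample ids differ between OTU table and environment table")
    if problems:
        raise FormatError("; ".join(problems))
    return {
        "n_samples": otu.n_samples,
        "n_taxa": otu.n_taxa,
        "n_sites": meta.data["site_id"].nunique(),
        "stages": sorted(meta.data["stage"].unique()),
        "env_variables": env.variables,
    }
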
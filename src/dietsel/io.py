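"""Domain containers and TSV readers/writers.

The pipeline consumes four tab-separated tables: an OTU count table
(samples x OTUs), a taxonomy map (OTU -> ranked lineage), per-sample
metadata (site, season, compartment) with environmental variables for
water samples, and — internally — relative-abundance tables derived from
counts.

Counts stay integral end to end; proportions appear only in
:class:`RelAbundanceTable`, which keeps subsampling combinatorics exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "SEASONS",
    "ENV_VARS",
    "OtuTable",
    "TaxonomyMap",
    "SampleFrame",
    "RelAbundanceTable",
    "read_otu_table",
    "read_taxonomy",
    "read_sample_frame",
]

#: Taxonomic ranks tracked per OTU, coarsest first.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Sentinel for a rank with no assignment.
UNASSIGNED = "UNASSIGNED"

#: Sampling seasons (quarterly campaign).
SEASONS = ("Dec", "Mar", "Jun", "Sep")

#: Environmental variables measured on water samples.
ENV_VARS = (
    "Temp",
    "DO",
    "pH",
    "Salinity",
    "Dep",
    "SD",
    "Chl_a",
    "COD_Mn",
    "TP",
    "NH4_N",
    "TN",
)

_QIIME_PREFIX = re.compile(r"^[a-zA-Z]__")


class TableFormatError(ValueError):
    """Raised when an input table violates the expected format."""


def _check_unique(labels: Iterable[str], kind: str) -> None:
    labels = list(labels)
    seen: set[str] = set()
    dupes = {x for x in labels if x in seen or seen.add(x)}
    if dupes:
        raise TableFormatError(f"duplicate {kind} ids: {sorted(dupes)!r}")


@dataclass(frozen=True)
class OtuTable:
    """Integer read counts, samples as rows and OTUs as columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1:
            raise TableFormatError("no samples")
        if df.shape[1] < 1:
            raise TableFormatError("no OTUs")
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "OTU")
        if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
            raise TableFormatError("counts must be integers")
        if (df.to_numpy() < 0).any():
            raise TableFormatError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def row_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def subset_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        return OtuTable(self.data.loc[list(sample_ids)])

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, transpose: bool = False) -> "OtuTable":
        return read_otu_table(path, transpose=transpose)


def read_otu_table(path: str | Path, transpose: bool = False) -> OtuTable:
    """Read a TSV count table; first column sample ids, header OTU ids.

    ``transpose=True`` accepts the OTU-as-rows dialect.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: no samples") from None
    if raw.shape[0] == 0:
        raise TableFormatError(f"{path}: no samples")
    if transpose:
        raw = raw.T
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise TableFormatError(
                f"{path}: malformed numeric cell at row {row!r}, column {col!r}: "
                f"{raw.at[row, col]!r}"
            )
        if converted.isna().any():
            row = converted.isna().idxmax()
            raise TableFormatError(f"{path}: missing value at row {row!r}, column {col!r}")
        numeric[col] = converted
    vals = numeric.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        i, j = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise TableFormatError(
            f"{path}: non-integer count at row {numeric.index[i]!r}, "
            f"column {numeric.columns[j]!r}"
        )
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise TableFormatError(
            f"{path}: negative count at row {numeric.index[i]!r}, "
            f"column {numeric.columns[j]!r}"
        )
    return OtuTable(numeric.astype(np.int64))


@dataclass(frozen=True)
class TaxonomyMap:
    """OTU id -> six-rank lineage (kingdom..genus), UNASSIGNED-padded.

    Lineages are canonicalised so that no named rank sits below an
    UNASSIGNED one: aggregation never resurrects information under a gap.
    """

    lineages: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for otu, lin in self.lineages.items():
            if len(lin) != len(RANKS):
                raise TableFormatError(f"{otu}: lineage must have {len(RANKS)} ranks")

    @staticmethod
    def canonicalise(lineage: Iterable[str]) -> tuple[str, ...]:
        out: list[str] = []
        broken = False
        for name in lineage:
            name = name.strip()
            name = _QIIME_PREFIX.sub("", name)
            if not name or name.lower() in {"unassigned", "unclassified", "na"}:
                name = UNASSIGNED
            if name == UNASSIGNED:
                broken = True
            out.append(UNASSIGNED if broken else name)
        out += [UNASSIGNED] * (len(RANKS) - len(out))
        return tuple(out[: len(RANKS)])

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        return tuple(self.lineages[otu_id])

    def name_at(self, otu_id: str, rank: str) -> str:
        return self.lineages[otu_id][RANKS.index(rank)]

    def label_at(self, otu_id: str, rank: str) -> str:
        """Aggregation label at ``rank``: the name there, or an
        ``unclassified <deepest assigned ancestor>`` bucket."""
        idx = RANKS.index(rank)
        lin = self.lineages[otu_id]
        if lin[idx] != UNASSIGNED:
            return lin[idx]
        for i in range(idx - 1, -1, -1):
            if lin[i] != UNASSIGNED:
                return f"unclassified {lin[i]}"
        return "unclassified"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("otu_id\tlineage\n")
            for otu, lin in self.lineages.items():
                fh.write(f"{otu}\t{';'.join(lin)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        return read_taxonomy(path)


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a TSV of ``otu_id<TAB>semicolon-delimited lineage``.

    QIIME-style ``k__`` prefixes are stripped; lineages are padded to the
    six tracked ranks with UNASSIGNED. An OTU listed twice with
    conflicting lineages is an error.
    """
    path = Path(path)
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise TableFormatError(f"{path}: empty taxonomy file")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TableFormatError(f"{path}:{lineno}: expected otu_id<TAB>lineage")
            otu, lin_str = parts[0].strip(), parts[1]
            lin = TaxonomyMap.canonicalise(lin_str.split(";"))
            if otu in lineages and lineages[otu] != lin:
                raise TableFormatError(f"{path}:{lineno}: conflicting lineages for {otu!r}")
            lineages[otu] = lin
    if not lineages:
        raise TableFormatError(f"{path}: no taxonomy records")
    return TaxonomyMap(lineages)


@dataclass(frozen=True)
class SampleFrame:
    """Per-sample metadata: site, season, compartment, env variables.

    Environmental variables are measured on water only; gut samples may
    leave them blank. Water rows must be complete in every env column
    that is present (constrained ordination needs complete rows).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        for col in ("site", "season", "compartment"):
            if col not in df.columns:
                raise TableFormatError(f"metadata missing column {col!r}")
        bad_comp = set(df["compartment"]) - {"gut", "water"}
        if bad_comp:
            raise TableFormatError(f"compartment must be gut|water, got {sorted(bad_comp)}")
        bad_season = set(df["season"]) - set(SEASONS)
        if bad_season:
            raise TableFormatError(f"unknown seasons {sorted(bad_season)}")
        env = [c for c in df.columns if c in ENV_VARS]
        if env:
            water = df[df["compartment"] == "water"]
            if water[env].isna().any().any():
                raise TableFormatError("water samples must have complete env values")
            vals = df.loc[df["compartment"] == "water", env].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise TableFormatError("non-finite env value on a water sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def env_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in ENV_VARS]

    def compartment(self, which: str) -> "SampleFrame":
        return SampleFrame(self.data[self.data["compartment"] == which])

    def season_of(self, sample_id: str) -> str:
        return str(self.data.at[sample_id, "season"])

    def env_matrix(self, sample_ids: Iterable[str] | None = None) -> pd.DataFrame:
        rows = self.data if sample_ids is None else self.data.loc[list(sample_ids)]
        return rows[self.env_columns].astype(float)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleFrame":
        return read_sample_frame(path)


def read_sample_frame(path: str | Path) -> SampleFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty metadata file") from None
    df.index = df.index.astype(str)
    return SampleFrame(df)


@dataclass(frozen=True)
class RelAbundanceTable:
    """Row-normalised proportions; all-zero input rows are flagged empty."""

    data: pd.DataFrame
    empty_samples: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "taxon")
        vals = df.to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 1 + 1e-9).any():
            raise TableFormatError("proportions must lie in [0, 1]")
        sums = vals.sum(axis=1)
        for i, sid in enumerate(df.index):
            if sid in self.empty_samples:
                if sums[i] != 0:
                    raise TableFormatError(f"empty-flagged sample {sid!r} has mass")
            elif abs(sums[i] - 1.0) > 1e-9:
                raise TableFormatError(f"row {sid!r} sums to {sums[i]}, not 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    def nonempty(self) -> "RelAbundanceTable":
        keep = [s for s in self.data.index if s not in self.empty_samples]
        return RelAbundanceTable(self.data.loc[keep])

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
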
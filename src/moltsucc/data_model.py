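"""Shared domain types, table I/O, and validation.

The universal substrate is the :class:`CountTable`: a samples x ASVs matrix of
non-negative integer read counts with aligned per-sample metadata
(:class:`SampleMeta`).  Relative abundances live in a distinct type
(:class:`RelAbundTable`) so that count-scale and fraction-scale quantities can
never be mixed silently.  Pathway relative abundances predicted upstream
(e.g. by PICRUSt2) are consumed as a :class:`FunctionTable`; this package
never computes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("moltsucc")

#: Gut habitats (sinks and derived groups).
GUT_HABITATS = ("foregut", "midgut", "hindgut", "whole_gut", "mixed_gut")
#: Candidate source habitats for source tracking.
SOURCE_HABITATS = ("carapace", "water", "gill", "hepatopancreas")
HABITATS = GUT_HABITATS + SOURCE_HABITATS

#: Taxonomic ranks, kingdom to species.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class ValidationError(ValueError):
    """An input table or metadata record violates its contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(str(i))
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass(frozen=True)
class CountTable:
    """Samples x ASVs matrix of non-negative integer read counts.

    Rows are samples, columns are ASVs.  Validation rejects duplicate ids,
    negative or non-integer counts (naming the offending cell), and samples
    with zero total reads.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index), "sample ids")
        _check_unique(list(df.columns), "ASV ids")
        values = df.to_numpy()
        if values.size == 0:
            raise ValidationError("empty count table")
        if not np.issubdtype(values.dtype, np.integer):
            fractional = values != np.floor(values)
            if np.any(fractional) or np.any(~np.isfinite(values.astype(float))):
                r, c = np.argwhere(fractional | ~np.isfinite(values.astype(float)))[0]
                raise ValidationError(
                    f"non-integer count at sample {df.index[r]!r}, ASV "
                    f"{df.columns[c]!r}: {values[r, c]!r}"
                )
            df = df.astype(np.int64)
            values = df.to_numpy()
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[r]!r}, ASV "
                f"{df.columns[c]!r}: {values[r, c]}"
            )
        totals = values.sum(axis=1)
        if np.any(totals == 0):
            bad = [str(s) for s in df.index[totals == 0]]
            raise ValidationError(f"samples with zero total counts: {bad}")
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def asv_ids(self) -> list[str]:
        return [str(a) for a in self.data.columns]

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        """Row subset preserving the requested order."""
        return CountTable(self.data.loc[list(sample_ids)])

    def select_asvs(self, asv_ids: Iterable[str]) -> pd.DataFrame:
        """Column subset (plain frame: the zero-row invariant may not hold)."""
        return self.data.loc[:, list(asv_ids)]


@dataclass(frozen=True)
class RelAbundTable:
    """Samples x ASVs relative abundances; every row sums to 1 (tol 1e-9)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        _check_unique(list(df.index), "sample ids")
        _check_unique(list(df.columns), "ASV ids")
        values = df.to_numpy()
        if np.any(values < 0) or np.any(values > 1 + 1e-12):
            raise ValidationError("relative abundances must lie in [0, 1]")
        sums = values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = [str(s) for s in df.index[np.abs(sums - 1.0) > 1e-9]]
            raise ValidationError(f"rows not summing to 1: {bad}")
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def asv_ids(self) -> list[str]:
        return [str(a) for a in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def select_samples(self, sample_ids: Iterable[str]) -> "RelAbundTable":
        return RelAbundTable(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class FunctionTable:
    """Samples x pathways relative abundances (rows sum to 1, tol 1e-6).

    Produced upstream (PICRUSt2 / shotgun annotation); consumed here for
    functional stability, multifunctionality, and taxon-function screens.
    Use :meth:`from_raw` to normalize arbitrary non-negative values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        _check_unique(list(df.index), "sample ids")
        _check_unique(list(df.columns), "pathway ids")
        values = df.to_numpy()
        if np.any(values < 0):
            raise ValidationError("pathway abundances must be non-negative")
        sums = values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = [str(s) for s in df.index[np.abs(sums - 1.0) > 1e-6]]
            raise ValidationError(
                f"pathway rows not summing to 1 (normalize with from_raw): {bad}"
            )
        object.__setattr__(self, "data", df)

    @classmethod
    def from_raw(cls, df: pd.DataFrame) -> "FunctionTable":
        values = df.astype(float)
        totals = values.sum(axis=1)
        if np.any(totals.to_numpy() <= 0):
            bad = [str(s) for s in values.index[totals.to_numpy() <= 0]]
            raise ValidationError(f"samples with zero total pathway abundance: {bad}")
        return cls(values.div(totals, axis=0))

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def pathway_ids(self) -> list[str]:
        return [str(p) for p in self.data.columns]

    def select_samples(self, sample_ids: Iterable[str]) -> "FunctionTable":
        return FunctionTable(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata.

    Exactly one of ``time_h`` / ``is_premolt_ck`` carries the temporal
    meaning: premolt control (CK) samples have no postmolt clock time.
    """

    sample_id: str
    habitat: str
    time_h: float | None = None
    is_premolt_ck: bool = False
    replicate: str = ""
    crab_weight: float | None = None
    crab_id: str = ""

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"unknown habitat {self.habitat!r} for sample {self.sample_id!r}; "
                f"expected one of {sorted(HABITATS)}"
            )
        if self.is_premolt_ck:
            if self.time_h is not None:
                raise ValidationError(
                    f"premolt CK sample {self.sample_id!r} must not carry a "
                    "postmolt time"
                )
        else:
            if self.time_h is None:
                raise ValidationError(
                    f"sample {self.sample_id!r} needs a postmolt time_h or the "
                    "CK flag"
                )
            if self.time_h < 0:
                raise ValidationError(
                    f"negative time_h for sample {self.sample_id!r}"
                )
        if self.crab_weight is not None and self.crab_weight <= 0:
            raise ValidationError(
                f"crab_weight must be positive for sample {self.sample_id!r}"
            )


def meta_frame(metas: Sequence[SampleMeta]) -> pd.DataFrame:
    """Metadata records as a DataFrame indexed by sample id."""
    _check_unique([m.sample_id for m in metas], "sample ids")
    rows = [
        {
            "sample_id": m.sample_id,
            "habitat": m.habitat,
            "time_h": m.time_h,
            "is_premolt_ck": m.is_premolt_ck,
            "replicate": m.replicate,
            "crab_weight": m.crab_weight,
            "crab_id": m.crab_id,
        }
        for m in metas
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def metas_from_frame(df: pd.DataFrame) -> list[SampleMeta]:
    metas = []
    for sid, row in df.iterrows():
        time_h = row.get("time_h")
        weight = row.get("crab_weight")
        metas.append(
            SampleMeta(
                sample_id=str(sid),
                habitat=str(row["habitat"]),
                time_h=None if pd.isna(time_h) else float(time_h),
                is_premolt_ck=bool(row.get("is_premolt_ck", False)),
                replicate=str(row.get("replicate", "")),
                crab_weight=None if pd.isna(weight) else float(weight),
                crab_id=str(row.get("crab_id", "")),
            )
        )
    return metas


@dataclass(frozen=True)
class TaxonomyTable:
    """ASV id -> ranked lineage (kingdom..species, unassigned ranks empty)."""

    data: pd.DataFrame  # index: asv_id; columns: RANKS

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index), "ASV ids")
        missing = [r for r in RANKS if r not in df.columns]
        if missing:
            raise ValidationError(f"taxonomy table missing rank columns: {missing}")
        object.__setattr__(self, "data", df[list(RANKS)].fillna("").astype(str))

    def lineage(self, asv_id: str) -> tuple[str, ...]:
        if asv_id not in self.data.index:
            return ("",) * len(RANKS)
        return tuple(self.data.loc[asv_id])


# ---------------------------------------------------------------------------
# TSV I/O
#
# Count-table dialects:
#   tsv            first cell "sample_id", ASV ids across the header, one row
#                  per sample.
#   dense_biom_tsv BIOM-style dense export: first cell "#OTU ID", samples
#                  across the header, one row per ASV (leading "# ..." comment
#                  lines tolerated).
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, fmt: str = "tsv") -> CountTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=None)
    elif fmt == "dense_biom_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None,
                         skiprows=_biom_comment_rows(path))
        df = df.T
    else:
        raise ValueError(f"unknown count-table format {fmt!r}")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    df.index.name = None
    df.columns.name = None
    return CountTable(df)


def _biom_comment_rows(path: Path) -> list[int]:
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if line.startswith("#") and not line.startswith("#OTU ID"):
                rows.append(i)
            else:
                break
    return rows


def write_count_table(t: CountTable, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        t.data.rename_axis("sample_id").to_csv(path, sep="\t")
    elif fmt == "dense_biom_tsv":
        t.data.T.rename_axis("#OTU ID").to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown count-table format {fmt!r}")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    return metas_from_frame(df)


def write_metadata(metas: Sequence[SampleMeta], path: str | Path) -> None:
    meta_frame(metas).to_csv(Path(path), sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(Path(path), sep="\t", index_col=0, dtype=str).fillna("")
    df.index = df.index.map(str)
    return TaxonomyTable(df)


def write_taxonomy(t: TaxonomyTable, path: str | Path) -> None:
    t.data.rename_axis("asv_id").to_csv(Path(path), sep="\t")


def read_function_table(path: str | Path, normalize: bool = True) -> FunctionTable:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return FunctionTable.from_raw(df) if normalize else FunctionTable(df)


def write_function_table(t: FunctionTable, path: str | Path) -> None:
    t.data.rename_axis("sample_id").to_csv(Path(path), sep="\t")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def to_relative(t: CountTable) -> RelAbundTable:
    """Row-normalize counts to relative abundances.

    Zero-total rows are impossible for a validated :class:`CountTable`, but
    the check is repeated defensively and names the sample.
    """
    totals = t.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = [t.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValidationError(f"cannot normalize zero-total samples: {bad}")
    rel = t.data.div(totals, axis=0)
    return RelAbundTable(rel)


def rarefy(t: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning.  Reproducible for a given seed; never creates counts for taxa
    absent from a sample (multivariate hypergeometric draw).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = t.counts.sum(axis=1)
    keep = totals >= depth
    dropped = [t.sample_ids[i] for i in np.flatnonzero(~keep)]
    if dropped:
        log.warning(
            "rarefy: dropping %d samples below depth %d: %s",
            len(dropped), depth, dropped,
        )
    if not np.any(keep):
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    rows = []
    for i in np.flatnonzero(keep):
        row = t.counts[i]
        if row.sum() == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    df = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=[t.sample_ids[i] for i in np.flatnonzero(keep)],
        columns=t.data.columns,
    )
    return CountTable(df)
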
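"""Data model, TSV I/O, validation and sample/taxon filtering.

The central object is :class:`TaxaTable`: a samples x taxa abundance matrix
(raw read counts and/or relative abundances) together with per-sample
metadata (subject, visit, race group, gestational ages, birth outcome,
optional qPCR total 16S copies and beta-defensin-2 concentration).

Filtering rules implemented here:

* read-depth filter — keep samples with strictly more than ``min_reads``
  sequences;
* study-wide frequency filter — drop taxa whose pooled study-wide
  proportion of reads falls below a floor (default 1e-5);
* prevalence gate — taxa detected in strictly more than 25% of samples,
  used to select taxa eligible for risk modelling;
* reagent-contaminant removal from a configurable name list.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "TaxaTable",
    "FilterReport",
    "DEFAULT_CONTAMINANTS",
    "VISIT_WINDOWS",
    "read_taxa_table",
    "write_taxa_table",
    "filter_min_reads",
    "filter_studywide_frequency",
    "filter_prevalence",
    "remove_contaminants",
    "absolute_abundance",
    "shannon_diversity",
]

#: Phylotypes flagged as potential reagent contaminants (observable in
#: negative extraction/PCR controls); removed from tables by default.
DEFAULT_CONTAMINANTS = (
    "Pseudomonas veroni",
    "Achromobacter xylosoxidans",
    "g Halomonas",
    "g Micrococcus",
    "g Heliorestis",
    "Arthrobacter cumminsii",
)

#: Nominal gestational-age windows (weeks) for the three study visits.
VISIT_WINDOWS = {1: (16.0, 20.0), 2: (20.0, 24.0), 3: (24.0, 28.0)}

META_COLUMNS = [
    "sample_id",
    "subject_id",
    "visit",
    "race_group",
    "ga_sample",
    "ga_delivery",
    "outcome",
    "nulliparous",
]
OPTIONAL_META_COLUMNS = ["total_16s_copies", "bd2_pg_ml"]

RACE_GROUPS = {"AA", "nonAA", "other"}
OUTCOMES = {"sPTB", "term"}


class SchemaError(ValueError):
    """Input file does not have the expected columns/keys."""


class DataError(ValueError):
    """Input values violate a data invariant (negative counts, zero rows...)."""


@dataclass
class SampleMeta:
    """Per-sample metadata record.

    ``outcome`` must be consistent with ``ga_delivery`` under the chosen
    preterm cutoff (default 37 completed weeks; 34 weeks supported as a
    sensitivity recoding via :meth:`with_outcome_cutoff`).
    """

    sample_id: str
    subject_id: str
    visit: int
    race_group: str
    ga_sample: float
    ga_delivery: float
    outcome: str
    nulliparous: bool
    total_16s_copies: float | None = None
    bd2_pg_ml: float | None = None

    def validate(self, cutoff: float = 37.0) -> None:
        if self.visit not in (1, 2, 3):
            raise DataError(f"{self.sample_id}: visit must be 1, 2 or 3")
        if self.race_group not in RACE_GROUPS:
            raise DataError(f"{self.sample_id}: unknown race_group {self.race_group!r}")
        if self.outcome not in OUTCOMES:
            raise DataError(f"{self.sample_id}: unknown outcome {self.outcome!r}")
        if self.ga_sample > self.ga_delivery:
            raise DataError(
                f"{self.sample_id}: sampled at {self.ga_sample}w after delivery "
                f"at {self.ga_delivery}w"
            )
        preterm = self.ga_delivery < cutoff
        if preterm != (self.outcome == "sPTB"):
            raise DataError(
                f"{self.sample_id}: outcome {self.outcome!r} inconsistent with "
                f"delivery at {self.ga_delivery}w (cutoff {cutoff}w)"
            )
        lo, hi = VISIT_WINDOWS[self.visit]
        if not (lo <= self.ga_sample <= hi):
            warnings.warn(
                f"{self.sample_id}: visit {self.visit} sampled at "
                f"{self.ga_sample}w, outside nominal window {lo}-{hi}w",
                stacklevel=2,
            )
        for attr in ("total_16s_copies", "bd2_pg_ml"):
            v = getattr(self, attr)
            if v is not None and not np.isnan(v) and v < 0:
                raise DataError(f"{self.sample_id}: negative {attr}")

    def with_outcome_cutoff(self, cutoff: float) -> "SampleMeta":
        """Recode the outcome with an alternative preterm cutoff (e.g. 34w)."""
        out = "sPTB" if self.ga_delivery < cutoff else "term"
        return SampleMeta(**{**asdict(self), "outcome": out})


@dataclass
class FilterReport:
    """Record of what a filtering step removed and under which thresholds."""

    rule: str
    removed_taxa: list[str] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


class TaxaTable:
    """Samples x taxa abundance matrix plus per-sample metadata.

    Parameters
    ----------
    rel_abund
        DataFrame (index = sample_id, columns = taxa) of relative
        abundances; each row sums to 1 over observed taxa unless the table
        was filtered without renormalisation.
    meta
        DataFrame with one row per sample carrying the
        :class:`SampleMeta` columns; indexed by ``sample_id``.
    counts
        Optional raw read counts with the same shape as ``rel_abund``.
    """

    def __init__(
        self,
        rel_abund: pd.DataFrame,
        meta: pd.DataFrame,
        counts: pd.DataFrame | None = None,
        check_row_sums: bool = True,
    ):
        if rel_abund.columns.duplicated().any():
            raise DataError("duplicate taxon names")
        if counts is not None:
            if not counts.index.equals(rel_abund.index) or not counts.columns.equals(
                rel_abund.columns
            ):
                raise DataError("counts and rel_abund not aligned")
            if (counts.to_numpy() < 0).any():
                raise DataError("negative counts")
        if (rel_abund.to_numpy() < 0).any():
            raise DataError("negative relative abundances")
        missing = [c for c in META_COLUMNS if c not in meta.reset_index().columns]
        if missing:
            raise SchemaError(f"metadata missing columns: {missing}")
        meta = meta.reset_index() if meta.index.name == "sample_id" else meta.copy()
        meta = meta.set_index("sample_id", drop=False)
        if not set(rel_abund.index) <= set(meta.index):
            extra = sorted(set(rel_abund.index) - set(meta.index))[:5]
            raise SchemaError(f"samples without metadata, e.g. {extra}")
        self.rel_abund = rel_abund
        self.counts = counts
        self.meta = meta.loc[rel_abund.index]
        if check_row_sums:
            sums = self.rel_abund.sum(axis=1).to_numpy()
            if (sums <= 0).any():
                bad = self.rel_abund.index[sums <= 0][0]
                raise DataError(f"sample {bad!r} has zero total abundance")

    # -- basic properties -------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.rel_abund.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rel_abund.index)

    @property
    def n_samples(self) -> int:
        return self.rel_abund.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.rel_abund.shape[1]

    def sample_meta(self, sample_id: str) -> SampleMeta:
        row = self.meta.loc[sample_id]
        return SampleMeta(
            sample_id=row["sample_id"],
            subject_id=row["subject_id"],
            visit=int(row["visit"]),
            race_group=row["race_group"],
            ga_sample=float(row["ga_sample"]),
            ga_delivery=float(row["ga_delivery"]),
            outcome=row["outcome"],
            nulliparous=bool(row["nulliparous"]),
            total_16s_copies=_opt(row, "total_16s_copies"),
            bd2_pg_ml=_opt(row, "bd2_pg_ml"),
        )

    def validate(self, cutoff: float = 37.0, row_sum_tol: float = 1e-9) -> None:
        """Check metadata invariants and row-sum closure."""
        for sid in self.sample_ids:
            self.sample_meta(sid).validate(cutoff=cutoff)
        sums = self.rel_abund.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=row_sum_tol):
            worst = (sums - 1.0).abs().idxmax()
            raise DataError(
                f"relative abundance rows do not sum to 1 (worst: {worst!r}, "
                f"sum {sums[worst]:.6g})"
            )
        if self.counts is not None:
            derived = self.counts.div(self.counts.sum(axis=1), axis=0)
            if not np.allclose(derived.to_numpy(), self.rel_abund.to_numpy(), atol=1e-8):
                raise DataError("rel_abund not derivable from counts")

    def subset_samples(self, sample_ids: Sequence[str]) -> "TaxaTable":
        ids = list(sample_ids)
        return TaxaTable(
            self.rel_abund.loc[ids],
            self.meta.loc[ids],
            None if self.counts is None else self.counts.loc[ids],
            check_row_sums=False,
        )

    def subset_taxa(self, taxa: Sequence[str], renormalize: bool = False) -> "TaxaTable":
        taxa = list(taxa)
        ra = self.rel_abund[taxa]
        counts = None if self.counts is None else self.counts[taxa]
        if renormalize:
            ra = ra.div(ra.sum(axis=1), axis=0)
        return TaxaTable(ra, self.meta, counts, check_row_sums=False)

    def with_outcome_cutoff(self, cutoff: float) -> "TaxaTable":
        meta = self.meta.copy()
        meta["outcome"] = np.where(meta["ga_delivery"] < cutoff, "sPTB", "term")
        return TaxaTable(self.rel_abund, meta, self.counts, check_row_sums=False)


def _opt(row, col):
    if col not in row.index:
        return None
    v = row[col]
    return None if pd.isna(v) else float(v)


# ---------------------------------------------------------------------------
# TSV I/O — tab-separated, header row of taxon names, first column sample_id;
# metadata in a companion TSV keyed by sample_id.
# ---------------------------------------------------------------------------

def read_taxa_table(
    path,
    meta_path,
    counts_path=None,
    renormalize: bool = False,
) -> TaxaTable:
    """Read a relative-abundance TSV and its metadata TSV into a TaxaTable.

    ``path`` holds the samples x taxa relative abundances; ``counts_path``
    optionally holds raw read counts in the same layout. Rows are
    renormalised to sum to 1 only when ``renormalize`` is set.
    """
    ra = pd.read_csv(path, sep="\t", index_col=0)
    ra.index = ra.index.astype(str)
    ra.index.name = None
    if ra.shape[1] == 0:
        raise SchemaError(f"{path}: no taxon columns")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"{meta_path}: missing columns {missing}")
    counts = None
    if counts_path is not None:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        counts.index.name = None
        counts = counts.loc[ra.index, ra.columns]
    if (ra.to_numpy() < 0).any():
        raise DataError(f"{path}: negative values")
    if renormalize:
        sums = ra.sum(axis=1)
        if (sums <= 0).any():
            raise DataError(f"{path}: zero-sum row, cannot renormalize")
        ra = ra.div(sums, axis=0)
    return TaxaTable(ra, meta, counts)


def write_taxa_table(t: TaxaTable, path, meta_path, counts_path=None) -> None:
    """Write a TaxaTable back to the TSV dialect read by :func:`read_taxa_table`."""
    t.rel_abund.rename_axis("sample_id").to_csv(path, sep="\t")
    t.meta.reset_index(drop=True).to_csv(meta_path, sep="\t", index=False)
    if counts_path is not None and t.counts is not None:
        t.counts.rename_axis("sample_id").to_csv(counts_path, sep="\t")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_min_reads(t: TaxaTable, min_reads: int = 1000) -> tuple[TaxaTable, FilterReport]:
    """Keep samples with strictly more than ``min_reads`` total sequences."""
    if t.counts is None:
        raise SchemaError("filter_min_reads requires raw counts")
    totals = t.counts.sum(axis=1)
    keep = totals > min_reads
    report = FilterReport(
        rule="min_reads",
        removed_samples=list(totals.index[~keep]),
        thresholds={"min_reads": min_reads},
    )
    return t.subset_samples(list(totals.index[keep])), report


def filter_studywide_frequency(
    t: TaxaTable,
    freq: float = 1e-5,
    mode: str = "pooled",
    renormalize: bool = False,
) -> tuple[TaxaTable, FilterReport]:
    """Drop taxa below a study-wide frequency floor.

    ``mode='pooled'`` (default) computes each taxon's share of all reads
    pooled across samples (total taxon reads / total reads; equivalently the
    read-weighted mean relative abundance). ``mode='per_sample_mean'`` uses
    the unweighted mean of per-sample relative abundances instead.
    """
    if mode == "pooled":
        if t.counts is not None:
            studywide = t.counts.sum(axis=0) / t.counts.to_numpy().sum()
        else:
            # without counts all samples carry equal weight
            studywide = t.rel_abund.mean(axis=0)
    elif mode == "per_sample_mean":
        studywide = t.rel_abund.mean(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = studywide >= freq
    report = FilterReport(
        rule="studywide_frequency",
        removed_taxa=list(studywide.index[~keep]),
        thresholds={"freq": freq, "mode": mode},
    )
    return t.subset_taxa(list(studywide.index[keep]), renormalize=renormalize), report


def filter_prevalence(t: TaxaTable, min_prev: float = 0.25) -> list[str]:
    """Taxa detected (rel_abund > 0) in strictly more than ``min_prev`` of samples.

    This is the gate for per-taxon risk modelling; it does not modify the
    table.
    """
    prev = (t.rel_abund > 0).mean(axis=0)
    return list(prev.index[prev > min_prev])


def remove_contaminants(
    t: TaxaTable,
    contaminant_list: Iterable[str] = DEFAULT_CONTAMINANTS,
    renormalize: bool = False,
) -> tuple[TaxaTable, FilterReport]:
    """Remove named reagent-contaminant taxa (exact name match)."""
    contaminants = set(contaminant_list)
    removed = [tx for tx in t.taxa if tx in contaminants]
    keep = [tx for tx in t.taxa if tx not in contaminants]
    report = FilterReport(
        rule="contaminants",
        removed_taxa=removed,
        thresholds={"n_listed": len(contaminants)},
    )
    return t.subset_taxa(keep, renormalize=renormalize), report


def read_contaminant_list(path) -> list[str]:
    """One taxon name per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def absolute_abundance(t: TaxaTable) -> pd.DataFrame:
    """Per-taxon absolute abundance: total 16S copies (qPCR) x relative abundance.

    Samples without a qPCR total get NaN rows rather than failing. Row sums
    equal the qPCR totals exactly (conservation).
    """
    if "total_16s_copies" not in t.meta.columns:
        totals = pd.Series(np.nan, index=t.rel_abund.index)
    else:
        totals = t.meta["total_16s_copies"].astype(float)
    return t.rel_abund.mul(totals, axis=0)


def shannon_diversity(p: np.ndarray) -> float:
    """Shannon diversity (nats) of a proportion vector: -sum p ln p over p>0."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())
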
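"""Core tabular containers for marker read counts and taxonomy.

Count tables are pandas DataFrames with ASV identifiers as the index
and sample identifiers as columns, mirroring the TSV layout used on
disk (rows = ASVs, first column = ASV id). Sample roles distinguish
true samples from the negative and positive controls that drive the
decontamination filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Taxonomic ranks, most to least inclusive. Empty string = unassigned.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Recognised sample roles.
ROLES = ("sample", "extraction_blank", "pcr_blank", "positive_control")

#: Roles counted as negative controls by the blank-sum filter.
BLANK_ROLES = ("extraction_blank", "pcr_blank")


@dataclass
class MarkerCountTable:
    """Integer read counts for one marker, ASVs x samples, with sample roles.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame; index = ASV ids, columns = sample ids.
    roles
        Series mapping each sample id to a role in :data:`ROLES`.
    marker
        Marker label, e.g. ``"18S-V7"``.
    """

    counts: pd.DataFrame
    roles: pd.Series
    marker: str = "marker"

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV ids: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        vals = self.counts.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.integer)):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if vals.size and (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.roles = self.roles.reindex(self.counts.columns)
        if self.roles.isna().any():
            missing = self.roles.index[self.roles.isna()].tolist()
            raise ValueError(f"samples missing a role: {missing}")
        bad = set(self.roles.unique()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")

    # -- column subsets ------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def asv_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def true_sample_ids(self) -> pd.Index:
        return self.counts.columns[self.roles.to_numpy() == "sample"]

    @property
    def blank_ids(self) -> pd.Index:
        return self.counts.columns[np.isin(self.roles.to_numpy(), BLANK_ROLES)]

    @property
    def true_counts(self) -> pd.DataFrame:
        """Counts restricted to true-sample columns."""
        return self.counts[self.true_sample_ids]

    def sample_totals(self, true_only: bool = True) -> pd.Series:
        tab = self.true_counts if true_only else self.counts
        return tab.sum(axis=0)

    def total_reads(self, true_only: bool = True) -> int:
        return int(self.sample_totals(true_only=true_only).sum())

    # -- derived tables ------------------------------------------------
    def with_counts(self, counts: pd.DataFrame) -> "MarkerCountTable":
        """New table with the same marker, roles restricted to ``counts`` columns."""
        return MarkerCountTable(counts=counts, roles=self.roles.reindex(counts.columns), marker=self.marker)

    def drop_asvs(self, asv_ids) -> "MarkerCountTable":
        keep = self.counts.index.difference(pd.Index(asv_ids), sort=False)
        return self.with_counts(self.counts.loc[keep])

    def copy(self) -> "MarkerCountTable":
        return replace(self, counts=self.counts.copy(), roles=self.roles.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"MarkerCountTable(marker={self.marker!r}, "
                f"{self.counts.shape[0]} ASVs x {self.counts.shape[1]} samples, "
                f"{self.total_reads(true_only=False)} reads)")


@dataclass
class TaxonomyTable:
    """Per-ASV taxonomy, one column per rank; empty string = unassigned.

    Optionally carries a per-ASV ``marine`` flag (True when the terminal
    taxon is categorised marine or estuarine) used to drop terrestrial
    signal before community modelling.
    """

    ranks: pd.DataFrame
    marine: pd.Series | None = None

    def __post_init__(self) -> None:
        missing_cols = [r for r in RANKS if r not in self.ranks.columns]
        if missing_cols:
            raise ValueError(f"taxonomy missing rank columns: {missing_cols}")
        self.ranks = self.ranks[list(RANKS)].fillna("").astype(str)
        if self.ranks.index.duplicated().any():
            raise ValueError("duplicate ASV ids in taxonomy")
        if self.marine is not None:
            self.marine = self.marine.reindex(self.ranks.index).fillna(False).astype(bool)

    def lineage(self, asv_id: str) -> tuple[str, ...]:
        """Full seven-rank tuple for one ASV (unassigned ranks as '')."""
        return tuple(self.ranks.loc[asv_id, list(RANKS)])

    def lineages(self) -> pd.Series:
        """Series of ';'-joined full lineage strings, indexed by ASV id."""
        return self.ranks[list(RANKS)].agg(";".join, axis=1)

    def subset(self, asv_ids) -> "TaxonomyTable":
        idx = pd.Index(asv_ids)
        marine = self.marine.loc[idx] if self.marine is not None else None
        return TaxonomyTable(ranks=self.ranks.loc[idx].copy(), marine=marine)

    def has_rank_group(self, asv_id: str, group: tuple[str, ...]) -> bool:
        return any(self.ranks.loc[asv_id, r] != "" for r in group)
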
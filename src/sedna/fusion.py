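"""Rarefaction, percent conversion and two-marker fusion.

Each marker's OTU table is rarefied to a common depth (default: the
lower quartile of its per-sample totals), converted to percent
abundance, and the two markers are fused by averaging percents over
the intersection of samples that survived both markers' filters. OTUs
are aligned across markers by their full taxonomy tuple — the only key
the two markers share.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import MarkerCountTable, TaxonomyTable


@dataclass
class FusedCommunityTable:
    """OTU-level percent abundances after rarefaction and fusion.

    ``percents`` is samples x OTUs (OTU key = ';'-joined taxonomy
    tuple); ``presence`` is percents > 0; ``provenance`` flags each OTU
    as detected by one marker or both.
    """

    percents: pd.DataFrame
    provenance: pd.Series
    rarefaction_depths: dict[str, int]
    seed: int
    fusion_mode: str = "mean_with_zero"
    dropped_samples: dict[str, list[str]] = field(default_factory=dict)

    @property
    def presence(self) -> pd.DataFrame:
        return self.percents > 0

    @property
    def sample_ids(self) -> pd.Index:
        return self.percents.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.percents.columns

    def drop_otus(self, otus) -> "FusedCommunityTable":
        keep = self.percents.columns.difference(pd.Index(otus), sort=False)
        return FusedCommunityTable(
            percents=self.percents[keep],
            provenance=self.provenance[keep],
            rarefaction_depths=dict(self.rarefaction_depths),
            seed=self.seed,
            fusion_mode=self.fusion_mode,
            dropped_samples=dict(self.dropped_samples),
        )

    def report(self) -> dict:
        prov = self.provenance.value_counts().to_dict()
        return {
            "n_samples": int(self.percents.shape[0]),
            "n_otus": int(self.percents.shape[1]),
            "rarefaction_depths": dict(self.rarefaction_depths),
            "provenance_counts": {str(k): int(v) for k, v in prov.items()},
            "fusion_mode": self.fusion_mode,
            "seed": self.seed,
        }


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Independent stream per sample, stable under column reordering."""
    digest = hashlib.blake2s(sample_id.encode(), digest_size=4).digest()
    return np.random.default_rng([seed, int.from_bytes(digest, "big")])


def lower_quartile_depth(table: MarkerCountTable) -> int:
    """Default rarefaction depth: lower quartile of per-sample totals."""
    totals = table.sample_totals(true_only=True).to_numpy()
    return int(np.floor(np.quantile(totals, 0.25)))


def rarefy(table: MarkerCountTable, depth: int, seed: int = 0,
           shallow: str = "error") -> MarkerCountTable:
    """Subsample each sample column to exactly ``depth`` reads without
    replacement (multivariate hypergeometric draw per sample).

    ``shallow`` controls samples whose total is below ``depth``:
    ``"error"`` (default) rejects them by name — they should have been
    dropped upstream; ``"keep"`` leaves them untouched, the usual
    behaviour when rarefying to the lower quartile, which by
    construction exceeds a quarter of the sample totals.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if shallow not in ("error", "keep"):
        raise ValueError(f"shallow must be 'error' or 'keep', got {shallow!r}")
    totals = table.sample_totals(true_only=False)
    low = totals[totals < depth]
    if len(low) and shallow == "error":
        raise ValueError(
            f"samples below rarefaction depth {depth}: {low.index.tolist()} "
            "(drop them upstream before rarefying, or pass shallow='keep')")
    out = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        total = int(col.sum())
        if total <= depth:
            out[sid] = col.copy()
        else:
            rng = _sample_rng(seed, str(sid))
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.asv_ids)
    return table.with_counts(counts)


def to_percent(table: MarkerCountTable) -> pd.DataFrame:
    """Convert counts to percent per sample; columns sum to 100."""
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = table.sample_ids[zero].tolist()
        raise ValueError(f"all-zero sample columns: {bad}")
    pct = counts / totals[None, :] * 100.0
    return pd.DataFrame(pct, index=table.asv_ids, columns=table.sample_ids)


def _to_taxonomy_keys(pct: pd.DataFrame, taxonomy: TaxonomyTable) -> pd.DataFrame:
    """Re-key OTU rows by full lineage string; collisions (same lineage,
    different centroid) are summed before fusion."""
    lineages = taxonomy.lineages().reindex(pct.index)
    if lineages.isna().any():
        raise ValueError(
            f"OTUs missing from taxonomy: {lineages.index[lineages.isna()].tolist()}")
    return pct.groupby(lineages).sum()


def fuse_markers(pct_a: pd.DataFrame, pct_b: pd.DataFrame,
                 taxonomy_a: TaxonomyTable, taxonomy_b: TaxonomyTable,
                 marker_names: tuple[str, str] = ("V7", "V9"),
                 mode: str = "mean_with_zero",
                 rarefaction_depths: dict[str, int] | None = None,
                 seed: int = 0) -> FusedCommunityTable:
    """Fuse two markers' percent tables by averaging on shared samples.

    OTUs are aligned by full taxonomy tuple; the sample set is the
    intersection. ``mode='mean_with_zero'`` treats the markers as
    replicate observations, so an OTU undetected by one marker
    contributes 0 to the mean (10% in one marker, absent in the other
    -> 5%). ``mode='mean_detected'`` averages over detecting markers
    only (-> 10%).
    """
    if mode not in ("mean_with_zero", "mean_detected"):
        raise ValueError(f"unknown fusion mode {mode!r}")
    a = _to_taxonomy_keys(pct_a, taxonomy_a)
    b = _to_taxonomy_keys(pct_b, taxonomy_b)
    shared = a.columns.intersection(b.columns)
    if len(shared) == 0:
        raise ValueError("no samples shared between the two markers")
    union = a.index.union(b.index)
    A = a.reindex(index=union, columns=shared).fillna(0.0)
    B = b.reindex(index=union, columns=shared).fillna(0.0)

    in_a = a.index
    in_b = b.index
    provenance = pd.Series(
        np.where(union.isin(in_a) & union.isin(in_b), "both",
                 np.where(union.isin(in_a), f"{marker_names[0]}-only",
                          f"{marker_names[1]}-only")),
        index=union,
    )
    if mode == "mean_with_zero":
        fused = (A + B) / 2.0
    else:
        n_det = (A.index.isin(in_a)).astype(float) + (B.index.isin(in_b)).astype(float)
        fused = (A + B).div(n_det, axis=0)

    dropped = {
        marker_names[0]: [c for c in a.columns if c not in set(shared)],
        marker_names[1]: [c for c in b.columns if c not in set(shared)],
    }
    return FusedCommunityTable(
        percents=fused.T,  # samples x OTUs
        provenance=provenance,
        rarefaction_depths=dict(rarefaction_depths or {}),
        seed=seed,
        fusion_mode=mode,
        dropped_samples=dropped,
    )


def remove_non_marine(table: FusedCommunityTable,
                      marine_flags: pd.Series) -> tuple[FusedCommunityTable, list[str]]:
    """Drop OTUs flagged neither marine nor estuarine.

    ``marine_flags`` is indexed by OTU key (lineage string); OTUs
    without a flag are retained with a warning, mirroring a habitat
    lookup that only removes positively categorised non-marine species.
    """
    flags = marine_flags.reindex(table.otu_ids)
    unknown = flags.index[flags.isna()].tolist()
    if unknown:
        warnings.warn(f"{len(unknown)} OTUs lack a marine/estuarine flag; retained")
    removed = flags.index[flags.eq(False)].tolist()
    return table.drop_otus(removed), removed


def marker_overlap_report(table: FusedCommunityTable) -> dict:
    """Tally OTUs unique to each marker vs shared, from provenance."""
    counts = table.provenance.value_counts().to_dict()
    return {str(k): int(v) for k, v in counts.items()}
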
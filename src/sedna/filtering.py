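"""Multi-stage ASV decontamination and filtering for one marker.

Five ASV-level steps in fixed order, then low-read sample dropping:

1. drop ASVs occurring in a single sample;
2. blank-sum contamination filter — for each ASV take its maximum read
   count over the negative controls, sum those maxima into the *blank
   sum*, and remove (from all samples) any ASV whose blank maximum
   exceeds ``blank_fraction`` of that sum;
3. global low-abundance filter — remove ASVs whose total reads fall
   below ``global_fraction`` of the library's grand total;
4. taxonomy completeness — keep an ASV only if at least one of
   family/genus/species and at least one of phylum/class/order is
   assigned;
5. greedy 97%-identity centroid clustering, summing reads of ASVs that
   share both a cluster and an identical full taxonomy (ASV -> OTU);
6. drop samples whose total reads fall below half the lower quartile
   of per-sample totals.

Every step logs removed ASVs, removed reads and the reads-per-sample
summary into a :class:`FilterAudit`, so the read/ASV accounting of the
whole cascade can be reconciled exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .tables import MarkerCountTable, TaxonomyTable

UPPER_RANKS = ("phylum", "class", "order")
LOWER_RANKS = ("family", "genus", "species")


@dataclass
class FilterParams:
    """Thresholds for the filter cascade.

    blank_fraction
        An ASV is removed when its maximum blank count exceeds this
        fraction of the blank sum (e.g. blank sum 230,000 -> any ASV
        with more than 230 reads in a blank is removed).
    global_fraction
        An ASV is removed when its total reads fall below this fraction
        of the grand total, i.e. below 0.001% by default (100 reads in
        a 10-million-read library).
    cluster_identity
        Minimum pairwise identity for OTU clustering.
    sample_read_floor_fraction
        Samples below this fraction of the lower-quartile read total
        are dropped.
    """

    blank_fraction: float = 0.001
    global_fraction: float = 1e-5
    cluster_identity: float = 0.97
    sample_read_floor_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("blank_fraction", "global_fraction", "cluster_identity",
                     "sample_read_floor_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class FilterStepRecord:
    step: str
    n_asvs_before: int
    n_asvs_after: int
    asvs_removed: list[str]
    reads_before: int
    reads_after: int
    reads_per_sample_before: tuple[float, float]  # mean, SE over true samples
    reads_per_sample_after: tuple[float, float]
    samples_removed: list[str] = field(default_factory=list)
    threshold: float | None = None
    notes: str = ""

    @property
    def reads_removed(self) -> int:
        return self.reads_before - self.reads_after

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "n_asvs_before": self.n_asvs_before,
            "n_asvs_after": self.n_asvs_after,
            "asvs_removed": sorted(self.asvs_removed),
            "reads_before": self.reads_before,
            "reads_after": self.reads_after,
            "reads_removed": self.reads_removed,
            "reads_per_sample_before": list(self.reads_per_sample_before),
            "reads_per_sample_after": list(self.reads_per_sample_after),
            "samples_removed": sorted(self.samples_removed),
            "threshold": self.threshold,
            "notes": self.notes,
        }


@dataclass
class FilterAudit:
    """Ordered record of every filter step applied to one marker."""

    marker: str = "marker"
    records: list[FilterStepRecord] = field(default_factory=list)

    def add(self, record: FilterStepRecord) -> None:
        self.records.append(record)

    def record(self, step: str) -> FilterStepRecord:
        matches = [r for r in self.records if r.step == step]
        if not matches:
            raise KeyError(f"no audit record for step {step!r}")
        return matches[-1]

    @property
    def total_reads_removed(self) -> int:
        return sum(r.reads_removed for r in self.records)

    def to_dict(self) -> dict:
        return {"marker": self.marker, "steps": [r.to_dict() for r in self.records]}

    def to_text(self) -> str:
        lines = [f"Filter audit — marker {self.marker}"]
        for r in self.records:
            mb, sb = r.reads_per_sample_before
            ma, sa = r.reads_per_sample_after
            lines.append(
                f"  {r.step}: ASVs {r.n_asvs_before} -> {r.n_asvs_after} "
                f"({len(r.asvs_removed)} removed), reads {r.reads_before} -> "
                f"{r.reads_after} ({r.reads_removed} removed); "
                f"reads/sample {mb:.0f} ± {sb:.0f} -> {ma:.0f} ± {sa:.0f}"
            )
            if r.threshold is not None:
                lines.append(f"    threshold: {r.threshold:g}")
            if r.samples_removed:
                lines.append(f"    samples removed: {', '.join(sorted(r.samples_removed))}")
            if r.notes:
                lines.append(f"    note: {r.notes}")
        lines.append(f"  total reads removed: {self.total_reads_removed}")
        return "\n".join(lines)


def _rps(table: MarkerCountTable) -> tuple[float, float]:
    """Mean ± SE of reads per true sample (the survey's summary style)."""
    totals = table.sample_totals(true_only=True).to_numpy(dtype=float)
    if totals.size == 0:
        return (0.0, 0.0)
    se = totals.std(ddof=1) / np.sqrt(totals.size) if totals.size > 1 else 0.0
    return (float(totals.mean()), float(se))


def _make_record(step: str, before: MarkerCountTable, after: MarkerCountTable,
                 removed: list[str], threshold: float | None = None,
                 samples_removed: list[str] | None = None, notes: str = "") -> FilterStepRecord:
    return FilterStepRecord(
        step=step,
        n_asvs_before=len(before.asv_ids),
        n_asvs_after=len(after.asv_ids),
        asvs_removed=list(removed),
        reads_before=before.total_reads(true_only=False),
        reads_after=after.total_reads(true_only=False),
        reads_per_sample_before=_rps(before),
        reads_per_sample_after=_rps(after),
        samples_removed=list(samples_removed or []),
        threshold=threshold,
        notes=notes,
    )


def _require_nonempty(table: MarkerCountTable) -> None:
    if len(table.asv_ids) == 0:
        raise ValueError("count table has no ASVs")


# ---------------------------------------------------------------------------
# step 1

def remove_single_sample_asvs(table: MarkerCountTable,
                              include_blanks: bool = True) -> tuple[MarkerCountTable, FilterStepRecord]:
    """Drop ASVs with nonzero counts in fewer than two columns.

    ``include_blanks`` controls whether blank columns count toward the
    occurrence tally (they do by default: a read is a read).
    """
    _require_nonempty(table)
    cols = table.counts if include_blanks else table.true_counts
    occ = (cols.to_numpy() > 0).sum(axis=1)
    removed = table.asv_ids[occ < 2].tolist()
    out = table.drop_asvs(removed)
    return out, _make_record("single_sample", table, out, removed)


# ---------------------------------------------------------------------------
# step 2

def blank_sum_filter(table: MarkerCountTable,
                     params: FilterParams = FilterParams()) -> tuple[MarkerCountTable, FilterStepRecord]:
    """Blank-sum contamination filter.

    blank_sum = sum over ASVs of each ASV's maximum count in any
    negative control; an ASV is removed from all samples when its blank
    maximum is strictly greater than ``blank_fraction * blank_sum``.
    """
    _require_nonempty(table)
    blanks = table.blank_ids
    if len(blanks) == 0:
        raise ValueError(
            "no extraction/PCR blank columns present; if the library truly has "
            "no negative controls, skip blank_sum_filter explicitly")
    blank_max = table.counts[blanks].max(axis=1)
    blank_sum = int(blank_max.sum())
    if blank_sum == 0:
        warnings.warn("blank sum is zero; blank filter is a no-op")
        rec = _make_record("blank_sum", table, table, [], threshold=0.0,
                           notes="blank sum 0 — no-op")
        rec.notes += f"; blank_sum={blank_sum}"
        return table, rec
    threshold = params.blank_fraction * blank_sum
    removed = table.asv_ids[blank_max.to_numpy() > threshold].tolist()
    out = table.drop_asvs(removed)
    rec = _make_record("blank_sum", table, out, removed, threshold=threshold,
                       notes=f"blank_sum={blank_sum}")
    return out, rec


# ---------------------------------------------------------------------------
# step 3

def global_abundance_filter(table: MarkerCountTable,
                            params: FilterParams = FilterParams()) -> tuple[MarkerCountTable, FilterStepRecord]:
    """Remove ASVs whose true-sample total is strictly below
    ``global_fraction`` of the grand true-sample total."""
    _require_nonempty(table)
    totals = table.true_counts.sum(axis=1)
    grand = int(totals.sum())
    threshold = params.global_fraction * grand
    removed = table.asv_ids[totals.to_numpy() < threshold].tolist()
    out = table.drop_asvs(removed)
    return out, _make_record("global_abundance", table, out, removed, threshold=threshold,
                             notes=f"grand_total={grand}")


# ---------------------------------------------------------------------------
# step 4

def taxonomy_completeness_filter(table: MarkerCountTable,
                                 taxonomy: TaxonomyTable) -> tuple[MarkerCountTable, FilterStepRecord]:
    """Keep ASVs assigned at >=1 of phylum/class/order AND >=1 of
    family/genus/species."""
    _require_nonempty(table)
    missing = table.asv_ids.difference(taxonomy.ranks.index)
    if len(missing):
        raise ValueError(f"ASVs missing from taxonomy: {missing.tolist()}")
    ranks = taxonomy.ranks.loc[table.asv_ids]
    upper_ok = (ranks[list(UPPER_RANKS)] != "").any(axis=1)
    lower_ok = (ranks[list(LOWER_RANKS)] != "").any(axis=1)
    keep = upper_ok & lower_ok
    removed = table.asv_ids[~keep.to_numpy()].tolist()
    out = table.drop_asvs(removed)
    return out, _make_record("taxonomy_completeness", table, out, removed)


# ---------------------------------------------------------------------------
# step 5

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq_a: str, seq_b: str,
                      aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / alignment length."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = aligner or _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length


def greedy_cluster(sequences: dict[str, str], abundances: pd.Series,
                   identity: float = 0.97) -> dict[str, str]:
    """Greedy abundance-ordered centroid clustering.

    ASVs are visited in decreasing total-abundance order (ties broken
    by id); each joins the first existing centroid it matches at
    >= ``identity``, else founds a new cluster. Returns ASV -> centroid.
    """
    aligner = _make_aligner()
    order = sorted(sequences, key=lambda a: (-int(abundances[a]), a))
    centroids: list[str] = []
    assignment: dict[str, str] = {}
    for aid in order:
        seq = sequences[aid]
        if not seq:
            raise ValueError(f"empty sequence for ASV {aid}")
        for cid in centroids:
            if pairwise_identity(seq, sequences[cid], aligner) >= identity:
                assignment[aid] = cid
                break
        else:
            centroids.append(aid)
            assignment[aid] = aid
    return assignment


def cluster_and_merge(table: MarkerCountTable, sequences: dict[str, str],
                      taxonomy: TaxonomyTable,
                      params: FilterParams = FilterParams()
                      ) -> tuple[MarkerCountTable, dict[str, str], FilterStepRecord]:
    """Cluster ASVs at ``cluster_identity`` and sum reads of ASVs that
    share both the cluster and an identical full seven-rank taxonomy.

    The OTU id is the cluster centroid's ASV id for the taxonomy group
    containing the centroid; other taxonomy groups within a cluster
    keep their own most abundant member's id. Total reads are conserved
    exactly. Returns (OTU table, ASV -> OTU mapping, audit record).
    """
    _require_nonempty(table)
    missing = [a for a in table.asv_ids if a not in sequences]
    if missing:
        raise ValueError(f"sequences missing for ASVs: {missing}")
    abund = table.counts.sum(axis=1)
    seqs = {a: sequences[a] for a in table.asv_ids}
    assignment = greedy_cluster(seqs, abund, identity=params.cluster_identity)

    lineages = taxonomy.lineages().reindex(table.asv_ids)
    if lineages.isna().any():
        raise ValueError(
            f"ASVs missing from taxonomy: {lineages.index[lineages.isna()].tolist()}")

    groups: dict[tuple[str, str], list[str]] = {}
    for aid in table.asv_ids:
        groups.setdefault((assignment[aid], lineages[aid]), []).append(aid)

    otu_rows = {}
    asv_to_otu: dict[str, str] = {}
    for (centroid, _lineage), members in groups.items():
        if centroid in members:
            otu_id = centroid
        else:
            otu_id = min(members, key=lambda a: (-int(abund[a]), a))
        otu_rows[otu_id] = table.counts.loc[members].sum(axis=0)
        for a in members:
            asv_to_otu[a] = otu_id
    otu_ids = [a for a in table.asv_ids if a in otu_rows]  # keep input order
    counts = pd.DataFrame({oid: otu_rows[oid] for oid in otu_ids}).T
    counts.columns = table.sample_ids
    out = table.with_counts(counts)
    merged = [a for a in table.asv_ids if asv_to_otu[a] != a]
    rec = _make_record("cluster_merge", table, out, merged,
                       threshold=params.cluster_identity,
                       notes=f"{len(groups)} OTUs from {len(table.asv_ids)} ASVs")
    return out, asv_to_otu, rec


# ---------------------------------------------------------------------------
# step 6

def drop_low_read_samples(table: MarkerCountTable,
                          params: FilterParams = FilterParams()) -> tuple[MarkerCountTable, FilterStepRecord]:
    """Drop true samples whose read total is strictly below
    ``sample_read_floor_fraction`` of the lower quartile of totals.

    The lower quartile uses linear interpolation between order
    statistics (numpy's default quantile definition).
    """
    _require_nonempty(table)
    totals = table.sample_totals(true_only=True)
    if len(totals) < 4:
        raise ValueError("need >= 4 true samples for a stable lower quartile")
    q1 = float(np.quantile(totals.to_numpy(), 0.25))
    cutoff = params.sample_read_floor_fraction * q1
    dropped = totals.index[totals.to_numpy() < cutoff].tolist()
    keep_cols = [c for c in table.sample_ids if c not in set(dropped)]
    out = table.with_counts(table.counts[keep_cols])
    rec = _make_record("low_read_samples", table, out, [], threshold=cutoff,
                       samples_removed=dropped, notes=f"Q1={q1:g}")
    return out, rec


# ---------------------------------------------------------------------------
# the cascade

def run_marker_filters(table: MarkerCountTable, taxonomy: TaxonomyTable,
                       sequences: dict[str, str],
                       params: FilterParams = FilterParams(),
                       drop_blanks: bool = True
                       ) -> tuple[MarkerCountTable, dict[str, str], FilterAudit]:
    """Apply the six steps in their fixed order for one marker.

    Returns the OTU-level table (blank columns retired at the end by
    default, once they have informed the blank filter), the ASV -> OTU
    mapping, and the full audit.
    """
    audit = FilterAudit(marker=table.marker)

    table, rec = remove_single_sample_asvs(table)
    audit.add(rec)
    table, rec = blank_sum_filter(table, params)
    audit.add(rec)
    table, rec = global_abundance_filter(table, params)
    audit.add(rec)
    table, rec = taxonomy_completeness_filter(table, taxonomy)
    audit.add(rec)
    table, asv_to_otu, rec = cluster_and_merge(table, sequences, taxonomy, params)
    audit.add(rec)
    table, rec = drop_low_read_samples(table, params)
    audit.add(rec)

    if drop_blanks:
        blanks = table.blank_ids.tolist()
        keep = [c for c in table.sample_ids if c not in set(blanks)]
        out = table.with_counts(table.counts[keep])
        audit.add(_make_record("retire_blanks", table, out, [],
                               samples_removed=blanks,
                               notes="negative controls removed after informing the blank filter"))
        table = out
    return table, asv_to_otu, audit
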
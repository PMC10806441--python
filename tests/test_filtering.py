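"""Filter cascade: definitions, brute-force oracles, order effects,
idempotence and audit conservation."""

import numpy as np
import pandas as pd
import pytest

import sedna
from sedna.filtering import (
    FilterParams,
    blank_sum_filter,
    cluster_and_merge,
    drop_low_read_samples,
    global_abundance_filter,
    greedy_cluster,
    pairwise_identity,
    remove_single_sample_asvs,
    run_marker_filters,
    taxonomy_completeness_filter,
)
from sedna.tables import RANKS, MarkerCountTable, TaxonomyTable

from conftest import random_table


def _tax(rows: dict[str, dict[str, str]]) -> TaxonomyTable:
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=RANKS).fillna("")
    return TaxonomyTable(ranks=df)


# ---------------------------------------------------------------------------
# single-sample filter

def test_single_sample_asv_removed_even_if_abundant(toy_table):
    counts = toy_table.counts.copy()
    counts.loc["BIG"] = [10_000, 0, 0, 0, 0]
    table = MarkerCountTable(counts=counts, roles=toy_table.roles, marker="t")
    out, rec = remove_single_sample_asvs(table)
    assert "BIG" in rec.asvs_removed
    assert "BIG" not in out.asv_ids


def test_two_single_reads_in_two_samples_retained(toy_table):
    counts = toy_table.counts.copy()
    counts.loc["RARE"] = [1, 1, 0, 0, 0]
    table = MarkerCountTable(counts=counts, roles=toy_table.roles, marker="t")
    out, _ = remove_single_sample_asvs(table)
    assert "RARE" in out.asv_ids


def test_single_sample_filter_matches_exhaustive_scan():
    rng = np.random.default_rng(17)
    for _ in range(20):
        table = random_table(rng, n_asvs=50, n_samples=17, n_blanks=3)
        out, _ = remove_single_sample_asvs(table)
        expected = {a for a in table.asv_ids
                    if int((table.counts.loc[a] > 0).sum()) >= 2}
        assert set(out.asv_ids) == expected


# ---------------------------------------------------------------------------
# blank-sum filter

def test_blank_sum_removal_cutoff_at_printed_example():
    """A library whose per-ASV blank maxima sum to 230,000 reads gets a
    removal cutoff of exactly 230 reads at the default blank fraction."""
    n_asvs = 23
    counts = pd.DataFrame(
        {"S1": 1000, "S2": 1000, "EB1": [10_000] * n_asvs},
        index=[f"A{i}" for i in range(n_asvs)])
    roles = pd.Series({"S1": "sample", "S2": "sample", "EB1": "extraction_blank"})
    table = MarkerCountTable(counts=counts, roles=roles)
    _, rec = blank_sum_filter(table)
    assert rec.threshold == pytest.approx(230.0)
    # boundary: 230 reads retained, 231 removed
    counts2 = counts.copy()
    counts2.loc["edge_lo", :] = [50, 50, 230]
    counts2.loc["edge_hi", :] = [50, 50, 231]
    counts2.loc["A0", "EB1"] = 10_000 - 461  # keep the blank sum at 230,000
    table2 = MarkerCountTable(counts=counts2, roles=roles)
    out, rec2 = blank_sum_filter(table2)
    assert rec2.notes.endswith("blank_sum=230000")
    assert "edge_lo" in out.asv_ids
    assert "edge_hi" in rec2.asvs_removed


def test_all_zero_blanks_is_noop(toy_table):
    counts = toy_table.counts.copy()
    counts[["EB1", "PB1"]] = 0
    table = MarkerCountTable(counts=counts, roles=toy_table.roles)
    with pytest.warns(UserWarning, match="no-op"):
        out, rec = blank_sum_filter(table)
    assert list(out.asv_ids) == list(table.asv_ids)


def test_no_blank_columns_is_an_error(toy_table):
    keep = ["S1", "S2", "S3"]
    table = MarkerCountTable(counts=toy_table.counts[keep],
                             roles=toy_table.roles[keep])
    with pytest.raises(ValueError, match="skip"):
        blank_sum_filter(table)


def test_blank_filter_matches_brute_force():
    rng = np.random.default_rng(23)
    params = FilterParams()
    for _ in range(20):
        table = random_table(rng, n_asvs=30, n_samples=10, n_blanks=3)
        out, _ = blank_sum_filter(table, params)
        blank_cols = table.blank_ids
        maxima = {a: int(table.counts.loc[a, blank_cols].max()) for a in table.asv_ids}
        blank_sum = sum(maxima.values())
        if blank_sum == 0:
            expected = set(table.asv_ids)
        else:
            thr = params.blank_fraction * blank_sum
            expected = {a for a, mx in maxima.items() if not mx > thr}
        assert set(out.asv_ids) == expected


# ---------------------------------------------------------------------------
# global abundance filter

def test_global_cutoff_at_printed_example():
    """A 10-million-read library yields a minimum-read cutoff of 100."""
    n_asvs = 100
    counts = pd.DataFrame({"S1": [50_000] * n_asvs, "S2": [50_000] * n_asvs},
                          index=[f"A{i}" for i in range(n_asvs)])
    roles = pd.Series({"S1": "sample", "S2": "sample"})
    table = MarkerCountTable(counts=counts, roles=roles)
    _, rec = global_abundance_filter(table)
    assert rec.threshold == pytest.approx(100.0)


def test_single_asv_table_retained_regardless_of_total():
    counts = pd.DataFrame({"S1": [3], "S2": [2]}, index=["only"])
    roles = pd.Series({"S1": "sample", "S2": "sample"})
    out, _ = global_abundance_filter(MarkerCountTable(counts=counts, roles=roles))
    assert list(out.asv_ids) == ["only"]


def test_global_filter_matches_brute_force():
    rng = np.random.default_rng(5)
    params = FilterParams(global_fraction=0.01)  # bite on small tables
    for _ in range(20):
        table = random_table(rng, n_asvs=40, n_samples=8, n_blanks=2)
        out, _ = global_abundance_filter(table, params)
        true_cols = table.true_sample_ids
        grand = int(table.counts[true_cols].to_numpy().sum())
        thr = params.global_fraction * grand
        expected = {a for a in table.asv_ids
                    if not int(table.counts.loc[a, true_cols].sum()) < thr}
        assert set(out.asv_ids) == expected


# ---------------------------------------------------------------------------
# taxonomy completeness

@pytest.mark.parametrize(
    "ranks, kept",
    [
        (dict(zip(RANKS, ["k", "p", "c", "o", "f", "g", "s"])), True),
        ({"kingdom": "k", "phylum": "p", "class": "c"}, False),   # no lower ranks
        ({"genus": "g"}, False),                                  # no upper ranks
        ({"order": "o", "family": "f"}, True),                    # one of each group
        ({"phylum": "p", "species": "s"}, True),
    ],
)
def test_taxonomy_completeness_truth_table(toy_table, ranks, kept):
    counts = toy_table.counts.iloc[:1].copy()
    counts.index = ["Q"]
    table = MarkerCountTable(counts=counts, roles=toy_table.roles)
    out, _ = taxonomy_completeness_filter(table, _tax({"Q": ranks}))
    assert ("Q" in out.asv_ids) is kept


def test_missing_taxonomy_is_an_error(toy_table):
    with pytest.raises(ValueError, match="missing from taxonomy"):
        taxonomy_completeness_filter(toy_table, _tax({"ASV1": {"genus": "g"}}))


# ---------------------------------------------------------------------------
# clustering

_FULL = dict(zip(RANKS, ["k", "p", "c", "o", "f", "g", "s"]))


def _two_asv_table(c1, c2):
    counts = pd.DataFrame({"S1": [c1, c2], "S2": [c1, c2]}, index=["X", "Y"])
    roles = pd.Series({"S1": "sample", "S2": "sample"})
    return MarkerCountTable(counts=counts, roles=roles)


def test_identical_sequences_same_taxonomy_merge():
    table = _two_asv_table(100, 40)
    seq = "ACGT" * 30
    tax = _tax({"X": _FULL, "Y": _FULL})
    out, mapping, rec = cluster_and_merge(table, {"X": seq, "Y": seq}, tax)
    assert mapping == {"X": "X", "Y": "X"}
    assert out.counts.loc["X"].tolist() == [140, 140]
    assert out.counts.to_numpy().sum() == table.counts.to_numpy().sum()


def test_same_cluster_different_genus_not_merged():
    table = _two_asv_table(100, 40)
    seq = "ACGTTGCA" * 15
    seq2 = seq[:-2] + "AA" if seq[-2:] != "AA" else seq[:-2] + "CC"
    other = dict(_FULL, genus="othergenus")
    tax = _tax({"X": _FULL, "Y": other})
    out, mapping, _ = cluster_and_merge(table, {"X": seq, "Y": seq2}, tax)
    assert pairwise_identity(seq, seq2) >= 0.97
    assert set(out.asv_ids) == {"X", "Y"}  # same cluster, two OTUs
    assert mapping["X"] != mapping["Y"]


def test_empty_sequence_is_an_error():
    table = _two_asv_table(10, 10)
    tax = _tax({"X": _FULL, "Y": _FULL})
    with pytest.raises(ValueError, match="empty sequence"):
        cluster_and_merge(table, {"X": "", "Y": "ACGT"}, tax)


def test_greedy_clustering_matches_all_pairs_alignment_oracle():
    """Cluster assignment equals an oracle that recomputes all pairwise
    identities by alignment and applies the same greedy rule."""
    rng = np.random.default_rng(31)
    bases = np.array(list("ACGT"))
    seqs, abund = {}, {}
    base_seqs = ["".join(bases[rng.integers(0, 4, 120)]) for _ in range(6)]
    idx = 0
    for b in base_seqs:
        for _ in range(rng.integers(1, 4)):
            arr = np.array(list(b))
            nmut = rng.integers(0, 3)
            for p in rng.choice(len(arr), size=nmut, replace=False):
                arr[p] = bases[rng.integers(0, 4)]
            aid = f"A{idx:02d}"
            seqs[aid] = "".join(arr)
            abund[aid] = int(rng.integers(1, 1000))
            idx += 1
    abund = pd.Series(abund)
    got = greedy_cluster(seqs, abund, identity=0.97)

    # oracle: same greedy rule from an explicitly computed identity matrix
    ids = sorted(seqs, key=lambda a: (-abund[a], a))
    ident = {(a, b): pairwise_identity(seqs[a], seqs[b]) for a in ids for b in ids}
    centroids, expected = [], {}
    for a in ids:
        for c in centroids:
            if ident[(a, c)] >= 0.97:
                expected[a] = c
                break
        else:
            centroids.append(a)
            expected[a] = a
    assert got == expected


# ---------------------------------------------------------------------------
# sample dropping

def test_equal_totals_drop_nothing():
    counts = pd.DataFrame(np.full((3, 5), 10), index=list("abc"),
                          columns=[f"S{i}" for i in range(5)])
    roles = pd.Series("sample", index=counts.columns)
    out, rec = drop_low_read_samples(MarkerCountTable(counts=counts, roles=roles))
    assert rec.samples_removed == []


def test_low_total_sample_dropped_at_half_quartile():
    totals = [100, 1000, 1000, 1000, 1000]
    counts = pd.DataFrame([totals], index=["a"], columns=[f"S{i}" for i in range(5)])
    roles = pd.Series("sample", index=counts.columns)
    out, rec = drop_low_read_samples(MarkerCountTable(counts=counts, roles=roles))
    assert rec.samples_removed == ["S0"]
    assert rec.threshold == pytest.approx(500.0)


def test_sample_drop_matches_quantile_oracle():
    rng = np.random.default_rng(8)
    for _ in range(20):
        table = random_table(rng, n_asvs=20, n_samples=11, n_blanks=2)
        out, rec = drop_low_read_samples(table)
        totals = table.sample_totals(true_only=True)
        cutoff = 0.5 * np.quantile(totals.to_numpy(), 0.25)
        expected = set(totals.index[totals.to_numpy() < cutoff])
        assert set(rec.samples_removed) == expected


def test_too_few_samples_is_an_error():
    counts = pd.DataFrame([[1, 2, 3]], index=["a"], columns=["S0", "S1", "S2"])
    roles = pd.Series("sample", index=counts.columns)
    with pytest.raises(ValueError, match="quartile"):
        drop_low_read_samples(MarkerCountTable(counts=counts, roles=roles))


# ---------------------------------------------------------------------------
# full cascade

def test_planted_contaminants_all_removed(small_dataset):
    """Contaminants planted at blank levels far above the threshold must
    all be removed, and no clean effect-carrying taxon may be lost to
    the blank filter (recall 1, blank-filter false removals 0)."""
    for mk, table in small_dataset.markers.items():
        out, _, audit = run_marker_filters(table, small_dataset.taxonomy,
                                           small_dataset.sequences[mk])
        removed_blank = set(audit.record("blank_sum").asvs_removed)
        contams = set(small_dataset.truth.contaminant_ids[mk])
        assert contams <= removed_blank | set(audit.record("single_sample").asvs_removed)
        real_asvs = set(small_dataset.truth.asv_to_taxon[mk])
        assert not (removed_blank & real_asvs)


def test_audit_read_totals_reconcile(small_dataset):
    table = small_dataset.markers["V7"]
    out, _, audit = run_marker_filters(table, small_dataset.taxonomy,
                                       small_dataset.sequences["V7"])
    initial = table.total_reads(true_only=False)
    final = out.total_reads(true_only=False)
    assert initial == final + audit.total_reads_removed
    removed_sets = [set(r.asvs_removed) for r in audit.records
                    if r.step != "cluster_merge"]
    for i, a in enumerate(removed_sets):
        for b in removed_sets[i + 1:]:
            assert a.isdisjoint(b)


def test_cascade_idempotent_once_blanks_are_clean():
    """A second pass over the filtered table removes nothing (holds when
    the first pass empties the blanks; residual blank leakage would
    re-trigger the blank filter at a shrunken blank sum)."""
    cfg = sedna.SyntheticConfig(seed=6, n_samples=16, n_taxa=12, blank_leak_rate=0.0)
    ds = sedna.generate_dataset(cfg)
    mk = "V7"
    out1, mapping, _ = run_marker_filters(ds.markers[mk], ds.taxonomy,
                                          ds.sequences[mk], drop_blanks=False)
    otu_seqs = {otu: ds.sequences[mk][otu] for otu in out1.asv_ids}
    out2, _, audit2 = run_marker_filters(out1, ds.taxonomy.subset(out1.asv_ids),
                                         otu_seqs, drop_blanks=False)
    pd.testing.assert_frame_equal(out1.counts, out2.counts)


def test_filter_order_is_not_commutative():
    """Blank-sum before global-abundance differs from the reverse on a
    crafted table: removing a heavy contaminant first shrinks the grand
    total and drags another ASV under the global threshold."""
    counts = pd.DataFrame(
        {
            "S1": [9000, 11, 500, 0],
            "S2": [0, 0, 500, 100],
            "EB1": [800, 0, 1, 0],
        },
        index=["contam", "tiny", "big", "mid"])
    roles = pd.Series({"S1": "sample", "S2": "sample", "EB1": "extraction_blank"})
    params = FilterParams(blank_fraction=0.001, global_fraction=0.005)
    t = MarkerCountTable(counts=counts, roles=roles)

    a1, _ = blank_sum_filter(t, params)
    a2, _ = global_abundance_filter(a1, params)
    b1, _ = global_abundance_filter(t, params)
    b2, _ = blank_sum_filter(b1, params)
    assert set(a2.asv_ids) != set(b2.asv_ids)


def test_passthrough_table_only_clusters():
    """With no contaminants, singletons or taxonomy gaps, the cascade
    reduces to the clustering merges."""
    cfg = sedna.SyntheticConfig(seed=2, n_samples=12, n_taxa=8, n_contaminants=0,
                                n_singletons=0, n_incomplete_taxonomy=0,
                                n_cluster_pairs=0, blank_leak_rate=0.0)
    ds = sedna.generate_dataset(cfg)
    table = ds.markers["V7"]
    out, _, audit = run_marker_filters(table, ds.taxonomy, ds.sequences["V7"],
                                       drop_blanks=False)
    survivors = [a for a in table.asv_ids
                 if a not in audit.record("single_sample").asvs_removed]
    assert set(audit.record("blank_sum").asvs_removed) == set()
    assert set(audit.record("global_abundance").asvs_removed) == set()
    assert set(audit.record("taxonomy_completeness").asvs_removed) == set()
    assert set(out.asv_ids) <= set(survivors)
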
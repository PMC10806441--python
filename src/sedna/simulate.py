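"""Synthetic two-marker eDNA datasets with known ground truth.

Emulates the data a sediment metabarcoding survey produces after
denoising: two markers (18S V7/V9-like) sharing one sample set,
negative-binomial read counts, taxon presence driven by a
complementary log-log linear function of correlated environmental
covariates, contaminant ASVs enriched in negative controls, singleton
ASVs, ASVs with incomplete taxonomy, and near-identical ASV pairs that
should co-cluster at 97% identity. Everything is generated from one
seeded RNG stream, so a fixed config gives bit-identical output.

The presence model is the one the downstream community GLM assumes:

    P(taxon j present in sample i) = 1 - exp(-exp(eta_ij)),
    eta_ij = b0_j + sum_k z_ik * B_jk

with ``z`` the per-covariate standardised environmental values and
``B`` the taxa x covariates effect matrix exported as ground truth.
Counts given presence are negative binomial around a lognormal
per-taxon abundance profile; the survey being emulated does not model
counts, only presence, so the count layer exists to exercise the
filtering and rarefaction stages realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .tables import RANKS, MarkerCountTable, TaxonomyTable

_BASES = np.array(list("ACGT"))


@dataclass
class CovariateSpec:
    name: str
    mean: float = 0.0
    sd: float = 1.0


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic survey.

    Defaults mirror the scale of an Arctic sediment survey: ~70 true
    samples, two extraction and two PCR blanks per marker, a few tens
    of taxa, and tens of thousands of reads per sample.
    """

    n_samples: int = 70
    n_blanks_extraction: int = 2
    n_blanks_pcr: int = 2
    n_taxa: int = 40
    n_contaminants: int = 5
    n_singletons: int = 5
    n_incomplete_taxonomy: int = 4
    n_cluster_pairs: int = 3
    n_nonmarine: int = 2
    covariates: tuple = (
        CovariateSpec("bottom_temperature", 1.0, 2.0),
        CovariateSpec("sst_change", 0.3, 0.15),
        CovariateSpec("par", 30.0, 8.0),
        CovariateSpec("primary_productivity", 0.01, 0.004),
        CovariateSpec("water_depth", 300.0, 250.0),
    )
    covariate_correlation: float | np.ndarray = 0.3
    effect_matrix: np.ndarray | None = None  # taxa x covariates, cloglog scale
    base_prevalence: tuple[float, float] = (0.15, 0.6)
    reads_mean: float = 30_000.0
    nb_dispersion: float = 5.0
    blank_leak_rate: float = 5e-4
    contaminant_blank_mean: float = 5_000.0
    marker_names: tuple[str, str] = ("V7", "V9")
    marker_detect_prob: float = 0.85
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        k = len(self.covariates)
        if np.isscalar(self.covariate_correlation):
            rho = float(self.covariate_correlation)
            C = np.full((k, k), rho)
            np.fill_diagonal(C, 1.0)
        else:
            C = np.asarray(self.covariate_correlation, dtype=float)
            if C.shape != (k, k):
                raise ValueError(f"correlation matrix must be {k}x{k}")
        if np.min(np.linalg.eigvalsh(C)) <= 1e-10:
            raise ValueError("covariate correlation matrix is not positive definite")
        return C

    def validate(self) -> None:
        counts = dict(n_samples=self.n_samples, n_blanks_extraction=self.n_blanks_extraction,
                      n_blanks_pcr=self.n_blanks_pcr, n_taxa=self.n_taxa,
                      n_contaminants=self.n_contaminants, n_singletons=self.n_singletons,
                      n_incomplete_taxonomy=self.n_incomplete_taxonomy)
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not (0.0 <= self.blank_leak_rate <= 1.0):
            raise ValueError("blank_leak_rate must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        self.correlation_matrix()

    def resolved_effects(self) -> np.ndarray:
        if self.effect_matrix is None:
            return np.zeros((self.n_taxa, len(self.covariates)))
        B = np.asarray(self.effect_matrix, dtype=float)
        if B.shape != (self.n_taxa, len(self.covariates)):
            raise ValueError("effect_matrix must be n_taxa x n_covariates")
        return B


@dataclass
class GroundTruth:
    """Exported generator truth for parameter-recovery tests."""

    true_effects: pd.DataFrame            # taxa x covariates (cloglog scale)
    intercepts: pd.Series                 # per-taxon b0
    presence_probs: pd.DataFrame          # samples x taxa
    true_presence: pd.DataFrame           # samples x taxa, bool
    contaminant_ids: dict[str, list[str]]  # per marker
    asv_to_taxon: dict[str, dict[str, str]]
    cluster_pairs: dict[str, dict[str, str]]  # secondary ASV -> primary ASV
    detected: pd.DataFrame                # taxa x markers, bool
    nonmarine_taxa: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "true_effects": {t: {c: float(v) for c, v in row.items()}
                             for t, row in self.true_effects.iterrows()},
            "intercepts": {t: float(v) for t, v in self.intercepts.items()},
            "true_presence": {s: [int(v) for v in row]
                              for s, row in self.true_presence.iterrows()},
            "contaminant_ids": {m: sorted(ids) for m, ids in self.contaminant_ids.items()},
            "asv_to_taxon": self.asv_to_taxon,
            "cluster_pairs": self.cluster_pairs,
            "detected": {t: {m: bool(v) for m, v in row.items()}
                         for t, row in self.detected.iterrows()},
            "nonmarine_taxa": list(self.nonmarine_taxa),
            "taxon_order": list(self.true_presence.columns),
        }


@dataclass
class SyntheticDataset:
    markers: dict[str, MarkerCountTable]
    taxonomy: TaxonomyTable
    sequences: dict[str, dict[str, str]]   # per marker: ASV id -> sequence
    metadata: pd.DataFrame                 # sample_id index; role, lat, lon, covariates
    truth: GroundTruth
    config: SyntheticConfig


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Config with a planted effect structure: ~20% of taxa respond to
    bottom temperature (the strongest gradient), a handful to SST change
    and primary productivity, echoing the gradients the survey targets."""
    cfg = SyntheticConfig(seed=seed, **overrides)
    n, k = cfg.n_taxa, len(cfg.covariates)
    B = np.zeros((n, k))
    n_temp = max(1, n // 5)
    signs = np.where(np.arange(n_temp) % 2 == 0, 1.0, -1.0)
    B[:n_temp, 0] = 1.3 * signs
    n_sst = max(1, n // 10)
    B[n_temp:n_temp + n_sst, 1] = 1.0
    if n_temp + n_sst < n:
        B[n_temp + n_sst, 3] = -1.0
    cfg.effect_matrix = B
    return cfg


# ---------------------------------------------------------------------------
# sequence helpers

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute ``n_subs`` distinct positions (no indels), keeping
    pairwise identity at (L - n_subs) / L."""
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# generator

def _taxon_lineage(j: int) -> dict[str, str]:
    return {
        "kingdom": "Eukaryota",
        "phylum": f"Phylum{j % 6:02d}",
        "class": f"Class{j % 12:02d}",
        "order": f"Order{j % 18:02d}",
        "family": f"Family{j:03d}",
        "genus": f"Genus{j:03d}",
        "species": f"Genus{j:03d} sp.",
    }


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic survey; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_taxa
    cov_names = [c.name for c in config.covariates]
    k = len(cov_names)

    # --- environmental covariates (correlated MVN) ---
    C = config.correlation_matrix()
    sds = np.array([c.sd for c in config.covariates])
    means = np.array([c.mean for c in config.covariates])
    Sigma = np.outer(sds, sds) * C
    Xraw = rng.multivariate_normal(means, Sigma, size=n, method="cholesky")
    Z = (Xraw - Xraw.mean(axis=0)) / Xraw.std(axis=0, ddof=1)

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    # coordinates: latitude tracks the first covariate (temperature falls
    # northwards), longitudes spread across a Greenland-like sector
    lat = 70.0 - 4.0 * Z[:, 0] + rng.normal(0, 1.2, size=n)
    lon = rng.uniform(-55.0, 15.0, size=n)

    # --- presence model ---
    B = config.resolved_effects()
    taxon_ids = [f"T{j:03d}" for j in range(m)]
    p_base = rng.uniform(*config.base_prevalence, size=m)
    b0 = np.log(-np.log(1.0 - p_base))
    eta = b0[None, :] + Z @ B.T
    probs = 1.0 - np.exp(-np.exp(np.clip(eta, -30, 3)))
    presence = rng.random((n, m)) < probs

    # --- abundance profile and marker detectability ---
    abund = rng.lognormal(mean=0.0, sigma=1.0, size=m)
    detect = rng.random((m, 2)) < config.marker_detect_prob
    none_det = ~detect.any(axis=1)
    detect[none_det, rng.integers(0, 2, size=none_det.sum())] = True

    blank_ids = ([f"EB{i + 1}" for i in range(config.n_blanks_extraction)]
                 + [f"PB{i + 1}" for i in range(config.n_blanks_pcr)])
    all_cols = sample_ids + blank_ids
    roles = pd.Series(
        ["sample"] * n
        + ["extraction_blank"] * config.n_blanks_extraction
        + ["pcr_blank"] * config.n_blanks_pcr,
        index=all_cols,
    )

    markers: dict[str, MarkerCountTable] = {}
    sequences: dict[str, dict[str, str]] = {}
    tax_rows: dict[str, dict[str, str]] = {}
    marine_flags: dict[str, bool] = {}
    contaminant_ids: dict[str, list[str]] = {}
    asv_to_taxon: dict[str, dict[str, str]] = {}
    cluster_pairs: dict[str, dict[str, str]] = {}

    nonmarine = set(taxon_ids[m - config.n_nonmarine:]) if config.n_nonmarine else set()
    seq_len = {config.marker_names[0]: 115, config.marker_names[1]: 140}
    disp = config.nb_dispersion

    for mi, marker in enumerate(config.marker_names):
        det = detect[:, mi]
        act = presence & det[None, :]
        weights = act * abund[None, :]
        wsum = weights.sum(axis=1, keepdims=True)
        wsum[wsum == 0] = 1.0
        mean_reads = config.reads_mean * weights / wsum

        counts = np.zeros((m, len(all_cols)), dtype=np.int64)
        pos_mean = mean_reads.T  # taxa x samples
        nz = pos_mean > 0
        p_nb = disp / (disp + pos_mean[nz])
        counts[:, :n][nz] = rng.negative_binomial(disp, p_nb)

        # leakage of true taxa into blanks
        if config.blank_leak_rate > 0:
            leak_mean = config.blank_leak_rate * config.reads_mean * (abund / abund.sum())
            for bi in range(len(blank_ids)):
                counts[:, n + bi] = rng.poisson(leak_mean * det)

        asv_ids = [f"{marker}_ASV{j:04d}" for j in range(m)]
        a2t = dict(zip(asv_ids, taxon_ids))
        seqs = {aid: _random_seq(rng, seq_len[marker] + int(rng.integers(-5, 6)))
                for aid in asv_ids}
        for aid, tid in a2t.items():
            j = int(tid[1:])
            tax_rows[aid] = _taxon_lineage(j)
            marine_flags[aid] = tid not in nonmarine

        rows = [counts[j] for j in range(m)]
        ids = list(asv_ids)

        # split some detected taxa into co-clustering ASV pairs (>=97% id)
        pairs: dict[str, str] = {}
        splittable = [j for j in range(m) if det[j]][: config.n_cluster_pairs]
        for j in splittable:
            primary = asv_ids[j]
            secondary = f"{marker}_ASV{j:04d}b"
            frac = rng.binomial(rows[j], 0.3)
            rows[j] = rows[j] - frac
            rows.append(frac)
            ids.append(secondary)
            L = len(seqs[primary])
            seqs[secondary] = _mutate(rng, seqs[primary], max(1, int(0.02 * L)))
            tax_rows[secondary] = dict(tax_rows[primary])
            marine_flags[secondary] = marine_flags[primary]
            a2t[secondary] = a2t[primary]
            pairs[secondary] = primary
        cluster_pairs[marker] = pairs

        # contaminants: heavy in blanks, scattered lightly in true samples
        contam = []
        for c in range(config.n_contaminants):
            aid = f"{marker}_CONT{c:02d}"
            row = np.zeros(len(all_cols), dtype=np.int64)
            row[n:] = rng.poisson(config.contaminant_blank_mean, size=len(blank_ids))
            hit = rng.random(n) < 0.3
            row[:n][hit] = rng.poisson(20, size=hit.sum()) + 1
            rows.append(row)
            ids.append(aid)
            contam.append(aid)
            seqs[aid] = _random_seq(rng, seq_len[marker])
            tax_rows[aid] = {
                "kingdom": "Fungi", "phylum": f"ContPhylum{c}", "class": f"ContClass{c}",
                "order": f"ContOrder{c}", "family": f"ContFamily{c}",
                "genus": f"ContGenus{c}", "species": f"ContGenus{c} sp.",
            }
            marine_flags[aid] = False
        contaminant_ids[marker] = contam

        # singletons: one sample only
        for s in range(config.n_singletons):
            aid = f"{marker}_SING{s:02d}"
            row = np.zeros(len(all_cols), dtype=np.int64)
            row[rng.integers(0, n)] = rng.poisson(200) + 1
            rows.append(row)
            ids.append(aid)
            seqs[aid] = _random_seq(rng, seq_len[marker])
            tax_rows[aid] = _taxon_lineage(rng.integers(0, m))
            marine_flags[aid] = True

        # incomplete taxonomy: present in several samples, fails the
        # completeness rule one of two ways
        for q in range(config.n_incomplete_taxonomy):
            aid = f"{marker}_UNKN{q:02d}"
            row = np.zeros(len(all_cols), dtype=np.int64)
            hit = rng.random(n) < 0.25
            if hit.sum() < 2:
                hit[:2] = True
            row[:n][hit] = rng.poisson(60, size=hit.sum()) + 1
            rows.append(row)
            ids.append(aid)
            seqs[aid] = _random_seq(rng, seq_len[marker])
            if q % 2 == 0:  # upper ranks only
                tax_rows[aid] = {"kingdom": "Eukaryota", "phylum": f"Phylum{q % 6:02d}",
                                 "class": f"Class{q:02d}", "order": "",
                                 "family": "", "genus": "", "species": ""}
            else:  # lower ranks only
                tax_rows[aid] = {"kingdom": "Eukaryota", "phylum": "", "class": "",
                                 "order": "", "family": f"OrphanFam{q}",
                                 "genus": f"OrphanGen{q}", "species": ""}
            marine_flags[aid] = True

        counts_df = pd.DataFrame(np.vstack(rows), index=ids, columns=all_cols)
        markers[marker] = MarkerCountTable(counts=counts_df, roles=roles.copy(), marker=marker)
        sequences[marker] = seqs
        asv_to_taxon[marker] = a2t

    taxonomy = TaxonomyTable(
        ranks=pd.DataFrame.from_dict(tax_rows, orient="index")[list(RANKS)],
        marine=pd.Series(marine_flags),
    )
    metadata = pd.DataFrame(
        {"role": roles.values, "lat": np.concatenate([lat, np.full(len(blank_ids), np.nan)]),
         "lon": np.concatenate([lon, np.full(len(blank_ids), np.nan)])},
        index=pd.Index(all_cols, name="sample_id"),
    )
    for ci, name in enumerate(cov_names):
        metadata[name] = np.concatenate([Xraw[:, ci], np.full(len(blank_ids), np.nan)])

    truth = GroundTruth(
        true_effects=pd.DataFrame(B, index=taxon_ids, columns=cov_names),
        intercepts=pd.Series(b0, index=taxon_ids),
        presence_probs=pd.DataFrame(probs, index=sample_ids, columns=taxon_ids),
        true_presence=pd.DataFrame(presence, index=sample_ids, columns=taxon_ids),
        contaminant_ids=contaminant_ids,
        asv_to_taxon=asv_to_taxon,
        cluster_pairs=cluster_pairs,
        detected=pd.DataFrame(detect, index=taxon_ids, columns=list(config.marker_names)),
        nonmarine_taxa=sorted(nonmarine),
    )
    # contaminants never overlap taxa carrying effects (separate id spaces)
    all_contam = {a for ids_ in contaminant_ids.values() for a in ids_}
    assert all_contam.isdisjoint(truth.true_effects.index)

    return SyntheticDataset(markers=markers, taxonomy=taxonomy, sequences=sequences,
                            metadata=metadata, truth=truth, config=config)


# ---------------------------------------------------------------------------
# fixtures on disk

def write_fixture(dataset: SyntheticDataset, directory) -> dict[str, Path]:
    """Write the dataset as plain-text files; returns the path map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for marker, table in dataset.markers.items():
        p = d / f"counts_{marker}.tsv"
        _io.write_count_table(table, p)
        paths[f"counts_{marker}"] = p
        p = d / f"seqs_{marker}.fasta"
        _io.write_fasta(dataset.sequences[marker], p)
        paths[f"seqs_{marker}"] = p
    paths["taxonomy"] = d / "taxonomy.tsv"
    _io.write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    paths["metadata"] = d / "metadata.tsv"
    _io.write_metadata(dataset.metadata, paths["metadata"])
    paths["ground_truth"] = d / "ground_truth.json"
    _io.write_json(dataset.truth.to_json_dict(), paths["ground_truth"])
    return paths


def read_fixture(directory, marker_names: tuple[str, str] = ("V7", "V9")):
    """Read back the count tables, taxonomy, sequences and metadata
    written by :func:`write_fixture` (ground truth is left as JSON)."""
    d = Path(directory)
    metadata = _io.read_metadata(d / "metadata.tsv")
    roles = _io.roles_from_metadata(metadata)
    markers = {}
    sequences = {}
    for marker in marker_names:
        markers[marker] = _io.read_count_table(d / f"counts_{marker}.tsv", roles, marker=marker)
        sequences[marker] = _io.read_fasta(d / f"seqs_{marker}.fasta")
    taxonomy = _io.read_taxonomy(d / "taxonomy.tsv")
    return markers, taxonomy, sequences, metadata
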
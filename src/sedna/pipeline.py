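"""End-to-end orchestration: filter -> fuse -> env -> assoc -> ordinate.

A single declarative YAML config drives the run; every stage's outputs
(TSV/JSON) land in the configured output directory together with a
manifest recording the config hash, master seed, package version and
output checksums, so a rerun with the same config byte-reproduces the
results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .assoc import community_anova, indicator_report, cluster_taxa_by_coefficients
from .envdesign import DEFAULT_PREFERENCE, prepare_design
from .filtering import FilterParams, run_marker_filters
from .fusion import fuse_markers, lower_quartile_depth, rarefy, remove_non_marine, to_percent
from .ordination import bray_curtis, distance_decay, fit_surface, nmds, surface_table
from .tables import MarkerCountTable, TaxonomyTable

log = logging.getLogger("sedna")

_META_COLS = ("role", "lat", "lon")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    counts: dict[str, str]                 # marker -> counts TSV
    sequences: dict[str, str]              # marker -> FASTA
    taxonomy: str
    metadata: str
    outdir: str
    filter_params: FilterParams = field(default_factory=FilterParams)
    fusion_mode: str = "mean_with_zero"
    rarefaction_depths: dict[str, int] = field(default_factory=dict)
    covariates: list[str] | None = None
    vif_threshold: float = 4.0
    preference: list[str] | None = None
    terms: list[str] | None = None
    n_resamples: int = 1000
    statistic: str = "wald"
    nmds_mode: str = "presence"
    nmds_restarts: int = 20
    n_permutations: int = 499
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fp = FilterParams(**raw.pop("filter", {}))
        return cls(filter_params=fp, **raw)

    def to_dict(self) -> dict:
        d = {
            "counts": dict(self.counts), "sequences": dict(self.sequences),
            "taxonomy": self.taxonomy, "metadata": self.metadata,
            "outdir": self.outdir,
            "filter": vars(self.filter_params),
            "fusion_mode": self.fusion_mode,
            "rarefaction_depths": dict(self.rarefaction_depths),
            "covariates": self.covariates, "vif_threshold": self.vif_threshold,
            "preference": self.preference, "terms": self.terms,
            "n_resamples": self.n_resamples, "statistic": self.statistic,
            "nmds_mode": self.nmds_mode, "nmds_restarts": self.nmds_restarts,
            "n_permutations": self.n_permutations, "seed": self.seed,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def validate_inputs(config: RunConfig) -> list[dict]:
    """Cross-check ids between tables; returns machine-readable
    diagnostics (empty list = consistent)."""
    diags: list[dict] = []

    def diag(kind: str, **info):
        diags.append({"kind": kind, **info})

    for label, path in [("taxonomy", config.taxonomy), ("metadata", config.metadata),
                        *[(f"counts:{m}", p) for m, p in config.counts.items()],
                        *[(f"sequences:{m}", p) for m, p in config.sequences.items()]]:
        if not Path(path).exists():
            diag("missing_file", input=label, path=str(path))
    if diags:
        return diags

    metadata = _io.read_metadata(config.metadata)
    taxonomy = _io.read_taxonomy(config.taxonomy)
    roles = _io.roles_from_metadata(metadata)
    for marker, path in config.counts.items():
        raw = pd.read_csv(path, sep="\t", index_col="asv_id")
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        if dup:
            diag("duplicate_asv_ids", marker=marker, ids=dup)
        missing_meta = [c for c in raw.columns if c not in metadata.index]
        if missing_meta:
            diag("samples_missing_from_metadata", marker=marker, ids=missing_meta)
        missing_tax = [a for a in raw.index if a not in taxonomy.ranks.index]
        if missing_tax:
            diag("asvs_missing_from_taxonomy", marker=marker, ids=missing_tax)
        seqs = _io.read_fasta(config.sequences[marker])
        missing_seq = [a for a in raw.index if a not in seqs]
        if missing_seq:
            diag("asvs_missing_sequence", marker=marker, ids=missing_seq)
    bad_roles = roles[~roles.isin(["sample", "extraction_blank", "pcr_blank",
                                   "positive_control"])]
    if len(bad_roles):
        diag("unknown_roles", ids=bad_roles.index.tolist())
    return diags


def _marine_flags_by_lineage(taxonomy: TaxonomyTable) -> pd.Series | None:
    if taxonomy.marine is None:
        return None
    lineages = taxonomy.lineages()
    return taxonomy.marine.groupby(lineages).any()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the result bundle; returns the
    in-memory results keyed by stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    diags = validate_inputs(config)
    fatal = [d for d in diags if d["kind"] in ("missing_file", "duplicate_asv_ids")]
    if fatal:
        raise ValueError(f"input validation failed: {fatal}")

    metadata = _io.read_metadata(config.metadata)
    taxonomy = _io.read_taxonomy(config.taxonomy)
    roles = _io.roles_from_metadata(metadata)
    results: dict = {"diagnostics": diags}

    # ---- stage: per-marker filtering -------------------------------------
    log.info("stage filter")
    otu_tables: dict[str, MarkerCountTable] = {}
    for marker, path in config.counts.items():
        table = _io.read_count_table(path, roles, marker=marker)
        seqs = _io.read_fasta(config.sequences[marker])
        otu, mapping, audit = run_marker_filters(table, taxonomy, seqs, config.filter_params)
        otu_tables[marker] = otu
        _io.write_json(audit.to_dict(), outdir / f"filter_audit_{marker}.json")
        (outdir / f"filter_audit_{marker}.txt").write_text(audit.to_text() + "\n")
        log.info("  %s: %d OTUs x %d samples after filtering", marker,
                 len(otu.asv_ids), len(otu.sample_ids))
        results[f"filter_{marker}"] = {"table": otu, "mapping": mapping, "audit": audit}

    # ---- stage: rarefaction + fusion -------------------------------------
    log.info("stage fuse")
    markers = list(config.counts)
    pcts, depths = {}, {}
    for marker in markers:
        depth = config.rarefaction_depths.get(marker) or lower_quartile_depth(otu_tables[marker])
        depths[marker] = depth
        rared = rarefy(otu_tables[marker], depth, seed=config.seed, shallow="keep")
        pcts[marker] = to_percent(rared)
    fused = fuse_markers(pcts[markers[0]], pcts[markers[1]],
                         taxonomy.subset(pcts[markers[0]].index),
                         taxonomy.subset(pcts[markers[1]].index),
                         marker_names=(markers[0], markers[1]),
                         mode=config.fusion_mode, rarefaction_depths=depths,
                         seed=config.seed)
    flags = _marine_flags_by_lineage(taxonomy)
    removed_nonmarine: list[str] = []
    if flags is not None:
        fused, removed_nonmarine = remove_non_marine(fused, flags)
    fused.percents.to_csv(outdir / "fused_percent.tsv", sep="\t", float_format="%.10g")
    report = fused.report()
    report["removed_non_marine"] = sorted(removed_nonmarine)
    _io.write_json(report, outdir / "fusion_report.json")
    results["fused"] = fused

    # ---- stage: environmental design -------------------------------------
    log.info("stage env")
    covs = config.covariates or [c for c in metadata.columns if c not in _META_COLS]
    design = prepare_design(metadata, covs, samples=fused.sample_ids,
                            vif_threshold=config.vif_threshold,
                            preference=config.preference if config.preference is not None
                            else DEFAULT_PREFERENCE)
    design.X.to_csv(outdir / "design.tsv", sep="\t", float_format="%.10g")
    _io.write_json({"vif_audit": design.vif_audit, "dropped": design.dropped},
                   outdir / "vif_audit.json")
    results["design"] = design

    # ---- stage: community association ------------------------------------
    log.info("stage assoc")
    shared = design.X.index.intersection(fused.sample_ids)
    Y = fused.presence.loc[shared]
    X = design.X.loc[shared]
    terms = config.terms or list(X.columns)
    assoc = community_anova(Y, X, term_order=terms, n_resamples=config.n_resamples,
                            seed=config.seed, statistic=config.statistic)
    assoc.anova.round(6).to_csv(outdir / "anova.tsv", sep="\t")
    for term, df in assoc.per_taxon.items():
        df.round(6).to_csv(outdir / f"per_taxon_{term}.tsv", sep="\t")
    if len(assoc.taxa) >= 2:
        clusters, _ = cluster_taxa_by_coefficients(assoc.coefficients[terms])
        assoc.clusters = clusters
        clusters.to_csv(outdir / "taxa_clusters.tsv", sep="\t")
    indicators = indicator_report(assoc)
    indicators.round(6).to_csv(outdir / "indicators.tsv", sep="\t", index=False)
    results["assoc"] = assoc

    # ---- stage: ordination + surfaces + distance decay --------------------
    log.info("stage ordinate")
    comm = fused.percents.loc[shared]
    D = bray_curtis(comm, mode=config.nmds_mode)
    ord_res = nmds(D, seed=config.seed, n_restarts=config.nmds_restarts,
                   input_mode=config.nmds_mode)
    ord_res.to_tsv(outdir / "nmds_coords.tsv")
    fits = [fit_surface(ord_res.coords, X[c], variable=c) for c in X.columns]
    stable = surface_table(fits)
    stable.to_csv(outdir / "surfaces.tsv", sep="\t")
    lat, lon = metadata["lat"], metadata["lon"]
    decay = distance_decay(comm, lat, lon, n_permutations=config.n_permutations,
                           seed=config.seed, mode=config.nmds_mode)
    _io.write_json(decay, outdir / "distance_decay.json")
    results.update({"ordination": ord_res, "surfaces": stable, "distance_decay": decay,
                    "nmds_stress": ord_res.stress})

    # ---- manifest ---------------------------------------------------------
    outputs = sorted(p for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "sedna_version": __import__("sedna").__version__,
        "outputs": {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs},
    }
    _io.write_json(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    return results
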
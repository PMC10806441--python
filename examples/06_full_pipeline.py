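"""Full pipeline run from a config: filter -> fuse -> env -> assoc ->
ordinate, with a reproducibility manifest.

Writes a synthetic fixture to disk, runs every stage from the file
inputs, and shows that the planted bottom-temperature effect tops the
sequential ANOVA.
"""

import tempfile
from pathlib import Path

import sedna
from sedna.pipeline import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    fix = Path(tmp) / "fixture"
    ds = sedna.generate_dataset(sedna.default_config(seed=3, n_samples=36, n_taxa=20))
    sedna.write_fixture(ds, fix)

    config = RunConfig(
        counts={"V7": str(fix / "counts_V7.tsv"), "V9": str(fix / "counts_V9.tsv")},
        sequences={"V7": str(fix / "seqs_V7.fasta"), "V9": str(fix / "seqs_V9.fasta")},
        taxonomy=str(fix / "taxonomy.tsv"),
        metadata=str(fix / "metadata.tsv"),
        outdir=str(Path(tmp) / "results"),
        n_resamples=199, nmds_restarts=6, n_permutations=99, seed=7,
    )
    results = run_pipeline(config)

    print("sequential community ANOVA:")
    print(results["assoc"].anova.round(4))
    print(f"\nNMDS stress: {results['nmds_stress']:.3f}")
    print("\nsurface fits (deviance explained % per covariate):")
    print(results["surfaces"])
    print(f"\nmanifest covers {len(results['manifest']['outputs'])} output files; "
          "rerunning with this config reproduces them byte-for-byte.")
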
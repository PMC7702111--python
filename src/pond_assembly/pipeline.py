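"""End-to-end demo pipeline: simulate -> denoise -> tables -> null models -> gas.

A single YAML-configurable entry point wires the stages together and writes
every artifact plus a manifest (versions, seeds, parameters, per-stage read
counts) to an output directory.  All randomness flows from the explicit seeds
recorded in the manifest; reruns are byte-identical.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, amplicon, assembly, community, geochem, io, synthetic

_ALLOWED_KEYS = {
    "seed",
    "out_dir",
    "n_genotypes",
    "genotype_length",
    "min_genotype_distance",
    "n_reads",
    "n_amplicon_samples",
    "error_model",
    "denoise",
    "metacommunity",
    "rarefy_depth",
    "null_model",
    "bnti_reps",
    "n_tree_taxa",
    "geochem_sites",
}


@dataclass
class RunConfig:
    """Resolved parameters for one demo run; unknown keys are rejected."""

    seed: int = 1
    out_dir: str = "pond_run"
    n_genotypes: int = 10
    genotype_length: int = 250
    min_genotype_distance: int = 5
    n_reads: int = 20000
    n_amplicon_samples: int = 4
    error_model: dict = field(default_factory=dict)
    denoise: dict = field(default_factory=dict)
    metacommunity: dict = field(default_factory=dict)
    rarefy_depth: int = 800
    null_model: dict = field(default_factory=dict)
    bnti_reps: int = 199
    geochem_sites: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full chain and return the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2 ** 31) for s in root.spawn(8)]
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "parameters": asdict(config),
        "counts": {},
    }

    # --- amplicon branch -------------------------------------------------
    model = synthetic.ErrorModel(**config.error_model)
    genotypes = synthetic.simulate_genotypes(
        config.n_genotypes,
        config.genotype_length,
        config.min_genotype_distance,
        seed=seeds[0],
    )
    rng = np.random.default_rng(seeds[1])
    # abundance-skewed genotypes, split over a few samples
    weights = np.sort(rng.dirichlet(np.ones(config.n_genotypes) * 0.8))[::-1]
    abundances = np.maximum(1, (weights * config.n_reads).astype(int))
    reads, truth = synthetic.simulate_reads(genotypes, list(abundances), model, seed=seeds[2])
    sample_ids = [
        f"s{(i % config.n_amplicon_samples) + 1:02d}" for i in range(len(reads))
    ]
    io.write_fastq(reads, out / "reads.fastq")
    io.write_truth_table(truth, out / "truth.tsv")

    params = amplicon.DenoiseParams(
        pcr_error_rate=model.pcr_error_rate,
        pcr_cycles=model.pcr_cycles,
        seq_error_rate=model.seq_error_rate,
        **config.denoise,
    )
    kept = amplicon.filter_reads(reads, max_ee=0.5)
    kept_samples = [s for r, s in zip(reads, sample_ids) if amplicon.expected_errors(r) <= 0.5]
    gts, assignment, counts = amplicon.denoise_reads(kept, params, samples=kept_samples)
    counts["reads_simulated"] = len(reads)
    counts["reads_after_ee_filter"] = len(kept)
    manifest["counts"] = counts
    io.write_genotypes_fasta(gts, out / "genotypes.fasta")
    assign_df = pd.DataFrame(
        [
            {
                "sequence": seq[:40],
                "status": rec["status"],
                "distance": rec.get("distance"),
                "p_value": rec.get("p_value"),
            }
            for seq, rec in assignment.items()
        ]
    )
    io.write_table(assign_df.set_index("sequence"), out / "assignment.tsv")
    per_sample = {
        f"g{i:04d}": dict(g.sample_counts) for i, g in enumerate(gts)
    }
    denoised_table = community.build_table(
        {s: {g: per_sample[g].get(s, 0) for g in per_sample}
         for s in sorted(set(sample_ids))}
    )
    io.write_table(denoised_table, out / "denoised_otu_table.tsv", index_label="otu_id")

    # --- metacommunity branch -------------------------------------------
    meta_cfg = synthetic.MetacommunityConfig(**config.metacommunity)
    table, meta = synthetic.simulate_metacommunity(meta_cfg, seed=seeds[3])
    io.write_table(table, out / "otu_table.tsv", index_label="otu_id")
    io.write_table(meta.set_index("sample_id"), out / "metadata.tsv")
    rare = community.rarefy(table, config.rarefy_depth, seed=seeds[4])
    io.write_table(rare, out / "otu_table_rarefied.tsv", index_label="otu_id")

    groups = dict(zip(meta["sample_id"], meta["pond_type"]))
    null_cfg = assembly.NullModelConfig(seed=seeds[5], **config.null_model)
    tree = synthetic.simulate_tree(
        rare.shape[0], seed=seeds[6], labels=list(rare.index)
    )
    (out / "tree.nwk").write_text(tree + "\n")
    tree_obj = io.read_newick(out / "tree.nwk", require_branch_lengths=True)

    summary = assembly.assembly_summary(
        rare, groups, tree=tree_obj, config=null_cfg, bnti_reps=config.bnti_reps
    )
    io.write_table(summary, out / "assembly_summary.tsv", index_label="contrast")
    rc = assembly.raup_crick(rare, null_cfg)
    io.write_table(rc, out / "rc_matrix.tsv", index_label="id")
    occ_curve = assembly.nst_by_occupancy(rare, groups, null_cfg)
    io.write_table(occ_curve, out / "nst_occupancy.tsv", index_label="k")

    # --- geochemistry branch ---------------------------------------------
    gas = synthetic.simulate_geochemistry(config.geochem_sites, seed=seeds[7])
    processed = geochem.process_gas_table(gas)
    ch4 = processed[processed["gas"] == "CH4"].copy()
    ch4["methanotrophs_per_ml"] = [
        geochem.methanotroph_abundance(f, c)
        for f, c in zip(ch4["methanotroph_fraction"], ch4["total_cells_per_ml"])
    ]
    usable = ch4[(ch4["methanotrophs_per_ml"] > 0) & (ch4["dissolved_uM"] > 0)]
    fit_y = geochem.fit_box_cox(usable["dissolved_uM"].to_numpy())
    fit_x = geochem.fit_box_cox(usable["methanotrophs_per_ml"].to_numpy())
    reg = geochem.regress(fit_y.transformed, fit_x.transformed)
    io.write_table(processed.set_index("sample_id"), out / "gas_results.tsv")
    manifest["geochem"] = {
        "boxcox_lambda_ch4": fit_y.lam,
        "boxcox_lambda_methanotrophs": fit_x.lam,
        "regression_slope": reg["slope"],
        "regression_p": reg["p_value"],
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out
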
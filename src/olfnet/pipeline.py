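"""End-to-end orchestration: synthesize -> behavior -> integrate -> couple
-> brainblood, driven by a single YAML config, with a reproducibility
manifest (seeds, parameters, output checksums).

Stage parameters default to the published analysis settings where one
exists (elastic-net mixing 0.5, 10 CV folds, 1000 bootstrap draws, 0.05
weight threshold, 10 blood / 4 brain components, FDR 0.05); cohort and
atlas sizes default to a desk-scale preset so a full run completes in
minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import brainblood as bb
from . import coupling as cp
from . import integration as ig
from . import synthetic as syn
from .exceptions import ConfigurationError, OlfnetError

logger = logging.getLogger(__name__)

STAGES = ("synth", "behavior", "integrate", "couple", "brainblood")

BEHAVIOR_OUTCOMES = ("auc_raw", "auc_norm", "anhedonia", "di", "ri_1h", "ri_24h", "ri_48h")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "olfnet_run"
    stages: list = field(default_factory=lambda: list(STAGES))

    # cohort / synthesis
    n_subjects: int = 120
    use_published_cohort: bool = False
    n_regions: int = 40
    n_genes: int = 600
    noise_sd: float = 1.0
    eigengene_metric_r: float = -0.5
    latent_loading: float = 0.6
    latent_edges: int = 20
    brain_tissues: list = field(default_factory=lambda: ["hippocampus", "hypothalamus"])

    # behavior stage: factors entering the factorial model (the full
    # five-factor design needs a cohort large enough to fill all 48 cells)
    anova_factors: list = field(default_factory=lambda: ["apoe", "diet", "age_group"])

    # elastic net
    en_alpha: float = 0.5
    en_folds: int = 10
    en_lambda_grid: list | None = None

    # MCCA + resampling
    boot_b: int = 1000
    perm_p: int = 2000
    weight_threshold: float = 0.05
    mcca_cutoff: float = 1e-3
    mcca_method: str = "sumcor"

    # eigengene / coupling
    blood_k: int = 10
    brain_k: int = 4
    fdr_level: float = 0.05
    top_regions_k: int = 5
    gmt: str | None = None

    def validate(self) -> "RunConfig":
        if not 0 <= self.en_alpha <= 1:
            raise ConfigurationError("en_alpha must be in [0, 1]")
        if not 0 < self.fdr_level < 1:
            raise ConfigurationError("fdr_level must be in (0, 1)")
        if self.weight_threshold < 0:
            raise ConfigurationError("weight_threshold must be >= 0")
        if self.mcca_method not in ("sumcor", "maxvar"):
            raise ConfigurationError(f"unknown mcca_method {self.mcca_method!r}")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
        if self.blood_k < 1 or self.brain_k < 1:
            raise ConfigurationError("component counts must be >= 1")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise ConfigurationError(f"gmt file not found: {self.gmt}")
        return self


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are an error, never
    silently ignored; all defaults are filled in."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {unknown}")
    return RunConfig(**raw).validate()


def _simulation_spec(config: RunConfig) -> syn.SimulationSpec:
    if config.use_published_cohort:
        return syn.published_cohort_spec(
            seed=config.seed,
            n_regions=config.n_regions,
            n_genes=config.n_genes,
            noise_sd=config.noise_sd,
            eigengene_metric_r=config.eigengene_metric_r,
        )
    spec = syn.SimulationSpec(
        n_subjects=config.n_subjects,
        seed=config.seed,
        n_regions=config.n_regions,
        n_genes=config.n_genes,
        noise_sd=config.noise_sd,
        eigengene_metric_r=config.eigengene_metric_r,
        latent_loadings={
            "behavior": config.latent_loading,
            "connectome": {"loading": config.latent_loading, "n_edges": config.latent_edges},
            "traits": 0.3,
        },
        effect_sizes={
            "ri": [({"apoe": "APOE4", "age_group": 18, "diet": "hfd"}, -0.5)],
            "anhedonia": [({"apoe": "APOE4", "age_group": 18}, +0.5)],
        },
    )
    spec.validate()
    return spec


def make_toy_gene_sets(spec: syn.SimulationSpec, n_decoys: int = 10) -> bb.GeneSetCollection:
    """A synthetic annotation collection over the simulated gene universe:
    one set per planted module plus seeded random decoy sets.  Stands in
    for a curated ontology in the bundled fixtures."""
    genes = syn.gene_symbols(spec)
    rng = np.random.default_rng([spec.seed, 101])
    sets = {}
    for m, members in syn.module_gene_blocks(spec).items():
        sets[f"MODULE_{m + 1:02d}"] = (f"planted co-expression module {m + 1}", members)
    for d in range(n_decoys):
        size = int(rng.integers(15, 60))
        members = sorted(rng.choice(genes, size=size, replace=False).tolist())
        sets[f"DECOY_{d + 1:02d}"] = ("random decoy set", members)
    return bb.GeneSetCollection(sets=sets, universe=genes)


# ---------------------------------------------------------------------------
# Stage implementations (file-level interfaces)
# ---------------------------------------------------------------------------


def _stage_synth(config: RunConfig, data_dir: Path) -> dict:
    spec = _simulation_spec(config)
    tissues = ("blood", *config.brain_tissues)
    manifest = syn.write_fixture_bundle(data_dir, spec, tissues=tissues)
    collection = make_toy_gene_sets(spec)
    bb.write_gmt(collection, data_dir / "gene_sets.gmt")
    return {"n_subjects": spec.n_subjects, "n_files": len(manifest["files"]),
            "tissues": list(tissues)}


def _stage_behavior(config: RunConfig, data_dir: Path, results: Path) -> dict:
    trials = pd.read_csv(data_dir / "behavior_trials.csv")
    traits = pd.read_csv(data_dir / "traits.csv")
    summary = bh.summarize_behavior(trials)
    summary.to_csv(results / "behavior_summary.csv", index=False, float_format="%.10g")
    effects = []
    for outcome in ("ri_24h", "anhedonia"):
        res = bh.factorial_anova(summary, traits, outcome, config.anova_factors)
        res.insert(0, "outcome", outcome)
        effects.append(res)
    pd.concat(effects).to_csv(results / "behavior_effects.csv", index=False,
                              float_format="%.10g")
    return {"n_subjects": len(summary)}


def _load_connectomes(data_dir: Path):
    files = sorted(data_dir.glob("connectome_*.tsv"))
    out = []
    ids = []
    for f in files:
        df = pd.read_csv(f, sep="\t", index_col=0)
        out.append(ig.Connectome(region_labels=df.index.tolist(),
                                 adjacency=df.to_numpy()))
        ids.append(f.stem.replace("connectome_", ""))
    return ids, out


def _stage_integrate(config: RunConfig, data_dir: Path, results: Path) -> dict:
    traits = pd.read_csv(data_dir / "traits.csv")
    summary = pd.read_csv(results / "behavior_summary.csv")
    ids, connectomes = _load_connectomes(data_dir)
    order = {sid: k for k, sid in enumerate(summary["subject_id"])}
    keep = [k for k, sid in enumerate(ids) if sid in order]
    connectomes = [connectomes[k] for k in keep]
    sids = [ids[k] for k in keep]
    summary = summary.set_index("subject_id").loc[sids]
    traits = traits.set_index("subject_id").loc[sids].reset_index()

    edges = ig.vectorize_connectomes(connectomes)
    Y = summary[list(BEHAVIOR_OUTCOMES)].to_numpy()
    en_spec = ig.ElasticNetSpec(alpha=config.en_alpha, n_folds=config.en_folds,
                                lambda_grid=config.en_lambda_grid, seed=config.seed)
    en = ig.fit_elastic_net(edges.X, Y, en_spec)
    selected_idx = en.selected
    X_sel = edges.X[:, selected_idx]
    sel_pairs = [edges.edge_index[k] for k in selected_idx]
    if len(sel_pairs) == 0:
        raise OlfnetError("elastic net selected no edges; lower the penalty grid")

    domains = [X_sel, ig._standardize(Y), ig.encode_traits(traits)]
    model = ig.fit_mcca(domains, method=config.mcca_method)
    resampling = ig.resample_sumcor(domains, B=config.boot_b, P=config.perm_p,
                                    seed=config.seed, method=config.mcca_method)
    subnet = ig.backproject_and_threshold(model, sel_pairs,
                                          threshold=config.weight_threshold,
                                          mcca_cutoff=config.mcca_cutoff)

    pd.DataFrame(subnet.retained_edges,
                 columns=["region_a", "region_b", "weight"]).to_csv(
        results / "subnetwork_edges.csv", index=False, float_format="%.10g")
    (results / "stagecounts.json").write_text(json.dumps({
        "n_after_elastic_net": subnet.stagecounts[0],
        "n_after_mcca": subnet.stagecounts[1],
        "n_after_threshold": subnet.stagecounts[2],
        "weight_threshold": subnet.weight_threshold,
    }, indent=2))
    (results / "resampling.json").write_text(json.dumps({
        "sumcor_observed": resampling.sumcor_observed,
        "ci95": list(resampling.ci95),
        "permutation_p": resampling.permutation_p,
        "B": config.boot_b,
        "P": config.perm_p,
        "converged": model.converged,
    }, indent=2))
    return {"sumcor": resampling.sumcor_observed,
            "stagecounts": list(subnet.stagecounts)}


def _stage_couple(config: RunConfig, data_dir: Path, results: Path) -> dict:
    expr = pd.read_csv(data_dir / "expr_blood.tsv", sep="\t", index_col=0)
    imaging = pd.read_csv(data_dir / "imaging.csv")
    normalized = cp.normalize_expression(expr)
    eig = cp.compute_eigengenes(normalized, K=config.blood_k, tissue="blood")
    grid = cp.coupling_grid(imaging, eig.scores,
                            metrics=list(syn.GRID_METRICS),
                            fdr_level=config.fdr_level)
    grid.to_csv(results / "coupling_grid.csv", index=False, float_format="%.10g")
    eig.loadings.to_csv(results / "eigengene_loadings.tsv", sep="\t",
                        float_format="%.10g")
    top = cp.top_regions_per_pair(grid, k=config.top_regions_k)
    top.to_csv(results / "coupling_top_regions.csv", index=False, float_format="%.10g")
    return {"n_records": len(grid), "n_significant": int(grid["significant"].sum())}


def _stage_brainblood(config: RunConfig, data_dir: Path, results: Path) -> dict:
    sets = {}
    for f in sorted(data_dir.glob("expr_*.tsv")):
        tissue = f.stem.replace("expr_", "")
        expr = pd.read_csv(f, sep="\t", index_col=0)
        K = config.blood_k if tissue == "blood" else config.brain_k
        sets[tissue] = cp.compute_eigengenes(cp.normalize_expression(expr), K=K,
                                             tissue=tissue)
    pairs = bb.pc_pair_correlations(sets, top_k=config.brain_k,
                                    fdr_level=config.fdr_level)
    gmt_path = Path(config.gmt) if config.gmt else data_dir / "gene_sets.gmt"
    collection = bb.read_gmt(gmt_path) if gmt_path.exists() else None
    written = bb.coupling_report(pairs, sets, collection, results / "brainblood")
    return {"n_pairs": len(pairs), "n_significant": int(pairs["significant"].sum()),
            "n_files": len(written)}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write
    ``run_manifest.json`` (parameters, seeds, stage timings, output
    checksums).  Identical config and seed reproduce identical checksums.
    A stage failure aborts with the stage name and an inventory of the
    outputs produced so far."""
    config.validate()
    out = Path(config.out_dir)
    data_dir = out / "data"
    results = out / "results"
    results.mkdir(parents=True, exist_ok=True)

    enabled = [s for s in STAGES if s in config.stages]
    for s in STAGES:
        if s not in enabled:
            logger.info("stage %s disabled, skipped", s)

    stage_info = {}
    for stage in enabled:
        t0 = time.perf_counter()
        try:
            if stage == "synth":
                info = _stage_synth(config, data_dir)
            elif stage == "behavior":
                info = _stage_behavior(config, data_dir, results)
            elif stage == "integrate":
                info = _stage_integrate(config, data_dir, results)
            elif stage == "couple":
                info = _stage_couple(config, data_dir, results)
            else:
                info = _stage_brainblood(config, data_dir, results)
        except Exception as exc:
            inventory = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
            raise OlfnetError(
                f"stage {stage!r} failed: {exc}; partial outputs: {inventory}"
            ) from exc
        info["seconds"] = round(time.perf_counter() - t0, 3)
        stage_info[stage] = info
        logger.info("stage %s done in %.2fs", stage, info["seconds"])

    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "run_manifest.json"
    }
    manifest = {
        "config": dataclasses.asdict(config),
        "stages": stage_info,
        "checksums": checksums,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
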
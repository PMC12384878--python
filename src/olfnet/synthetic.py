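"""Synthetic cohort generator with planted, recoverable structure.

Emulates the study design of a humanized-APOE mouse aging cohort: a trait
table stratified by APOE genotype, diet, sex, age group and NOS2 immune
background; odor-guided behavior trials (preference over a concentration
series, habituation/dishabituation, delayed recognition memory);
streamline-count connectomes; regional diffusion/volumetric imaging
metrics; and blood/brain expression count matrices.

Every generator is a pure function of a :class:`SimulationSpec` (one master
seed; per-table child seeds derived by fixed offsets), and every planted
effect — habituation decay, edge-latent loadings, eigengene-metric
correlations, blood-brain module sharing — is parameterized so downstream
stages have ground-truth recovery tests.  All planted effects default to
zero (a null configuration); :func:`published_cohort_spec` returns the preset
that mirrors the published cohort (465 subjects, published cohort margins) with
nonzero planted structure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataIntegrityError

# ---------------------------------------------------------------------------
# Factor levels and presets
# ---------------------------------------------------------------------------

APOE_LEVELS = ("APOE2", "APOE3", "APOE4")
DIET_LEVELS = ("control", "hfd")
SEX_LEVELS = ("F", "M")
AGE_LEVELS = (12, 18)
NOS2_LEVELS = ("mNOS2", "HN")

#: Published behavioral-cohort margins per (APOE, diet) cell:
#: total, females, 18-month-olds, HN-background animals.
PUBLISHED_COHORT_CELLS = {
    ("APOE2", "control"): {"total": 94, "female": 46, "age18": 51, "hn": 46},
    ("APOE2", "hfd"): {"total": 71, "female": 37, "age18": 31, "hn": 42},
    ("APOE3", "control"): {"total": 86, "female": 45, "age18": 41, "hn": 43},
    ("APOE3", "hfd"): {"total": 68, "female": 35, "age18": 32, "hn": 38},
    ("APOE4", "control"): {"total": 76, "female": 41, "age18": 28, "hn": 33},
    ("APOE4", "hfd"): {"total": 70, "female": 39, "age18": 23, "hn": 36},
}

PREFERENCE_CONCENTRATIONS = (0.0, 0.001, 0.01, 0.1)  # v/v lemon in mineral oil
MEMORY_PROBES = ("1h", "24h", "48h")

#: Eight a priori olfactory-memory regions used for gene-imaging coupling.
APRIORI_REGIONS = (
    "Piriform Cortex",
    "Amygdalopiriform Transition Area",
    "Posterolateral Cortical Amygdaloid Area",
    "Perirhinal Cortex",
    "Hippocampus",
    "Postsubiculum",
    "Parasubiculum",
    "Ventral Orbital Cortex",
)

#: Seven diffusion/propagator metrics entering the coupling grid, plus
#: regional volume as percent of intracranial volume.
GRID_METRICS = ("AD", "RD", "MD", "FA", "MSD", "QIV", "RTOP")
IMAGING_METRICS = GRID_METRICS + ("volume_pct",)
KNOWN_METRICS = frozenset(
    {"FA", "MD", "RD", "AD", "MSD", "NG", "QIV", "RTOP", "RTPP", "RTAP", "volume_pct"}
)

# metric location/scale used to place z-scale signals on plausible units
_METRIC_SCALE = {
    "FA": (0.45, 0.06),
    "MD": (7.0e-4, 6.0e-5),
    "RD": (6.0e-4, 6.0e-5),
    "AD": (9.0e-4, 7.0e-5),
    "MSD": (1.1e-4, 1.0e-5),
    "NG": (0.35, 0.04),
    "QIV": (4.0e-9, 5.0e-10),
    "RTOP": (2.3e6, 2.5e5),
    "RTPP": (150.0, 15.0),
    "RTAP": (1.6e4, 1.8e3),
    "volume_pct": (0.8, 0.12),
}

_SEED_STREAMS = {
    "traits": 1,
    "latent": 2,
    "behavior": 3,
    "connectome": 4,
    "imaging": 5,
    "expression": 6,
    "modules": 7,
}


def default_region_labels(n: int = 332) -> list[str]:
    """Anonymous atlas labels; 332 matches the mouse-brain parcellation."""
    return [f"ROI_{i + 1:03d}" for i in range(n)]


# ---------------------------------------------------------------------------
# SimulationSpec
# ---------------------------------------------------------------------------


@dataclass
class SimulationSpec:
    """Parameter bundle controlling every synthetic table.

    ``effect_sizes`` maps an outcome name ("ri", "anhedonia", "habituation")
    to a list of ``(conditions, shift)`` entries; ``conditions`` is a dict of
    trait column -> required level and ``shift`` is a mean shift in SD units
    applied to subjects matching all conditions.

    ``latent_loadings`` controls the single shared cross-domain factor: a
    standard-normal score per subject injected linearly into designated
    connectome edges (``connectome: {loading, n_edges}``), into the
    behavioral recognition/anhedonia outcomes (``behavior``), and tilted
    along an APOE4/HFD/age risk contrast in the trait table (``traits``).
    """

    n_subjects: int = 120
    cell_counts: dict | None = None
    effect_sizes: dict = field(default_factory=dict)
    latent_loadings: dict = field(default_factory=dict)
    eigengene_metric_r: float = -0.5
    noise_sd: float = 1.0
    seed: int = 0

    # behavior generator
    habituation_decay: float = 0.8
    dishabituation_bump: float = 0.6
    base_investigation_s: float = 10.0
    ri_sd: float = 0.08
    anhedonia_mean: float = 0.8
    anhedonia_sd: float = 0.05

    # connectome generator
    n_regions: int = 332
    streamline_mean: float = 50.0
    streamline_sd: float = 10.0

    # imaging generator: list of (region, metric, module_index) cells that
    # carry the planted eigengene-metric correlation
    planted_imaging_cells: tuple = (
        ("Parasubiculum", "AD", 1),
        ("Parasubiculum", "MD", 1),
        ("Parasubiculum", "RD", 1),
        ("Hippocampus", "AD", 1),
        ("Postsubiculum", "AD", 1),
    )

    # expression generator
    n_genes: int = 600
    n_modules: int = 10
    module_size: int = 40
    module_loading: float = 1.0
    module_decay: float = 0.88  # per-module strength decay; distinct module
    # variances keep the PCA from rotating within a degenerate eigenspace,
    # so eigengene order tracks module index
    dispersion: float = 0.3  # negative-binomial dispersion
    library_cv: float = 0.2  # log-normal library-size CV
    shared_module_r: float = 0.7  # blood <-> brain module-score correlation

    def validate(self) -> None:
        if self.n_subjects <= 0 and self.cell_counts is None:
            raise ConfigurationError("n_subjects must be positive")
        if not abs(self.eigengene_metric_r) < 1:
            raise ConfigurationError("|eigengene_metric_r| must be < 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0 < self.habituation_decay <= 1:
            raise ConfigurationError("habituation_decay must be in (0, 1]")
        if self.cell_counts is not None:
            total = sum(c["total"] for c in self.cell_counts.values())
            if total != self.n_subjects:
                raise ConfigurationError(
                    f"cell_counts sum to {total}, but n_subjects={self.n_subjects}"
                )
            for key, c in self.cell_counts.items():
                for margin in ("female", "age18", "hn"):
                    if not 0 <= c[margin] <= c["total"]:
                        raise ConfigurationError(
                            f"margin {margin!r} of cell {key} exceeds its total"
                        )

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for one table; offsets fixed so tables are
        independently reproducible."""
        return np.random.default_rng([self.seed, _SEED_STREAMS[stream]])


def published_cohort_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """The bundled preset mirroring the published cohort design: exact
    published cohort margins (465 animals) plus planted genotype x diet x age shifts
    and a shared latent factor at moderate loading."""
    spec = SimulationSpec(
        n_subjects=465,
        cell_counts=dict(PUBLISHED_COHORT_CELLS),
        effect_sizes={
            "ri": [
                ({"apoe": "APOE4", "age_group": 18, "diet": "hfd"}, -0.5),
                ({"apoe": "APOE2", "age_group": 12}, +0.3),
            ],
            "anhedonia": [({"apoe": "APOE4", "age_group": 18}, +0.5)],
        },
        latent_loadings={
            "behavior": 0.6,
            "connectome": {"loading": 0.6, "n_edges": 20},
            "traits": 0.3,
        },
        seed=seed,
        **overrides,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def _allocate_margin(rng, n, k, level_true, level_false):
    """Vector of length n with exactly k `level_true`, randomly placed."""
    values = np.array([level_true] * k + [level_false] * (n - k), dtype=object)
    return values[rng.permutation(n)]


def generate_traits(spec: SimulationSpec) -> pd.DataFrame:
    """One row per subject: subject_id, apoe, diet, sex, age_group, nos2,
    plus the hidden ground-truth `latent` score.

    With ``cell_counts`` given (e.g. the published-cohort preset), each
    (APOE, diet) cell is filled to its exact size and the sex/age/NOS2
    margins are matched exactly via seeded permutations; otherwise factors
    are drawn independently (proportional multinomial allocation).
    """
    spec.validate()
    rng = spec.rng("traits")
    rows = []
    if spec.cell_counts is not None:
        for (apoe, diet), counts in spec.cell_counts.items():
            n = counts["total"]
            sex = _allocate_margin(rng, n, counts["female"], "F", "M")
            age = _allocate_margin(rng, n, counts["age18"], 18, 12)
            nos2 = _allocate_margin(rng, n, counts["hn"], "HN", "mNOS2")
            for i in range(n):
                rows.append((apoe, diet, sex[i], int(age[i]), nos2[i]))
    else:
        for _ in range(spec.n_subjects):
            rows.append(
                (
                    APOE_LEVELS[rng.integers(3)],
                    DIET_LEVELS[rng.integers(2)],
                    SEX_LEVELS[rng.integers(2)],
                    AGE_LEVELS[rng.integers(2)],
                    NOS2_LEVELS[rng.integers(2)],
                )
            )
    traits = pd.DataFrame(rows, columns=["apoe", "diet", "sex", "age_group", "nos2"])
    traits.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(len(traits))])

    # shared latent factor, optionally tilted along a risk contrast so the
    # trait domain carries a recoverable signal
    lrng = spec.rng("latent")
    noise = lrng.standard_normal(len(traits))
    tilt = float(spec.latent_loadings.get("traits", 0.0))
    if tilt:
        risk = (
            (traits["apoe"] == "APOE4").astype(float)
            + (traits["diet"] == "hfd").astype(float)
            + (traits["age_group"] == 18).astype(float)
        )
        risk = (risk - risk.mean()) / risk.std(ddof=0)
        latent = tilt * risk.to_numpy() + np.sqrt(1 - tilt**2) * noise
    else:
        latent = noise
    traits["latent"] = latent
    return traits


def _planted_shift(traits: pd.DataFrame, entries) -> np.ndarray:
    """Sum of planted SD-unit shifts per subject for one outcome."""
    shift = np.zeros(len(traits))
    for conditions, delta in entries:
        mask = np.ones(len(traits), dtype=bool)
        for col, level in conditions.items():
            mask &= (traits[col] == level).to_numpy()
        shift[mask] += delta
    return shift


# ---------------------------------------------------------------------------
# Behavior trials
# ---------------------------------------------------------------------------


def generate_behavior(traits: pd.DataFrame, spec: SimulationSpec) -> pd.DataFrame:
    """Long-format trial table covering the three assays.

    * ``preference``: 4 trials x 4 objects, objects odorized at the four
      lemon concentrations (0, 0.001, 0.01, 0.1 v/v); investigation time
      rises with concentration rank.
    * ``habituation``: 5 trials x 4 objects with multiplicative decay over
      trials 1-4 and a novelty bump on the odor-switched object at trial 5.
    * ``memory``: novel/familiar investigation pairs at 1 h, 24 h, 48 h,
      with planted genotype x age x diet shifts on the recognition index.

    All times are nonnegative and ``tracked_s`` >= summed object time per
    trial (non-engaged time is what the anhedonia index measures).
    """
    if len(traits) == 0:
        raise DataIntegrityError("traits table is empty")
    spec.validate()
    rng = spec.rng("behavior")
    n = len(traits)
    latent = traits["latent"].to_numpy()
    b_load = float(spec.latent_loadings.get("behavior", 0.0))

    ri_shift = _planted_shift(traits, spec.effect_sizes.get("ri", []))
    anh_shift = _planted_shift(traits, spec.effect_sizes.get("anhedonia", []))
    hab_shift = _planted_shift(traits, spec.effect_sizes.get("habituation", []))

    # subject-level anhedonia propensity (fraction of tracked time not at odors)
    anh_subj = np.clip(
        spec.anhedonia_mean
        + spec.anhedonia_sd * (anh_shift + b_load * latent)
        + spec.anhedonia_sd * rng.standard_normal(n),
        0.05,
        0.95,
    )

    records = []

    def emit(i, task, trial, obj, odor, conc, t_inv, tracked):
        records.append(
            (
                traits["subject_id"].iat[i],
                task,
                trial,
                obj,
                odor,
                conc,
                float(t_inv),
                float(tracked),
            )
        )

    base = spec.base_investigation_s
    for i in range(n):
        # --- preference: investigation scales with concentration rank ---
        for trial in range(1, 5):
            times = []
            for rank, conc in enumerate(PREFERENCE_CONCENTRATIONS):
                mu = base * (0.6 + 0.2 * rank)
                times.append(max(0.0, mu + spec.noise_sd * rng.standard_normal()))
            tracked = sum(times) / (1 - anh_subj[i])
            for rank, conc in enumerate(PREFERENCE_CONCENTRATIONS):
                emit(i, "preference", trial, f"obj{rank + 1}", "lemon", conc, times[rank], tracked)

        # --- habituation / dishabituation ---
        decay = spec.habituation_decay * (1 + 0.02 * hab_shift[i])
        for trial in range(1, 6):
            times = []
            for obj in range(4):
                if trial <= 4:
                    mu = base * decay ** (trial - 1)
                    odor, conc = "lemon", 0.01
                elif obj == 0:  # odor-switched object, novelty rebound
                    mu = base * decay**3 * (1 + spec.dishabituation_bump + 0.3 * b_load * latent[i])
                    odor, conc = "vanilla", 0.01
                else:
                    mu = base * decay**4
                    odor, conc = "lemon", 0.01
                times.append(max(0.0, mu + spec.noise_sd * rng.standard_normal()))
            tracked = sum(times) / (1 - anh_subj[i])
            for obj in range(4):
                odor = "vanilla" if (trial == 5 and obj == 0) else "lemon"
                emit(i, "habituation", trial, f"obj{obj + 1}", odor, 0.01, times[obj], tracked)

        # --- delayed recognition memory ---
        for probe_idx, probe in enumerate(MEMORY_PROBES):
            ri_mu = (0.65, 0.60, 0.55)[probe_idx]
            ri = np.clip(
                ri_mu
                + spec.ri_sd * (ri_shift[i] + b_load * latent[i])
                + spec.ri_sd * rng.standard_normal(),
                0.02,
                0.98,
            )
            total = max(1.0, 12.0 + 2.0 * rng.standard_normal())
            novel_t, familiar_t = total * ri, total * (1 - ri)
            tracked = total / (1 - anh_subj[i])
            novel_odor = ("almond", "anise", "banana")[probe_idx]
            emit(i, f"memory_{probe}", probe_idx + 1, "novel", novel_odor, 0.01, novel_t, tracked)
            emit(i, f"memory_{probe}", probe_idx + 1, "familiar", "coconut", 0.01, familiar_t, tracked)

    return pd.DataFrame(
        records,
        columns=[
            "subject_id",
            "task",
            "trial",
            "object",
            "odor",
            "concentration",
            "investigation_s",
            "tracked_s",
        ],
    )


# ---------------------------------------------------------------------------
# Connectomes
# ---------------------------------------------------------------------------


def planted_edges(spec: SimulationSpec, labels: list[str]) -> list[tuple[int, int]]:
    """Upper-triangle (i, j) index pairs carrying the latent factor,
    drawn deterministically from the connectome seed stream."""
    conn = spec.latent_loadings.get("connectome", {})
    n_edges = int(conn.get("n_edges", 0))
    if n_edges == 0:
        return []
    p = len(labels)
    iu = np.triu_indices(p, k=1)
    pick_rng = np.random.default_rng([spec.seed, _SEED_STREAMS["connectome"], 99])
    chosen = pick_rng.choice(len(iu[0]), size=min(n_edges, len(iu[0])), replace=False)
    return [(int(iu[0][c]), int(iu[1][c])) for c in sorted(chosen)]


def generate_connectomes(
    traits: pd.DataFrame, spec: SimulationSpec, region_labels: list[str] | None = None
) -> list["Connectome"]:
    """Symmetric nonnegative integer streamline-count matrices, one per
    subject.  Designated edges covary with the subject's latent score at
    the configured loading; all other edges are independent noise around a
    per-edge baseline."""
    from .integration import Connectome  # deferred: integration owns the type

    spec.validate()
    labels = list(region_labels) if region_labels is not None else default_region_labels(spec.n_regions)
    if len(labels) < 3:
        raise ConfigurationError("need at least 3 regions for a connectome")
    rng = spec.rng("connectome")
    n, p = len(traits), len(labels)
    iu = np.triu_indices(p, k=1)
    n_edges_total = len(iu[0])

    # stable per-edge baseline so streamline counts differ across pairs
    base = spec.streamline_mean * np.exp(0.3 * rng.standard_normal(n_edges_total))

    conn_cfg = spec.latent_loadings.get("connectome", {})
    loading = float(conn_cfg.get("loading", 0.0))
    flat_of_pair = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu[0], iu[1]))}
    planted_flat = sorted(flat_of_pair[pair] for pair in planted_edges(spec, labels))
    latent = traits["latent"].to_numpy()

    out = []
    for s in range(n):
        g = rng.standard_normal(n_edges_total)
        if loading and planted_flat:
            idx = np.asarray(planted_flat, dtype=int)
            g[idx] = loading * latent[s] + np.sqrt(1 - loading**2) * rng.standard_normal(len(idx))
        counts = np.maximum(0, np.rint(base + spec.streamline_sd * g)).astype(int)
        A = np.zeros((p, p), dtype=int)
        A[iu] = counts
        A = A + A.T
        out.append(Connectome(region_labels=labels, adjacency=A))
    return out


# ---------------------------------------------------------------------------
# Module scores shared by imaging and expression
# ---------------------------------------------------------------------------


def module_scores(spec: SimulationSpec, n_subjects: int) -> np.ndarray:
    """(subjects x modules) standard-normal ground-truth module scores.

    Drawn from a dedicated seed stream so the imaging and expression
    generators plant correlations against the *same* latent modules."""
    rng = spec.rng("modules")
    return rng.standard_normal((n_subjects, spec.n_modules))


# ---------------------------------------------------------------------------
# Imaging metrics
# ---------------------------------------------------------------------------


def generate_imaging_metrics(
    traits: pd.DataFrame,
    spec: SimulationSpec,
    regions: tuple | None = None,
    metrics: tuple | None = None,
) -> pd.DataFrame:
    """Long table of subject x region x metric values.

    Cells listed in ``spec.planted_imaging_cells`` correlate with the
    designated expression module score at ``spec.eigengene_metric_r``;
    everything else is independent noise on a metric-plausible scale.
    FA is clipped to [0, 1]."""
    spec.validate()
    regions = tuple(regions) if regions is not None else APRIORI_REGIONS
    metrics = tuple(metrics) if metrics is not None else IMAGING_METRICS
    for m in metrics:
        if m not in KNOWN_METRICS:
            raise ConfigurationError(f"unknown imaging metric {m!r}")
    rng = spec.rng("imaging")
    n = len(traits)
    ms = module_scores(spec, n)
    planted = {
        (reg, met): mod for reg, met, mod in spec.planted_imaging_cells
    }
    r = spec.eigengene_metric_r

    rows = []
    for region in regions:
        for metric in metrics:
            mu, sd = _METRIC_SCALE[metric]
            mod = planted.get((region, metric))
            if mod is not None and mod < spec.n_modules and r != 0:
                z = r * ms[:, mod] + np.sqrt(1 - r**2) * rng.standard_normal(n)
            else:
                z = rng.standard_normal(n)
            values = mu + sd * z
            if metric == "FA":
                values = np.clip(values, 0.0, 1.0)
            elif metric != "NG":
                values = np.maximum(values, 0.0)
            for i in range(n):
                rows.append((traits["subject_id"].iat[i], region, metric, float(values[i])))
    return pd.DataFrame(rows, columns=["subject_id", "region", "metric", "value"])


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def gene_symbols(spec: SimulationSpec) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(spec.n_genes)]


def module_gene_blocks(spec: SimulationSpec) -> dict[int, list[str]]:
    """Module index -> planted member genes (contiguous blocks)."""
    genes = gene_symbols(spec)
    blocks = {}
    for m in range(spec.n_modules):
        start = m * spec.module_size
        blocks[m] = genes[start : start + spec.module_size]
    return blocks


def generate_expression(
    traits: pd.DataFrame, spec: SimulationSpec, tissues: tuple = ("blood",)
) -> dict[str, pd.DataFrame]:
    """Per-tissue genes x subjects negative-binomial count matrices.

    Gene blocks load on the shared module scores; brain tissues see the
    blood module scores mixed at ``spec.shared_module_r`` so blood-brain
    PC coupling is recoverable.  Library sizes are log-normal (CV
    ``spec.library_cv``) so the CPM normalization step matters."""
    spec.validate()
    if spec.n_genes < 50:
        raise ConfigurationError("need at least 50 genes")
    if not tissues:
        raise ConfigurationError("tissues must be non-empty")
    rng = spec.rng("expression")
    n = len(traits)
    genes = gene_symbols(spec)
    blocks = module_gene_blocks(spec)
    ms_blood = module_scores(spec, n)

    base_logmean = rng.normal(3.0, 1.0, size=spec.n_genes)  # log counts scale
    sigma_lib = np.sqrt(np.log(1 + spec.library_cv**2))

    out = {}
    for tissue in tissues:
        if tissue == "blood":
            ms = ms_blood
        else:
            rho = spec.shared_module_r
            ms = rho * ms_blood + np.sqrt(1 - rho**2) * rng.standard_normal(ms_blood.shape)
        log_mu = np.tile(base_logmean[:, None], (1, n))
        for m, members in blocks.items():
            if not members:  # module blocks beyond the gene count
                continue
            idx = np.asarray([genes.index(g) for g in members], dtype=int)
            scale = spec.module_loading * spec.module_decay**m
            # signed loadings: half of each module loads negatively, so a
            # module is a within-library contrast (as real expression PCs
            # are) rather than a library-size shift
            signs = np.where(np.arange(len(idx)) % 2 == 0, 1.0, -1.0)
            log_mu[idx, :] += scale * signs[:, None] * ms[:, m][None, :]
        lib = np.exp(rng.normal(0.0, sigma_lib, size=n))
        mu = np.exp(log_mu) * lib[None, :]
        if spec.dispersion > 0:
            size = 1.0 / spec.dispersion
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p)
        else:
            counts = rng.poisson(mu)
        out[tissue] = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                                   columns=traits["subject_id"].tolist())
    return out


def exact_correlation_pair(r: float, n: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two length-n vectors whose *sample* Pearson correlation equals r
    exactly (by Gram-Schmidt construction), for calibration checks."""
    if not -1 <= r <= 1:
        raise ConfigurationError("correlation must be in [-1, 1]")
    if n < 3:
        raise ConfigurationError("need n >= 3")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a -= a.mean()
    a /= np.linalg.norm(a)
    b -= b.mean()
    b -= (b @ a) * a
    b /= np.linalg.norm(b)
    return a, r * a + np.sqrt(1 - r**2) * b


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    out_dir: str | Path,
    spec: SimulationSpec,
    tissues: tuple = ("blood", "hippocampus"),
    region_labels: list[str] | None = None,
) -> dict:
    """Write every synthetic table plus a JSON manifest of seeds and
    parameters.  Re-running with the same spec reproduces every file
    byte-identically (the manifest records sha256 checksums)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec.validate()

    traits = generate_traits(spec)
    trials = generate_behavior(traits, spec)
    connectomes = generate_connectomes(traits, spec, region_labels)
    imaging = generate_imaging_metrics(traits, spec)
    expr = generate_expression(traits, spec, tissues)

    files = {}

    def write_csv(df, name, sep=","):
        path = out / name
        df.to_csv(path, sep=sep, index=False, float_format="%.10g")
        files[name] = _sha256(path)

    write_csv(traits, "traits.csv")
    write_csv(trials, "behavior_trials.csv")
    write_csv(imaging, "imaging.csv")
    for conn, sid in zip(connectomes, traits["subject_id"]):
        name = f"connectome_{sid}.tsv"
        path = out / name
        pd.DataFrame(conn.adjacency, index=conn.region_labels, columns=conn.region_labels).to_csv(
            path, sep="\t"
        )
        files[name] = _sha256(path)
    for tissue, mat in expr.items():
        name = f"expr_{tissue}.tsv"
        path = out / name
        mat.to_csv(path, sep="\t")
        files[name] = _sha256(path)

    manifest = {
        "seed": spec.seed,
        "seed_streams": dict(_SEED_STREAMS),
        "parameters": _jsonable_spec(spec),
        "tissues": list(tissues),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable_spec(spec: SimulationSpec) -> dict:
    d = asdict(spec)
    if d.get("cell_counts"):
        d["cell_counts"] = {f"{a}|{b}": v for (a, b), v in d["cell_counts"].items()}
    d["effect_sizes"] = {
        k: [[cond, s] for cond, s in v] for k, v in d["effect_sizes"].items()
    }
    d["planted_imaging_cells"] = [list(c) for c in d["planted_imaging_cells"]]
    return d
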
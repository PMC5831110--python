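"""Synthetic multi-batch expression compendia with known ground truth.

The generator emulates the statistical structure of a multi-study microarray
compendium on a log2-like scale: every sample expresses a shared gene-baseline
profile (which makes the first principal component of the sample correlation
matrix dominant, as it is on real arrays), a small set of "module" genes is
planted with exact population Pearson correlation to a designated seed gene,
the remaining genes are independent null genes, and a few injected outlier
columns carry pure noise with no shared profile (emulating degraded arrays).
Linked clinical tables with group-dependent exponential survival can be drawn
for the same samples.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionBatch",
    "SimConfig",
    "GroundTruth",
    "ClinicalSimConfig",
    "generate_compendium",
    "generate_clinical",
    "write_fixture_bundle",
    "PATHWAY_CATEGORIES",
]

# The nine single-assignment pathway categories used for annotation.
PATHWAY_CATEGORIES = (
    "BCR signaling",
    "cytoskeleton regulation",
    "DNA repair and cell cycle",
    "histone modification",
    "immune regulation",
    "metabolism",
    "protein processing",
    "RNA processing",
    "signaling protein",
)


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class ExpressionBatch:
    """One batch's probe x sample expression matrix.

    A batch is a platform x experiment grouping within which associations are
    computed before cross-batch pooling.
    """

    batch_id: str
    data: pd.DataFrame  # rows: probes, columns: samples

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GroundTruth:
    """What the simulator planted: truly associated genes, outliers, batches."""

    associated_genes: dict[str, float]  # gene symbol -> generating correlation
    outlier_samples: set[str]
    batch_assignments: dict[str, str]  # sample id -> batch id

    def to_json(self) -> str:
        return json.dumps(
            {
                "associated_genes": self.associated_genes,
                "outlier_samples": sorted(self.outlier_samples),
                "batch_assignments": self.batch_assignments,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            associated_genes=dict(d["associated_genes"]),
            outlier_samples=set(d["outlier_samples"]),
            batch_assignments=dict(d["batch_assignments"]),
        )


@dataclass
class SimConfig:
    """Parameters of the synthetic compendium.

    Defaults give three batches totalling 1,200 samples, 2,000 genes, and a
    50-gene module planted at Pearson correlations 0.5..0.9 with the seed —
    the stock fixture every downstream stage is exercised on.
    """

    n_batches: int = 3
    samples_per_batch: Sequence[int] = (500, 400, 300)
    n_genes: int = 2000
    probes_per_gene: int | Mapping[int, float] = 1
    seed_gene: str = "MS4A1"
    module_size: int = 50
    module_correlations: Sequence[float] | None = None  # default linspace(.5,.9)
    common_factor_sd: float = 2.0
    batch_shift_sd: float = 0.5
    noise_sd: float = 0.8
    sample_factor_sd: float = 0.0
    probe_noise_sd: float = 0.1
    outlier_sd: float = 2.0
    n_outliers: int = 6
    rng_seed: int = 0

    baseline_mean: float = 8.0  # RMA-like log2 scale

    def resolved_correlations(self) -> np.ndarray:
        if self.module_correlations is not None:
            return np.asarray(list(self.module_correlations), dtype=float)
        if self.module_size == 0:
            return np.empty(0)
        if self.module_size == 1:
            return np.array([0.9])
        return np.linspace(0.5, 0.9, self.module_size)

    def validate(self) -> None:
        if self.n_batches < 1:
            raise SimulationConfigError("n_batches must be >= 1")
        spb = list(self.samples_per_batch)
        if len(spb) != self.n_batches:
            raise SimulationConfigError(
                "samples_per_batch must list one size per batch "
                f"(got {len(spb)} sizes for n_batches={self.n_batches})"
            )
        if any(n < 2 for n in spb):
            raise SimulationConfigError("samples_per_batch entries must be >= 2")
        if not 0 <= self.module_size < self.n_genes:
            raise SimulationConfigError("module_size must satisfy 0 <= module_size < n_genes")
        rho = self.resolved_correlations()
        if len(rho) != self.module_size:
            raise SimulationConfigError(
                "module_correlations length must equal module_size "
                f"({len(rho)} != {self.module_size})"
            )
        if rho.size and (np.abs(rho) >= 1).any():
            raise SimulationConfigError("module_correlations must lie strictly inside (-1, 1)")
        if self.noise_sd <= 0:
            raise SimulationConfigError("noise_sd must be > 0")
        for name in ("common_factor_sd", "batch_shift_sd", "sample_factor_sd",
                     "probe_noise_sd", "outlier_sd"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        if self.n_outliers < 0:
            raise SimulationConfigError("n_outliers must be >= 0")
        if isinstance(self.probes_per_gene, Mapping):
            probs = np.array(list(self.probes_per_gene.values()), dtype=float)
            if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
                raise SimulationConfigError("probes_per_gene distribution must sum to 1")
            if any(int(k) < 1 for k in self.probes_per_gene):
                raise SimulationConfigError("probes_per_gene counts must be >= 1")
        elif int(self.probes_per_gene) < 1:
            raise SimulationConfigError("probes_per_gene must be >= 1")


def _gene_symbols(config: SimConfig) -> tuple[list[str], list[str]]:
    """Return (module gene symbols, null gene symbols); seed is separate."""
    width = len(str(max(config.n_genes, 1)))
    module = [f"COEX{i + 1:0{width}d}" for i in range(config.module_size)]
    n_null = config.n_genes - config.module_size - 1  # minus the seed itself
    null = [f"GENE{i + 1:0{width}d}" for i in range(n_null)]
    return module, null


def _draw_probe_counts(config: SimConfig, genes: Sequence[str],
                       rng: np.random.Generator) -> dict[str, int]:
    if isinstance(config.probes_per_gene, Mapping):
        counts = np.array([int(k) for k in config.probes_per_gene], dtype=int)
        probs = np.array([config.probes_per_gene[k] for k in config.probes_per_gene],
                         dtype=float)
        draws = rng.choice(counts, size=len(genes), p=probs / probs.sum())
    else:
        draws = np.full(len(genes), int(config.probes_per_gene))
    return dict(zip(genes, (int(d) for d in draws)))


def generate_compendium(config: SimConfig) -> tuple[list[ExpressionBatch], GroundTruth]:
    """Simulate a multi-batch compendium with a planted seed-correlated module.

    Per batch, gene-level expression is

        x[g, j] = baseline_mean + loading[g] * f[j] + shift[b, g]
                  + module term + noise[g, j]

    with ``loading ~ N(0, common_factor_sd^2)`` shared across batches and
    ``f[j] = 1 + sample_factor_sd * xi[j]``. Module gene deviations are exact
    scaled copies of the seed's deviation plus independent noise so the
    population Pearson correlation with the seed equals the configured value;
    negative targets flip the sign of the copy. Outlier samples are replaced
    by pure noise columns carrying no shared profile. Probe-level rows add
    probe offsets and ``probe_noise_sd`` jitter around the gene value.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    module_genes, null_genes = _gene_symbols(config)
    rhos = config.resolved_correlations()
    genes = [config.seed_gene] + module_genes + null_genes

    probe_counts = _draw_probe_counts(config, genes, rng)
    probe_ids: list[str] = []
    probe_gene: list[str] = []
    for g in genes:
        for k in range(probe_counts[g]):
            probe_ids.append(f"{g}.p{k + 1}")
            probe_gene.append(g)
    probe_gene_arr = np.array(probe_gene)
    n_probes = len(probe_ids)

    loading = rng.normal(0.0, config.common_factor_sd, size=len(genes))
    probe_offset = rng.normal(0.0, config.probe_noise_sd, size=n_probes)

    # Spread injected outliers over batches deterministically.
    outlier_batches = rng.integers(0, config.n_batches, size=config.n_outliers)

    batches: list[ExpressionBatch] = []
    outlier_samples: set[str] = set()
    batch_assignments: dict[str, str] = {}
    gene_index = {g: i for i, g in enumerate(genes)}

    for b, n in enumerate(config.samples_per_batch):
        batch_id = f"B{b + 1:02d}"
        sample_ids = [f"{batch_id}.S{j + 1:03d}" for j in range(n)]
        for s in sample_ids:
            batch_assignments[s] = batch_id

        f = 1.0 + config.sample_factor_sd * rng.standard_normal(n)
        shift = rng.normal(0.0, config.batch_shift_sd, size=len(genes))
        seed_dev = rng.normal(0.0, config.noise_sd, size=n)

        dev = rng.normal(0.0, config.noise_sd, size=(len(genes), n))
        dev[gene_index[config.seed_gene]] = seed_dev
        for g, rho in zip(module_genes, rhos):
            eps = rng.normal(0.0, config.noise_sd, size=n)
            dev[gene_index[g]] = rho * seed_dev + np.sqrt(1.0 - rho**2) * eps

        gene_expr = (config.baseline_mean
                     + np.outer(loading, f)
                     + shift[:, None]
                     + dev)

        # probe rows: gene value + probe offset + probe jitter
        probe_rows = gene_expr[[gene_index[g] for g in probe_gene], :]
        if config.probe_noise_sd > 0:
            probe_rows = (probe_rows + probe_offset[:, None]
                          + rng.normal(0.0, config.probe_noise_sd, size=probe_rows.shape))

        n_out = int((outlier_batches == b).sum())
        if n_out:
            out_idx = rng.choice(n, size=min(n_out, n), replace=False)
            for j in out_idx:
                probe_rows[:, j] = config.baseline_mean + rng.normal(
                    0.0, config.outlier_sd, size=n_probes
                )
                outlier_samples.add(sample_ids[j])

        batches.append(ExpressionBatch(
            batch_id=batch_id,
            data=pd.DataFrame(probe_rows, index=probe_ids, columns=sample_ids),
        ))

    truth = GroundTruth(
        associated_genes={g: float(r) for g, r in zip(module_genes, rhos)},
        outlier_samples=outlier_samples,
        batch_assignments=batch_assignments,
    )
    return batches, truth


def probe_map_frame(batches: Sequence[ExpressionBatch]) -> pd.DataFrame:
    """Probe-to-gene map recovered from the simulator's probe naming."""
    probes = list(dict.fromkeys(p for b in batches for p in b.probe_ids))
    return pd.DataFrame({
        "probe_id": probes,
        "gene_symbol": [p.rsplit(".p", 1)[0] for p in probes],
    })


# ---------------------------------------------------------------------------
# clinical metadata
# ---------------------------------------------------------------------------

COO_LEVELS = ("ABC", "GCB", "unclassified")
ARM_LEVELS = ("CHOP", "R-CHOP", "other")


@dataclass
class ClinicalSimConfig:
    """Group-dependent exponential survival for simulated patients.

    Cell-of-origin proportions default to the composition of a large pooled
    lymphoma cohort (35.2% ABC / 49.3% GCB / 15.5% unclassified); treatment
    arms default to the same cohort's CHOP / R-CHOP / other split. Hazards are
    per month; ``log_hazard_effects`` maps a covariate label (an expression
    group, arm, or cell-of-origin level) to its additive log hazard ratio.
    """

    n_patients: int = 1000
    coo_probs: Sequence[float] = (0.352, 0.493, 0.155)
    arm_probs: Sequence[float] = (0.233, 0.719, 0.048)
    baseline_hazard: float = 0.02
    log_hazard_effects: Mapping[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.01
    rng_seed: int = 0

    def validate(self) -> None:
        for name, probs, levels in (("coo_probs", self.coo_probs, COO_LEVELS),
                                    ("arm_probs", self.arm_probs, ARM_LEVELS)):
            p = np.asarray(list(probs), dtype=float)
            if len(p) != len(levels):
                raise SimulationConfigError(f"{name} must have {len(levels)} entries")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise SimulationConfigError(f"{name} must be nonnegative and sum to 1")
        if self.baseline_hazard <= 0:
            raise SimulationConfigError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise SimulationConfigError("censoring_rate must be >= 0")
        if self.n_patients < 1:
            raise SimulationConfigError("n_patients must be >= 1")


VALID_GROUP_LABELS = frozenset({"high", "low"})


def generate_clinical(config: ClinicalSimConfig,
                      expression_groups: Mapping[str, str]) -> pd.DataFrame:
    """Draw a clinical table for the given sample -> expression-group map.

    Event times are exponential with hazard ``baseline_hazard *
    exp(sum of log-hazard effects)`` where effects are looked up by the
    record's expression group, arm, and cell-of-origin labels; censoring is
    independent exponential at ``censoring_rate`` (0 disables censoring).
    """
    config.validate()
    unknown = set(expression_groups.values()) - VALID_GROUP_LABELS
    if unknown:
        raise ValueError(f"unknown expression group label(s): {sorted(unknown)}")

    samples = list(expression_groups)
    if len(samples) != config.n_patients:
        # the map defines the cohort; n_patients is advisory when they differ
        pass
    rng = np.random.default_rng(config.rng_seed)
    n = len(samples)

    coo = rng.choice(COO_LEVELS, size=n, p=np.asarray(config.coo_probs, dtype=float))
    arm = rng.choice(ARM_LEVELS, size=n, p=np.asarray(config.arm_probs, dtype=float))
    groups = np.array([expression_groups[s] for s in samples])

    log_hr = np.zeros(n)
    for label, eff in config.log_hazard_effects.items():
        for labels in (groups, arm, coo):
            log_hr += np.where(labels == label, float(eff), 0.0)

    hazard = config.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)

    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    return pd.DataFrame({
        "sample_id": samples,
        "time": time,
        "event": event,
        "arm": arm,
        "coo": coo,
        "group": groups,
    })


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def _default_gene_sets(truth: GroundTruth, seed_gene: str,
                       universe: Sequence[str]) -> dict[str, list[str]]:
    """Gene sets for enrichment/exclusion tests, built from the ground truth.

    Planted genes are spread round-robin over the nine pathway categories;
    the "BCR signaling" set (the exclusion set downstream) gets the seed too.
    """
    planted = sorted(truth.associated_genes)
    sets: dict[str, list[str]] = {c.upper().replace(" ", "_"): [] for c in PATHWAY_CATEGORIES}
    names = list(sets)
    for i, g in enumerate(planted):
        sets[names[i % len(names)]].append(g)
    sets["BCR_SIGNALING"] = sorted(set(sets["BCR_SIGNALING"]) | {seed_gene})
    # one decoy set of null genes so enrichment has a negative control
    null_genes = [g for g in universe if g not in truth.associated_genes and g != seed_gene]
    sets["NULL_DECOY"] = null_genes[: max(5, len(planted) // 2)]
    return {k: v for k, v in sets.items() if v}


def _default_interactions(truth: GroundTruth, universe: Sequence[str]) -> pd.DataFrame:
    """A small drug-gene interaction table covering planted and null genes."""
    planted = sorted(truth.associated_genes)
    rows = []
    for i, g in enumerate(planted[: max(1, 2 * len(planted) // 3)]):
        rows.append((g, f"drug{i + 1:03d}", "synthetic-interactions"))
    null_genes = [g for g in universe if g not in truth.associated_genes][:10]
    for i, g in enumerate(null_genes):
        rows.append((g, f"nulldrug{i + 1:02d}", "synthetic-interactions"))
    return pd.DataFrame(rows, columns=["gene", "drug", "source"])


def write_fixture_bundle(outdir: str | Path,
                         config: SimConfig | None = None,
                         clinical_config: ClinicalSimConfig | None = None) -> dict[str, Path]:
    """Write a complete synthetic input bundle that round-trips through io.

    Emits one GCT and one TSV matrix per batch, the probe map, gene sets
    (GMT), a drug-interaction table, a clinical table keyed to the samples of
    the first batch (median split on the seed gene), and the ground truth.
    Returns a name -> path map.
    """
    from . import io as cio
    from .clinical import dichotomize_expression

    config = config or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    batches, truth = generate_compendium(config)

    paths: dict[str, Path] = {}
    for b in batches:
        gct = outdir / f"expr_{b.batch_id}.gct"
        tsv = outdir / f"expr_{b.batch_id}.tsv"
        cio.write_gct(gct, b.data)
        cio.write_matrix_tsv(tsv, b.data)
        paths[f"gct_{b.batch_id}"] = gct
        paths[f"tsv_{b.batch_id}"] = tsv

    pmap = probe_map_frame(batches)
    paths["probe_map"] = outdir / "probe_map.tsv"
    pmap.to_csv(paths["probe_map"], sep="\t", index=False)

    genes = sorted(set(pmap["gene_symbol"]))
    sets = _default_gene_sets(truth, config.seed_gene, genes)
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    cio.write_gmt(paths["gene_sets"], sets)

    inter = _default_interactions(truth, genes)
    paths["interactions"] = outdir / "interactions.tsv"
    inter.to_csv(paths["interactions"], sep="\t", index=False)

    clinical_config = clinical_config or ClinicalSimConfig(
        n_patients=batches[0].n_samples, rng_seed=config.rng_seed
    )
    seed_probes = pmap.loc[pmap["gene_symbol"] == config.seed_gene, "probe_id"]
    seed_expr = batches[0].data.loc[seed_probes].mean(axis=0)
    groups = dichotomize_expression(seed_expr.to_numpy())
    group_map = dict(zip(batches[0].sample_ids, groups))
    clin = generate_clinical(clinical_config, group_map)
    paths["clinical"] = outdir / "clinical.tsv"
    clin.to_csv(paths["clinical"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(truth.to_json())

    paths["sim_config"] = outdir / "sim_config.json"
    cfg = dataclasses.asdict(config)
    cfg["samples_per_batch"] = list(cfg["samples_per_batch"])
    if cfg["module_correlations"] is not None:
        cfg["module_correlations"] = [float(r) for r in cfg["module_correlations"]]
    paths["sim_config"].write_text(json.dumps(cfg, indent=1, default=float))
    return paths
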
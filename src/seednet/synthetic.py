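"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator plants a single co-expressed module spanning the seed genes
and a set of linker genes: module gene values follow a one-factor model
``x_g = lambda * f + eps`` with ``f ~ N(0,1)`` per sample and unit noise,
where ``lambda = sqrt(rho / (1 - rho))`` gives an expected pairwise
correlation of ``rho`` between module genes.  Background genes are
independent noise.  The PPI graph is an Erdos-Renyi background plus the
planted module edges (each included with a coverage probability), written
in the STRING links dialect.  Survival is exponential, with the hazard
multiplied by a chosen ratio for samples in the top half of the latent
factor, independent censoring, and a stated fraction of samples lacking
clinical records.  Everything is reproducible from one integer seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as io_formats
from .types import SeednetError, validate_graph

BASELINE_HAZARD = np.log(2) / 500.0  # baseline median survival of 500 days


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; the defaults describe the reference scenario
    used throughout the test-bed: a 10-gene planted module (5 seeds + 5
    linkers) among 300 background genes, 100 samples, within-module
    correlation 0.8, and a clinical table in which 16/179 of samples lack
    survival records."""

    n_genes: int = 310
    n_samples: int = 100
    n_seeds: int = 5
    n_planted_linkers: int = 5
    module_corr: float = 0.8
    background_edge_prob: float = 0.01
    ppi_cover_prob: float = 1.0
    hazard_ratio: float = 3.0
    censor_rate: float = 0.3
    missing_clinical_frac: float = 16 / 179
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds + self.n_planted_linkers > self.n_genes:
            raise SeednetError("module larger than the gene universe")
        for name in ("module_corr", "background_edge_prob"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise SeednetError(f"{name} must lie in (0, 1)")
        if not 0 < self.ppi_cover_prob <= 1:
            raise SeednetError("ppi_cover_prob must lie in (0, 1]")
        if self.hazard_ratio <= 0:
            raise SeednetError("hazard_ratio must be positive")
        if not 0 <= self.censor_rate < 1:
            raise SeednetError("censor_rate must lie in [0, 1)")
        if not 0 <= self.missing_clinical_frac < 1:
            raise SeednetError("missing_clinical_frac must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted structure for recovery checks."""

    seeds: list[str]
    planted_linkers: list[str]
    module_genes: list[str]
    factor: dict[str, float]
    high_risk_samples: list[str] = field(default_factory=list)


def module_loading(module_corr: float) -> float:
    """Factor loading giving expected pairwise correlation ``module_corr``
    under unit noise: r = lambda^2 / (lambda^2 + 1)."""
    if not 0 < module_corr < 1:
        raise SeednetError("module_corr must lie in (0, 1) for a finite loading")
    return float(np.sqrt(module_corr / (1.0 - module_corr)))


def simulate_clinical(
    sample_ids,
    high_mask: np.ndarray,
    hazard_ratio: float,
    censor_rate: float,
    missing_frac: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential survival with a binary hazard group.

    ``high_mask`` marks samples whose hazard is ``BASELINE_HAZARD *
    hazard_ratio``.  A ``censor_rate`` fraction of samples (rounded) is
    censored at a uniform fraction of their event time; a
    ``missing_frac`` fraction (rounded) loses both ``os_days`` and
    ``event``.  Covariates gender/alcohol/smoking are independent coin
    flips, unrelated to expression or survival.
    """
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    hazard = np.where(np.asarray(high_mask, bool), BASELINE_HAZARD * hazard_ratio, BASELINE_HAZARD)
    t_event = rng.exponential(1.0 / hazard)
    event = np.ones(n, dtype=float)
    os_days = t_event.copy()

    n_censor = int(round(censor_rate * n))
    censored_idx = rng.choice(n, size=n_censor, replace=False)
    os_days[censored_idx] = t_event[censored_idx] * rng.uniform(size=n_censor)
    event[censored_idx] = 0.0

    clinical = pd.DataFrame(
        {
            "os_days": np.round(os_days, 1),
            "event": event,
            "gender": rng.choice(["male", "female"], size=n),
            "alcohol": rng.choice(["yes", "no"], size=n),
            "smoking": rng.choice(["yes", "no"], size=n),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    n_missing = int(round(missing_frac * n))
    missing_idx = rng.choice(n, size=n_missing, replace=False)
    clinical.iloc[missing_idx, clinical.columns.get_loc("os_days")] = np.nan
    clinical.iloc[missing_idx, clinical.columns.get_loc("event")] = np.nan
    return clinical


def generate_cohort(params: SynthParams | None = None):
    """Generate (ppi_graph, expression, seed_list, clinical, truth).

    See the module docstring for the generative model.  Outputs are
    byte-identical for a fixed ``rng_seed``.
    """
    if params is None:
        params = SynthParams()
    rng = np.random.default_rng(params.rng_seed)

    seeds = [f"SEED{i + 1:02d}" for i in range(params.n_seeds)]
    linkers = [f"LINK{i + 1:02d}" for i in range(params.n_planted_linkers)]
    n_bg = params.n_genes - params.n_seeds - params.n_planted_linkers
    background = [f"BG{i + 1:04d}" for i in range(n_bg)]
    module = seeds + linkers
    genes = module + background
    samples = [f"S{i + 1:03d}" for i in range(params.n_samples)]

    lam = module_loading(params.module_corr)
    factor = rng.standard_normal(params.n_samples)
    values = np.empty((params.n_genes, params.n_samples))
    for gi, g in enumerate(genes):
        noise = rng.standard_normal(params.n_samples)
        if g in set(module):
            values[gi] = lam * factor + noise
        else:
            values[gi] = noise
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)

    ppi = nx.Graph()
    # planted module interactions: seed-linker and linker-linker pairs,
    # each covered with ppi_cover_prob.  Seed-seed pairs are left to the
    # background rate so that, as in the disease setting being emulated,
    # seeds connect through linker genes rather than directly.
    seed_set = set(seeds)
    planted_pairs = {
        (module[i], module[j])
        for i in range(len(module))
        for j in range(i + 1, len(module))
        if not (module[i] in seed_set and module[j] in seed_set)
    }
    for u, v in sorted(planted_pairs):
        if rng.uniform() < params.ppi_cover_prob:
            score = int(rng.integers(700, 1000))
            ppi.add_edge(u, v, weight=score / 1000.0)
    # Erdos-Renyi background over the whole gene universe
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if (genes[i], genes[j]) in planted_pairs:
                continue
            if rng.uniform() < params.background_edge_prob:
                score = int(rng.integers(150, 1000))
                ppi.add_edge(genes[i], genes[j], weight=score / 1000.0)
    validate_graph(ppi)

    high_mask = factor > np.median(factor)
    clinical = simulate_clinical(
        samples, high_mask, params.hazard_ratio, params.censor_rate,
        params.missing_clinical_frac, rng,
    )

    truth = SyntheticTruth(
        seeds=seeds,
        planted_linkers=linkers,
        module_genes=module,
        factor={s: float(f) for s, f in zip(samples, factor)},
        high_risk_samples=[s for s, h in zip(samples, high_mask) if h],
    )
    return ppi, expr, seeds, clinical, truth


def planted_linker_recovery(
    n_replicates: int = 20,
    base_seed: int = 0,
    params: SynthParams | None = None,
) -> list[float]:
    """Run the full pipeline on generated cohorts and score linker recovery.

    For each replicate the cohort is written to disk in the external file
    formats, the end-to-end pipeline is run on the files, and the
    precision of the top-``n_planted_linkers`` ranked linkers against the
    planted truth is recorded.  Returns the per-replicate precisions.
    """
    import tempfile

    from .pipeline import PipelineConfig, run_pipeline

    template = params or SynthParams()
    k = template.n_planted_linkers
    precisions = []
    for rep in range(n_replicates):
        p = SynthParams(**{**asdict(template), "rng_seed": base_seed + rep})
        outputs = generate_cohort(p)
        truth = outputs[4]
        with tempfile.TemporaryDirectory() as d:
            paths = write_fixture_bundle(outputs, d)
            cfg = PipelineConfig(
                ppi_path=str(paths["ppi"]),
                expression_path=str(paths["expression"]),
                seeds_path=str(paths["seeds"]),
                clinical_path=None,
                out_dir=str(Path(d) / "out"),
                rs_cutoff=None,
                top_k=k,
                rng_seed=p.rng_seed,
            )
            manifest = run_pipeline(cfg)
        candidates = manifest["stages"]["candidate_selection"]["genes"]
        precisions.append(len(set(candidates) & set(truth.planted_linkers)) / k)
    return precisions


def null_rejection_rate(
    n_reps: int = 1000,
    n_samples: int = 179,
    missing_frac: float = 16 / 179,
    censor_rate: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null replicates (no expression-survival link) rejected.

    Risk scores are independent of survival, so the log-rank test should
    reject at about the nominal rate.
    """
    from .clinical import stratify_and_test

    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    rejections = 0
    for _ in range(n_reps):
        scores = pd.Series(rng.standard_normal(n_samples), index=ids)
        clinical = simulate_clinical(
            ids, np.zeros(n_samples, bool), 1.0, censor_rate, missing_frac, rng
        )
        strat = stratify_and_test(scores, clinical, compute_km=False)
        rejections += strat.logrank_p < alpha
    return rejections / n_reps


def stratification_power(
    hazard_ratio: float = 3.0,
    n_reps: int = 100,
    n_samples: int = 200,
    censor_rate: float = 0.3,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of replicates with log-rank p below ``alpha`` when the
    planted high-score half of the cohort carries ``hazard_ratio`` times
    the baseline hazard."""
    from .clinical import stratify_and_test

    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    hits = 0
    for _ in range(n_reps):
        scores = pd.Series(rng.standard_normal(n_samples), index=ids)
        high = (scores > scores.median()).to_numpy()
        clinical = simulate_clinical(ids, high, hazard_ratio, censor_rate, 0.0, rng)
        strat = stratify_and_test(scores, clinical, compute_km=False)
        hits += strat.logrank_p < alpha
    return hits / n_reps


def write_fixture_bundle(outputs, directory) -> dict[str, Path]:
    """Write a generated cohort in the pipeline's external file formats.

    Produces ``ppi_links.txt`` (STRING dialect), ``expression.tsv``,
    ``clinical.tsv``, ``seeds.txt`` and ``truth.json`` under
    ``directory``; returns the path of each file.
    """
    ppi, expr, seeds, clinical, truth = outputs
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / fname for name, fname in (
        ("ppi", "ppi_links.txt"),
        ("expression", "expression.tsv"),
        ("clinical", "clinical.tsv"),
        ("seeds", "seeds.txt"),
        ("truth", "truth.json"),
    )}

    with open(paths["ppi"], "w", encoding="utf-8") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v, d in sorted((min(u, v), max(u, v), d) for u, v, d in ppi.edges(data=True)):
            score = int(round(d["weight"] * 1000))
            fh.write(f"{u} {v} {score}\n")
            fh.write(f"{v} {u} {score}\n")

    io_formats.write_expression_matrix(expr, paths["expression"])
    io_formats.write_clinical_table(clinical, paths["clinical"])
    paths["seeds"].write_text("\n".join(seeds) + "\n", encoding="utf-8")
    paths["truth"].write_text(json.dumps(asdict(truth), indent=1, sort_keys=True), encoding="utf-8")
    return paths
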
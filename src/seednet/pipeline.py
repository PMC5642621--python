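"""End-to-end orchestration of the candidate-gene workflow.

Stages, in order: read inputs; build the co-expression network; intersect
with the PPI network into the common network; filter the seed list; run
limited k-walks and extract the seed-connecting subnetwork; rank linkers
by ranking score; select candidates; extract the minimal subnetwork
connecting them; seed-candidate correlation and covariate statistics; and
median-split survival stratification of the candidate signature.  Every
intermediate artifact is written to the output directory and a manifest
JSON records input digests, parameters and the counts at each stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import clinical as clinical_mod
from . import coexpr, io, kwalks, ranking
from .coexpr import CoexprParams
from .types import SeednetError

logger = logging.getLogger(__name__)

STAGES = (
    "read_inputs",
    "coexpression_network",
    "common_network",
    "seed_filter",
    "kwalks_subnetwork",
    "ranking",
    "candidate_selection",
    "minimal_subnetwork",
    "correlation_stats",
    "survival",
)


@dataclass
class PipelineConfig:
    """All paths and parameters of one pipeline run."""

    ppi_path: str
    expression_path: str
    seeds_path: str
    clinical_path: str | None = None
    id_map_path: str | None = None
    out_dir: str = "seednet_out"
    score_min: int = 0
    coexpr: CoexprParams = field(default_factory=CoexprParams)
    L: int = 50
    rs_cutoff: float | None = 1.0
    top_k: int | None = None
    signature: list[str] | None = None  # explicit list overrides selected candidates
    covariates: tuple[str, ...] = ("gender", "alcohol", "smoking")
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        coexpr_raw = raw.pop("coexpr", {})
        cfg = cls(coexpr=CoexprParams(**coexpr_raw), **raw)
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _graph_counts(graph) -> dict:
    return {"nodes": graph.number_of_nodes(), "edges": graph.number_of_edges()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest.

    Any stage failure aborts the run with the stage name attached and a
    partial manifest written to the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "score_min": config.score_min,
            "beta": config.coexpr.beta,
            "abs_r_threshold": config.coexpr.abs_r_threshold,
            "target_edge_count": config.coexpr.target_edge_count,
            "L": config.L,
            "rs_cutoff": config.rs_cutoff,
            "top_k": config.top_k,
            "rng_seed": config.rng_seed,
            "median_tie_rule": "ties at the median go to the low-risk group",
        },
        "stages": {},
    }
    stage = STAGES[0]
    try:
        ppi = io.read_string_links(config.ppi_path, score_min=config.score_min,
                                   id_map=config.id_map_path)
        expr = io.read_expression_matrix(config.expression_path)
        clin = io.read_clinical_table(config.clinical_path) if config.clinical_path else None
        manifest["inputs"] = {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (
                ("ppi", config.ppi_path),
                ("expression", config.expression_path),
                ("seeds", config.seeds_path),
                ("clinical", config.clinical_path),
            )
            if p is not None
        }
        manifest["stages"][stage] = {
            "ppi": _graph_counts(ppi),
            "expression_shape": list(expr.shape),
            "clinical_samples": 0 if clin is None else len(clin),
        }

        stage = "coexpression_network"
        coexpr_net = coexpr.correlation_adjacency(expr, config.coexpr)
        io.write_network(coexpr_net, out / "coexpression_network.tsv")
        manifest["stages"][stage] = _graph_counts(coexpr_net)

        stage = "common_network"
        common = coexpr.intersect_networks(ppi, coexpr_net)
        io.write_network(common, out / "common_network.tsv")
        manifest["stages"][stage] = _graph_counts(common)

        stage = "seed_filter"
        seed_set = io.read_seed_list(config.seeds_path, common)
        manifest["stages"][stage] = {
            "seeds_retained": len(seed_set.genes),
            "seeds_dropped": len(seed_set.dropped),
            "dropped": list(seed_set.dropped),
        }

        stage = "kwalks_subnetwork"
        relevance = kwalks.limited_kwalks_relevance(common, seed_set, L=config.L)
        sub = kwalks.extract_subnetwork(common, relevance, seed_set)
        io.write_subnetwork(sub, out / "subnetwork.graphml")
        io.write_network(sub.graph, out / "subnetwork.tsv")
        with open(out / "edge_relevance.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\trelevance\n")
            for (u, v), r in sorted(relevance.edge_relevance.items()):
                fh.write(f"{u}\t{v}\t{r!r}\n")
        n_linkers = len(sub.nodes_with_role("linker"))
        manifest["stages"][stage] = {
            **_graph_counts(sub.graph),
            "seeds": len(sub.nodes_with_role("seed")),
            "linkers": n_linkers,
            "L": relevance.L,
        }

        stage = "ranking"
        ranked = ranking.ranking_score(sub)
        (out / "ranked_linkers.tsv").write_text(ranking.format_ranked_table(ranked),
                                                encoding="utf-8")
        manifest["stages"][stage] = {"ranked": len(ranked)}

        stage = "candidate_selection"
        candidates = ranking.select_candidates(ranked, rs_cutoff=config.rs_cutoff,
                                               top_k=config.top_k)
        (out / "candidates.txt").write_text("\n".join(candidates) + "\n", encoding="utf-8")
        manifest["stages"][stage] = {"candidates": len(candidates), "genes": candidates}

        stage = "minimal_subnetwork"
        if candidates:
            minimal = ranking.minimal_connecting_subnetwork(common, candidates)
            io.write_subnetwork(minimal, out / "minimal_candidate_subnetwork.graphml")
            manifest["stages"][stage] = _graph_counts(minimal.graph)
        else:
            manifest["stages"][stage] = {"skipped": "no candidates"}

        stage = "correlation_stats"
        pairs = sorted(
            (min(u, v), max(u, v))
            for u, v in sub.graph.edges
            if (sub.roles[u] == "seed") != (sub.roles[v] == "seed")
            and (u in set(candidates) or v in set(candidates))
        )
        pair_stats = clinical_mod.pairwise_correlation(expr, pairs) if pairs else []
        with open(out / "seed_candidate_correlations.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tr\tp\tp_adj\tn\n")
            for st in pair_stats:
                fh.write(f"{st.gene_a}\t{st.gene_b}\t{st.statistic!r}\t{st.p!r}\t"
                         f"{st.p_adj!r}\t{st.n}\n")
        cov_rows = []
        if clin is not None:
            for cov in config.covariates:
                if cov in clin.columns and clin[cov].dropna().nunique() == 2:
                    cov_rows.extend(clinical_mod.covariate_tests(expr, clin, candidates, cov))
        with open(out / "covariate_tests.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene\tcontrast\tt\tp\tn\n")
            for st in cov_rows:
                fh.write(f"{st.gene_a}\t{st.gene_b}\t{st.statistic!r}\t{st.p!r}\t{st.n}\n")
        manifest["stages"][stage] = {
            "seed_candidate_pairs": len(pair_stats),
            "covariate_tests": len(cov_rows),
        }

        stage = "survival"
        if clin is not None:
            signature = config.signature or candidates
            if not signature:
                raise SeednetError("no signature genes: selection returned no candidates")
            scores = clinical_mod.risk_score(expr, signature)
            strat = clinical_mod.stratify_and_test(scores, clin)
            summary = {
                "signature": list(signature),
                "n_retained": strat.n_retained,
                "n_excluded": strat.n_excluded,
                "threshold": strat.threshold,
                "logrank_chisq": strat.logrank_chisq,
                "logrank_p": strat.logrank_p,
            }
            (out / "survival_summary.json").write_text(
                json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8")
            for name, curve in strat.km_curves.items():
                with open(out / f"km_curve_{name}.tsv", "w", encoding="utf-8") as fh:
                    fh.write("time\tsurvival\n")
                    for t, sprob in curve:
                        fh.write(f"{t!r}\t{sprob!r}\n")
            manifest["stages"][stage] = summary
        else:
            manifest["stages"][stage] = {"skipped": "no clinical table supplied"}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True),
                                           encoding="utf-8")
        raise SeednetError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True),
                                       encoding="utf-8")
    return manifest
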
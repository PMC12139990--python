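"""Stage orchestration: score → similarity → predict → benchmark → targets
→ corroborate, each stage reading the previous stage's artifacts so that
any stage can also be run on its own."""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__, benchmark, consensus, io, scoring, similarity, targets
from .config import RunConfig
from .errors import DrugsigError, StageError

log = logging.getLogger(__name__)

STAGES = ("score", "similarity", "predict", "benchmark", "targets", "corroborate")


def _header(cfg: RunConfig, stage: str) -> list[str]:
    return [f"stage={stage}", f"config={cfg.hash()}", f"tool=drugsig {__version__}"]


def _require(cfg: RunConfig, stage: str, *attrs: str) -> None:
    for a in attrs:
        if getattr(cfg, a) is None:
            raise StageError(stage, f"config field {a!r} is required")


def stage_score(cfg: RunConfig) -> Path:
    _require(cfg, "score", "compounds", "binding_sites")
    compounds = io.read_compound_library(cfg.compounds, cfg.fingerprint_width)
    proteins = io.read_binding_site_table(cfg.binding_sites, cfg.fingerprint_width)
    matrix = scoring.build_signature_matrix(compounds, proteins, cfg.scoring_variant)
    out = cfg.path("matrix.tsv")
    io.write_matrix(matrix, out, cfg.matrix_precision, _header(cfg, "score"))
    return out


def stage_similarity(cfg: RunConfig) -> Path:
    matrix = io.read_matrix(cfg.path("matrix.tsv"))
    lists = similarity.rank_all(matrix)
    out = cfg.path("similarity.tsv")
    io.write_similarity_lists(lists, out, _header(cfg, "similarity"))
    return out


def stage_predict(cfg: RunConfig) -> Path:
    _require(cfg, "predict", "compounds", "mapping")
    compounds = io.read_compound_library(cfg.compounds, cfg.fingerprint_width)
    mappings = io.read_indication_mapping(cfg.mapping, compounds)
    lists = io.read_similarity_lists(cfg.path("similarity.tsv"))
    unscoreable = {c.id for c in compounds if not c.scoreable}
    names = {c.id: c.name for c in compounds}
    rows = []
    for m in mappings:
        cons = consensus.build_consensus(m, lists, cfg.prediction_cutoff)
        if cfg.include_approved:
            entries = cons.entries[: cfg.top_n]
        else:
            entries = consensus.novel_candidates(cons, m, cfg.top_n, exclude=unscoreable)
        for e in entries:
            rows.append({
                "indication_id": m.indication_id, "rank": e.overall_rank,
                "compound_id": e.compound_id, "name": names.get(e.compound_id, ""),
                "consensus_score": e.consensus_score,
                "average_score": f"{e.average_score:.6f}",
                "probability": f"{e.probability:.6e}", "novel": int(e.novel),
            })
    out = cfg.path("predictions.tsv")
    cols = ["indication_id", "rank", "compound_id", "name", "consensus_score",
            "average_score", "probability", "novel"]
    io.write_table(pd.DataFrame(rows, columns=cols), out, _header(cfg, "predict"))
    return out


def stage_benchmark(cfg: RunConfig) -> tuple[Path, Path]:
    _require(cfg, "benchmark", "compounds", "mapping")
    compounds = io.read_compound_library(cfg.compounds, cfg.fingerprint_width)
    mappings = io.read_indication_mapping(cfg.mapping, compounds)
    lists = io.read_similarity_lists(cfg.path("similarity.tsv"))
    results, aggregates = benchmark.benchmark_all(
        mappings, lists, cfg.cutoffs, strict_loo_nia=cfg.strict_loo_nia)
    per = pd.DataFrame([asdict(r) for r in results])
    agg = pd.DataFrame([asdict(a) for a in aggregates])
    p1 = cfg.path("benchmark_per_indication.tsv")
    p2 = cfg.path("benchmark_aggregate.tsv")
    io.write_table(per, p1, _header(cfg, "benchmark"), float_format="%.6f")
    io.write_table(agg, p2, _header(cfg, "benchmark"), float_format="%.6f")
    return p1, p2


def _candidates_by_indication(cfg: RunConfig) -> dict[str, list[str]]:
    df = pd.read_csv(cfg.path("predictions.tsv"), sep="\t", comment="#", dtype=str)
    out: dict[str, list[str]] = {}
    for ind, grp in df.groupby("indication_id", sort=False):
        out[str(ind)] = grp.sort_values("rank", key=lambda s: s.astype(int))[
            "compound_id"].tolist()
    return out


def stage_targets(cfg: RunConfig) -> Path:
    matrix = io.read_matrix(cfg.path("matrix.tsv"))
    cands = _candidates_by_indication(cfg)
    rows = []
    for ind, compound_ids in cands.items():
        for cid in compound_ids[: cfg.control_k]:
            for t in targets.top_targets(cid, matrix, cfg.target_depth).targets:
                rows.append({"indication_id": ind, "compound_id": cid,
                             "target_rank": t.rank, "protein_id": t.protein_id,
                             "score": f"{t.score:.6f}"})
    out = cfg.path("top_targets.tsv")
    cols = ["indication_id", "compound_id", "target_rank", "protein_id", "score"]
    io.write_table(pd.DataFrame(rows, columns=cols), out, _header(cfg, "targets"))
    return out


def stage_corroborate(cfg: RunConfig) -> tuple[Path, Path]:
    _require(cfg, "corroborate", "compounds", "gold")
    matrix = io.read_matrix(cfg.path("matrix.tsv"))
    compounds = {c.id: c for c in io.read_compound_library(cfg.compounds,
                                                           cfg.fingerprint_width)}
    gold_sets = io.read_gold_standards(cfg.gold)
    cands = _candidates_by_indication(cfg)
    report_rows, bin_rows = [], []
    for ind, candidate_ids in cands.items():
        sets = targets.control_drug_sets(candidate_ids, compounds, cfg.control_k, cfg.seed)
        for label, drug_set in sets.items():
            for gold in gold_sets:
                rep = targets.overlap_analysis(
                    drug_set, gold, matrix, jaccard_cutoff=cfg.jaccard_cutoff,
                    drug_set_label=label)
                for cutoff, pct in rep.cumulative_overlap.items():
                    report_rows.append({
                        "indication_id": ind, "drug_set": label,
                        "gold_label": gold.source_label, "rank_cutoff": cutoff,
                        "cumulative_overlap_pct": f"{pct:.4f}",
                        "jaccard": f"{rep.jaccard:.6f}",
                        "jaccard_cutoff": rep.jaccard_cutoff})
                for (lo, hi), freq in rep.bin_frequencies.items():
                    bin_rows.append({
                        "indication_id": ind, "drug_set": label,
                        "gold_label": gold.source_label, "bin_lo": lo, "bin_hi": hi,
                        "frequency": f"{freq:.6f}",
                        "unbinned_fraction": f"{rep.unbinned_fraction:.6f}"})
    p1 = cfg.path("corroboration.tsv")
    p2 = cfg.path("corroboration_bins.tsv")
    io.write_table(pd.DataFrame(report_rows), p1, _header(cfg, "corroborate"))
    io.write_table(pd.DataFrame(bin_rows), p2, _header(cfg, "corroborate"))
    return p1, p2


_STAGE_FUNCS = {
    "score": stage_score,
    "similarity": stage_similarity,
    "predict": stage_predict,
    "benchmark": stage_benchmark,
    "targets": stage_targets,
    "corroborate": stage_corroborate,
}


def run_pipeline(cfg: RunConfig) -> dict[str, object]:
    """Run every stage in order; aborts with the failing stage's name.

    Deterministic and idempotent: identical config and inputs give
    byte-identical artifacts. The resolved config is written next to the
    outputs.
    """
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(cfg.path("run_config.yaml"))
    artifacts: dict[str, object] = {}
    for stage in STAGES:
        log.info("running stage %s", stage)
        try:
            artifacts[stage] = _STAGE_FUNCS[stage](cfg)
        except StageError:
            raise
        except (DrugsigError, OSError, KeyError, ValueError) as exc:
            raise StageError(stage, str(exc)) from exc
    return artifacts
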
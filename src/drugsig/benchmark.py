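"""Recovery benchmarks over similarity and consensus lists.

Metrics (all leave-one-out in the sense that each similarity list already
excludes its own query compound):

IA   — indication accuracy: percentage of an indication's approved drugs
       whose similarity list contains at least one *other* approved drug
       within the rank cutoff.
AIA  — unweighted mean of IA over all benchmarkable indications (≥2
       approved drugs).
nIA  — percentage of approved drugs appearing within the cutoff of the
       indication's consensus list (built from all approved drugs' lists);
       a stricter variant rebuilds the consensus without the evaluated
       drug's own list.
NDCG — normalized discounted cumulative gain with binary relevance and
       log2(rank+1) discount, averaged per approved drug then per
       indication; nNDCG applies the same form once to the consensus list.

The random control is the hypergeometric chance of catching at least one
of the K−1 relevant compounds in a cutoff-sized uniform draw from the
library minus the query.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .consensus import ConsensusList, build_consensus
from .errors import ValidationError
from .model import IndicationMapping
from .similarity import SimilarityList

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkResult:
    indication_id: str
    cutoff: int
    ia: float
    nia: float
    ndcg: float
    nndcg: float
    n_approved: int


@dataclass(frozen=True)
class AggregateResult:
    cutoff: int
    aia: float
    naia: float
    ndcg_mean: float
    nndcg_mean: float
    control_aia: float
    n_indications: int


def _approved_with_lists(indication: IndicationMapping,
                         lists: Mapping[str, SimilarityList]) -> list[str]:
    drugs = sorted(d for d in indication.approved_compound_ids if d in lists)
    if len(drugs) < 2:
        raise ValidationError(
            f"indication {indication.indication_id} has {len(drugs)} approved drug(s) "
            "with similarity lists; benchmarking requires at least 2")
    return drugs


def indication_accuracy(indication: IndicationMapping,
                        lists: Mapping[str, SimilarityList], cutoff: int) -> float:
    drugs = _approved_with_lists(indication, lists)
    others = set(drugs)
    successes = 0
    for d in drugs:
        for e in lists[d].entries:
            if e.rank > cutoff:
                break
            if e.compound_id in others and e.compound_id != d:
                successes += 1
                break
    return 100.0 * successes / len(drugs)


def new_indication_accuracy(indication: IndicationMapping, consensus: ConsensusList,
                            cutoff: int) -> float:
    """Share of approved drugs ranked within ``cutoff`` of the consensus list."""
    drugs = sorted(indication.approved_compound_ids)
    if len(drugs) < 2:
        raise ValidationError("nIA requires at least 2 approved drugs")
    hits = sum(1 for d in drugs
               if (r := consensus.rank_of(d)) is not None and r <= cutoff)
    return 100.0 * hits / len(drugs)


def new_indication_accuracy_loo(indication: IndicationMapping,
                                lists: Mapping[str, SimilarityList], cutoff: int,
                                library_size: Optional[int] = None,
                                consensus_cutoff: Optional[int] = None) -> float:
    """Strict variant: each drug is scored against a consensus rebuilt from the
    other approved drugs' lists only."""
    drugs = _approved_with_lists(indication, lists)
    hits = 0
    for d in drugs:
        held_out = IndicationMapping(indication.indication_id, indication.indication_name,
                                     frozenset(set(drugs) - {d}))
        cons = build_consensus(held_out, lists, consensus_cutoff or cutoff, library_size)
        r = cons.rank_of(d)
        if r is not None and r <= cutoff:
            hits += 1
    return 100.0 * hits / len(drugs)


def _dcg(relevances: Sequence[int]) -> float:
    return sum(rel / math.log2(i + 2) for i, rel in enumerate(relevances))


def ndcg_at_k(indication: IndicationMapping, lists: Mapping[str, SimilarityList],
              cutoff: int) -> float:
    """Mean over approved drugs of NDCG of their similarity lists, binary
    relevance = "is another approved drug"."""
    drugs = _approved_with_lists(indication, lists)
    total = 0.0
    for d in drugs:
        relevant = set(drugs) - {d}
        rels = [1 if e.compound_id in relevant else 0
                for e in lists[d].entries[:cutoff]]
        ideal = min(len(relevant), cutoff)
        idcg = _dcg([1] * ideal)
        total += _dcg(rels) / idcg if idcg > 0 else 0.0
    return total / len(drugs)


def nndcg_at_k(indication: IndicationMapping, consensus: ConsensusList,
               cutoff: int) -> float:
    """NDCG of the consensus list with the approved drugs as relevant items."""
    approved = indication.approved_compound_ids
    if len(approved) < 2:
        raise ValidationError("nNDCG requires at least 2 approved drugs")
    rels = [1 if e.compound_id in approved else 0
            for e in consensus.entries[:cutoff]]
    ideal = min(len(approved), cutoff)
    idcg = _dcg([1] * ideal)
    return _dcg(rels) / idcg if idcg > 0 else 0.0


def random_control_ia(n_approved: int, cutoff: int, library_size: int) -> float:
    """Expected IA (percent) under uniform random ranking.

    Success per query = at least one of the n_approved−1 relevant compounds
    among ``cutoff`` draws without replacement from library_size−1
    candidates: 100 × [1 − C(L−1−(K−1), c) / C(L−1, c)].
    """
    if n_approved < 2:
        raise ValidationError("random control requires n_approved >= 2")
    pool = library_size - 1
    if cutoff >= pool:
        return 100.0
    k_rel = n_approved - 1
    if pool - k_rel < cutoff:
        return 100.0
    return 100.0 * (1.0 - math.comb(pool - k_rel, cutoff) / math.comb(pool, cutoff))


def benchmark_all(mappings: Sequence[IndicationMapping],
                  lists: Mapping[str, SimilarityList],
                  cutoffs: Sequence[int] = (10, 25, 50, 100),
                  library_size: Optional[int] = None,
                  strict_loo_nia: bool = False,
                  consensus_cutoff: Optional[int] = None,
                  ) -> tuple[list[BenchmarkResult], list[AggregateResult]]:
    """Per-indication and per-cutoff aggregate benchmark over every
    benchmarkable indication (≥2 approved drugs with lists).

    One consensus list per indication is built at ``consensus_cutoff``
    (default: the largest evaluation cutoff) and then evaluated at each
    cutoff, so nIA and nNDCG are measured against a single fixed ranking —
    this keeps nIA nondecreasing in the evaluation cutoff.
    """
    if library_size is None and lists:
        library_size = len(next(iter(lists.values())).entries) + 1
    if consensus_cutoff is None:
        consensus_cutoff = max(cutoffs)

    usable = []
    for m in mappings:
        n_with = sum(1 for d in m.approved_compound_ids if d in lists)
        if n_with >= 2:
            usable.append(m)
        else:
            log.info("skipping indication %s (fewer than 2 approved drugs with lists)",
                     m.indication_id)

    consensus_by_ind = {m.indication_id: build_consensus(m, lists, consensus_cutoff,
                                                         library_size)
                        for m in usable}
    results: list[BenchmarkResult] = []
    aggregates: list[AggregateResult] = []
    for cutoff in cutoffs:
        per_cutoff = []
        controls = []
        for m in usable:
            cons = consensus_by_ind[m.indication_id]
            if strict_loo_nia:
                nia = new_indication_accuracy_loo(m, lists, cutoff, library_size,
                                                  consensus_cutoff)
            else:
                nia = new_indication_accuracy(m, cons, cutoff)
            res = BenchmarkResult(
                indication_id=m.indication_id, cutoff=cutoff,
                ia=indication_accuracy(m, lists, cutoff),
                nia=nia,
                ndcg=ndcg_at_k(m, lists, cutoff),
                nndcg=nndcg_at_k(m, cons, cutoff),
                n_approved=m.n_approved)
            per_cutoff.append(res)
            controls.append(random_control_ia(cons.n_lists, cutoff, library_size))
        results.extend(per_cutoff)
        if per_cutoff:
            n = len(per_cutoff)
            aggregates.append(AggregateResult(
                cutoff=cutoff,
                aia=sum(r.ia for r in per_cutoff) / n,
                naia=sum(r.nia for r in per_cutoff) / n,
                ndcg_mean=sum(r.ndcg for r in per_cutoff) / n,
                nndcg_mean=sum(r.nndcg for r in per_cutoff) / n,
                control_aia=sum(controls) / n,
                n_indications=n))
    return results, aggregates
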
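"""Top-target ranking and overlap with gold-standard protein sets.

For each candidate drug the proteins are ranked by interaction score
descending ("top targets"). Corroboration pools the rank-≤cutoff targets
of a drug set and compares them against an independently curated
("gold standard") protein set with three statistics: a frequency
histogram of best ranks in width-20 bins over ranks 1–100, the cumulative
percentage of gold proteins overlapped as the rank cutoff grows, and the
Jaccard coefficient of the pooled target set against the gold set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import Compound, GoldStandardTargets, SignatureMatrix

log = logging.getLogger(__name__)

DEFAULT_BINS: tuple[tuple[int, int], ...] = ((1, 20), (21, 40), (41, 60), (61, 80), (81, 100))
DEFAULT_CUTOFFS: tuple[int, ...] = tuple(range(10, 101, 10))


@dataclass(frozen=True)
class TargetEntry:
    protein_id: str
    score: float
    rank: int


@dataclass
class TopTargets:
    compound_id: str
    targets: list[TargetEntry]


@dataclass
class OverlapReport:
    drug_set_label: str
    gold_label: str
    bin_frequencies: dict[tuple[int, int], float]
    unbinned_fraction: float
    cumulative_overlap: dict[int, float]   # rank cutoff -> percent of gold proteins
    jaccard: float
    jaccard_cutoff: int


def _ranked_proteins(matrix: SignatureMatrix, compound_id: str) -> list[str]:
    """Protein ids sorted by score descending, ties by protein id ascending."""
    row = matrix.row(compound_id)
    order = sorted(range(len(matrix.protein_ids)),
                   key=lambda j: (-row[j], matrix.protein_ids[j]))
    return [matrix.protein_ids[j] for j in order]


def top_targets(compound_id: str, matrix: SignatureMatrix, depth: int = 10) -> TopTargets:
    """The ``depth`` strongest predicted protein interactions for a compound."""
    if not matrix.has_compound(compound_id):
        raise ValidationError(f"compound {compound_id!r} not in matrix")
    row = matrix.row(compound_id)
    idx = {p: j for j, p in enumerate(matrix.protein_ids)}
    ranked = _ranked_proteins(matrix, compound_id)[:depth]
    return TopTargets(compound_id, [
        TargetEntry(pid, float(row[idx[pid]]), r + 1) for r, pid in enumerate(ranked)])


def jaccard(a: Set[str], b: Set[str]) -> float:
    """|a∩b| / |a∪b|; defined as 0 when both sets are empty."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def pooled_prediction_targets(drug_set: Sequence[str], matrix: SignatureMatrix,
                              rank_cutoff: int = 10) -> set[str]:
    """Union over the drug set of each drug's rank-≤cutoff targets."""
    pooled: set[str] = set()
    for cid in drug_set:
        pooled.update(_ranked_proteins(matrix, cid)[:rank_cutoff])
    return pooled


def best_ranks(drug_set: Sequence[str], matrix: SignatureMatrix) -> dict[str, int]:
    """For every protein, its best (minimum) per-drug target rank across the set."""
    best: dict[str, int] = {}
    for cid in drug_set:
        for r, pid in enumerate(_ranked_proteins(matrix, cid), start=1):
            if pid not in best or r < best[pid]:
                best[pid] = r
    return best


def overlap_analysis(drug_set: Sequence[str], gold: GoldStandardTargets,
                     matrix: SignatureMatrix,
                     bins: Sequence[tuple[int, int]] = DEFAULT_BINS,
                     cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
                     jaccard_cutoff: int = 10,
                     drug_set_label: str = "") -> OverlapReport:
    """All three corroboration statistics for one drug set vs one gold set.

    The histogram's unit is the gold protein: each gold protein found in the
    drug set's pooled top-100 targets contributes its best rank to one bin;
    gold proteins beyond rank 100 are reported as unbinned mass.
    """
    ranks = best_ranks(drug_set, matrix)
    gold_ranks = [ranks[p] for p in gold.protein_ids if p in ranks]

    max_binned = max(hi for _, hi in bins)
    binned = [r for r in gold_ranks if r <= max_binned]
    freqs = {}
    for lo, hi in bins:
        count = sum(1 for r in binned if lo <= r <= hi)
        freqs[(lo, hi)] = count / len(binned) if binned else 0.0
    unbinned = (len(gold.protein_ids) - len(binned)) / len(gold.protein_ids)

    cumulative = {c: 100.0 * sum(1 for r in gold_ranks if r <= c) / len(gold.protein_ids)
                  for c in cutoffs}
    jac = jaccard(pooled_prediction_targets(drug_set, matrix, jaccard_cutoff),
                  set(gold.protein_ids))
    return OverlapReport(drug_set_label, gold.source_label, freqs, unbinned,
                         cumulative, jac, jaccard_cutoff)


def control_drug_sets(candidate_ids: Sequence[str], compounds: Mapping[str, Compound],
                      k: int = 24, seed: int = 0,
                      min_heavy_atoms: int = 5) -> dict[str, list[str]]:
    """Top-k / seeded random-k / bottom-k slices of a ranked candidate table.

    The bottom set is taken after filtering out compounds with fewer than
    ``min_heavy_atoms`` non-hydrogen atoms (or with an unknown count), so
    trivially small molecules do not stand in as controls.
    """
    if len(candidate_ids) < k:
        raise ValidationError(f"candidate table has {len(candidate_ids)} rows; need >= {k}")
    top = list(candidate_ids[:k])
    rng = np.random.default_rng(seed)
    random_k = [candidate_ids[i] for i in sorted(rng.choice(len(candidate_ids), size=k,
                                                            replace=False))]
    eligible = [cid for cid in candidate_ids
                if (c := compounds.get(cid)) is not None
                and c.heavy_atoms is not None and c.heavy_atoms >= min_heavy_atoms]
    if len(eligible) < k:
        raise ValidationError(
            f"only {len(eligible)} candidates pass the >= {min_heavy_atoms} heavy-atom "
            f"filter; need {k} for the bottom control set")
    bottom = eligible[-k:]
    return {"top": top, "random": random_k, "bottom": bottom}


def cross_indication_jaccard(candidates_by_indication: Mapping[str, Sequence[str]],
                             matrix: SignatureMatrix,
                             gold_sets: Sequence[GoldStandardTargets],
                             top_ns: Sequence[int] = (24, 100),
                             rank_cutoff: int = 10) -> pd.DataFrame:
    """Jaccard of each indication's pooled top-candidate targets vs each gold set."""
    rows = []
    for ind, cand in candidates_by_indication.items():
        for top_n in top_ns:
            subset = list(cand[:top_n])
            if not subset:
                log.warning("indication %s: empty candidate table", ind)
            pooled = pooled_prediction_targets(subset, matrix, rank_cutoff) if subset else set()
            for g in gold_sets:
                rows.append({"indication_id": ind, "top_n": top_n,
                             "gold_label": g.source_label,
                             "jaccard": jaccard(pooled, set(g.protein_ids))})
    return pd.DataFrame(rows, columns=["indication_id", "top_n", "gold_label", "jaccard"])
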
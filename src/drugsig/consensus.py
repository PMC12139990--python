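"""Per-indication consensus lists and novel-candidate tables.

For an indication with approved drugs d1..dn, a compound's *consensus
score* counts in how many of the drugs' similarity lists it appears within
the rank cutoff; its *average score* is the mean of those ranks (only over
lists where it appears). Candidates are ordered by consensus score
descending, then average score ascending, then compound id. Each entry
carries the tail probability of reaching its consensus score by chance
under an independent-lists model: each of the n lists independently
includes a fixed compound in its top ``cutoff`` with probability
cutoff/(library_size − 1), and P(X ≥ k) is summed exactly over the
binomial tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Collection, Mapping, Optional

from .errors import ValidationError
from .model import IndicationMapping
from .similarity import SimilarityList

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusEntry:
    compound_id: str
    consensus_score: int
    average_score: float
    probability: float
    overall_rank: int
    novel: bool


@dataclass
class ConsensusList:
    indication_id: str
    cutoff: int
    n_lists: int
    library_size: int
    entries: list[ConsensusEntry]

    def rank_of(self, compound_id: str) -> Optional[int]:
        for e in self.entries:
            if e.compound_id == compound_id:
                return e.overall_rank
        return None


def consensus_probability(consensus_score: int, n_lists: int, cutoff: int,
                          library_size: int) -> float:
    """Exact binomial tail P(X ≥ k) for k appearances across n independent lists."""
    if n_lists < 1 or not (0 <= consensus_score <= n_lists):
        raise ValidationError(
            f"invalid consensus parameters: k={consensus_score}, n={n_lists}")
    if not (1 <= cutoff < library_size):
        raise ValidationError(
            f"cutoff must satisfy 1 <= cutoff < library_size ({cutoff}, {library_size})")
    if consensus_score == 0:
        return 1.0
    p = cutoff / (library_size - 1)
    if p >= 1.0:
        return 1.0
    return sum(math.comb(n_lists, j) * p ** j * (1.0 - p) ** (n_lists - j)
               for j in range(consensus_score, n_lists + 1))


def build_consensus(indication: IndicationMapping, lists: Mapping[str, SimilarityList],
                    cutoff: int, library_size: Optional[int] = None) -> ConsensusList:
    """Tally appearances of every compound within ``cutoff`` across the
    similarity lists of the indication's approved drugs."""
    if cutoff < 1:
        raise ValidationError(f"cutoff must be >= 1, got {cutoff}")
    drugs = sorted(d for d in indication.approved_compound_ids if d in lists)
    if not drugs:
        log.warning("indication %s: no approved drug has a similarity list",
                    indication.indication_id)
        return ConsensusList(indication.indication_id, cutoff, 0, library_size or 0, [])
    if library_size is None:
        library_size = len(lists[drugs[0]].entries) + 1

    counts: dict[str, int] = {}
    rank_sums: dict[str, int] = {}
    for d in drugs:
        for e in lists[d].entries:
            if e.rank > cutoff:
                break
            counts[e.compound_id] = counts.get(e.compound_id, 0) + 1
            rank_sums[e.compound_id] = rank_sums.get(e.compound_id, 0) + e.rank

    approved = indication.approved_compound_ids
    scored = sorted(
        ((cid, k, rank_sums[cid] / k) for cid, k in counts.items()),
        key=lambda t: (-t[1], t[2], t[0]))
    entries = [
        ConsensusEntry(
            compound_id=cid, consensus_score=k, average_score=avg,
            probability=consensus_probability(k, len(drugs), cutoff, library_size),
            overall_rank=r + 1, novel=cid not in approved)
        for r, (cid, k, avg) in enumerate(scored)
    ]
    return ConsensusList(indication.indication_id, cutoff, len(drugs), library_size, entries)


def novel_candidates(consensus: ConsensusList, indication: IndicationMapping,
                     top_n: int = 100,
                     exclude: Collection[str] = ()) -> list[ConsensusEntry]:
    """Keep entries not approved for the indication (and not excluded, e.g.
    unscoreable compounds), preserve order, truncate at ``top_n``, re-rank."""
    excluded = set(exclude) | set(indication.approved_compound_ids)
    out = []
    for e in consensus.entries:
        if e.compound_id in excluded:
            continue
        out.append(replace(e, overall_rank=len(out) + 1, novel=True))
        if len(out) == top_n:
            break
    return out
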
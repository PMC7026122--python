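"""Target/decoy q-values, FDR filtering, single-hit removal, sequence
coverage and modification-level reporting."""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .search_engine import OligoSpectrumMatch

__all__ = [
    "compute_qvalues",
    "filter_fdr",
    "remove_single_hits",
    "majority_replicate_filter",
    "effective_fdr",
    "CoverageReport",
    "sequence_coverage",
    "aggregate_modification_report",
]


def compute_qvalues(osms: Sequence[OligoSpectrumMatch],
                    allow_no_decoys: bool = False,
                    ) -> List[OligoSpectrumMatch]:
    """Annotate rank-1 matches with target/decoy q-values.

    For a score threshold ``s``, ``FDR(s) = #decoys(>=s) / max(1,
    #targets(>=s))`` (simple ratio, no +1 correction); the q-value is the
    minimum FDR over all thresholds at or below the match's score, capped at
    1.  Decoy matches are annotated too but are excluded by the filtering
    helpers downstream.

    With no decoy matches at all this raises, instructing decoy database
    use — unless ``allow_no_decoys`` is set (a decoy database was searched
    but no decoy ever scored), in which case every q-value is 0.
    """
    rank1 = [o for o in osms if o.rank == 1]
    if not rank1:
        return []
    if not any(o.is_decoy for o in rank1) and not allow_no_decoys:
        raise ValueError(
            "no decoy matches present: run the search against a database "
            "with decoy entries to estimate FDR")
    order = sorted(rank1, key=lambda o: -o.hyperscore)
    n_targets = 0
    n_decoys = 0
    fdrs: List[float] = []
    for osm in order:
        if osm.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        fdrs.append(min(1.0, n_decoys / max(1, n_targets)))
    # q = running minimum from the low-score end
    qvals = [0.0] * len(order)
    running = float("inf")
    for i in range(len(order) - 1, -1, -1):
        running = min(running, fdrs[i])
        qvals[i] = running
    for osm, q in zip(order, qvals):
        osm.q_value = q
    return order


def filter_fdr(osms: Sequence[OligoSpectrumMatch],
               threshold: float) -> List[OligoSpectrumMatch]:
    """Target rank-1 matches with q <= threshold, ordered by score."""
    kept = [o for o in osms
            if not o.is_decoy and o.q_value is not None
            and o.q_value <= threshold]
    return sorted(kept, key=lambda o: -o.hyperscore)


def _seq_key(osm: OligoSpectrumMatch) -> str:
    return osm.sequence_string


def remove_single_hits(osms: Sequence[OligoSpectrumMatch]
                       ) -> List[OligoSpectrumMatch]:
    """Drop oligonucleotides (sequence incl. modification state) supported by
    only one spectrum."""
    counts = Counter(_seq_key(o) for o in osms)
    return [o for o in osms if counts[_seq_key(o)] > 1]


def majority_replicate_filter(osms_by_replicate: Mapping[str, Sequence[OligoSpectrumMatch]]
                              ) -> List[OligoSpectrumMatch]:
    """Keep oligonucleotides found in the majority of replicates."""
    n_rep = len(osms_by_replicate)
    if n_rep == 0:
        return []
    presence: Dict[str, Set[str]] = defaultdict(set)
    for rep, osms in osms_by_replicate.items():
        for o in osms:
            presence[_seq_key(o)].add(rep)
    need = n_rep // 2 + 1
    kept = []
    for rep, osms in osms_by_replicate.items():
        kept.extend(o for o in osms if len(presence[_seq_key(o)]) >= need)
    return kept


def effective_fdr(osms: Sequence[OligoSpectrumMatch]) -> float:
    """decoys / targets among the surviving (filtered) matches."""
    n_decoys = sum(1 for o in osms if o.is_decoy)
    n_targets = sum(1 for o in osms if not o.is_decoy)
    return n_decoys / max(1, n_targets)


@dataclass
class CoverageReport:
    parent_id: str
    parent_length: int
    covered_positions: Set[int]
    spectral_counts: Dict[str, int]  # per oligonucleotide sequence string

    @property
    def coverage_fraction(self) -> float:
        return len(self.covered_positions) / self.parent_length


def sequence_coverage(osms: Sequence[OligoSpectrumMatch],
                      parent_lengths: Mapping[str, int],
                      unique_only: bool = False,
                      ) -> Dict[str, CoverageReport]:
    """Union of matched oligo coordinate ranges per parent sequence.

    Multi-mapping oligonucleotides credit every matching location unless
    ``unique_only`` is set.
    """
    reports = {pid: CoverageReport(pid, length, set(), {})
               for pid, length in parent_lengths.items()}
    for osm in osms:
        locations = osm.candidate.locations
        if unique_only and len({loc[0] for loc in locations}) > 1:
            continue
        for parent_id, start, end in locations:
            rep = reports.get(parent_id)
            if rep is None:
                continue
            rep.covered_positions.update(range(start, end + 1))
            key = _seq_key(osm)
            rep.spectral_counts[key] = rep.spectral_counts.get(key, 0) + 1
    return reports


def aggregate_modification_report(osms: Sequence[OligoSpectrumMatch]
                                  ) -> Dict[str, int]:
    """Spectral counts per modification search code.

    A match carrying two distinct modification codes increments both rows; a
    match with two modifications of the same code increments that row once
    per spectrum-level occurrence of the code (i.e. counted once per OSM).
    """
    table: Counter = Counter()
    for osm in osms:
        codes = {m.search_code for _, m, _ in osm.candidate.sequence.modifications}
        for code in codes:
            table[code] += 1
    return dict(table)
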
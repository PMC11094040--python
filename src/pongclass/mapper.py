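"""Ungapped <=1-mismatch alignment of piRNA cores to a transposon panel.

This is a small, deterministic re-creation of ``bowtie -v 1`` semantics:
end-to-end ungapped alignment under Hamming distance, reporting only the
best stratum (exact hits suppress 1-mismatch hits), with either a single
deterministically tie-broken placement (TE-level counting) or all
best-stratum placements (per-piRNA 5'-anchor matching, where multi-mapping
is permitted and a read matching k reference anchors contributes 1/k to
each).

The index is a pigeonhole seed table: every 6-mer position of every TE is
recorded; a query aligned with at most one mismatch must match one of its
two leading 6-mer seeds exactly, so candidate placements are looked up and
then verified by full Hamming comparison.  Queries are searched forward
(plus strand) and as reverse complements (minus strand: the reverse
complement of the read matches the TE window).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .datamodel_io import (
    AlignmentHit,
    LibraryCounts,
    ReadRecord,
    ReferencePiRNA,
    TESequence,
    five_prime_from_interval,
    revcomp,
)

SEED_LEN = 6  # two disjoint 6-mer seeds fit in any >=13-nt query


@dataclass
class MapperConfig:
    max_mismatches: int = 1
    report_policy: str = "best_single"  # or "all_best"
    # 5'-anchor matching: when True, a mismatch at the read's 5' nucleotide
    # disqualifies the hit as an anchor match
    strict_anchor: bool = False

    def __post_init__(self) -> None:
        if self.max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        if self.report_policy not in ("best_single", "all_best"):
            raise ValueError(f"unknown report_policy {self.report_policy!r}")


class SearchIndex:
    """Seed table over a TE panel supporting exact and 1-mismatch lookup."""

    def __init__(self, panel: Sequence[TESequence]):
        if not panel:
            raise ValueError("empty TE panel")
        ids = [t.te_id for t in panel]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate te_id in panel: {dup}")
        self.panel = {t.te_id: t for t in panel}
        self.te_ids = sorted(self.panel)  # deterministic iteration order
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for te_id in self.te_ids:
            seq = self.panel[te_id].sequence
            for i in range(len(seq) - SEED_LEN + 1):
                self._seeds[seq[i:i + SEED_LEN]].append((te_id, i))

    def candidate_starts(self, query: str) -> set[tuple[str, int]]:
        """Placements (te_id, start) where an <=1-mismatch end-to-end match
        of ``query`` could begin, via the two leading disjoint seeds."""
        out: set[tuple[str, int]] = set()
        for off in (0, SEED_LEN):
            seed = query[off:off + SEED_LEN]
            if len(seed) < SEED_LEN:
                continue
            for te_id, pos in self._seeds.get(seed, ()):
                start = pos - off
                if start >= 0 and start + len(query) <= len(self.panel[te_id]):
                    out.add((te_id, start))
        return out


def build_index(panel: Sequence[TESequence]) -> SearchIndex:
    """Build the search index; deterministic for a given panel."""
    return SearchIndex(panel)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance capped at limit+1 (early exit)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _hit_sort_key(hit: AlignmentHit) -> tuple:
    # fewest mismatches, then te_id, then lowest start, then + before -
    return (hit.mismatches, hit.te_id, hit.start, 0 if hit.strand == "+" else 1)


def map_read(core: ReadRecord | str, index: SearchIndex,
             config: MapperConfig = MapperConfig()) -> list[AlignmentHit]:
    """Map one core to the panel, reporting the best stratum only.

    Under ``best_single`` exactly one hit is returned, chosen by the
    deterministic tie-break (mismatches, te_id, start, strand); under
    ``all_best`` all best-stratum hits are returned in tie-break order.
    No hit -> empty list.
    """
    if isinstance(core, ReadRecord):
        read_id, seq = core.read_id, core.sequence
    else:
        read_id, seq = "read", core
    hits: list[AlignmentHit] = []
    best = config.max_mismatches
    seen: set[tuple[str, str, int]] = set()
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        for te_id, start in index.candidate_starts(query):
            if (strand, te_id, start) in seen:
                continue
            seen.add((strand, te_id, start))
            window = index.panel[te_id].sequence[start:start + len(query)]
            mm = _count_mismatches(query, window, config.max_mismatches)
            if mm <= config.max_mismatches:
                hits.append(AlignmentHit(read_id, te_id, strand,
                                         start, start + len(query), mm))
                best = min(best, mm)
    hits = sorted((h for h in hits if h.mismatches == best), key=_hit_sort_key)
    if not hits:
        return []
    if config.report_policy == "best_single":
        return [hits[0]]
    return hits


def _anchor_matches(hit: AlignmentHit, seq: str, index: SearchIndex,
                    strict_anchor: bool) -> bool:
    """Under strict anchoring, the 5' nucleotide itself must match the TE."""
    if not strict_anchor or hit.mismatches == 0:
        return True
    te_seq = index.panel[hit.te_id].sequence
    if hit.strand == "+":
        return seq[0] == te_seq[hit.start]
    return revcomp(seq)[-1] == te_seq[hit.end - 1]


def match_five_prime(core: ReadRecord | str, index: SearchIndex,
                     refs: Sequence[ReferencePiRNA],
                     config: MapperConfig = MapperConfig()) -> list[str]:
    """Reference piRNAs whose 5' anchor equals the 5' anchor of any
    best-stratum hit of ``core``.

    A 5'-end match is an anchor criterion — the read's best alignment
    places its 5' nucleotide at the annotated (te_id, strand,
    five_prime_pos) — so read and reference lengths need not agree.
    Multi-mapped reads return every matched id (sorted).
    """
    seq = core.sequence if isinstance(core, ReadRecord) else core
    anchor_to_ids: dict[tuple[str, str, int], list[str]] = defaultdict(list)
    for r in refs:
        anchor_to_ids[(r.te_id, r.strand, r.five_prime_pos)].append(r.pirna_id)
    cfg = MapperConfig(config.max_mismatches, "all_best", config.strict_anchor)
    matched: set[str] = set()
    for hit in map_read(core, index, cfg):
        if not _anchor_matches(hit, seq, index, config.strict_anchor):
            continue
        key = (hit.te_id, hit.strand,
               five_prime_from_interval(hit.start, hit.end, hit.strand))
        matched.update(anchor_to_ids.get(key, ()))
    return sorted(matched)


# ---------------------------------------------------------------------------
# Library-level counting and normalization
# ---------------------------------------------------------------------------

def _aggregate_cores(cores: Iterable[ReadRecord]) -> dict[str, int]:
    """Molecule count per distinct core sequence (maps each sequence once)."""
    agg: dict[str, int] = defaultdict(int)
    for rec in cores:
        agg[rec.sequence] += rec.count
    return dict(agg)


def count_te_library(cores: Iterable[ReadRecord], index: SearchIndex,
                     config: MapperConfig = MapperConfig()
                     ) -> tuple[dict[str, float], int]:
    """Per-TE molecule counts under best_single placement.

    Returns (counts by te_id, number of molecules with a best-stratum hit);
    the latter is the ``genome_mapped`` normalization denominator when the
    panel stands in for the genome.
    """
    cfg = MapperConfig(config.max_mismatches, "best_single", config.strict_anchor)
    counts: dict[str, float] = defaultdict(float)
    mapped = 0
    for seq, n in sorted(_aggregate_cores(cores).items()):
        hits = map_read(seq, index, cfg)
        if hits:
            counts[hits[0].te_id] += n
            mapped += n
    return dict(counts), mapped


@dataclass
class ReferenceCountResult:
    """Per-reference counts plus the two normalization denominators.

    ``five_prime_tally`` is the raw 5'-end tally over every best-stratum
    placement, keyed by (te_id, strand, five_prime_pos) — the input to
    ping-pong partner lookup, where the partner need not be an annotated
    piRNA.
    """

    counts: dict[str, float]
    reference_matched: int
    genome_mapped: int
    five_prime_tally: dict[tuple[str, str, int], float]


def count_reference_library(cores: Iterable[ReadRecord], index: SearchIndex,
                            refs: Sequence[ReferencePiRNA],
                            config: MapperConfig = MapperConfig()
                            ) -> ReferenceCountResult:
    """Per-reference-piRNA counts by 5'-anchor matching (all_best).

    A molecule matching k reference anchors contributes 1/k to each
    (fractional assignment conserves totals).  ``reference_matched`` is
    the number of molecules with at least one anchor match (the IP
    normalization denominator); ``genome_mapped`` counts molecules with
    any best-stratum hit on the panel.
    """
    counts: dict[str, float] = defaultdict(float)
    matched_molecules = 0
    mapped_molecules = 0
    five_prime_tally: dict[tuple[str, str, int], float] = defaultdict(float)
    anchor_to_ids: dict[tuple[str, str, int], list[str]] = defaultdict(list)
    for r in refs:
        anchor_to_ids[(r.te_id, r.strand, r.five_prime_pos)].append(r.pirna_id)
    cfg = MapperConfig(config.max_mismatches, "all_best", config.strict_anchor)
    for seq, n in sorted(_aggregate_cores(cores).items()):
        hits = map_read(seq, index, cfg)
        if hits:
            mapped_molecules += n
        ids: set[str] = set()
        for hit in hits:
            key = (hit.te_id, hit.strand,
                   five_prime_from_interval(hit.start, hit.end, hit.strand))
            five_prime_tally[key] += n
            if _anchor_matches(hit, seq, index, cfg.strict_anchor):
                ids.update(anchor_to_ids.get(key, ()))
        if ids:
            matched_molecules += n
            w = n / len(ids)
            for pid in ids:
                counts[pid] += w
    return ReferenceCountResult(dict(counts), matched_molecules,
                                mapped_molecules, dict(five_prime_tally))


def normalize_library(counts: dict[str, float], denominator: float,
                      library_id: str, role: str,
                      denominator_mode: str = "genome_mapped"
                      ) -> LibraryCounts:
    """Wrap raw counts as :class:`LibraryCounts` with RPM normalization.

    rpm[k] = counts[k] / denominator * 1e6.  ``denominator_mode`` is
    recorded for provenance and checked by downstream consumers.
    """
    if denominator_mode not in ("genome_mapped", "reference_matched"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if denominator <= 0:
        raise ValueError(f"empty library {library_id!r}")
    return LibraryCounts(library_id, role, dict(counts), denominator,
                         denominator_mode)


# ---------------------------------------------------------------------------
# Brute-force oracle (used by tests; kept here so it is import-stable)
# ---------------------------------------------------------------------------

def brute_force_map(seq: str, panel: Sequence[TESequence],
                    max_mismatches: int = 1) -> list[AlignmentHit]:
    """Exhaustive Hamming scan over every placement on both strands.

    Independent of the seed index; returns all best-stratum hits in the
    same tie-break order as :func:`map_read`.
    """
    hits: list[AlignmentHit] = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        for te in panel:
            for start in range(len(te.sequence) - len(query) + 1):
                window = te.sequence[start:start + len(query)]
                mm = sum(1 for a, b in zip(query, window) if a != b)
                if mm <= max_mismatches:
                    hits.append(AlignmentHit("read", te.te_id, strand,
                                             start, start + len(query), mm))
    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    return sorted((h for h in hits if h.mismatches == best), key=_hit_sort_key)
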
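"""Read cleanup: 3'-adapter trimming, duplicate collapsing, UMI stripping.

The library layout this module inverts is::

    [4-nt UMI] [insert 23-32 nt] [4-nt UMI] [3'-adapter core] ...

i.e. four randomized nucleotides sit at both adapter junctions, so the
sequenced read begins with a 5' UMI and the 3'-adapter core follows the 3'
UMI.  Cleanup proceeds in the order the original pipeline ran:

1. :func:`trim_adapter3` removes everything from the leftmost adapter
   occurrence onward (reads without a detectable adapter are discarded);
2. :func:`collapse_exact_duplicates` removes PCR duplicates — full
   sequences (UMIs included) that are completely identical are thinned to
   one molecule;
3. :func:`strip_umis` removes the 4-nt randomized ends, keeping cores
   strictly longer than 12 nt;
4. :func:`length_gate_pirna` keeps 23-32 nt cores as piRNA candidates.

Adapter matching is ungapped (Hamming), cutadapt-like: leftmost window,
minimum 3'-terminal overlap, allowed mismatches = floor(overlap x
max_error_rate).  Quality strings are carried through but never used for
filtering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .datamodel_io import ReadRecord

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class PreprocessConfig:
    """Parameters of the cleanup chain.

    ``min_len_after`` is the minimum kept core length after UMI removal;
    the default 13 encodes the strict "longer than 12 nt" rule.
    """

    adapter3_core: str = DEFAULT_ADAPTER3
    umi_len_5p: int = 4
    umi_len_3p: int = 4
    min_len_after: int = 13
    adapter_min_overlap: int = 6
    adapter_max_error_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.umi_len_5p < 0 or self.umi_len_3p < 0:
            raise ValueError("UMI lengths must be >= 0")
        if self.min_len_after < 1:
            raise ValueError("min_len_after must be >= 1")
        if not 0 <= self.adapter_max_error_rate < 0.5:
            raise ValueError("adapter_max_error_rate must be in [0, 0.5)")
        if self.adapter_min_overlap < 1:
            raise ValueError("adapter_min_overlap must be >= 1")


@dataclass
class PreprocessReport:
    """Per-stage discard accounting for one library."""

    input_reads: int = 0
    no_adapter: int = 0
    trimmed: int = 0
    unique_molecules: int = 0
    too_short_for_umi: int = 0
    short_core: int = 0
    cores: int = 0
    length_gate_kept: int = 0
    length_gate_discarded_by_length: dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["length_gate_discarded_by_length"] = {
            str(k): v for k, v in sorted(self.length_gate_discarded_by_length.items())
        }
        return d


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    """True iff Hamming(a, b) <= limit (equal lengths assumed)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def find_adapter(seq: str, config: PreprocessConfig) -> Optional[int]:
    """Leftmost start of the 3'-adapter in ``seq`` under the overlap/error
    policy, or None if no window qualifies.

    A window starting at ``i`` compares ``seq[i:i+overlap]`` with the
    adapter prefix of the same length, where ``overlap`` is the full
    adapter length or whatever remains of the read at its 3' end, and must
    be at least ``adapter_min_overlap``.  Allowed mismatches are
    ``floor(overlap * adapter_max_error_rate)``.

    Full-length windows are located by pigeonhole seeding (a window with
    at most ``a`` mismatches contains one of ``a+1`` disjoint adapter
    fragments exactly), then verified; partial windows at the read's 3'
    end are scanned directly.  Equivalent to the brute-force sliding
    Hamming search.
    """
    adapter = config.adapter3_core
    rate = config.adapter_max_error_rate
    n, m = len(seq), len(adapter)
    full_last = n - m  # last start with a full-length window
    candidates: set[int] = set()
    if full_last >= 0:
        allowed_full = int(m * rate)
        k = allowed_full + 1
        frag_len = m // k
        if frag_len >= 1:
            for fi in range(k):
                off = fi * frag_len
                frag = adapter[off:off + frag_len]
                j = seq.find(frag)
                while j != -1:
                    i = j - off
                    if 0 <= i <= full_last:
                        candidates.add(i)
                    j = seq.find(frag, j + 1)
        else:  # degenerate: more allowed mismatches than fragments fit
            candidates.update(range(full_last + 1))
    for i in sorted(candidates):
        if _hamming_leq(seq[i:i + m], adapter, int(m * rate)):
            return i
    # partial windows hanging off the 3' end (all lie right of full windows)
    for i in range(max(full_last + 1, 0), n - config.adapter_min_overlap + 1):
        overlap = n - i
        if _hamming_leq(seq[i:i + overlap], adapter[:overlap],
                        int(overlap * rate)):
            return i
    return None


def trim_adapter3(read: ReadRecord, config: PreprocessConfig
                  ) -> Optional[ReadRecord]:
    """Trim the read at the leftmost adapter occurrence.

    Returns the insert (the prefix preceding the adapter) or None when no
    adapter is found — such reads are adapter-dimer/garbage by library
    design and are discarded, not kept untrimmed.  An adapter at position 0
    yields an empty insert, also reported as None (discarded downstream in
    either reading; reported here for simple accounting).
    """
    pos = find_adapter(read.sequence, config)
    if pos is None or pos == 0:
        return None
    qual = read.quality[:pos] if read.quality is not None else None
    return ReadRecord(read.read_id, read.sequence[:pos], qual, read.count)


def collapse_exact_duplicates(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Thin completely duplicated sequences to one record each.

    Operates on full trimmed sequences with UMIs still attached, so
    identical inserts carrying different UMIs remain distinct molecules.
    Output is sorted lexicographically by sequence; every surviving record
    has count 1 (this is PCR deduplication, not abundance counting).
    Idempotent.
    """
    first_id: dict[str, str] = {}
    for rec in reads:
        if rec.sequence not in first_id:
            first_id[rec.sequence] = rec.read_id
    return [ReadRecord(first_id[s], s, None, 1) for s in sorted(first_id)]


def strip_umis(read: ReadRecord, config: PreprocessConfig
               ) -> tuple[Optional[ReadRecord], Optional[str]]:
    """Remove the randomized 4-nt ends, keeping the core.

    Returns ``(core_record, discard_reason)``; exactly one of the two is
    None.  The stripped UMI pair is recorded in the read id suffix for
    audit.  Cores not strictly longer than 12 nt (``min_len_after`` - 1)
    are discarded.
    """
    u5, u3 = config.umi_len_5p, config.umi_len_3p
    if len(read.sequence) < u5 + u3 + 1:
        return None, "too_short_for_umi"
    core = read.sequence[u5:len(read.sequence) - u3 or None]
    if len(core) < config.min_len_after:
        return None, "short_core"
    umi5 = read.sequence[:u5]
    umi3 = read.sequence[len(read.sequence) - u3:] if u3 else ""
    rid = f"{read.read_id}|umi={umi5}.{umi3}"
    qual = (read.quality[u5:len(read.quality) - u3 or None]
            if read.quality is not None else None)
    return ReadRecord(rid, core, qual, read.count), None


def length_gate_pirna(reads: Iterable[ReadRecord], lo: int = 23, hi: int = 32
                      ) -> tuple[list[ReadRecord], Counter]:
    """Keep reads with lo <= length <= hi (both inclusive).

    Returns the kept reads and a Counter of discarded lengths.
    """
    if lo > hi:
        raise ValueError(f"length gate misconfigured: lo={lo} > hi={hi}")
    kept: list[ReadRecord] = []
    discarded: Counter = Counter()
    for rec in reads:
        if lo <= len(rec.sequence) <= hi:
            kept.append(rec)
        else:
            discarded[len(rec.sequence)] += 1
    return kept, discarded


def preprocess_reads(reads: Iterable[ReadRecord], config: PreprocessConfig,
                     gate_lo: int = 23, gate_hi: int = 32
                     ) -> tuple[list[ReadRecord], PreprocessReport]:
    """Run trim -> collapse -> strip -> length-gate on one library.

    Returns the surviving piRNA-sized cores (count 1 per unique molecule;
    identical cores from distinct molecules appear as multiple records)
    and a :class:`PreprocessReport` with full discard accounting.
    """
    report = PreprocessReport()
    trimmed: list[ReadRecord] = []
    pos_cache: dict[str, Optional[int]] = {}  # PCR duplicates share sequences
    for rec in reads:
        report.input_reads += 1
        pos = pos_cache.get(rec.sequence, -2)
        if pos == -2:
            pos = find_adapter(rec.sequence, config)
            pos_cache[rec.sequence] = pos
        if pos is None or pos == 0:
            report.no_adapter += 1
        else:
            trimmed.append(ReadRecord(rec.read_id, rec.sequence[:pos],
                                      None, rec.count))
    report.trimmed = len(trimmed)

    unique = collapse_exact_duplicates(trimmed)
    report.unique_molecules = len(unique)

    cores: list[ReadRecord] = []
    for rec in unique:
        core, reason = strip_umis(rec, config)
        if core is not None:
            cores.append(core)
        elif reason == "too_short_for_umi":
            report.too_short_for_umi += 1
        else:
            report.short_core += 1
    report.cores = len(cores)

    gated, discarded = length_gate_pirna(cores, gate_lo, gate_hi)
    report.length_gate_kept = len(gated)
    report.length_gate_discarded_by_length = dict(discarded)
    return gated, report
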
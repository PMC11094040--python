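"""Ping-pong partner analysis and A->S / S->A / S->S classification.

The ping-pong amplification cycle produces piRNA pairs on opposite strands
of a transposon whose 5' ends overlap by exactly 10 complementary
nucleotides.  Given PIWI-IP sequencing libraries (Siwi-IP and BmAgo3-IP),
each reference piRNA is assigned the PIWI protein it is predominantly
bound to, its partner coordinate is derived from the 10-nt overlap
geometry, the partner's bound PIWI is called from 5'-end tallies at that
coordinate, and the piRNA is classified by the flow of RNA fragments:
``X_to_Y`` means the piRNA is bound by Y and was generated by cleavage
guided by an X-bound partner (so the partner's PIWI precedes the arrow).

Exclusions, in order of precedence: piRNAs from an rRNA-carrying TE
(``excl_rrna``); piRNAs whose own or partner call cannot be determined —
equal RPM in the two IPs, or raw counts of at most ``low_count_threshold``
in both (``excl_undetermined``); and BmAgo3-BmAgo3 configurations
(``excl_ambiguous``, the operational reading of BmAgo3-bound piRNAs
abundant on both strands — a switch reports them as an ``A_to_A`` class
instead).  The output is always a partition of the reference set.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .datamodel_io import (
    LibraryCounts,
    PingPongRecord,
    ReferencePiRNA,
    TESequence,
)
from .te_expression import ma_stats

OVERLAP = 10  # nt of 5'-end complementarity in a ping-pong pair


@dataclass
class PiwiAssignment:
    """Which PIWI a reference piRNA is predominantly bound to.

    ``call`` is S when the Siwi-IP RPM strictly exceeds the BmAgo3-IP RPM,
    A for the converse, and undetermined on an RPM tie or when raw counts
    are at most ``low_count_threshold`` in both IP libraries.
    """

    pirna_id: str
    siwi_raw: float
    ago3_raw: float
    siwi_rpm: float
    ago3_rpm: float
    call: str


@dataclass
class PartnerSite:
    """IP abundance at the 10-nt-overlap partner coordinate of a piRNA.

    Reads of any length whose 5' anchor sits at the partner coordinate are
    pooled; the partner does not need to be an annotated reference piRNA.
    A partner coordinate falling outside the TE is recorded as absent
    (``te_id=None``) with an undetermined call.
    """

    pirna_id: str
    te_id: Optional[str]
    strand: Optional[str]
    five_prime_pos: Optional[int]
    siwi_raw: float = 0.0
    ago3_raw: float = 0.0
    siwi_rpm: float = 0.0
    ago3_rpm: float = 0.0
    call: str = "undetermined"


def _call_piwi(siwi_raw: float, ago3_raw: float, siwi_rpm: float,
               ago3_rpm: float, low_count_threshold: float) -> str:
    if max(siwi_raw, ago3_raw) <= low_count_threshold:
        return "undetermined"
    if siwi_rpm > ago3_rpm:
        return "S"
    if ago3_rpm > siwi_rpm:
        return "A"
    return "undetermined"


def assign_piwi(siwi_lib: LibraryCounts, ago3_lib: LibraryCounts,
                refs: Sequence[ReferencePiRNA],
                low_count_threshold: float = 1.0
                ) -> dict[str, PiwiAssignment]:
    """Per-reference-piRNA bound-PIWI call from the two IP libraries.

    Both libraries must carry reference-matched normalization (RPM over
    the total reference-matched read count), the rule used for IP
    libraries.
    """
    for lib in (siwi_lib, ago3_lib):
        if lib.denominator_mode != "reference_matched":
            raise ValueError(
                f"library {lib.library_id!r}: IP assignment requires "
                f"reference_matched normalization, got {lib.denominator_mode!r}"
            )
    out: dict[str, PiwiAssignment] = {}
    for ref in refs:
        pid = ref.pirna_id
        s_raw = siwi_lib.counts.get(pid, 0.0)
        a_raw = ago3_lib.counts.get(pid, 0.0)
        s_rpm = siwi_lib.rpm_of(pid)
        a_rpm = ago3_lib.rpm_of(pid)
        call = _call_piwi(s_raw, a_raw, s_rpm, a_rpm, low_count_threshold)
        out[pid] = PiwiAssignment(pid, s_raw, a_raw, s_rpm, a_rpm, call)
    return out


def partner_coordinate(ref: ReferencePiRNA,
                       panel: Mapping[str, TESequence]
                       ) -> Optional[tuple[str, str, int]]:
    """(te_id, strand, five_prime_pos) of the 10-nt-overlap partner.

    A plus-strand piRNA with 5' at p pairs a minus-strand partner with 5'
    at p+9; a minus-strand piRNA at p pairs a plus-strand partner at p-9 —
    in both cases the two 10-nt 5' prefixes occupy the same ten TE
    positions on opposite strands.  Returns None when the partner 5' falls
    outside the TE.
    """
    te = panel[ref.te_id]
    if ref.strand == "+":
        pos, strand = ref.five_prime_pos + (OVERLAP - 1), "-"
    else:
        pos, strand = ref.five_prime_pos - (OVERLAP - 1), "+"
    if not 1 <= pos <= len(te):
        return None
    return ref.te_id, strand, pos


def partner_abundance(ref: ReferencePiRNA, panel: Mapping[str, TESequence],
                      siwi_tally: Mapping[tuple[str, str, int], float],
                      ago3_tally: Mapping[tuple[str, str, int], float],
                      siwi_denominator: float, ago3_denominator: float,
                      low_count_threshold: float = 1.0) -> PartnerSite:
    """IP abundance and PIWI call at the partner coordinate of ``ref``.

    ``siwi_tally``/``ago3_tally`` are per-library 5'-end tallies keyed by
    (te_id, strand, five_prime_pos), aggregated over read lengths; RPM
    uses the same reference-matched denominators as :func:`assign_piwi`.
    """
    coord = partner_coordinate(ref, panel)
    if coord is None:
        return PartnerSite(ref.pirna_id, None, None, None)
    s_raw = siwi_tally.get(coord, 0.0)
    a_raw = ago3_tally.get(coord, 0.0)
    s_rpm = s_raw / siwi_denominator * 1e6
    a_rpm = a_raw / ago3_denominator * 1e6
    call = _call_piwi(s_raw, a_raw, s_rpm, a_rpm, low_count_threshold)
    return PartnerSite(ref.pirna_id, *coord, s_raw, a_raw, s_rpm, a_rpm, call)


def classify_pingpong(assignments: Mapping[str, PiwiAssignment],
                      partner_sites: Mapping[str, PartnerSite],
                      refs: Sequence[ReferencePiRNA],
                      panel: Mapping[str, TESequence],
                      report_a_to_a: bool = False) -> list[PingPongRecord]:
    """Classify every reference piRNA; output partitions the reference set.

    Precedence: excl_rrna > excl_undetermined > excl_ambiguous > class.
    The class name is ``<partner>_to_<own>``; BmAgo3->BmAgo3 is excluded
    as ambiguous unless ``report_a_to_a``.
    """
    out: list[PingPongRecord] = []
    for ref in refs:
        pid = ref.pirna_id
        if pid not in assignments:
            raise ValueError(f"reference piRNA {pid!r} missing from assignments")
        own = assignments[pid].call
        site = partner_sites.get(pid) or PartnerSite(pid, None, None, None)
        partner = site.call
        if panel[ref.te_id].is_rrna_te:
            klass = "excl_rrna"
        elif own == "undetermined" or partner == "undetermined":
            klass = "excl_undetermined"
        elif own == "A" and partner == "A":
            klass = "A_to_A" if report_a_to_a else "excl_ambiguous"
        else:
            klass = f"{partner}_to_{own}"
        out.append(PingPongRecord(pid, own, site.te_id, site.strand,
                                  site.five_prime_pos, partner, klass))
    return out


def class_counts(records: Sequence[PingPongRecord]) -> dict[str, int]:
    counts = {k: 0 for k in PingPongRecord.CLASSES + PingPongRecord.EXCLUSIONS}
    for rec in records:
        counts[rec.klass] = counts.get(rec.klass, 0) + 1
    return counts


def class_expression_change(records: Sequence[PingPongRecord],
                            ctrl_lib: LibraryCounts, kd_lib: LibraryCounts,
                            pseudocount: float = 1.0
                            ) -> dict[str, dict[str, float]]:
    """Per-class distribution of per-piRNA M values (KD vs control).

    For each of the three ping-pong classes with members: n, median M and
    quartiles.  Under an Spn-E-like knockdown the expected signs are
    median M < 0 for A_to_S and > 0 for S_to_S.  Classes with no members
    are absent from the result.
    """
    by_class: dict[str, list[float]] = {}
    ctrl_rpm, kd_rpm = ctrl_lib.rpm, kd_lib.rpm
    for rec in records:
        if rec.klass not in PingPongRecord.CLASSES and rec.klass != "A_to_A":
            continue
        m, _ = ma_stats(ctrl_rpm.get(rec.pirna_id, 0.0),
                        kd_rpm.get(rec.pirna_id, 0.0), pseudocount)
        by_class.setdefault(rec.klass, []).append(m)
    out: dict[str, dict[str, float]] = {}
    for klass, ms in by_class.items():
        q = statistics.quantiles(ms, n=4) if len(ms) >= 2 else [ms[0]] * 3
        out[klass] = {
            "n": len(ms),
            "median_m": statistics.median(ms),
            "q1_m": q[0],
            "q3_m": q[2],
        }
    return out
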
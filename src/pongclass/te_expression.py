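"""Expression-change (MA) statistics and the three-group piRNA partition.

Knockdown vs control comparison at TE and at reference-piRNA resolution:

* M = log2((kd + c) / (ctrl + c)), the pseudocounted log2 fold change;
* A = (log2(kd + c) + log2(ctrl + c)) / 2, the mean log abundance;

with c a pseudocount in RPM units (default 1).  Ranked by M, the piRNA set
is split into three contiguous near-equal groups — "increased",
"unchanged", "decreased" — mirroring the MA-plot grouping of Spn-E
knockdown analyses.  When n is not divisible by 3, the extra items go to
the outer groups: remainder 1 enlarges "increased"; remainder 2 enlarges
both "increased" and "decreased".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .datamodel_io import LibraryCounts

GROUPS = ("increased", "unchanged", "decreased")


@dataclass
class ExpressionChange:
    key: str
    ctrl_rpm: float
    kd_rpm: float
    a_value: float
    m_value: float
    group: Optional[str] = None  # one of GROUPS, or None when filtered out


def ma_stats(ctrl_rpm: float, kd_rpm: float, pseudocount: float = 1.0
             ) -> tuple[float, float]:
    """Return (M, A) for one key. Negative inputs are an error."""
    if ctrl_rpm < 0 or kd_rpm < 0:
        raise ValueError("rpm values must be >= 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    lc = math.log2(ctrl_rpm + pseudocount)
    lk = math.log2(kd_rpm + pseudocount)
    return lk - lc, (lk + lc) / 2


def expression_filter(ctrl_rpm: Mapping[str, float], kd_rpm: Mapping[str, float],
                      min_rpm: float = 0.0,
                      rrna_keys: frozenset | set | Sequence = ()
                      ) -> list[str]:
    """Keys passing the expression filter: rRNA-TE keys removed first, then
    keep max(ctrl, kd) >= min_rpm.  Sorted for determinism."""
    rrna = set(rrna_keys)
    keys = set(ctrl_rpm) | set(kd_rpm)
    return sorted(
        k for k in keys - rrna
        if max(ctrl_rpm.get(k, 0.0), kd_rpm.get(k, 0.0)) >= min_rpm
    )


def tertile_sizes(n: int) -> tuple[int, int, int]:
    """Sizes of (increased, unchanged, decreased) rank groups.

    Near-equal thirds; remainder 2 -> both outer groups get one extra,
    remainder 1 -> the increased group gets it.  n=2474 -> (825, 824, 825).
    """
    if n < 3:
        raise ValueError(f"need at least 3 keys to form tertiles, got {n}")
    base, rem = divmod(n, 3)
    if rem == 0:
        return base, base, base
    if rem == 1:
        return base + 1, base, base
    return base + 1, base, base + 1


def tertile_groups(keys_ranked_by_m: Sequence[str]) -> dict[str, str]:
    """Assign each key (pre-sorted by M descending, ties broken by key) to
    increased / unchanged / decreased by rank tertile."""
    n = len(keys_ranked_by_m)
    n_inc, n_unch, n_dec = tertile_sizes(n)
    out: dict[str, str] = {}
    for i, k in enumerate(keys_ranked_by_m):
        if i < n_inc:
            out[k] = "increased"
        elif i < n_inc + n_unch:
            out[k] = "unchanged"
        else:
            out[k] = "decreased"
    return out


def pirna_expression_table(ctrl: LibraryCounts, kd: LibraryCounts,
                           pseudocount: float = 1.0, min_rpm: float = 0.0,
                           rrna_keys: Sequence | set = ()
                           ) -> list[ExpressionChange]:
    """Per-piRNA M/A with the filter + tertile grouping applied.

    Filtered-out keys (rRNA-TE, or below ``min_rpm`` in both libraries)
    appear with ``group=None``.  Ranking is by M descending with
    lexicographic tie-break.
    """
    ctrl_rpm, kd_rpm = ctrl.rpm, kd.rpm
    all_keys = sorted(set(ctrl_rpm) | set(kd_rpm))
    kept = expression_filter(ctrl_rpm, kd_rpm, min_rpm, rrna_keys)
    rows = {}
    for k in all_keys:
        c, d = ctrl_rpm.get(k, 0.0), kd_rpm.get(k, 0.0)
        m, a = ma_stats(c, d, pseudocount)
        rows[k] = ExpressionChange(k, c, d, a, m)
    ranked = sorted(kept, key=lambda k: (-rows[k].m_value, k))
    for k, g in tertile_groups(ranked).items():
        rows[k].group = g
    return [rows[k] for k in all_keys]


def te_ma_table(te_ctrl: LibraryCounts, te_kd: LibraryCounts,
                panel_ids: Sequence[str], pseudocount: float = 1.0
                ) -> list[ExpressionChange]:
    """Per-TE M/A table (no tertile grouping at TE level).

    Both libraries must be counted over the same panel; TEs absent from a
    library count as zero.
    """
    unknown = (set(te_ctrl.counts) | set(te_kd.counts)) - set(panel_ids)
    if unknown:
        raise ValueError(f"counts reference TEs outside the panel: {sorted(unknown)}")
    ctrl_rpm, kd_rpm = te_ctrl.rpm, te_kd.rpm
    out = []
    for te_id in sorted(panel_ids):
        c, d = ctrl_rpm.get(te_id, 0.0), kd_rpm.get(te_id, 0.0)
        m, a = ma_stats(c, d, pseudocount)
        out.append(ExpressionChange(te_id, c, d, a, m))
    return out
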
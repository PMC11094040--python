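"""1U/10A nucleotide-bias classification of piRNA sequences.

Siwi-bound piRNAs characteristically carry uridine at position 1 (1U);
BmAgo3-bound piRNAs carry adenine at position 10 (10A) — position 10 being
the nucleotide paired to position 1 of the partner across the 10-nt 5'
overlap of the ping-pong cycle.  Every sequence of length >= 10 falls in
exactly one of four classes: 1U10A, 1U-only, 10A-only, neither.

Positions are 1-based on the mature piRNA; sequences use the DNA alphabet,
so uridine is tested as T.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

BIAS_CLASSES = ("U1A10", "U1_only", "A10_only", "neither")


def classify_bias(sequence: str) -> str:
    """Classify one sequence into U1A10 / U1_only / A10_only / neither."""
    if len(sequence) < 10:
        raise ValueError(
            f"sequence of length {len(sequence)} has no position 10"
        )
    u1 = sequence[0] == "T"
    a10 = sequence[9] == "A"
    if u1 and a10:
        return "U1A10"
    if u1:
        return "U1_only"
    if a10:
        return "A10_only"
    return "neither"


def bias_fraction_table(groups: Mapping[str, Iterable[str]]
                        ) -> dict[str, dict[str, dict[str, float]]]:
    """Per-group counts and fractions of the four bias classes.

    ``groups`` maps a group label to its member sequences.  Empty groups
    are omitted (fractions undefined).  Fractions per group sum to 1.
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for group, seqs in groups.items():
        counts = Counter(classify_bias(s) for s in seqs)
        total = sum(counts.values())
        if total == 0:
            continue
        out[group] = {
            cls: {"count": counts.get(cls, 0),
                  "fraction": counts.get(cls, 0) / total}
            for cls in BIAS_CLASSES
        }
    return out
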
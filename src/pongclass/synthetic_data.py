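"""Synthetic small-RNA study generator with full ground truth.

Builds, from a single seed, everything the analysis consumes: a random
transposon panel with planted ping-pong piRNA pairs (exact 10-nt 5'
overlaps on opposite strands, 1U/10A biases wired into the TE sequence
itself), a reference piRNA annotation, a count model for the four
libraries (Siwi-IP, BmAgo3-IP, control KD, Spn-E-like KD), and raw FASTQ
reads carrying 4-nt randomized UMIs at both adapter junctions, PCR
duplication and substitution errors.

Pair geometry and bias coupling
-------------------------------
A pair is a plus-strand species with 5' at TE position p and a
minus-strand species with 5' at p+9; their 10-nt 5' prefixes cover the
same ten TE positions.  Because the prefixes are complementary, position 1
of one species is the base pair of position 10 of the other: planting a U
at position 1 of a Siwi-bound piRNA automatically plants an A at position
10 of its partner.  Heterotypic pairs therefore draw one biased base
(probability ``bias_1U``) shared by the S-side 1U and the A-side 10A;
homotypic S-S pairs draw both shared bases, making 1U10A species.

Strand roles follow the biology: Siwi-bound piRNAs are antisense (minus
strand of the TE), BmAgo3-bound piRNAs sense (plus strand); homotypic S-S
pairs place Siwi on both strands.

Classes are named for the reference-side species: an ``A_to_S`` pair
contributes a Siwi-bound reference piRNA whose partner is BmAgo3-bound
(the partner itself is generated and sequenced but is not part of the
reference annotation, as real partners need not be annotated).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datamodel_io import (
    LibraryCounts,
    ReferencePiRNA,
    TESequence,
    TruthTable,
    revcomp,
    write_fasta,
    write_fastq,
    write_reference_pirnas,
    ReadRecord,
)
from .preprocess import DEFAULT_ADAPTER3

LIBRARIES = ("siwi_ip", "ago3_ip", "control", "kd")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    ``ip_enrichment`` is the fold by which a species is enriched in the IP
    of its bound PIWI (and depleted in the other); ``math.inf`` gives the
    cognate-only (noiseless-assignment) limit.  ``kd_effects`` are
    abundance fold changes in the knockdown library per ping-pong class:
    A->S piRNAs collapse, S->S piRNAs rise, S->A piRNAs dip mildly —
    the directions of an Spn-E-like knockdown.  ``nb_dispersion`` is the
    negative-binomial dispersion (variance = m + phi * m^2); 0 selects
    Poisson counts.
    """

    seed: int = 7
    n_te: int = 8
    te_length: int = 800
    n_pairs: dict[str, int] = field(default_factory=lambda: {
        "A_to_S": 30, "S_to_A": 30, "S_to_S": 30,
    })
    n_rrna_pirnas: int = 6
    n_offsize: int = 6
    frac_low_count: float = 0.1
    ip_enrichment: float = 8.0
    bias_1U: float = 0.9
    bias_10A: float = 0.9
    kd_effects: dict[str, float] = field(default_factory=lambda: {
        "A_to_S": 0.3, "S_to_A": 0.7, "S_to_S": 2.5,
    })
    depth: int = 200_000
    pcr_duplication_mean: float = 1.5
    seq_error_rate: float = 0.001
    nb_dispersion: float = 0.05
    abundance_sigma: float = 0.75  # log-normal spread of base abundances
    adapter3_core: str = DEFAULT_ADAPTER3

    def __post_init__(self) -> None:
        for p in (self.bias_1U, self.bias_10A, self.frac_low_count):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if any(f <= 0 for f in self.kd_effects.values()):
            raise ValueError("kd_effects folds must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.te_length < 80:
            raise ValueError("te_length must be >= 80")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["ip_enrichment"] = (None if math.isinf(self.ip_enrichment)
                              else self.ip_enrichment)
        return d


@dataclass
class PlantedSpecies:
    """One planted small-RNA species and its ground truth."""

    pirna_id: str
    te_id: str
    strand: str
    five_prime_pos: int
    sequence: str
    bound_piwi: str          # "S" | "A"
    true_class: str          # A_to_S | S_to_A | S_to_S | excl_rrna |
                             # excl_undetermined | offsize
    partner_id: Optional[str]
    in_reference: bool
    low_count: bool = False
    base_abundance: float = 1.0
    kd_fold: float = 1.0


_PAIR_ROLES = {
    # class of the reference-side species -> (ref side, partner side) PIWIs;
    # the reference side sits on the strand its PIWI favors
    "A_to_S": ("S", "A"),
    "S_to_A": ("A", "S"),
    "S_to_S": ("S", "S"),
}


def _rand_te(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)].copy()


def _te_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def simulate_panel(config: SimConfig
                   ) -> tuple[list[TESequence], list[ReferencePiRNA], TruthTable]:
    """Generate the TE panel, reference annotation and ground truth.

    Deterministic in ``config.seed``.  Pairs are placed on a rotating TE
    schedule with generous spacing so 5' anchors never collide; raises
    when the requested pairs do not fit the panel.
    """
    rng = np.random.default_rng(config.seed)
    te_arrays = {f"te{i:02d}": _rand_te(rng, config.te_length)
                 for i in range(config.n_te)}
    rrna_id = "te_rrna"
    te_arrays[rrna_id] = _rand_te(rng, config.te_length)

    te_ids = [t for t in sorted(te_arrays) if t != rrna_id]
    # pair footprint: minus body reaches p-22, plus body reaches p+31
    step, margin = 60, 35
    cursor = {t: margin for t in te_ids}
    species: list[PlantedSpecies] = []

    def next_anchor() -> tuple[str, int]:
        for _ in range(len(te_ids)):
            te = te_ids[next_anchor.rr % len(te_ids)]
            next_anchor.rr += 1
            p = cursor[te]
            if p + margin <= config.te_length - 1:
                cursor[te] = p + step
                return te, p
        raise ValueError("panel too small for the requested planted pairs")
    next_anchor.rr = 0

    n_pairs_total = sum(config.n_pairs.values())
    n_low = int(round(config.frac_low_count * n_pairs_total))
    low_ranks = set(rng.choice(n_pairs_total, size=n_low, replace=False).tolist()
                    ) if n_low else set()

    pair_rank = 0
    for klass in ("A_to_S", "S_to_A", "S_to_S"):
        ref_piwi, partner_piwi = _PAIR_ROLES[klass]
        for i in range(config.n_pairs.get(klass, 0)):
            te, p = next_anchor()
            arr = te_arrays[te]
            q = p + 9  # minus-side 5' (1-based)
            # strand roles: S on minus, A on plus; S_to_S puts S on both
            if klass == "S_to_A":
                ref_strand, partner_strand = "+", "-"
            else:
                ref_strand, partner_strand = "-", "+"
            # bias planting: TE base q is shared by minus-pos1 and plus-pos10,
            # so the minus 1U and the plus 10A are one event (see docstring)
            shared_p = (config.bias_1U if klass == "S_to_S"
                        else max(config.bias_1U, config.bias_10A))
            if rng.random() < shared_p:
                arr[q - 1] = b"A"  # minus 1U and plus 10A
            if klass == "S_to_S" and rng.random() < config.bias_1U:
                arr[p - 1] = b"T"  # plus 1U and minus 10A
            len_minus = int(rng.integers(23, 33))
            len_plus = int(rng.integers(23, 33))
            minus_seq = revcomp(_te_str(arr[q - len_minus:q]))
            plus_seq = _te_str(arr[p - 1:p - 1 + len_plus])
            low = pair_rank in low_ranks
            rid = f"pi_{klass}_{i:03d}"
            pid = f"{rid}_partner"
            if ref_strand == "-":
                ref_seq, ref_pos = minus_seq, q
                par_seq, par_pos = plus_seq, p
            else:
                ref_seq, ref_pos = plus_seq, p
                par_seq, par_pos = minus_seq, q
            true_class = "excl_undetermined" if low else klass
            species.append(PlantedSpecies(rid, te, ref_strand, ref_pos, ref_seq,
                                          ref_piwi, true_class, pid, True, low))
            species.append(PlantedSpecies(pid, te, partner_strand, par_pos,
                                          par_seq, partner_piwi,
                                          _partner_class(klass), rid, False, low))
            pair_rank += 1

    # rRNA-TE piRNAs: annotated, excluded by TE flag regardless of calls
    arr = te_arrays[rrna_id]
    pos = margin
    for i in range(config.n_rrna_pirnas):
        L = int(rng.integers(23, 33))
        seq = _te_str(arr[pos - 1:pos - 1 + L])
        species.append(PlantedSpecies(f"pi_rrna_{i:03d}", rrna_id, "+", pos, seq,
                                      "S" if i % 2 == 0 else "A",
                                      "excl_rrna", None, True))
        pos += step
        if pos + margin > config.te_length:
            raise ValueError("rRNA TE too small for requested rRNA piRNAs")

    # off-size background species (outside 23-32 nt) exercise the length gate
    for i in range(config.n_offsize):
        te, p = next_anchor()
        L = 20 if i % 2 == 0 else 35
        if p - 1 + L > config.te_length:
            continue
        seq = _te_str(te_arrays[te][p - 1:p - 1 + L])
        species.append(PlantedSpecies(f"bg_offsize_{i:03d}", te, "+", p, seq,
                                      "S", "offsize", None, False))

    panel = [TESequence(t, _te_str(a), is_rrna_te=(t == rrna_id))
             for t, a in sorted(te_arrays.items())]
    refs = [ReferencePiRNA(s.pirna_id, s.te_id, s.strand, s.five_prime_pos,
                           s.sequence)
            for s in species if s.in_reference]
    # base abundances and KD folds belong to the truth, drawn here so the
    # panel+truth pair is reproducible from the seed alone
    for s in species:
        s.base_abundance = float(rng.lognormal(0.0, config.abundance_sigma))
        s.kd_fold = config.kd_effects.get(s.true_class if not s.low_count
                                          else _unlowered_class(s), 1.0)
    truth = TruthTable(seed=config.seed, params=config.as_dict(),
                       species=species)
    return panel, refs, truth


def _partner_class(ref_class: str) -> str:
    """Implied class of the partner-side species of a pair."""
    return {"A_to_S": "S_to_A", "S_to_A": "A_to_S", "S_to_S": "S_to_S"}[ref_class]


def _unlowered_class(s: PlantedSpecies) -> str:
    # low-count species keep the KD fold of the class their pair encodes
    pid = s.pirna_id.replace("_partner", "")
    for klass in ("A_to_S", "S_to_A", "S_to_S"):
        if pid.startswith(f"pi_{klass}"):
            return klass if not s.pirna_id.endswith("_partner") \
                else _partner_class(klass)
    return "none"


def simulate_counts(truth: TruthTable, config: SimConfig
                    ) -> dict[str, dict[str, int]]:
    """Draw per-species molecule counts for the four libraries.

    Expected count = depth x (library weight / total library weight); the
    library weight is the species' log-normal base abundance times the IP
    enrichment factor (IP libraries) or the KD fold (kd library).  Counts
    are negative-binomial with dispersion ``nb_dispersion`` (Poisson when
    0).  Low-count species get a fixed tiny IP mean so their IP raw counts
    land at or below the low-count threshold.
    """
    rng = np.random.default_rng(config.seed + 1)
    cognate_only = math.isinf(config.ip_enrichment)
    out: dict[str, dict[str, int]] = {}
    for lib in LIBRARIES:
        weights: dict[str, float] = {}
        for s in truth.species:
            w = s.base_abundance
            if lib in ("siwi_ip", "ago3_ip"):
                cognate = (lib == "siwi_ip") == (s.bound_piwi == "S")
                if cognate_only:
                    w = w if cognate else 0.0
                else:
                    w = w * config.ip_enrichment if cognate \
                        else w / config.ip_enrichment
            elif lib == "kd":
                w = w * s.kd_fold
            weights[s.pirna_id] = w
        total = sum(weights.values())
        means = {k: v / total * config.depth for k, v in weights.items()}
        if lib in ("siwi_ip", "ago3_ip"):
            for s in truth.species:
                if s.low_count:
                    means[s.pirna_id] = 0.4
        counts: dict[str, int] = {}
        for k in sorted(means):
            m = means[k]
            if m == 0:
                counts[k] = 0
            elif config.nb_dispersion > 0:
                n = 1.0 / config.nb_dispersion
                counts[k] = int(rng.negative_binomial(n, n / (n + m)))
            else:
                counts[k] = int(rng.poisson(m))
        out[lib] = counts
    return out


def counts_to_libraries(truth: TruthTable,
                        lib_counts: Mapping[str, Mapping[str, int]]
                        ) -> dict[str, LibraryCounts]:
    """Wrap simulated species counts as normalized LibraryCounts.

    A count-level shortcut past sequencing: reference piRNAs keep their
    counts keyed by pirna_id; IP libraries are reference-matched
    normalized (denominator = total reference count), control/kd use the
    total mapped count as the genome stand-in denominator.
    """
    ref_ids = {s.pirna_id for s in truth.species if s.in_reference}
    roles = {"siwi_ip": "siwi_ip", "ago3_ip": "ago3_ip",
             "control": "control", "kd": "kd"}
    out = {}
    for lib, counts in lib_counts.items():
        ref_counts = {k: float(v) for k, v in counts.items() if k in ref_ids}
        if lib in ("siwi_ip", "ago3_ip"):
            denom = sum(ref_counts.values())
            mode = "reference_matched"
        else:
            denom = sum(counts.values())
            mode = "genome_mapped"
        out[lib] = LibraryCounts(lib, roles[lib], ref_counts,
                                 max(denom, 1e-9), mode)
    return out


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

def _random_umis(rng: np.random.Generator, n: int, k: int) -> list[str]:
    arr = _BASES[rng.integers(0, 4, (n, k))]
    return [row.tobytes().decode() for row in arr]


def _apply_k_errors(seq: str, k: int, rng: np.random.Generator) -> str:
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for p in pos:
        alt = "ACGT".replace(chars[p], "")
        chars[p] = alt[rng.integers(0, 3)]
    return "".join(chars)


def emit_fastq(lib_counts: Mapping[str, Mapping[str, int]], truth: TruthTable,
               config: SimConfig, outdir: str | Path) -> dict:
    """Write one FASTQ per library plus a manifest; returns the manifest.

    Each molecule is ``UMI5(4nt) + insert + UMI3(4nt) + adapter core``,
    PCR-duplicated Geometric(1/pcr_duplication_mean) times; every emitted
    copy independently receives substitution errors at ``seq_error_rate``.
    Read ids embed the originating species (``lib:species:mNN:dNN``), which
    keeps the read-to-truth mapping in the reads themselves; the manifest
    records per-library species counts and the UMI-collision bound (two
    molecules of one species collapse spuriously only when both 4-nt UMI
    pairs coincide, probability 4^-8 per molecule pair).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 2)
    by_id = {s.pirna_id: s for s in truth.species}
    manifest: dict = {
        "seed": config.seed,
        "params": config.as_dict(),
        "umi_pair_collision_probability": 4.0 ** -8,
        "libraries": {},
    }
    paths = {}
    for lib in LIBRARIES:
        counts = lib_counts[lib]
        path = outdir / f"{lib}.fastq"
        n_reads = 0
        with open(path, "w") as fh:
            for sid in sorted(counts):
                c = counts[sid]
                if c == 0:
                    continue
                insert = by_id[sid].sequence
                u5 = _random_umis(rng, c, 4)
                u3 = _random_umis(rng, c, 4)
                if config.pcr_duplication_mean > 1:
                    dups = rng.geometric(1.0 / config.pcr_duplication_mean, c)
                else:
                    dups = np.ones(c, dtype=int)
                read_len = 8 + len(insert) + len(config.adapter3_core)
                total = int(dups.sum())
                if config.seq_error_rate > 0:
                    err_k = rng.binomial(read_len, config.seq_error_rate, total)
                else:
                    err_k = np.zeros(total, dtype=int)
                qual = "I" * read_len
                r = 0
                for j in range(c):
                    base = u5[j] + insert + u3[j] + config.adapter3_core
                    for d in range(int(dups[j])):
                        seq = _apply_k_errors(base, int(err_k[r]), rng)
                        r += 1
                        fh.write(f"@{lib}:{sid}:m{j}:d{d}\n{seq}\n+\n{qual}\n")
                        n_reads += 1
        manifest["libraries"][lib] = {
            "path": str(path),
            "reads": n_reads,
            "molecules": int(sum(counts.values())),
            "species_counts": {k: int(v) for k, v in sorted(counts.items())},
        }
        paths[lib] = path
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def simulate_study(config: SimConfig, outdir: str | Path) -> dict:
    """Full generator run: panel FASTA, reference TSV, truth TSV, 4 FASTQs.

    Returns the manifest augmented with the file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, refs, truth = simulate_panel(config)
    lib_counts = simulate_counts(truth, config)
    manifest = emit_fastq(lib_counts, truth, config, outdir)
    write_fasta(panel, outdir / "panel.fa")
    write_reference_pirnas(refs, outdir / "reference_pirnas.tsv")
    pd.DataFrame([asdict(s) for s in truth.species]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False)
    manifest["panel"] = str(outdir / "panel.fa")
    manifest["reference"] = str(outdir / "reference_pirnas.tsv")
    manifest["truth"] = str(outdir / "truth.tsv")
    manifest["rrna_te_ids"] = [t.te_id for t in panel if t.is_rrna_te]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
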
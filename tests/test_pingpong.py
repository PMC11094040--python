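"""PIWI assignment, 10-nt-overlap partner geometry, and classification."""

import numpy as np
import pytest

from pongclass import (
    LibraryCounts,
    ReferencePiRNA,
    SimConfig,
    TESequence,
    assign_piwi,
    class_counts,
    class_expression_change,
    classify_pingpong,
    counts_to_libraries,
    partner_abundance,
    partner_coordinate,
    simulate_counts,
    simulate_panel,
)
from pongclass.datamodel_io import revcomp
from pongclass.pingpong import PartnerSite, PiwiAssignment


def _ip_lib(counts, role):
    return LibraryCounts(role, role, counts,
                         sum(counts.values()) or 1, "reference_matched")


def _ref_on(te, pirna_id="p1", strand="+", pos=21, length=24):
    if strand == "+":
        seq = te.sequence[pos - 1:pos - 1 + length]
    else:
        seq = revcomp(te.sequence[pos - length:pos])
    return ReferencePiRNA(pirna_id, te.te_id, strand, pos, seq)


class TestAssignPiwi:
    def test_clear_siwi_call(self, tiny_panel):
        refs = [_ref_on(tiny_panel[0])]
        siwi = _ip_lib({"p1": 40}, "siwi_ip")
        ago3 = _ip_lib({"p1": 5, "q": 35}, "ago3_ip")
        assert assign_piwi(siwi, ago3, refs)["p1"].call == "S"

    def test_low_count_undetermined(self, tiny_panel):
        # at most 1 read in both IP libraries -> no call
        refs = [_ref_on(tiny_panel[0])]
        siwi = _ip_lib({"p1": 1, "x": 99}, "siwi_ip")
        ago3 = _ip_lib({"x": 100}, "ago3_ip")
        assert assign_piwi(siwi, ago3, refs)["p1"].call == "undetermined"

    def test_rpm_tie_undetermined(self, tiny_panel):
        refs = [_ref_on(tiny_panel[0])]
        siwi = _ip_lib({"p1": 10, "x": 90}, "siwi_ip")
        ago3 = _ip_lib({"p1": 10, "x": 90}, "ago3_ip")
        assert assign_piwi(siwi, ago3, refs)["p1"].call == "undetermined"

    def test_wrong_normalization_rejected(self, tiny_panel):
        refs = [_ref_on(tiny_panel[0])]
        bad = LibraryCounts("s", "siwi_ip", {"p1": 5}, 5, "genome_mapped")
        with pytest.raises(ValueError, match="reference_matched"):
            assign_piwi(bad, _ip_lib({"p1": 5}, "ago3_ip"), refs)


class TestPartnerCoordinate:
    def test_plus_strand_by_base_pairing_enumeration(self, tiny_panel):
        """The two 10-nt 5' prefixes occupy TE positions 101-110 and are
        exact reverse complements — checked base by base."""
        te = TESequence("te", "".join(
            np.random.default_rng(1).choice(list("ACGT"), 200)))
        ref = _ref_on(te, strand="+", pos=101)
        coord = partner_coordinate(ref, {"te": te})
        assert coord == ("te", "-", 110)
        partner_prefix = revcomp(te.sequence[110 - 10:110])[:10]
        ref_prefix = ref.sequence[:10]
        assert partner_prefix == revcomp(ref_prefix)
        for i in range(10):  # explicit pairing: ref pos i+1 vs partner pos 10-i
            pair = {"A": "T", "T": "A", "C": "G", "G": "C"}
            assert partner_prefix[9 - i] == pair[ref_prefix[i]]

    def test_minus_strand_inverse(self, tiny_panel):
        te = tiny_panel[0]
        ref = _ref_on(te, strand="-", pos=110)
        assert partner_coordinate(ref, {"te_a": te}) == ("te_a", "+", 101)

    def test_near_start_still_valid(self):
        te = TESequence("te", "ACGT" * 50)  # 200 nt
        ref = ReferencePiRNA("p", "te", "+", 3, te.sequence[2:2 + 23])
        assert partner_coordinate(ref, {"te": te}) == ("te", "-", 12)

    def test_partner_outside_te_absent(self):
        # a minus-strand 5' at position 5 would need its partner at -4;
        # such an annotation implies a truncated body, so only the anchor
        # fields matter here
        te = TESequence("te", "ACGT" * 10)  # 40 nt
        ref = ReferencePiRNA("p", "te", "-", 5, "ACGTACGTACGTACGTACGTACG")
        assert partner_coordinate(ref, {"te": te}) is None

    def test_symmetry(self, tiny_panel):
        """If q is p's partner coordinate then p is q's (in bounds)."""
        te = tiny_panel[0]
        panel = {"te_a": te}
        for pos, strand in [(50, "+"), (80, "-"), (120, "+")]:
            ref = _ref_on(te, "p", strand, pos)
            te_id, pstrand, ppos = partner_coordinate(ref, panel)
            back = _ref_on(te, "q", pstrand, ppos)
            assert partner_coordinate(back, panel) == ("te_a", strand, pos)


class TestPartnerAbundance:
    def test_partner_bound_to_ago3(self, tiny_panel):
        te = tiny_panel[0]
        ref = _ref_on(te, strand="+", pos=50)
        site = partner_abundance(ref, {"te_a": te},
                                 siwi_tally={},
                                 ago3_tally={("te_a", "-", 59): 30},
                                 siwi_denominator=1000, ago3_denominator=1000)
        assert site.call == "A"
        assert site.ago3_rpm == pytest.approx(30000)

    def test_lengths_pooled_at_anchor(self, tiny_panel):
        # two read lengths share the partner 5' anchor; tally already pools
        # by construction, so totals reflect both
        te = tiny_panel[0]
        ref = _ref_on(te, strand="+", pos=50)
        tally = {("te_a", "-", 59): 12 + 8}  # 25-nt and 28-nt reads
        site = partner_abundance(ref, {"te_a": te}, tally, {}, 100, 100)
        assert site.siwi_raw == 20 and site.call == "S"

    def test_no_reads_undetermined(self, tiny_panel):
        te = tiny_panel[0]
        ref = _ref_on(te, strand="+", pos=50)
        site = partner_abundance(ref, {"te_a": te}, {}, {}, 100, 100)
        assert site.call == "undetermined"


def _toy_setup():
    """Six reference piRNAs, one per outcome (3 classes + 3 exclusions)."""
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), 600))
    te = TESequence("te", seq)
    rrna = TESequence("rte", seq, is_rrna_te=True)
    panel = {"te": te, "rte": rrna}
    refs = [_ref_on(te, f"p{i}", "+", 40 + 60 * i) for i in range(5)]
    refs.append(_ref_on(rrna, "p5", "+", 40))
    calls = {  # own call, partner call
        "p0": ("S", "A"),  # A_to_S
        "p1": ("A", "S"),  # S_to_A
        "p2": ("S", "S"),  # S_to_S
        "p3": ("undetermined", "S"),  # excl_undetermined
        "p4": ("A", "A"),  # excl_ambiguous
        "p5": ("S", "A"),  # excl_rrna wins over the would-be class
    }
    assignments = {p: PiwiAssignment(p, 10, 10, 10, 10, c[0])
                   for p, c in calls.items()}
    sites = {p: PartnerSite(p, refs[i].te_id, "-",
                            refs[i].five_prime_pos + 9, call=calls[p][1])
             for i, p in enumerate(calls)}
    return panel, refs, assignments, sites


class TestClassify:
    def test_partner_to_own_naming(self, tiny_panel):
        panel, refs, assignments, sites = _toy_setup()
        by_id = {r.pirna_id: r.klass
                 for r in classify_pingpong(assignments, sites, refs, panel)}
        assert by_id == {"p0": "A_to_S", "p1": "S_to_A", "p2": "S_to_S",
                         "p3": "excl_undetermined", "p4": "excl_ambiguous",
                         "p5": "excl_rrna"}

    def test_partition_sums_to_reference_size(self):
        panel, refs, assignments, sites = _toy_setup()
        records = classify_pingpong(assignments, sites, refs, panel)
        assert sum(class_counts(records).values()) == len(refs)

    def test_a_to_a_switch(self):
        panel, refs, assignments, sites = _toy_setup()
        records = classify_pingpong(assignments, sites, refs, panel,
                                    report_a_to_a=True)
        assert {r.klass for r in records if r.pirna_id == "p4"} == {"A_to_A"}

    def test_missing_assignment_rejected(self):
        panel, refs, assignments, sites = _toy_setup()
        del assignments["p2"]
        with pytest.raises(ValueError, match="p2"):
            classify_pingpong(assignments, sites, refs, panel)

    def test_swapping_ip_libraries_swaps_s_and_a_roles(self):
        """Feeding the BmAgo3-IP data as the Siwi-IP input (and vice versa)
        swaps every S and A call, so A_to_S <-> S_to_A exactly, homotypic
        S-S configurations become homotypic A-A, and exclusions that do not
        depend on the S/A identity are unchanged."""
        sim = SimConfig(seed=21, depth=30000)
        panel_list, refs, truth = simulate_panel(sim)
        panel = {t.te_id: t for t in panel_list}
        raw = simulate_counts(truth, sim)
        libs = counts_to_libraries(truth, raw)

        def tally(libname):
            t = {}
            for sp in truth.species:
                key = (sp.te_id, sp.strand, sp.five_prime_pos)
                t[key] = t.get(key, 0) + raw[libname][sp.pirna_id]
            return t

        t_s, t_a = tally("siwi_ip"), tally("ago3_ip")

        def classify_with(siwi, ago3, ts, ta):
            assignments = assign_piwi(siwi, ago3, refs)
            sites = {r.pirna_id: partner_abundance(
                r, panel, ts, ta, siwi.denominator, ago3.denominator)
                for r in refs}
            return {r.pirna_id: r.klass for r in classify_pingpong(
                assignments, sites, refs, panel, report_a_to_a=True)}

        fwd = classify_with(libs["siwi_ip"], libs["ago3_ip"], t_s, t_a)
        as_siwi = LibraryCounts("siwi_ip", "siwi_ip", libs["ago3_ip"].counts,
                                libs["ago3_ip"].denominator,
                                "reference_matched")
        as_ago3 = LibraryCounts("ago3_ip", "ago3_ip", libs["siwi_ip"].counts,
                                libs["siwi_ip"].denominator,
                                "reference_matched")
        swapped = classify_with(as_siwi, as_ago3, t_a, t_s)
        swap = {"A_to_S": "S_to_A", "S_to_A": "A_to_S", "S_to_S": "A_to_A",
                "A_to_A": "S_to_S", "excl_rrna": "excl_rrna",
                "excl_undetermined": "excl_undetermined"}
        assert any(k in ("A_to_S", "S_to_A", "S_to_S") for k in fwd.values())
        for pid, k in fwd.items():
            assert swapped[pid] == swap[k]


class TestClassExpression:
    def test_identical_libraries_zero_medians(self):
        panel, refs, assignments, sites = _toy_setup()
        records = classify_pingpong(assignments, sites, refs, panel)
        lib = LibraryCounts("c", "control", {f"p{i}": 10 for i in range(6)}, 60)
        kd = LibraryCounts("k", "kd", {f"p{i}": 10 for i in range(6)}, 60)
        out = class_expression_change(records, lib, kd)
        assert all(v["median_m"] == 0 for v in out.values())

    def test_kd_folds_separate_classes_and_permutation_destroys_it(self):
        """Planted folds 0.3 (A->S) and 2.5 (S->S) push the class medians
        past -1 and +1; permuting labels collapses the separation."""
        sim = SimConfig(seed=13)
        _, _, truth = simulate_panel(sim)
        libs = counts_to_libraries(truth, simulate_counts(truth, sim))
        records = []
        from pongclass.datamodel_io import PingPongRecord
        for sp in truth.species:
            if sp.in_reference and sp.true_class in PingPongRecord.CLASSES:
                records.append(PingPongRecord(
                    sp.pirna_id, "S", None, None, None, "S", sp.true_class))
        out = class_expression_change(records, libs["control"], libs["kd"])
        assert out["A_to_S"]["median_m"] <= -1
        assert out["S_to_S"]["median_m"] >= 1
        real_gap = out["S_to_S"]["median_m"] - out["A_to_S"]["median_m"]

        rng = np.random.default_rng(99)
        labels = [r.klass for r in records]
        rng.shuffle(labels)
        permuted = [PingPongRecord(r.pirna_id, "S", None, None, None, "S", k)
                    for r, k in zip(records, labels)]
        pout = class_expression_change(permuted, libs["control"], libs["kd"])
        perm_gap = abs(pout["S_to_S"]["median_m"] - pout["A_to_S"]["median_m"])
        assert perm_gap < real_gap / 2
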
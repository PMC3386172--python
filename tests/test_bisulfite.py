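import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from msapkit.bisulfite import (
    BisulfiteRead,
    ReferenceSeq,
    align_converted,
    call_sites,
    classify_context,
    compare_conditions,
    consensus_calls,
    estimate_conversion_rate,
    methylation_percent,
)
from msapkit.errors import (
    EmptyInputError,
    IncompatibleReportError,
    InvalidPositionError,
    LowQualityAlignmentError,
)
from msapkit.simulate import simulate_bisulfite_reads

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


def calls_for(ref, read_seq, **kwargs):
    read = BisulfiteRead("r", read_seq)
    return call_sites(align_converted(ref, read, **kwargs), ref)


@pytest.mark.parametrize("seq,pos,expected", [
    ("ACGT", 2, "CG"),
    ("ACAGT", 2, "CHG"),
    ("ACAAT", 2, "CHH"),
    ("ACG", 2, "CG"),        # CG resolvable with a single trailing base
    ("AAC", 3, "undefined"),  # cannot tell CHG from CHH at the edge
    ("AC", 2, "undefined"),
    ("ACNG", 2, "undefined"),
    ("ACAN", 2, "undefined"),
])
def test_classify_context_definitions_and_boundaries(seq, pos, expected):
    assert classify_context(ReferenceSeq("x", seq), pos) == expected


def test_classify_context_rejects_non_c_or_out_of_range():
    ref = ReferenceSeq("x", "ACGT")
    with pytest.raises(InvalidPositionError):
        classify_context(ref, 1)
    with pytest.raises(InvalidPositionError):
        classify_context(ref, 5)


@given(dna)
@settings(max_examples=200, deadline=None)
def test_context_partition_covers_every_cytosine(seq):
    ref = ReferenceSeq("x", seq)
    contexts = [classify_context(ref, i + 1)
                for i, b in enumerate(seq) if b == "C"]
    assert len(contexts) == seq.count("C")
    assert set(contexts) <= {"CG", "CHG", "CHH", "undefined"}


def test_alignment_of_identical_sequences_is_identity():
    ref = ReferenceSeq("x", "ACGTACGT")
    aln = align_converted(ref, BisulfiteRead("r", "ACGTACGT"))
    assert (aln.indices >= 0).all()
    assert aln.indices.shape[1] == 8


def test_single_conversion_aligns_without_gaps():
    ref = ReferenceSeq("x", "ACGT")
    aln = align_converted(ref, BisulfiteRead("r", "ATGT"))
    assert aln.indices.shape[1] == 4
    assert (aln.indices >= 0).all()


def test_low_identity_alignment_raises():
    ref = ReferenceSeq("x", "ACGTACGTACGTACGTACGT")
    with pytest.raises(LowQualityAlignmentError):
        align_converted(ref, BisulfiteRead("r", "GGGGGGGGGGGGGGGGGGGG"))


@pytest.mark.parametrize("read_seq,call", [
    ("ACGT", "methylated"),
    ("ATGT", "unmethylated"),
    ("ANGT", "ambiguous"),
])
def test_call_at_a_cg_site(read_seq, call):
    ref = ReferenceSeq("x", "ACGT")
    (only,) = calls_for(ref, read_seq)
    assert (only.ref_pos, only.context, only.call) == (2, "CG", call)


def test_calls_survive_small_indels(ref300):
    """Deleting two read bases far from the cytosines leaves every other
    site's call unchanged."""
    reads, _ = simulate_bisulfite_reads(ref300, 0.8, 0.3, 0.05,
                                        conversion_rate=0.99, n_reads=1, seed=4)
    read = reads[0]
    seq = read.seq
    mutated = seq[:50] + seq[51:200] + seq[201:]  # drop positions 51 and 201
    base = {c.ref_pos: c.call for c in calls_for(ref300, seq)}
    with_indels = {c.ref_pos: c.call
                   for c in calls_for(ref300, mutated, min_identity=0.5)}
    affected = {51, 201}
    shared = set(base) & set(with_indels) - affected
    assert len(shared) >= len(base) - 6  # indel neighbourhoods may drop out
    assert all(base[p] == with_indels[p] for p in shared)


def test_probability_extremes_recover_perfectly(ref300):
    reads0, _ = simulate_bisulfite_reads(ref300, 0, 0, 0, conversion_rate=1.0,
                                         n_reads=2, seed=0)
    for read in reads0:
        assert all(c.call == "unmethylated"
                   for c in call_sites(align_converted(ref300, read), ref300))
    reads1, _ = simulate_bisulfite_reads(ref300, 1, 1, 1, n_reads=2, seed=0)
    for read in reads1:
        assert read.seq == ref300.seq
        assert all(c.call == "methylated"
                   for c in call_sites(align_converted(ref300, read), ref300))


def test_methylation_percent_direct_formula(ref300):
    calls = calls_for(ref300, ref300.seq)  # untouched ref: everything "methylated"
    report = methylation_percent(calls, ref_id=ref300.id)
    assert report.overall_pct == 100.0
    n_c = sum(report.n_total.values())
    assert n_c <= ref300.seq.count("C")
    assert all(report.pct[c] in (100.0, None) for c in ("CG", "CHG", "CHH"))


def test_methylation_percent_excludes_ambiguous_and_errors_when_all_are():
    ref = ReferenceSeq("x", "ACGTACGT")
    calls = calls_for(ref, "ANGTATGT")
    report = methylation_percent(calls)
    assert report.n_total["CG"] == 1  # the ambiguous CG call is excluded
    assert report.pct["CG"] == 0.0
    with pytest.raises(EmptyInputError):
        methylation_percent([c for c in calls if c.call == "ambiguous"])


def test_context_probability_recovery_within_99pct_binomial_ci(ref300):
    """Per-context methylated fractions estimated from 50 simulated reads
    fall inside the 99% binomial CI around the generating probabilities."""
    truth_p = {"CG": 0.8, "CHG": 0.3, "CHH": 0.05}
    reads, _ = simulate_bisulfite_reads(
        ref300, truth_p["CG"], truth_p["CHG"], truth_p["CHH"],
        conversion_rate=1.0, n_reads=50, seed=42)
    n_meth = {c: 0 for c in truth_p}
    n_tot = {c: 0 for c in truth_p}
    for read in reads:
        for c in call_sites(align_converted(ref300, read), ref300):
            if c.context in truth_p and c.call != "ambiguous":
                n_tot[c.context] += 1
                n_meth[c.context] += c.call == "methylated"
    for ctx, p in truth_p.items():
        lo, hi = stats.binom.interval(0.99, n_tot[ctx], p)
        assert lo <= n_meth[ctx] <= hi, (ctx, n_meth[ctx], n_tot[ctx])


def test_calls_invariant_to_non_c_padding():
    ref = ReferenceSeq("x", "ACGTACAGT")
    padded = ReferenceSeq("x", "TTTT" + "ACGTACAGT" + "AAAA")
    base = calls_for(ref, "ATGTACAGT")
    shifted = calls_for(padded, "TTTT" + "ATGTACAGT" + "AAAA")
    assert [(c.ref_pos + 4, c.call, c.context) for c in base] == \
           [(c.ref_pos, c.call, c.context) for c in shifted]


def test_consensus_majority_and_ties(ref300):
    ref = ReferenceSeq("x", "ACGT")
    meth = calls_for(ref, "ACGT")
    unmeth = calls_for(ref, "ATGT")
    (c,) = consensus_calls([meth, meth, unmeth])
    assert c.call == "methylated"
    (c,) = consensus_calls([meth, unmeth])
    assert c.call == "ambiguous"


def test_conversion_rate_qc_estimate(ref300):
    reads, _ = simulate_bisulfite_reads(ref300, 0, 0, 0, conversion_rate=0.95,
                                        n_reads=50, seed=8)
    calls = [c for read in reads
             for c in call_sites(align_converted(ref300, read), ref300)]
    chh = [c for c in calls if c.context == "CHH"]
    est = estimate_conversion_rate(chh)
    assert est == pytest.approx(0.95, abs=0.03)


def test_compare_conditions_detects_flips(ref300):
    control = methylation_percent(calls_for(ref300, ref300.seq), ref_id=ref300.id)
    comparison = compare_conditions(control, control)
    assert comparison.delta_overall == 0.0
    assert comparison.demethylation_events == ()

    # unconvert-one-site stress read: flip the first CG site to T
    first_cg = next(c.ref_pos for c in control.calls if c.context == "CG")
    stress_seq = (ref300.seq[:first_cg - 1] + "T" + ref300.seq[first_cg:])
    stress = methylation_percent(calls_for(ref300, stress_seq), ref_id=ref300.id)
    comparison = compare_conditions(control, stress)
    assert comparison.demethylation_events == (first_cg,)
    assert comparison.methylation_events == ()
    assert comparison.delta_pct["CG"] < 0


def test_compare_conditions_rejects_mismatched_references(ref300):
    a = methylation_percent(calls_for(ref300, ref300.seq), ref_id="A")
    b = methylation_percent(calls_for(ref300, ref300.seq), ref_id="B")
    with pytest.raises(IncompatibleReportError):
        compare_conditions(a, b)
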
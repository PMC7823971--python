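"""Window counting, metrics and tiling against a brute-force oracle."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytocomp import (
    ContractViolation,
    MaskedSequenceRecord,
    ParameterError,
    count_window,
    profile_sequence,
    window_metrics,
)

from conftest import ALPHABET_FULL, random_sequence
from oracle import oracle_counts, oracle_metrics, oracle_profile


def rec(seq: str, rid: str = "t") -> MaskedSequenceRecord:
    return MaskedSequenceRecord(id=rid, description=rid, residues=seq)


# ---------------------------------------------------------------------------
# count_window
# ---------------------------------------------------------------------------


def test_count_window_mixed_case_example():
    counts = count_window(rec("ACGTacgt"), 0, 8)
    assert counts.upper_counts == {"A": 1, "C": 1, "G": 1, "T": 1}
    assert counts.lower_counts == {"a": 1, "c": 1, "g": 1, "t": 1}
    assert counts.other_count == 0


def test_count_window_all_n_is_other():
    counts = count_window(rec("NNNNNNNN"), 0, 8)
    assert counts.other_count == 8
    assert sum(counts.upper_counts.values()) + sum(counts.lower_counts.values()) == 0


def test_count_window_start_out_of_range():
    with pytest.raises(ContractViolation):
        count_window(rec("ACGT"), 4, 1)
    with pytest.raises(ContractViolation):
        count_window(rec("ACGT"), -1, 1)


def test_count_window_random_starts_match_oracle(rng):
    seq = random_sequence(rng, 100_000)
    record = rec(seq)
    for _ in range(25):
        start = rng.randrange(len(seq))
        size = rng.randrange(1, 5000)
        counts = count_window(record, start, size)
        upper, lower, other = oracle_counts(seq, start, size)
        assert (counts.upper_counts, counts.lower_counts, counts.other_count) == (
            upper, lower, other,
        )
        assert counts.covered == min(size, len(seq) - start)


# ---------------------------------------------------------------------------
# window_metrics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("ACGTacgt", dict(gc_pct=50.0, rep_pct=50.0, gc_pct_masked=50.0,
                          gc_pct_unmasked=50.0, counted_bases=8)),
        ("GGGGgggg", dict(gc_pct=100.0, rep_pct=50.0, gc_pct_masked=100.0,
                          gc_pct_unmasked=100.0, counted_bases=8)),
        ("NNNN", dict(gc_pct=None, rep_pct=None, gc_pct_masked=None,
                      gc_pct_unmasked=None, counted_bases=0)),
        # repeats can carry all the GC of a window: unique DNA 0% GC,
        # repeat DNA 100% GC, overall 50%
        ("AATTggcc", dict(gc_pct=50.0, rep_pct=50.0, gc_pct_masked=100.0,
                          gc_pct_unmasked=0.0, counted_bases=8)),
    ],
)
def test_window_metrics_examples(seq, expected):
    record = window_metrics(count_window(rec(seq), 0, len(seq)))
    for key, value in expected.items():
        assert getattr(record, key) == value


def test_fully_lowercase_window_is_100pct_repeats():
    record = window_metrics(count_window(rec("gggg"), 0, 4))
    assert record.rep_pct == 100.0 and record.gc_pct == 100.0
    assert record.gc_pct_unmasked is None  # empty unmasked fraction


# ---------------------------------------------------------------------------
# profile_sequence
# ---------------------------------------------------------------------------


def test_55_41_mbp_chromosome_yields_55410_windows():
    # a 55.41 Mbp chromosome at w=1 kbp must plot as exactly 55,410 points
    record = rec("A" * 55_410_000)
    profile = profile_sequence(record, 1000)
    assert len(profile) == 55_410


def test_trailing_partial_window_emitted(rng):
    seq = random_sequence(rng, 10_250)
    profile = profile_sequence(rec(seq), 1000)
    assert len(profile) == 11
    rows = oracle_profile(seq, 1000)
    last = profile.records[-1]
    assert last.counted_bases == rows[-1]["counted_bases"]
    assert last.start_bp == 10_001
    for got, want in zip(profile.records, rows):
        assert got.gc_pct == want["gc_pct"]
        assert got.rep_pct == want["rep_pct"]


def test_gc_is_strand_symmetric(rng):
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    seq = random_sequence(rng, 1000, alphabet="ACGTacgt")
    revcomp = seq.translate(comp)[::-1]
    fwd = profile_sequence(rec(seq), 1000).records[0]
    back = profile_sequence(rec(revcomp), 1000).records[0]
    assert fwd.gc_pct == back.gc_pct
    assert fwd.rep_pct == back.rep_pct


def test_window_size_below_one_rejected():
    with pytest.raises(ParameterError):
        profile_sequence(rec("ACGT"), 0)


def test_zero_length_record_gives_empty_profile():
    profile = profile_sequence(rec(""), 1000)
    assert len(profile) == 0 and profile.record_length == 0


def test_consecutive_start_positions():
    profile = profile_sequence(rec("ACGT" * 1000), 7)
    for k, record in enumerate(profile.records, start=1):
        assert record.index == k
        assert record.start_bp == (k - 1) * 7 + 1


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    seq=st.text(alphabet=ALPHABET_FULL, min_size=1, max_size=3000),
    w=st.sampled_from([1, 7, 256, 1000]),
)
def test_profile_matches_bruteforce_oracle(seq, w):
    profile = profile_sequence(rec(seq), w)
    rows = oracle_profile(seq, w)
    assert len(profile) == len(rows) == math.ceil(len(seq) / w)
    for got, want in zip(profile.records, rows):
        assert got.index == want["index"]
        assert got.start_bp == want["start_bp"]
        assert got.counted_bases == want["counted_bases"]
        for key in ("gc_pct", "rep_pct", "gc_pct_masked", "gc_pct_unmasked"):
            assert getattr(got, key) == want[key], key


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seq=st.text(alphabet=ALPHABET_FULL, min_size=1, max_size=2000),
       w=st.integers(min_value=1, max_value=500))
def test_window_counts_conserve_whole_record_count(seq, w):
    record = rec(seq)
    whole = count_window(record, 0, len(seq))
    windows = [count_window(record, s, w) for s in range(0, len(seq), w)]
    for base in "ACGT":
        assert sum(c.upper_counts[base] for c in windows) == whole.upper_counts[base]
    for base in "acgt":
        assert sum(c.lower_counts[base] for c in windows) == whole.lower_counts[base]
    assert sum(c.other_count for c in windows) == whole.other_count


def test_case_flip_zeroes_or_saturates_rep(rng):
    seq = random_sequence(rng, 20_000)
    w = 1000
    base = profile_sequence(rec(seq), w)
    upper = profile_sequence(rec(seq.upper()), w)
    lower = profile_sequence(rec(seq.lower()), w)
    for b, u, l in zip(base.records, upper.records, lower.records):
        assert u.gc_pct == b.gc_pct  # case carries no GC information
        assert l.gc_pct == b.gc_pct
        if b.counted_bases > 0:
            assert u.rep_pct == 0.0
            assert l.rep_pct == 100.0


def test_3w_window_is_weighted_mean_of_w_windows(rng):
    seq = random_sequence(rng, 30_000 + 1234)
    w = 500
    fine = profile_sequence(rec(seq), w).records
    coarse = profile_sequence(rec(seq), 3 * w).records
    for k, big in enumerate(coarse):
        parts = fine[3 * k : 3 * k + 3]
        weight = sum(p.counted_bases for p in parts)
        assert weight == big.counted_bases
        if weight == 0:
            assert big.gc_pct is None
            continue
        mean = sum(p.gc_pct * p.counted_bases for p in parts if p.gc_pct is not None) / weight
        assert big.gc_pct == pytest.approx(mean, abs=1e-9)


def test_parameter_recovery_from_known_gc_probability():
    # windows over a p=0.41 Bernoulli GC sequence must average to 100p
    # within 4 binomial standard deviations
    import numpy as np

    from cytocomp import GenomeSpec, SegmentSpec, generate_records

    p = 0.41
    n = 1_000_000
    spec = GenomeSpec(
        chromosomes=(("c", (SegmentSpec(n, gc_prob=p),)),), seed=99
    )
    record = generate_records(spec)[0]
    profile = profile_sequence(record, 1000)
    mean_gc = float(np.mean([r.gc_pct for r in profile.records]))
    tol = 4 * (p * (1 - p) / n) ** 0.5 * 100
    assert abs(mean_gc - 100 * p) < tol
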
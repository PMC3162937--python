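"""The two-entropy score: entropies, corner distance, aggregation, ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sstea.bw import BWPosition, TM_POSITIONS, parse_bw
from sstea.msa import ALPHABET, AlignedRecord, TMAlignment
from sstea.score import (
    MAX_ENTROPY,
    EntropyPair,
    aggregate_branches,
    column_entropy,
    combined_score,
    score_with_subfamilies,
    two_entropy,
)
from sstea.simulate import default_spec, generate_msa
from sstea.tree import Subfamily


@pytest.mark.parametrize(
    "column,expected",
    [
        ("D" * 50, 0.0),
        (ALPHABET, math.log(20)),
        ("A" * 10 + "V" * 10, math.log(2)),
    ],
)
def test_column_entropy_analytic_cases(column, expected):
    assert column_entropy(column) == pytest.approx(expected)


def test_column_entropy_excludes_ambiguity_codes():
    assert column_entropy("DDDDXX") == 0.0
    with pytest.raises(ValueError, match="no countable"):
        column_entropy("XXX")
    with pytest.raises(ValueError):
        column_entropy("D-D")


def test_entropy_is_symbol_relabeling_invariant():
    col = "A" * 7 + "V" * 3 + "W" * 2
    relabeled = col.translate(str.maketrans("AVW", "KYC"))
    assert column_entropy(col) == pytest.approx(column_entropy(relabeled))


def _two_group_alignment(inside_cols, outside_cols):
    """n_in + n_out records; column 0 varies, the rest is constant 'A'."""
    recs = []
    for i, c in enumerate(inside_cols):
        recs.append(AlignedRecord(f"in{i}", "sp", c + "A" * 170))
    for i, c in enumerate(outside_cols):
        recs.append(AlignedRecord(f"out{i}", "sp", c + "A" * 170))
    sf = Subfamily(frozenset(f"in{i}" for i in range(len(inside_cols))), len(inside_cols))
    return TMAlignment(recs), sf


def test_two_entropy_composes_analytic_cases():
    aln, sf = _two_group_alignment("D" * 10, ALPHABET)
    pair = two_entropy(aln, sf, BWPosition(1, 33))
    assert pair.e_in == 0.0
    assert pair.e_out == pytest.approx(math.log(20))
    assert pair.n_in + pair.n_out == len(aln)


def test_two_entropy_matches_brute_force_recount():
    rng = np.random.default_rng(4)
    inside = "".join(ALPHABET[a] for a in rng.integers(20, size=12))
    outside = "".join(ALPHABET[a] for a in rng.integers(20, size=25))
    aln, sf = _two_group_alignment(inside, outside)
    pair = two_entropy(aln, sf, BWPosition(1, 33))

    def brute(col):
        n = len(col)
        return -sum(
            (col.count(a) / n) * math.log(col.count(a) / n)
            for a in set(col)
        )

    assert pair.e_in == pytest.approx(brute(inside))
    assert pair.e_out == pytest.approx(brute(outside))


def test_two_entropy_requires_nonempty_out_set():
    aln, _ = _two_group_alignment("DD", "DD")
    full = Subfamily(frozenset(aln.ids), 4)
    with pytest.raises(ValueError, match="out-set"):
        two_entropy(aln, full, BWPosition(1, 33))


@pytest.mark.parametrize(
    "e_in,e_out,expected",
    [
        (0.0, MAX_ENTROPY, 0.0),
        (MAX_ENTROPY, 0.0, math.sqrt(2)),
        (0.5 * MAX_ENTROPY, 0.5 * MAX_ENTROPY, math.sqrt(0.5)),
    ],
)
def test_combined_score_corner_geometry(e_in, e_out, expected):
    pair = EntropyPair(BWPosition(1, 33), e_in, e_out, 10, 10)
    assert combined_score(pair) == pytest.approx(expected)


@given(
    e_in=st.floats(0, MAX_ENTROPY),
    e_out=st.floats(0, MAX_ENTROPY),
    delta=st.floats(0.01, 1.0),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_combined_score_monotonicity(e_in, e_out, delta):
    """s increases in E_in at fixed E_out and decreases in E_out at fixed E_in."""
    s = combined_score((e_in, e_out))
    if e_in + delta <= MAX_ENTROPY:
        assert combined_score((e_in + delta, e_out)) > s
    if e_out + delta <= MAX_ENTROPY:
        assert combined_score((e_in, e_out + delta)) < s


def test_aggregate_branches_min_and_weighted():
    assert aggregate_branches({60: 0.5, 100: 0.3, 200: 0.7}) == 0.3
    assert aggregate_branches({60: 0.42}) == 0.42
    weighted = aggregate_branches({60: 0.4, 240: 0.2}, "size_weighted_mean")
    assert weighted == pytest.approx(0.24)
    with pytest.raises(ValueError, match="size window"):
        aggregate_branches({})


def _truth_subfamily(truth, k=0):
    members = truth.subfamily_members(k)
    return Subfamily(members, len(members))


def test_planted_binding_columns_rank_first(synthetic_msa):
    aln, truth = synthetic_msa
    sf = _truth_subfamily(truth)
    table = score_with_subfamilies(aln, [sf], "SF00_R000")
    planted = truth.binding_positions(0)
    assert len(planted) == 5
    assert {table.rank_of(p) for p in planted} <= set(range(1, 11))
    assert sorted(table.table["rank"]) == list(range(1, 172))


def test_structural_columns_rank_between_binding_and_background(synthetic_msa):
    aln, truth = synthetic_msa
    sf = _truth_subfamily(truth)
    table = score_with_subfamilies(aln, [sf], "SF00_R000")
    s = dict(zip(table.table["position"], table.table["score"]))
    roles = truth.position_role
    binding = np.mean([s[str(p)] for p, r in roles.items() if r.startswith("binding")])
    struct = np.mean([s[str(p)] for p, r in roles.items() if r == "structural"])
    backg = np.mean([s[str(p)] for p, r in roles.items() if r == "background"])
    assert binding < struct < backg


def test_count_conservation_in_and_out_sum_to_total(synthetic_msa):
    aln, truth = synthetic_msa
    sf = _truth_subfamily(truth)
    pos = parse_bw("3.32")
    pair = two_entropy(aln, sf, pos)
    col = aln.column(pos)
    for a in set(col):
        in_count = sum(
            1 for rid, sym in zip(aln.ids, col) if sym == a and rid in sf.members
        )
        out_count = sum(
            1 for rid, sym in zip(aln.ids, col) if sym == a and rid not in sf.members
        )
        assert in_count + out_count == col.count(a)
    assert pair.n_in + pair.n_out == len(aln)


def test_scoring_is_invariant_to_record_order(synthetic_msa):
    aln, truth = synthetic_msa
    sf = _truth_subfamily(truth)
    table = score_with_subfamilies(aln, [sf], "SF00_R000")
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(aln.ids))
    shuffled = aln.subset(perm)
    table2 = score_with_subfamilies(shuffled, [sf], "SF00_R000")
    assert (table.table["rank"] == table2.table["rank"]).all()
    assert np.allclose(table.table["score"], table2.table["score"])


def test_score_table_tsv_roundtrip(tmp_path, synthetic_msa):
    aln, truth = synthetic_msa
    sf = _truth_subfamily(truth)
    table = score_with_subfamilies(aln, [sf], "SF00_R000")
    path = tmp_path / "scores.tsv"
    table.to_tsv(path)
    back = type(table).from_tsv(path)
    assert back.receptor_id == "SF00_R000"
    assert back.subfamily_sizes == table.subfamily_sizes
    assert list(back.table["rank"]) == list(table.table["rank"])


def test_empirical_corner_preserves_planted_ranking(synthetic_msa):
    aln, truth = synthetic_msa
    sf = _truth_subfamily(truth)
    table = score_with_subfamilies(aln, [sf], "SF00_R000", corner="empirical")
    planted = truth.binding_positions(0)
    assert {table.rank_of(p) for p in planted} <= set(range(1, 11))


def test_scores_are_invariant_under_amino_acid_relabeling(synthetic_msa):
    aln, truth = synthetic_msa
    sf = _truth_subfamily(truth)
    table = score_with_subfamilies(aln, [sf], "SF00_R000")
    swap = str.maketrans(ALPHABET, ALPHABET[1:] + ALPHABET[0])
    relabeled = TMAlignment(
        [AlignedRecord(r.id, r.species, r.seq.translate(swap)) for r in aln]
    )
    table2 = score_with_subfamilies(relabeled, [sf], "SF00_R000")
    assert np.allclose(table.table["score"], table2.table["score"])
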
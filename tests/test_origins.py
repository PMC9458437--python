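"""Sequence-side calculus: library sizing, dot-bracket loops, loop/copy
regression and the NGS counting pipeline."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oricompat.origins import (
    DEFAULT_FLANK_MOTIFS,
    IUPAC_BASES,
    LoopFit,
    OriginVariant,
    count_variants,
    degenerate_space_size,
    extract_variant_region,
    fit_copy_number_vs_loop,
    hairpin_loops,
    loop_length_sum,
    parse_dot_bracket,
    top_k_fraction,
)
from oricompat.synthetic import gen_reads, variant_region

# ---------------------------------------------------------------------------
# oracles

def brute_force_expansions(template):
    """Enumerate every concrete sequence a small template encodes."""
    return ["".join(t) for t in itertools.product(*(IUPAC_BASES[c] for c in template))]


def recursive_descent_pairs(s):
    """Independent dot-bracket parser: recursive descent, not a stack."""
    pairs = []

    def parse(i):
        # consume until an unmatched ')' or end; return its index
        while i < len(s):
            if s[i] == ".":
                i += 1
            elif s[i] == "(":
                j = parse(i + 1)
                pairs.append((i, j))
                i = j + 1
            else:
                return i
        return i

    parse(0)
    return sorted(pairs)


balanced_structures = st.recursive(
    st.text(alphabet=".", max_size=4),
    lambda children: st.tuples(children, children).map(
        lambda t: "(" + t[0] + ")" + t[1]
    ),
    max_leaves=12,
)


# ---------------------------------------------------------------------------
# degenerate library sizing

@pytest.mark.parametrize(
    "template, expected",
    [
        ("ACGT", 1),
        ("N", 4),
        ("NKA", 8),
        ("RYSWKM", 2**6),
        ("BDHV", 3**4),
    ],
)
def test_space_size_matches_enumeration(template, expected):
    assert degenerate_space_size(template) == expected
    assert len(brute_force_expansions(template)) == expected


def test_space_size_exact_big_integer():
    assert degenerate_space_size("N" * 100) == 4**100  # no float overflow


def test_space_size_additive_over_templates():
    assert degenerate_space_size(["NN", "KK"]) == 16 + 4


def test_space_size_invalid_code_names_position():
    with pytest.raises(ValueError, match="position 2"):
        degenerate_space_size("ACXG")
    with pytest.raises(ValueError):
        degenerate_space_size([])


@given(a=st.text(alphabet="ACGTNKRYSWMBDHV", max_size=8),
       b=st.text(alphabet="ACGTNKRYSWMBDHV", max_size=8))
@settings(max_examples=50, deadline=None)
def test_space_size_multiplicative_and_order_invariant(a, b):
    if a or b:
        sa = degenerate_space_size(a) if a else 1
        sb = degenerate_space_size(b) if b else 1
        assert degenerate_space_size(a + b) == sa * sb
        assert degenerate_space_size(b + a) == sa * sb
        shuffled = "".join(sorted(a + b))
        assert degenerate_space_size(shuffled) == sa * sb


# ---------------------------------------------------------------------------
# dot-bracket parsing

@pytest.mark.parametrize(
    "structure, expected",
    [
        ("...", []),
        ("((...))", [(0, 6), (1, 5)]),
        ("()", [(0, 1)]),
        (".(.).", [(1, 3)]),
    ],
)
def test_parse_dot_bracket_basic(structure, expected):
    assert parse_dot_bracket(structure) == expected


def test_parse_dot_bracket_rejects_unbalanced_with_index():
    with pytest.raises(ValueError, match="position 0"):
        parse_dot_bracket(")(")
    with pytest.raises(ValueError, match="position 2"):
        parse_dot_bracket("..(")
    with pytest.raises(ValueError, match="position 1"):
        parse_dot_bracket(".x.")


@given(balanced_structures)
@settings(max_examples=100, deadline=None)
def test_parse_agrees_with_recursive_descent_oracle(structure):
    assert parse_dot_bracket(structure) == recursive_descent_pairs(structure)


# ---------------------------------------------------------------------------
# hairpin loops

@pytest.mark.parametrize(
    "structure, lengths",
    [
        ("((...))", [3]),
        ("((..))((....))", [2, 4]),
        ("...", []),
        ("((((..((...))..))))", [3]),  # internal loop is not a hairpin
    ],
)
def test_hairpin_loop_lengths(structure, lengths):
    assert [length for _, length in hairpin_loops(structure)] == lengths


def test_three_hairpin_scaffold(three_hairpin_structure):
    loops = hairpin_loops(three_hairpin_structure)
    assert [length for _, length in loops] == [7, 6, 7]
    assert loop_length_sum(three_hairpin_structure) == 20


def test_loop_sum_trivial_cases():
    assert loop_length_sum("((...))") == 3
    assert loop_length_sum("......") == 0


@given(balanced_structures)
@settings(max_examples=100, deadline=None)
def test_loops_are_disjoint_and_unpaired(structure):
    paired = {i for pair in parse_dot_bracket(structure) for i in pair}
    seen = set()
    for (start, end), length in hairpin_loops(structure):
        span = set(range(start, end))
        assert length == end - start
        assert not span & paired
        assert not span & seen
        seen |= span


# ---------------------------------------------------------------------------
# copy number vs loop length regression

def normal_equations(x, y):
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return beta[1], beta[0], r2


def _variants_from_points(points):
    out = []
    for k, (loop, cn) in enumerate(points):
        stem = 4
        seq = "G" * stem + "A" * loop + "C" * stem
        struct = "(" * stem + "." * loop + ")" * stem
        out.append(OriginVariant(f"v{k}", seq, struct, copy_number=cn))
    return out


def test_fit_exact_line_gives_r2_one():
    pts = [(4, 200.0), (6, 180.0), (8, 160.0), (10, 140.0)]
    fit = fit_copy_number_vs_loop(_variants_from_points(pts))
    assert fit.slope == pytest.approx(-10.0)
    assert fit.intercept == pytest.approx(240.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_fit_matches_normal_equations_oracle(rng):
    loops = rng.integers(4, 20, size=12)
    y = 250 - 8.0 * loops + rng.normal(0, 10, size=12)
    fit = fit_copy_number_vs_loop(_variants_from_points(list(zip(loops, y))))
    slope, intercept, r2 = normal_equations(loops.astype(float), y)
    assert fit.slope == pytest.approx(slope, abs=1e-10)
    assert fit.intercept == pytest.approx(intercept, abs=1e-10)
    assert fit.r_squared == pytest.approx(r2, abs=1e-10)


def test_fit_invariant_to_order_and_y_shift(rng):
    loops = [4, 7, 11, 14]
    y = [190.0, 171.0, 130.0, 111.0]
    pts = list(zip(loops, y))
    f1 = fit_copy_number_vs_loop(_variants_from_points(pts))
    f2 = fit_copy_number_vs_loop(_variants_from_points(pts[::-1]))
    f3 = fit_copy_number_vs_loop(
        _variants_from_points([(l, v + 50.0) for l, v in pts])
    )
    assert f1.slope == pytest.approx(f2.slope) == pytest.approx(f3.slope)
    assert f1.r_squared == pytest.approx(f2.r_squared) == pytest.approx(f3.r_squared)
    assert f3.intercept == pytest.approx(f1.intercept + 50.0)


def test_fit_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match=">=3"):
        fit_copy_number_vs_loop(_variants_from_points([(4, 10.0), (6, 8.0)]))
    with pytest.raises(ValueError, match="variance"):
        fit_copy_number_vs_loop(
            _variants_from_points([(5, 10.0), (5, 11.0), (5, 12.0)])
        )


# ---------------------------------------------------------------------------
# NGS counting

def brute_force_survivors(seqs, motifs):
    """String-scan oracle for the flank filter (no trimming)."""
    n = 0
    for s in seqs:
        pos = 0
        ok = True
        for m in motifs:
            idx = s.find(m, pos)
            if idx < 0:
                ok = False
                break
            pos = idx + len(m)
        n += ok
    return n


def test_single_variant_table():
    region = variant_region(["ACGTACG", "TTGACAA", "GGCATGC"])
    reads = gen_reads([(region, 1.0)], n_reads=100, seed=0)
    table = count_variants(reads)
    assert len(table) == 1
    assert table["count"].iloc[0] == 100
    assert table["frequency"].iloc[0] == pytest.approx(1.0)


def test_mixture_round_trip_exact():
    mix = [
        (variant_region(["ACGTACG", "TTGACAA", "GGCATGC"]), 0.6),
        (variant_region(["CCCTACG", "TTGACAA", "GGCATGC"]), 0.3),
        (variant_region(["ACGTACG", "AAAACAA", "GGCATGC"]), 0.1),
    ]
    reads = gen_reads(mix, n_reads=1000, error_rate=0.0, seed=5)
    table = count_variants(reads)
    assert list(table["frequency"]) == pytest.approx([0.6, 0.3, 0.1])
    assert table["count"].sum() == 1000


def test_flank_filter_matches_string_scan_oracle():
    region = variant_region(["ACGTACG", "TTGACAA", "GGCATGC"])
    good = gen_reads([(region, 1.0)], n_reads=40, seed=1)
    # corrupt half the reads: delete the first flank motif entirely
    from Bio.Seq import Seq

    for rec in good[:20]:
        s = str(rec.seq).replace(DEFAULT_FLANK_MOTIFS[0], "")
        rec.letter_annotations = {}
        rec.seq = Seq(s)
        rec.letter_annotations["phred_quality"] = [38] * len(s)
    table = count_variants(good)
    expected = brute_force_survivors(
        [str(r.seq) for r in good], DEFAULT_FLANK_MOTIFS
    )
    assert table["count"].sum() == expected == 20


def test_counts_sum_to_survivors_and_failing_read_is_inert():
    region = variant_region(["ACGTACG", "TTGACAA", "GGCATGC"])
    reads = gen_reads([(region, 1.0)], n_reads=30, seed=2)
    t1 = count_variants(reads)
    junk = gen_reads([("TTTTTTT", 1.0)], n_reads=5, seed=3, motifs=["A", "C", "G", "T"])
    t2 = count_variants(list(reads) + list(junk))
    assert t1.equals(t2)


def test_quality_trimming_removes_low_quality_tail():
    region = variant_region(["ACGTACG", "TTGACAA", "GGCATGC"])
    reads = gen_reads([(region, 1.0)], n_reads=50, seed=4, low_quality_tail=20)
    table = count_variants(reads)
    assert table["count"].sum() == 50  # tail trimmed, motifs recovered
    assert table["sequence"].iloc[0] == region


def test_low_quality_read_discarded_entirely():
    reads = [("r1", "ACGT" * 10, [2] * 40)]
    assert count_variants(reads).empty


def test_empty_input_and_empty_motifs():
    assert count_variants([]).empty
    with pytest.raises(ValueError):
        count_variants([], flank_motifs=[])


def test_extract_variant_region_requires_order():
    motifs = ["AAA", "CCC"]
    assert extract_variant_region("AAATTTCCC", motifs) == "TTT"
    assert extract_variant_region("CCCTTTAAA", motifs) is None


# ---------------------------------------------------------------------------
# top-k fraction

def test_top_k_fraction_against_direct_summation(rng):
    import pandas as pd

    # Zipf-like counts
    counts = np.sort(rng.zipf(1.5, size=50))[::-1]
    seqs = [f"SEQ{i:03d}" for i in range(50)]
    table = pd.DataFrame({"sequence": seqs, "count": counts})
    table["frequency"] = table["count"] / table["count"].sum()
    for k in (1, 5, 20, 100):
        direct = (
            table.sort_values(["count", "sequence"], ascending=[False, True])
            ["frequency"].head(k).sum()
        )
        assert top_k_fraction(table, k) == pytest.approx(direct)
    assert top_k_fraction(table, 100) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        top_k_fraction(table, 0)


# ---------------------------------------------------------------------------
# domain type invariants

def test_origin_variant_validation(three_hairpin_structure):
    n = len(three_hairpin_structure)
    v = OriginVariant("wt", "A" * n, three_hairpin_structure, copy_number=120.0)
    assert v.loop_lengths == [7, 6, 7]
    assert v.loop_sum == 20
    with pytest.raises(ValueError, match="length"):
        OriginVariant("bad", "ACGT", "((...))")
    with pytest.raises(ValueError, match="inconsistent"):
        OriginVariant("bad", "A" * n, three_hairpin_structure, loop_lengths=[1, 2, 3])
    with pytest.raises(ValueError, match="positive"):
        OriginVariant("bad", "AAAAAAA", "((...))", copy_number=0.0)


def test_u_and_t_equivalent_on_input():
    v = OriginVariant("rna", "GGUUUCC", "((...))")
    assert v.sequence == "GGTTTCC"
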
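"""Mutant protein construction, MCP extraction and core enumeration."""

import pytest
from hypothesis import given, strategies as st

from neoscreen.peptides import (
    ConsistencyError,
    CoordinateError,
    MutationContext,
    Variant,
    VariantClass,
    build_mutant_protein,
    enumerate_cores,
    extract_mcp,
    mutation_context,
)


def snp(pid="P1", gene="G1", pos=2, ref="C", alt="W"):
    return Variant(pid, gene, pos, ref, alt, VariantClass.SNP)


class TestBuildMutantProtein:
    @pytest.mark.parametrize(
        "wt, variant, expected",
        [
            ("ACDEF", snp(pos=2, ref="C", alt="W"), "AWDEF"),
            ("ACDEF", Variant("P1", "G1", 3, "DE", "", VariantClass.DELETION), "ACF"),
            ("ACDEF", Variant("P1", "G1", 3, "", "KK", VariantClass.INSERTION),
             "ACKKDEF"),
            ("ACDEF",
             Variant("P1", "G1", 3, "D", "V", VariantClass.FRAMESHIFT,
                     mutant_tail="VWYW"),
             "ACVWYW"),
        ],
    )
    def test_edits(self, wt, variant, expected):
        assert build_mutant_protein(wt, variant) == expected

    def test_ref_mismatch_raises(self):
        with pytest.raises(ConsistencyError):
            build_mutant_protein("ACDEF", snp(pos=2, ref="G", alt="W"))

    def test_position_out_of_range_raises(self):
        with pytest.raises(CoordinateError):
            build_mutant_protein("ACDEF", snp(pos=9, ref="C", alt="W"))


def _snp_context(length=100, m=50):
    wt = ("ACDEFGHIKL" * 20)[:length]
    alt = "W" if wt[m - 1] != "W" else "Y"
    return mutation_context(wt, snp(pos=m, ref=wt[m - 1], alt=alt))


class TestExtractMcp:
    def test_full_class1_window_is_45mer(self):
        mcp = extract_mcp(_snp_context(100, 50), "I")
        assert (mcp.start, mcp.end) == (28, 72)
        assert len(mcp.sequence) == 45

    def test_terminal_clipping_shortens_window(self):
        mcp = extract_mcp(_snp_context(100, 3), "I")
        assert (mcp.start, mcp.end) == (1, 25)
        assert len(mcp.sequence) == 25

    def test_full_class2_window_is_55mer(self):
        assert len(extract_mcp(_snp_context(100, 50), "II").sequence) == 55

    def test_mutant_residue_at_local_coordinate(self):
        ctx = _snp_context(100, 50)
        mcp = extract_mcp(ctx, "I")
        local = ctx.position - mcp.start + 1
        assert mcp.sequence[local - 1] == ctx.mut_sequence[ctx.position - 1]
        assert mcp.mutated_offsets == frozenset({local})


class TestEnumerateCores:
    def test_window_count_45mer(self):
        cores = enumerate_cores(extract_mcp(_snp_context(100, 50), "I"))
        assert len(cores) == 45 - 9 + 1 == 37

    def test_mutation_covering_9mers_for_centred_snp(self):
        cores = enumerate_cores(extract_mcp(_snp_context(100, 50), "I"))
        assert sum(c.contains_mutation for c in cores) == 9

    def test_mutation_covering_15mers_for_centred_snp(self):
        cores = enumerate_cores(extract_mcp(_snp_context(120, 60), "II"))
        assert sum(c.contains_mutation for c in cores) == 15

    def test_wt_and_mutant_cores_differ_only_at_snp(self):
        ctx = _snp_context(100, 50)
        mcp = extract_mcp(ctx, "I")
        (local,) = mcp.mutated_offsets
        for c in enumerate_cores(mcp):
            assert c.wt_core is not None
            diffs = [k for k in range(9) if c.mutant_core[k] != c.wt_core[k]]
            if c.contains_mutation:
                assert diffs == [local - c.offset]
            else:
                assert diffs == []

    def test_short_mcp_yields_empty_list(self):
        mcp = extract_mcp(_snp_context(6, 3), "I")
        assert enumerate_cores(mcp) == []

    def test_non_canonical_core_disqualified(self):
        wt = "ACDEFGHIKLMNPQRSTVWY" * 3
        ctx = MutationContext(
            "P1", "G1", 30, VariantClass.SNP,
            wt_sequence=wt, mut_sequence=wt[:29] + "X" + wt[30:],
            mutated_positions=frozenset({30}),
        )
        cores = enumerate_cores(extract_mcp(ctx, "I"))
        assert all("X" not in c.mutant_core for c in cores)
        assert not any(c.contains_mutation for c in cores)

    def test_frameshift_cores_lose_wt_counterpart(self):
        wt = "ACDEFGHIKL" * 10
        var = Variant("P1", "G1", 50, wt[49], "V", VariantClass.FRAMESHIFT,
                      mutant_tail="V" + "WYWAC" * 8)
        ctx = mutation_context(wt, var)
        cores = enumerate_cores(extract_mcp(ctx, "I"))
        assert any(c.contains_mutation for c in cores)
        for c in cores:
            if c.contains_mutation:
                assert c.wt_core is None
            else:
                assert c.wt_core is not None


@given(
    length=st.integers(min_value=9, max_value=140),
    m=st.data(),
)
def test_core_count_identities(length, m):
    """Core count = L - c + 1; mutation-covering count matches the closed form."""
    pos = m.draw(st.integers(min_value=1, max_value=length))
    ctx = _snp_context(length, pos)
    mcp = extract_mcp(ctx, "I")
    cores = enumerate_cores(mcp)
    L = len(mcp.sequence)
    assert len(cores) == max(0, L - 9 + 1)
    if cores:
        (local,) = mcp.mutated_offsets
        expected = min(9, local, L - local + 1, L - 9 + 1)
        assert sum(c.contains_mutation for c in cores) == expected
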
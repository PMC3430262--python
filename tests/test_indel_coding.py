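"""SIC/MCIC coders, matrix extension and VC/PIC accounting.

The coders are cross-checked against an independent brute-force oracle that
re-derives the termini-grouping and scoring rules directly from each row's
gap runs, on the toy nested-gap alignment and on random small alignments.
"""

import numpy as np
import pytest

from indelbarcode import (
    AlignedLocus,
    build_extended_matrix,
    code_mcic,
    code_sic,
    count_characters,
    gap_regions_for,
)
from indelbarcode.errors import ConsistencyError
from indelbarcode.gap_annotation import IndelSet, Indel
from indelbarcode.indel_coding import INAPPLICABLE, MISSING


# ---------------------------------------------------------------- oracle ----

def _runs(row):
    """(start, end) of every maximal internal gap run, 1-based; terminal runs
    reported separately."""
    runs, terminal = [], []
    i = 0
    L = len(row)
    while i < L:
        if row[i] == "-":
            j = i
            while j < L and row[j] == "-":
                j += 1
            span = (i + 1, j)
            (terminal if (i == 0 or j == L) else runs).append(span)
            i = j
        else:
            i += 1
    return runs, terminal


def oracle_indels(locus):
    """Distinct internal (start, end) spans across rows, sorted."""
    spans = set()
    for row in locus.rows:
        spans.update(_runs(row)[0])
    return sorted(spans)


def oracle_sic_states(locus, span):
    """Per-row SIC state by literal application of the coding rules."""
    out = []
    for row in locus.rows:
        runs, terminal = _runs(row)
        if any(t[0] <= span[0] and span[1] <= t[1] for t in terminal):
            out.append("?")
        elif span in runs:
            out.append("1")
        elif any(r[0] <= span[0] and span[1] <= r[1] and r != span for r in runs):
            out.append("-")
        else:
            out.append("0")
    return out


def oracle_components(spans):
    """Connected components of spans under pairwise intersection (brute force
    over all pairs with union-find)."""
    parent = list(range(len(spans)))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            a, b = spans[i], spans[j]
            if not (a[1] < b[0] or b[1] < a[0]):
                parent[find(i)] = find(j)
    comps = {}
    for i, s in enumerate(spans):
        comps.setdefault(find(i), []).append(s)
    return sorted(sorted(c) for c in comps.values())


def random_locus(rng, n_rows=None, L=None):
    n = n_rows or int(rng.integers(4, 9))
    L = L or int(rng.integers(12, 40))
    bases = rng.choice(list("ACGT"), size=L)
    rows = []
    for _ in range(n):
        row = bases.copy()
        for _ in range(int(rng.integers(0, 4))):
            a = int(rng.integers(1, L - 1))
            b = min(L - 1, a + int(rng.integers(0, 6)))
            row[a : b + 1] = "-"
        rows.append("".join(row))
    rows = [r if set(r) != {"-"} else "A" + r[1:] for r in rows]
    return AlignedLocus("rand", tuple(f"s{i}" for i in range(n)), tuple(rows))


# ----------------------------------------------------------------- tests ----

class TestCodeSic:
    def test_toy_hand_coded(self, toy_locus):
        block = code_sic(toy_locus, gap_regions_for(toy_locus))
        by_span = {ch.span: list(ch.states) for ch in block.characters}
        assert set(by_span) == {(5, 8), (3, 10)}
        assert by_span[(5, 8)] == [0, 1, 1, INAPPLICABLE]
        assert by_span[(3, 10)] == [0, 0, 0, 1]

    def test_gap_free_locus_empty_block(self):
        locus = AlignedLocus("L", ("a", "b"), ("ACGT", "ACGA"))
        assert len(code_sic(locus, gap_regions_for(locus))) == 0

    def test_shared_indel_single_character(self):
        locus = AlignedLocus(
            "L", ("a", "b", "c"),
            ("ACGT----ACGT", "ACGT----ACGT", "ACGTACGTACGT"),
        )
        block = code_sic(locus, gap_regions_for(locus))
        assert len(block) == 1
        assert list(block.characters[0].states) == [1, 1, 0]

    def test_terminal_coverage_scored_missing(self):
        locus = AlignedLocus(
            "L", ("a", "b"), ("ACG--TACGTAC", "-------TACGT")
        )
        block = code_sic(locus, gap_regions_for(locus))
        (ch,) = block.characters
        assert ch.span == (4, 5)
        assert list(ch.states) == [1, MISSING]

    def test_out_of_range_indel_rejected(self, toy_locus):
        bad = IndelSet(
            indels=(Indel(5, 99, ("s2",)),), alignment_length=12
        )
        with pytest.raises(ConsistencyError):
            code_sic(toy_locus, bad)

    def test_oracle_equivalence_on_random_alignments(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            locus = random_locus(rng)
            iset = gap_regions_for(locus)
            assert list(iset.spans) == oracle_indels(locus)
            block = code_sic(locus, iset)
            for ch in block.characters:
                expected = oracle_sic_states(locus, ch.span)
                got = [
                    "?" if s == MISSING else "-" if s == INAPPLICABLE else str(s)
                    for s in ch.states
                ]
                assert got == expected, (locus.rows, ch.span)


class TestCodeMcic:
    def test_toy_single_multistate_character(self, toy_locus):
        block = code_mcic(toy_locus, gap_regions_for(toy_locus))
        assert len(block) == 1
        (ch,) = block.characters
        assert ch.span == (3, 10)
        assert len(ch.alphabet) == 3
        s1, s2, s3, s4 = ch.states
        assert s1 == 0  # no-gap state
        assert s2 == s3 != s4 and s4 != s1
        assert ch.step_matrix.shape == (3, 3)
        assert np.array_equal(ch.step_matrix, ch.step_matrix.T)
        assert np.all(np.diag(ch.step_matrix) == 0)
        assert np.all(ch.step_matrix[~np.eye(3, dtype=bool)] >= 1)

    def test_disjoint_indels_stay_separate(self):
        locus = AlignedLocus(
            "L", ("a", "b", "c"),
            ("AC--GTACGTAC", "ACGTACGT--AC", "ACGTACGTACGT"),
        )
        block = code_mcic(locus, gap_regions_for(locus))
        assert len(block) == 2

    def test_gap_free_locus_empty_block(self):
        locus = AlignedLocus("L", ("a", "b"), ("ACGT", "ACGA"))
        assert len(code_mcic(locus, gap_regions_for(locus))) == 0

    def test_component_count_matches_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            locus = random_locus(rng)
            iset = gap_regions_for(locus)
            block = code_mcic(locus, iset)
            comps = oracle_components(list(iset.spans))
            assert len(block) == len(comps)
            assert sorted(sorted(ch.member_spans) for ch in block.characters) == comps

    def test_step_matrices_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            locus = random_locus(rng)
            for ch in code_mcic(locus, gap_regions_for(locus)).characters:
                S = ch.step_matrix
                assert np.array_equal(S, S.T)
                assert np.all(np.diag(S) == 0)
                off = S[~np.eye(S.shape[0], dtype=bool)]
                assert np.all(off >= 1)

    def test_no_gap_to_k_run_pattern_costs_k(self):
        # one sequence carrying two disjoint gaps inside one component needs
        # a bridging sequence to connect them
        locus = AlignedLocus(
            "L", ("a", "b", "c"),
            ("A--GT--CGTAC", "A------CGTAC", "ACGTACGTACGT"),
        )
        block = code_mcic(locus, gap_regions_for(locus))
        (ch,) = block.characters
        idx = {p: i for i, p in enumerate(ch.alphabet)}
        two_run = idx[((2, 3), (6, 7))]
        assert ch.step_matrix[0, two_run] == 2  # two gap-gain events


class TestBuildExtendedMatrix:
    def test_sic_total_length(self, toy_locus):
        m = build_extended_matrix(toy_locus, "SIC")
        assert m.total_length == 12 + 2 == 14

    def test_cd_removes_gap_columns(self, toy_locus):
        m = build_extended_matrix(toy_locus, "CD")
        assert m.total_length == 4
        assert m.source_columns == (1, 2, 11, 12)
        assert all("-" not in r for r in m.nucleotides.rows)

    def test_pwd_untouched(self, toy_locus):
        m = build_extended_matrix(toy_locus, "PWD")
        assert m.total_length == 12
        assert m.nucleotides.rows == toy_locus.rows

    def test_gap_free_locus_same_length_all_schemes(self):
        locus = AlignedLocus("L", ("a", "b"), ("ACGTAC", "ACGTAA"))
        lengths = {
            s: build_extended_matrix(locus, s).total_length
            for s in ("CD", "PWD", "SIC", "MCIC")
        }
        assert set(lengths.values()) == {6}

    def test_unknown_scheme_rejected(self, toy_locus):
        with pytest.raises(ValueError):
            build_extended_matrix(toy_locus, "XYZ")


class TestCountCharacters:
    def test_toy_sic_counts(self, toy_locus):
        counts = count_characters(build_extended_matrix(toy_locus, "SIC"))
        assert (counts.vc, counts.pic) == (2, 0)

    @pytest.mark.parametrize(
        "col,vc,pic",
        [(("A", "A", "A", "A"), 0, 0),
         (("A", "A", "G", "G"), 1, 1),
         (("A", "A", "A", "G"), 1, 0)],
    )
    def test_single_column_classification(self, col, vc, pic):
        rows = tuple("AC" + c for c in col)
        locus = AlignedLocus("L", ("a", "b", "c", "d"), rows)
        counts = count_characters(build_extended_matrix(locus, "PWD"))
        assert (counts.vc, counts.pic) == (vc, pic)

    def test_ambiguity_codes_are_missing(self):
        locus = AlignedLocus("L", ("a", "b", "c"), ("ART", "AGT", "AGT"))
        counts = count_characters(build_extended_matrix(locus, "PWD"))
        assert counts.vc == 0  # {R,G,G} -> only G usable

    def test_percentages_use_scheme_length(self, toy_locus):
        counts = count_characters(build_extended_matrix(toy_locus, "SIC"))
        assert counts.vc_pct == round(100 * 2 / 14, 2)


class TestSchemeOrderingInvariants:
    def _counts(self, locus):
        iset = gap_regions_for(locus)
        return {
            s: count_characters(build_extended_matrix(locus, s, iset))
            for s in ("CD", "PWD", "SIC", "MCIC")
        }

    def test_vc_pic_ordering_on_random_alignments(self):
        """CD = PWD <= MCIC <= SIC, strict between MCIC and SIC whenever
        straddling-overlapping indels exist."""
        rng = np.random.default_rng(2024)
        seen_strict = 0
        for _ in range(100):
            locus = _overlap_prone_locus(rng)
            iset = gap_regions_for(locus)
            c = self._counts(locus)
            assert c["CD"].vc == c["PWD"].vc
            assert c["CD"].pic == c["PWD"].pic
            assert c["PWD"].vc <= c["MCIC"].vc <= c["SIC"].vc
            assert c["PWD"].pic <= c["MCIC"].pic <= c["SIC"].pic
            has_overlap = any(
                IndelSet.relation(a, b) != "disjoint"
                for i, a in enumerate(iset.spans)
                for b in iset.spans[i + 1 :]
            )
            if has_overlap:
                seen_strict += 1
                assert c["MCIC"].vc < c["SIC"].vc
                assert c["MCIC"].pic < c["SIC"].pic
        assert seen_strict >= 20  # the generator exercises the strict case

    def test_character_counts_vs_indel_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            locus = random_locus(rng)
            iset = gap_regions_for(locus)
            sic = code_sic(locus, iset)
            mcic = code_mcic(locus, iset)
            assert len(sic) == len(iset)
            assert len(mcic) <= len(sic)
            disjoint = all(
                IndelSet.relation(a, b) == "disjoint"
                for i, a in enumerate(iset.spans)
                for b in iset.spans[i + 1 :]
            )
            if disjoint:
                assert len(mcic) == len(sic)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            locus = random_locus(rng)
            perm = rng.permutation(locus.n_seqs)
            shuffled = AlignedLocus(
                locus.locus_name,
                tuple(locus.ids[i] for i in perm),
                tuple(locus.rows[i] for i in perm),
            )
            a = code_sic(locus, gap_regions_for(locus))
            b = code_sic(shuffled, gap_regions_for(shuffled))
            assert [ch.span for ch in a.characters] == [ch.span for ch in b.characters]
            for ca, cb in zip(a.characters, b.characters):
                assert list(ca.states[perm]) == list(cb.states)


def _overlap_prone_locus(rng):
    """Random alignment whose indels may straddle but never strictly contain
    one another, each carried by 2–4 of 8 rows (keeps every coded character
    parsimony-informative, so strictness of the VC/PIC ordering is decidable
    from overlap alone)."""
    L = 40
    n = 8
    bases = rng.choice(list("ACGT"), size=L)
    n_spans = int(rng.integers(2, 6))
    spans = []
    attempts = 0
    while len(spans) < n_spans and attempts < 200:
        attempts += 1
        a = int(rng.integers(2, L - 6))
        b = a + int(rng.integers(1, 5))
        cand = (a, b)
        rel = [IndelSet.relation(cand, s) for s in spans]
        if any(r in ("identical", "nested") for r in rel):
            continue
        spans.append(cand)
    rows = [bases.copy() for _ in range(n)]
    assigned: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    kept = []
    for span in spans:
        # overlapping spans get disjoint carrier sets (alternative gap forms),
        # so no row merges two spans into a longer run with new termini
        candidates = [
            r
            for r in range(n)
            if all(
                span[1] + 1 < s[0] or s[1] + 1 < span[0]  # non-adjacent disjoint
                for s in assigned[r]
            )
        ]
        k = int(rng.integers(2, 5))
        if len(candidates) < 2:
            continue
        k = min(k, len(candidates))
        carriers = rng.choice(candidates, size=k, replace=False)
        kept.append(span)
        for c in carriers:
            rows[c][span[0] - 1 : span[1]] = "-"
            assigned[c].append(span)
    return AlignedLocus(
        "ovl", tuple(f"s{i}" for i in range(n)), tuple("".join(r) for r in rows)
    )
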
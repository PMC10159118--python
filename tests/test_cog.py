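"""Representative filters, per-member composition, and the H/E/C aligner."""

import itertools

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from gcstruct.cog import (
    DEFAULT_SCORING,
    COGError,
    COGGroup,
    COGMember,
    align_ss,
    alignment_from_rows,
    build_groups,
    cog_gc_table,
    guide_order,
    pairwise_align,
    pairwise_score,
    select_representatives,
)
from gcstruct.io import COGMembership, ProteinRecord

from conftest import random_ss_string


def member(pid, length, domain_len=None, gc=0.5, ss=None):
    domain_len = domain_len if domain_len is not None else length
    return COGMember(
        protein=ProteinRecord(pid, "A" * length, ss_string=ss),
        gene_gc=gc,
        membership=COGMembership(pid, "COG1", 1, domain_len, "org"),
    )


# --- oracle: exhaustive enumeration of all global alignments -----------------

def brute_force_best_score(s1, s2, scoring=DEFAULT_SCORING):
    """Max score over every global alignment, scored column by column with
    affine gap runs (open + (k-1) * extend per maximal run)."""

    best = [-np.inf]

    def recurse(i, j, cols):
        if i == len(s1) and j == len(s2):
            best[0] = max(best[0], score_columns(cols, scoring))
            return
        if i < len(s1) and j < len(s2):
            recurse(i + 1, j + 1, cols + [(s1[i], s2[j])])
        if i < len(s1):
            recurse(i + 1, j, cols + [(s1[i], "-")])
        if j < len(s2):
            recurse(i, j + 1, cols + [("-", s2[j])])

    recurse(0, 0, [])
    return best[0]


def score_columns(cols, scoring):
    total = 0.0
    for row in (0, 1):
        run = 0
        for col in cols:
            if col[row] == "-":
                run += 1
            else:
                total += scoring.gap_cost(run)
                run = 0
        total += scoring.gap_cost(run)
    total += sum(
        scoring.substitution(a, b) for a, b in cols if a != "-" and b != "-"
    )
    return total


class TestSelectRepresentatives:
    def test_zero_sd_boundary_inclusive(self):
        group = COGGroup("COG1", [member(f"p{i}", 100) for i in range(3)])
        kept = select_representatives(group)
        assert len(kept.members) == 3 and kept.dropped == []

    def test_one_sd_length_window(self):
        # lengths (90,100,110,300): mean 150, sample SD ~100.33 -> drop 300
        group = COGGroup(
            "COG1",
            [member(p, l, domain_len=80) for p, l in
             [("a", 90), ("b", 100), ("c", 110), ("d", 300)]],
        )
        assert group.length_mean == 150.0
        assert group.length_sd == pytest.approx(np.sqrt(30200 / 3), abs=1e-9)
        kept = select_representatives(group)
        assert [m.protein.protein_id for m in kept.members] == ["a", "b", "c"]
        assert kept.dropped[0][0] == "d"

    def test_domain_coverage_filter(self):
        # equal lengths (SD filter passes all); domain spans mean 200,
        # the 150 span covers 75% < 80% -> dropped
        spans = {"a": 250, "b": 200, "c": 200, "d": 150}
        group = COGGroup(
            "COG1", [member(p, 300, domain_len=s) for p, s in spans.items()]
        )
        kept = select_representatives(group)
        assert [m.protein.protein_id for m in kept.members] == ["a", "b", "c"]

    def test_exact_80_percent_boundary_inclusive(self):
        spans = {"a": 240, "b": 200, "c": 200, "d": 160}  # mean 200, 0.8*200 = 160
        group = COGGroup(
            "COG1", [member(p, 300, domain_len=s) for p, s in spans.items()]
        )
        assert len(select_representatives(group).members) == 4

    def test_pure_filter_subset_and_frozen_stats_fixpoint(self, rng):
        lengths = rng.integers(50, 400, size=12)
        group = COGGroup(
            "COG1",
            [member(f"p{i}", int(l), domain_len=int(rng.integers(30, l + 1)))
             for i, l in enumerate(lengths)],
        )
        mean0, sd0, dom0 = group.length_mean, group.length_sd, group.domain_length_mean
        kept = select_representatives(group)
        ids_in = {m.protein.protein_id for m in group.members}
        assert {m.protein.protein_id for m in kept.members} <= ids_in
        for m in kept.members:  # pass-1 statistics admit every survivor again
            assert abs(m.length - mean0) <= sd0
            assert m.domain_length >= 0.8 * dom0

    def test_singleton_rejected(self):
        with pytest.raises(COGError):
            select_representatives(COGGroup("COG1", [member("p1", 100)]))


class TestCogGcTable:
    def test_member_triple(self):
        m = member("p1", 10, gc=0.6, ss="HHHHCCCCCC")
        (gc, comp), = cog_gc_table(COGGroup("COG1", [m]))
        assert gc == 0.6
        assert comp.as_tuple() == (0.4, 0.0, 0.6)

    def test_missing_gc_is_error(self):
        m = member("p1", 4, ss="HHCC")
        m.gene_gc = None
        with pytest.raises(COGError):
            cog_gc_table(COGGroup("COG1", [m]))

    def test_build_groups_wires_gc(self):
        proteins = {"p1": ProteinRecord("p1", "AAAA", ss_string="HHCC")}
        ms = [COGMembership("p1", "COG9", 1, 4, "org")]
        groups = build_groups(ms, proteins, {"p1": 0.41})
        assert groups["COG9"].members[0].gene_gc == 0.41


class TestPairwiseAlignment:
    def test_identical_strings(self):
        a, b, score = pairwise_align("HHEC", "HHEC")
        assert (a, b) == ("HHEC", "HHEC") and score == 8.0

    def test_single_gap_example(self):
        # best of all alignments of HHH vs HH: 2 matches - one length-1 gap
        assert pairwise_score("HHH", "HH") == 0.0

    @pytest.mark.parametrize(
        "s1,s2",
        [("H", "E"), ("HE", "EH"), ("HHEC", "HEC"), ("CCC", "HHH"),
         ("HECHEC", "HCHC"), ("EEE", "E"), ("HEHE", "CCCC"), ("H", "HECHEC")],
    )
    def test_matches_exhaustive_oracle(self, s1, s2):
        assert pairwise_score(s1, s2) == brute_force_best_score(s1, s2)

    def test_matches_exhaustive_oracle_random(self, rng):
        for _ in range(15):
            s1 = random_ss_string(rng, int(rng.integers(1, 7)))
            s2 = random_ss_string(rng, int(rng.integers(1, 7)))
            assert pairwise_score(s1, s2) == brute_force_best_score(s1, s2)

    def test_matches_biopython_affine_global(self, rng):
        mat = substitution_matrices.Array(alphabet="HEC", dims=2)
        for a, b in itertools.product("HEC", repeat=2):
            mat[a, b] = DEFAULT_SCORING.substitution(a, b)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = mat
        aligner.open_gap_score = DEFAULT_SCORING.gap_open
        aligner.extend_gap_score = DEFAULT_SCORING.gap_extend
        for _ in range(25):
            s1 = random_ss_string(rng, int(rng.integers(1, 30)))
            s2 = random_ss_string(rng, int(rng.integers(1, 30)))
            assert pairwise_score(s1, s2) == aligner.score(s1, s2)

    def test_symmetry(self, rng):
        for _ in range(10):
            s1 = random_ss_string(rng, int(rng.integers(1, 15)))
            s2 = random_ss_string(rng, int(rng.integers(1, 15)))
            assert pairwise_score(s1, s2) == pairwise_score(s2, s1)


class TestProgressiveAlignment:
    def _group(self, strings):
        return COGGroup(
            "COG1",
            [member(f"p{i}", len(s), ss=s) for i, s in enumerate(strings)],
        )

    def test_identical_pair_merges_first(self):
        # brute-force 3-leaf average-linkage check: the identical pair is
        # strictly closest, so it must be the first merge
        seqs = ["HHEECC", "HHCC", "HHEECC"]
        order = guide_order(seqs)
        assert order[0] == (0, 2)

    def test_rows_round_trip(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 6))
            strings = [random_ss_string(rng, int(rng.integers(5, 40))) for _ in range(n)]
            aln = align_ss(self._group(strings))
            assert [aln.ungapped(i) for i in range(n)] == strings
            assert len({len(r) for r in aln.rows}) == 1

    def test_deterministic(self):
        strings = ["HHEECC", "HHCC", "HECEC", "HHEEC"]
        a1 = align_ss(self._group(strings))
        a2 = align_ss(self._group(strings))
        assert a1.rows == a2.rows

    def test_too_few_members(self):
        with pytest.raises(COGError):
            align_ss(self._group(["HHH"]))

    def test_consensus_fraction(self):
        aln = alignment_from_rows("COG1", ("a", "b"), ("HE-C", "HEEC"))
        assert aln.consensus_fraction() == pytest.approx([1.0, 1.0, 0.5, 1.0])

    def test_external_alignment_validation(self):
        with pytest.raises(COGError):
            alignment_from_rows("COG1", ("a",), ("HZX",))
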
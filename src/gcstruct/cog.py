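"""COG representative selection, per-member structure composition, and
progressive alignment of three-state secondary-structure strings.

Representative selection applies two single-pass filters, both computed
on the unfiltered group: a member is retained when (1) its protein
length lies within one sample standard deviation of the group's mean
length — excluding multidomain outliers — and (2) its COG domain span
covers at least 80% of the group's mean domain length — excluding
partial domains.  Boundaries are inclusive.

Secondary-structure strings (alphabet H/E/C) are aligned with a
progressive aligner: all pairwise global Needleman-Wunsch/Gotoh
alignments give a distance matrix, average-linkage joining fixes the
merge order (ties broken toward the lowest row index), and profiles are
merged by profile-to-profile dynamic programming.  Default scoring:
match +2, H/E mismatch -2, mismatch against C -1, gap open -4, gap
extend -1 (a length-k gap costs 4 + (k-1)).  Externally produced
alignments (e.g. MUSCLE on the letter strings) can be imported from
gapped FASTA instead via :func:`alignment_from_rows`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SS_STATES, COGMembership, ProteinRecord
from .structure import SSComposition, ss_composition

GAP = "-"


class COGError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 2.0
    he_mismatch: float = -2.0
    coil_mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def substitution(self, a: str, b: str) -> float:
        if a == b:
            return self.match
        if "C" in (a, b):
            return self.coil_mismatch
        return self.he_mismatch

    def gap_cost(self, length: int) -> float:
        if length <= 0:
            return 0.0
        return self.gap_open + (length - 1) * self.gap_extend

    def matrix(self) -> np.ndarray:
        """3x3 substitution matrix in H, E, C order."""
        m = np.empty((3, 3))
        for i, a in enumerate(SS_STATES):
            for j, b in enumerate(SS_STATES):
                m[i, j] = self.substitution(a, b)
        return m


DEFAULT_SCORING = ScoringScheme()


@dataclass
class COGMember:
    protein: ProteinRecord
    gene_gc: float | None
    membership: COGMembership

    @property
    def length(self) -> int:
        return len(self.protein)

    @property
    def domain_length(self) -> int:
        return self.membership.domain_length


@dataclass
class COGGroup:
    """One COG with its member proteins and group length statistics."""

    cog_id: str
    members: list[COGMember]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (protein_id, reason)

    def __post_init__(self) -> None:
        if not self.members:
            raise COGError(f"COG {self.cog_id}: no members")

    @property
    def length_mean(self) -> float:
        return float(np.mean([m.length for m in self.members]))

    @property
    def length_sd(self) -> float:
        lengths = [m.length for m in self.members]
        if len(lengths) < 2:
            raise COGError(f"COG {self.cog_id}: sample SD undefined for a singleton")
        return float(np.std(lengths, ddof=1))

    @property
    def domain_length_mean(self) -> float:
        return float(np.mean([m.domain_length for m in self.members]))


def build_groups(
    memberships: Sequence[COGMembership],
    proteins: Mapping[str, ProteinRecord],
    gene_gc: Mapping[str, float] | None = None,
) -> dict[str, COGGroup]:
    """Assemble COGGroups from a membership table and a protein lookup."""
    by_cog: dict[str, list[COGMember]] = {}
    for m in memberships:
        p = proteins.get(m.protein_id)
        if p is None:
            raise COGError(f"membership references unknown protein {m.protein_id!r}")
        if m.domain_end > len(p):
            raise COGError(
                f"{m.protein_id}: domain_end {m.domain_end} exceeds length {len(p)}"
            )
        gc = gene_gc.get(m.protein_id) if gene_gc is not None else None
        by_cog.setdefault(m.cog_id, []).append(COGMember(p, gc, m))
    return {cid: COGGroup(cid, ms) for cid, ms in by_cog.items()}


def select_representatives(group: COGGroup) -> COGGroup:
    """Apply the 1-SD length filter and the 80% domain-coverage filter.

    Both statistics come from the unfiltered group (single pass); the
    retained set is always a subset of the input, and re-applying the
    filter with the same statistics changes nothing.
    """
    mean_len = group.length_mean
    sd_len = group.length_sd  # raises on singleton
    mean_dom = group.domain_length_mean
    kept: list[COGMember] = []
    dropped: list[tuple[str, str]] = list(group.dropped)
    for m in group.members:
        if abs(m.length - mean_len) > sd_len:
            dropped.append(
                (m.protein.protein_id,
                 f"length {m.length} beyond 1 SD ({mean_len:.2f} +/- {sd_len:.2f})")
            )
            continue
        if m.domain_length < 0.8 * mean_dom:
            dropped.append(
                (m.protein.protein_id,
                 f"domain {m.domain_length} < 80% of mean {mean_dom:.2f}")
            )
            continue
        kept.append(m)
    if not kept:
        raise COGError(f"COG {group.cog_id}: no members survive the filters")
    return COGGroup(group.cog_id, kept, dropped)


def cog_gc_table(group: COGGroup) -> list[tuple[float, SSComposition]]:
    """Per-member (gene GC, helix/sheet/coil composition) pairs.

    Each member's composition is its own |ss(p)|/|p| fractions, ready for
    the biased-COG regression call.
    """
    out: list[tuple[float, SSComposition]] = []
    for m in group.members:
        if m.gene_gc is None:
            raise COGError(f"{m.protein.protein_id}: no gene GC recorded")
        comp = ss_composition([m.protein], scope="protein")[m.protein.protein_id]
        out.append((m.gene_gc, comp))
    return out


# ---------------------------------------------------------------------------
# Progressive alignment over the three-letter alphabet


@dataclass(frozen=True)
class SSAlignment:
    """A gapped multiple alignment of H/E/C strings."""

    cog_id: str
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise COGError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def consensus_fraction(self) -> np.ndarray:
        """Per-column fraction of rows agreeing with the modal state (gaps count)."""
        cols = np.array([list(r) for r in self.rows])
        out = np.empty(cols.shape[1])
        for j in range(cols.shape[1]):
            col = cols[:, j]
            best = max((col == s).sum() for s in SS_STATES)
            out[j] = best / len(col)
        return out

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    """(n_columns, 4) counts over H, E, C, gap."""
    idx = {s: i for i, s in enumerate(SS_STATES + GAP)}
    n_col = len(rows[0])
    counts = np.zeros((n_col, 4))
    for r in rows:
        for j, c in enumerate(r):
            counts[j, idx[c]] += 1
    return counts


def _align_profiles(
    rows_a: list[str], rows_b: list[str], scoring: ScoringScheme
) -> tuple[list[str], list[str], float]:
    """Global affine-gap (Gotoh) alignment of two profiles.

    Column-column score is the average over all cross-profile residue
    pairs of the substitution score, with gap characters inside existing
    columns contributing 0.  New gaps pay open/extend unscaled.
    """
    sub = scoring.matrix()
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    na, nb = ca.shape[0], cb.shape[0]
    # pair_score[i, j]: mean substitution score of column i of A vs column j of B
    letters_a, letters_b = ca[:, :3], cb[:, :3]
    denom = np.outer(ca.sum(axis=1), cb.sum(axis=1))
    pair = (letters_a @ sub @ letters_b.T) / denom

    neg = -math.inf
    go, ge = scoring.gap_open, scoring.gap_extend
    M = np.full((na + 1, nb + 1), neg)
    X = np.full((na + 1, nb + 1), neg)  # gap in B (consumes A)
    Y = np.full((na + 1, nb + 1), neg)  # gap in A (consumes B)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, nb + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = pair[i - 1, j - 1]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)
    end_state = max(("M", "X", "Y"), key=lambda k: {"M": M, "X": X, "Y": Y}[k][na, nb])
    score = {"M": M, "X": X, "Y": Y}[end_state][na, nb]

    # traceback; preference order M > X > Y keeps the result deterministic
    i, j, state = na, nb, end_state
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = pair[i - 1, j - 1]
            prev = M[i, j] - s
            for cand, mat in (("M", M), ("X", X), ("Y", Y)):
                if math.isclose(mat[i - 1, j - 1], prev, rel_tol=0, abs_tol=1e-9):
                    state = cand
                    break
            ops.append("M")
            i, j = i - 1, j - 1
        elif state == "X":
            if i == 0:
                raise AssertionError("bad traceback")
            val = X[i, j]
            if math.isclose(M[i - 1, j] + go, val, abs_tol=1e-9):
                nxt = "M"
            elif math.isclose(X[i - 1, j] + ge, val, abs_tol=1e-9):
                nxt = "X"
            else:
                nxt = "Y"
            ops.append("X")
            i, state = i - 1, nxt
        else:
            val = Y[i, j]
            if math.isclose(M[i, j - 1] + go, val, abs_tol=1e-9):
                nxt = "M"
            elif math.isclose(X[i, j - 1] + go, val, abs_tol=1e-9):
                nxt = "X"
            else:
                nxt = "Y"
            ops.append("Y")
            j, state = j - 1, nxt
    ops.reverse()

    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ai = bi = 0
    for op in ops:
        if op == "M":
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ai])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[bi])
            ai += 1
            bi += 1
        elif op == "X":
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ai])
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
            ai += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
            for k, r in enumerate(rows_b):
                out_b[k].append(r[bi])
            bi += 1
    return (["".join(r) for r in out_a], ["".join(r) for r in out_b], float(score))


def pairwise_align(
    s1: str, s2: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> tuple[str, str, float]:
    """Optimal global alignment of two H/E/C strings with affine gaps."""
    a, b, score = _align_profiles([s1], [s2], scoring)
    return a[0], b[0], score


def pairwise_score(s1: str, s2: str, scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    return pairwise_align(s1, s2, scoring)[2]


def align_ss(
    group: COGGroup, scoring: ScoringScheme = DEFAULT_SCORING
) -> SSAlignment:
    """Progressive multiple alignment of the group's H/E/C strings."""
    annotated = [m for m in group.members if m.protein.ss_string is not None]
    if len(annotated) < 2:
        raise COGError(f"COG {group.cog_id}: need >= 2 annotated members to align")
    ids = [m.protein.protein_id for m in annotated]
    seqs = [m.protein.ss_string for m in annotated]
    order = guide_order(seqs, scoring)
    # clusters: map of active cluster -> (leaf indices, gapped rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [s]) for i, s in enumerate(seqs)
    }
    next_id = len(seqs)
    for a, b in order:
        leaves_a, rows_a = clusters.pop(a)
        leaves_b, rows_b = clusters.pop(b)
        new_a, new_b, _ = _align_profiles(rows_a, rows_b, scoring)
        clusters[next_id] = (leaves_a + leaves_b, new_a + new_b)
        next_id += 1
    (leaves, rows), = clusters.values()
    by_leaf = dict(zip(leaves, rows))
    return SSAlignment(
        cog_id=group.cog_id,
        ids=tuple(ids),
        rows=tuple(by_leaf[i] for i in range(len(seqs))),
    )


def guide_order(
    seqs: Sequence[str], scoring: ScoringScheme = DEFAULT_SCORING
) -> list[tuple[int, int]]:
    """Average-linkage merge order from pairwise alignment-score distances.

    Distances are negated pairwise alignment scores.  At every step the
    closest cluster pair merges; exact ties go to the pair with the
    lowest cluster indices (clusters keep the creation order, leaves
    first).  Returns the sequence of merged cluster-ID pairs; merge k
    creates cluster ``len(seqs) + k``.
    """
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = -pairwise_score(seqs[i], seqs[j], scoring)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    order: list[tuple[int, int]] = []
    next_id = n
    while len(members) > 1:
        keys = sorted(members)
        best: tuple[int, int] | None = None
        best_d = math.inf
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                la, lb = members[a], members[b]
                dist = float(np.mean([d[x, y] for x in la for y in lb]))
                if dist < best_d - 1e-12:
                    best_d = dist
                    best = (a, b)
        a, b = best
        members[next_id] = members.pop(a) + members.pop(b)
        order.append((a, b))
        next_id += 1
    return order


def alignment_from_rows(
    cog_id: str, ids: Sequence[str], rows: Sequence[str]
) -> SSAlignment:
    """Wrap an externally produced gapped alignment (e.g. MUSCLE output)."""
    allowed = set(SS_STATES + GAP)
    for rid, r in zip(ids, rows):
        bad = set(r) - allowed
        if bad:
            raise COGError(f"{rid}: illegal alignment character(s) {sorted(bad)!r}")
    return SSAlignment(cog_id=cog_id, ids=tuple(ids), rows=tuple(rows))


def filter_audit_frame(group: COGGroup) -> pd.DataFrame:
    return pd.DataFrame(group.dropped, columns=["protein_id", "reason"])
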
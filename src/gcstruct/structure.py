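"""Per-structure amino-acid frequencies, Chou-Fasman conformational parameters,
and secondary-structure composition.

All statistics run over proteins carrying a three-state annotation
(H = alpha-helix, E = beta-sheet, C = random coil), one state per residue.
For a proteome P(G):

*  aa_ss^G(aa)  = pooled count of aa in state ss / pooled residues in ss
   (per-structure amino-acid frequency);
*  F_ss^aa      = pooled count of aa in ss / pooled count of aa
   (share of that amino acid's residues lying in ss);
*  F_ss         = pooled residues in ss / all residues
   (overall share of the state);
*  CP(aa, ss)   = F_ss^aa / F_ss
   (Chou-Fasman conformational parameter: >1 marks a former of the
   state, <1 a breaker).

These satisfy the identities sum_ss F_ss^aa = 1 per amino acid,
sum_ss F_ss = 1, and sum_aa f(aa) * CP(aa, ss) = 1 for each state, with
f the proteome amino-acid frequencies.  X residues (and their annotation
positions) are dropped from every count so the identities stay exact.

Secondary-structure composition (Alfa_G/Beta_G/Coil_G at proteome scope,
|ss(p)|/|p| per protein) shares the same counting conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import AAFrequencyTable, EmptyInputError
from .io import SS_STATES, STANDARD_AA, ProteinRecord

SS_NAMES = {"H": "helix", "E": "sheet", "C": "coil"}

CP_CATEGORY_LABELS = (
    "strong breaker",
    "breaker",
    "indifferent",
    "former",
    "strong former",
)
#: Default CP category cut points; configurable, see categorize_cp.
DEFAULT_CP_THRESHOLDS = (0.6, 0.9, 1.1, 1.4)


class AnnotationError(ValueError):
    """Structure statistics requested on proteins without annotations."""


def _require_annotated(proteins: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    if not proteins:
        raise EmptyInputError("empty proteome")
    missing = [p.protein_id for p in proteins if p.ss_string is None]
    if missing:
        raise AnnotationError(
            f"{len(missing)} protein(s) lack secondary-structure annotations "
            f"(first: {missing[0]!r})"
        )
    return list(proteins)


def _count_matrix(proteins: Sequence[ProteinRecord]) -> pd.DataFrame:
    """20x3 residue counts (amino acid x state), X positions dropped."""
    counts = np.zeros((len(STANDARD_AA), len(SS_STATES)), dtype=np.int64)
    aa_idx = {aa: i for i, aa in enumerate(STANDARD_AA)}
    ss_idx = {s: j for j, s in enumerate(SS_STATES)}
    for p in proteins:
        for aa, ss in zip(p.sequence, p.ss_string):
            if aa == "X":
                continue
            counts[aa_idx[aa], ss_idx[ss]] += 1
    return pd.DataFrame(counts, index=list(STANDARD_AA), columns=list(SS_STATES))


@dataclass(frozen=True)
class ConformationalParams:
    """Chou-Fasman quantities for one annotated proteome.

    ``table`` is indexed by amino acid with per-state columns
    ``f_<ss>`` (F_ss^aa), ``cp_<ss>`` and ``n_<ss>`` (occurrence count),
    plus ``n_total``.  CP cells for amino acids absent from the proteome
    are missing (NaN) and listed in ``absent_aa`` — "absent" is distinct
    from "never observed in the state" (CP 0).  ``f_ss`` holds F_ss.
    """

    table: pd.DataFrame
    f_ss: pd.Series
    total_residues: int

    @property
    def absent_aa(self) -> tuple[str, ...]:
        return tuple(self.table.index[self.table["n_total"] == 0])

    def cp(self, aa: str, ss: str) -> float:
        return float(self.table.at[aa, f"cp_{ss}"])


@dataclass(frozen=True)
class SSComposition:
    """Fractions of residues in helix/sheet/coil for a proteome or protein."""

    frac_helix: float
    frac_sheet: float
    frac_coil: float
    total_residues: int
    scope: Literal["proteome", "protein"] = "proteome"

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.frac_helix, self.frac_sheet, self.frac_coil)


def aa_frequencies_by_ss(
    proteins: Sequence[ProteinRecord],
) -> dict[str, AAFrequencyTable | None]:
    """Per-state amino-acid frequency tables aa_ss^G, keyed by 'H'/'E'/'C'.

    A state with zero residues in the proteome yields None for that
    state rather than a division by zero.
    """
    proteins = _require_annotated(proteins)
    counts = _count_matrix(proteins)
    out: dict[str, AAFrequencyTable | None] = {}
    context = {"H": "helix", "E": "sheet", "C": "coil"}
    for ss in SS_STATES:
        total = int(counts[ss].sum())
        if total == 0:
            out[ss] = None
            continue
        out[ss] = AAFrequencyTable(
            frequency={aa: counts.at[aa, ss] / total for aa in STANDARD_AA},
            count={aa: int(counts.at[aa, ss]) for aa in STANDARD_AA},
            context=context[ss],  # type: ignore[arg-type]
            total=total,
        )
    return out


def conformational_params(proteins: Sequence[ProteinRecord]) -> ConformationalParams:
    """Compute F_ss^aa, F_ss and CP for every (amino acid, state) cell."""
    proteins = _require_annotated(proteins)
    counts = _count_matrix(proteins)
    n_total = counts.sum(axis=1)
    grand = int(n_total.sum())
    if grand == 0:
        raise EmptyInputError("no standard residues in annotated proteome")
    f_ss = counts.sum(axis=0) / grand

    table = pd.DataFrame(index=counts.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        for ss in SS_STATES:
            f_ss_aa = counts[ss] / n_total.replace(0, np.nan)
            table[f"f_{ss}"] = f_ss_aa
            table[f"cp_{ss}"] = f_ss_aa / f_ss[ss] if f_ss[ss] > 0 else np.nan
            table[f"n_{ss}"] = counts[ss]
    table["n_total"] = n_total
    return ConformationalParams(table=table, f_ss=f_ss, total_residues=grand)


def ss_composition(
    proteins: Sequence[ProteinRecord],
    scope: Literal["proteome", "protein"] = "proteome",
) -> SSComposition | dict[str, SSComposition]:
    """Helix/sheet/coil residue fractions.

    ``proteome`` scope pools residues over all proteins and returns one
    :class:`SSComposition`; ``protein`` scope returns a dict keyed by
    protein ID with each protein's own |ss(p)|/|p| fractions.
    """
    proteins = _require_annotated(proteins)
    if scope == "proteome":
        return _pooled_composition(proteins, "proteome")
    if scope == "protein":
        return {
            p.protein_id: _pooled_composition([p], "protein") for p in proteins
        }
    raise ValueError(f"unknown scope {scope!r}")


def _pooled_composition(
    proteins: Sequence[ProteinRecord], scope: Literal["proteome", "protein"]
) -> SSComposition:
    n = {s: 0 for s in SS_STATES}
    for p in proteins:
        for aa, ss in zip(p.sequence, p.ss_string):
            if aa == "X":
                continue
            n[ss] += 1
    total = sum(n.values())
    if total == 0:
        raise EmptyInputError("no standard residues to classify")
    return SSComposition(
        frac_helix=n["H"] / total,
        frac_sheet=n["E"] / total,
        frac_coil=n["C"] / total,
        total_residues=total,
        scope=scope,
    )


def categorize_cp(
    params: ConformationalParams,
    thresholds: Sequence[float] = DEFAULT_CP_THRESHOLDS,
) -> pd.DataFrame:
    """Map each CP value to one of the five Chou-Fasman labels.

    ``thresholds`` are four strictly increasing cut points (t1..t4);
    cp <= t1 -> strong breaker, t1 < cp <= t2 -> breaker,
    t2 < cp <= t3 -> indifferent, t3 < cp <= t4 -> former,
    cp > t4 -> strong former.  Missing CP cells stay missing.
    """
    thresholds = tuple(thresholds)
    if len(thresholds) != 4 or any(
        b <= a for a, b in zip(thresholds, thresholds[1:])
    ):
        raise ValueError(f"thresholds must be 4 increasing cut points, got {thresholds!r}")
    out = pd.DataFrame(index=params.table.index)
    bins = [-np.inf, *thresholds, np.inf]
    for ss in SS_STATES:
        cp = params.table[f"cp_{ss}"]
        cat = pd.cut(cp, bins=bins, labels=CP_CATEGORY_LABELS, right=True)
        out[f"category_{ss}"] = cat.astype(object).where(cp.notna(), None)
    return out


def composition_frame(
    compositions: Mapping[str, SSComposition], id_name: str = "protein_id"
) -> pd.DataFrame:
    """Tabulate per-ID compositions (helix, sheet, coil, length)."""
    rows = [
        {
            id_name: k,
            "frac_helix": c.frac_helix,
            "frac_sheet": c.frac_sheet,
            "frac_coil": c.frac_coil,
            "total_residues": c.total_residues,
        }
        for k, c in compositions.items()
    ]
    return pd.DataFrame(rows).set_index(id_name)
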
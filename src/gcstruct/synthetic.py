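"""Synthetic coding genomes with known GC content and secondary-structure ground truth.

The generator emulates the inputs the pipeline consumes — prokaryote-like
coding genomes spanning a wide GC gradient (the real comparative panels
span roughly 20-74% GC), the proteomes translated from them, and
three-state secondary-structure annotations — so every downstream
statistic can be validated against parameters that are known exactly.

Codon model.  Sense codons are drawn i.i.d. with weight
w(c) proportional to exp(lambda * gc(c)), where gc(c) is the codon's G+C
count.  The tilt lambda is the single free parameter and is solved by
bisection so that the expected GC fraction of the generated codon stream
— including the deterministic ATG start and the (tilted) stop codon at
their expected share of codons — equals the requested target.  Gene
body lengths follow a negative binomial (mean/dispersion in the spec)
truncated below at 50 codons; genes are ATG + body + stop under
translation table 11, and proteins are the body translations.

Structure model.  Each residue's state is drawn from the conditional
propensity row P(state | amino acid); with probability ``persistence``
a residue instead copies its predecessor's state, creating run-length
structure like real helices and strands.  With persistence 0 the
conformational parameters have the closed form

    CP(aa, ss) = P(ss | aa) / sum_aa' f(aa') P(ss | aa'),

which :func:`expected_cp_from_spec` evaluates as the recovery oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .composition import AAFrequencyTable, aa_frequencies, compute_coding_gc
from .io import SS_STATES, STANDARD_AA, CodingGene, GenomeRecord, ProteinRecord
from .structure import ConformationalParams

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
#: 61 sense codons of the standard / bacterial (table 11) code.
SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product(_BASES, repeat=3)) if c not in _STOPS
)

# codon -> amino acid under the bacterial/archaeal code (table 11)
from Bio.Data import CodonTable as _CT  # noqa: E402

_CODON_TO_AA = dict(_CT.unambiguous_dna_by_id[11].forward_table)

_MIN_BODY_CODONS = 50

# Classic Chou-Fasman helix/sheet/turn propensities, used only to shape a
# realistic default conditional-state matrix; any row-stochastic matrix
# may be supplied instead.
_CF_PROPENSITY = {
    "A": (1.42, 0.83, 0.66), "R": (0.98, 0.93, 0.95), "N": (0.67, 0.89, 1.56),
    "D": (1.01, 0.54, 1.46), "C": (0.70, 1.19, 1.19), "Q": (1.11, 1.10, 0.98),
    "E": (1.51, 0.37, 0.74), "G": (0.57, 0.75, 1.56), "H": (1.00, 0.87, 0.95),
    "I": (1.08, 1.60, 0.47), "L": (1.21, 1.30, 0.59), "K": (1.14, 0.74, 1.01),
    "M": (1.45, 1.05, 0.60), "F": (1.13, 1.38, 0.60), "P": (0.57, 0.55, 1.52),
    "S": (0.77, 0.75, 1.43), "T": (0.83, 1.19, 0.96), "W": (1.08, 1.37, 0.96),
    "Y": (0.69, 1.47, 1.14), "V": (1.06, 1.70, 0.50),
}
#: Typical three-state background used to convert propensities into
#: conditional probabilities (helix, sheet, coil).
_STATE_BACKGROUND = (0.35, 0.22, 0.43)


def default_propensity_matrix() -> pd.DataFrame:
    """Row-stochastic P(state | aa) over H/E/C, shaped by Chou-Fasman propensities."""
    rows = {}
    for aa, prop in _CF_PROPENSITY.items():
        w = np.array(prop) * np.array(_STATE_BACKGROUND)
        rows[aa] = w / w.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SS_STATES)).loc[
        list(STANDARD_AA)
    ]


def coil_tilted_propensity(
    gc: float,
    strength: float = 0.4,
    pivot: float = 0.475,
    base: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Propensity matrix whose coil probability rises linearly with GC.

    For every amino acid, P(C|aa) is shifted by ``strength * (gc - pivot)``
    (clipped to keep rows valid) and H/E are rescaled proportionally.
    Used to manufacture genomes in which coil content grows with GC while
    helix and sheet shrink — the qualitative coil-up/helix-down pattern
    the pipeline should detect.
    """
    m = (base if base is not None else default_propensity_matrix()).copy()
    delta = strength * (gc - pivot)
    new_c = np.clip(m["C"] + delta, 0.02, 0.96)
    scale = (1.0 - new_c) / (m["H"] + m["E"])
    m["H"] = m["H"] * scale
    m["E"] = m["E"] * scale
    m["C"] = new_c
    return m


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic organism."""

    target_gc: float
    n_genes: int
    mean_gene_length: float = 300.0  # body codons
    length_dispersion: float = 8.0  # negative-binomial shape; larger = tighter
    propensity_matrix: pd.DataFrame = field(default_factory=default_propensity_matrix)
    persistence: float = 0.0
    seed: int = 0
    organism_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0.15 <= self.target_gc <= 0.80):
            raise ValueError(f"target_gc {self.target_gc} outside [0.15, 0.80]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must be in [0, 1)")
        m = self.propensity_matrix
        if sorted(m.index) != sorted(STANDARD_AA) or list(m.columns) != list(SS_STATES):
            raise ValueError("propensity_matrix must be 20 amino acids x states H,E,C")
        if not np.allclose(m.to_numpy().sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("propensity_matrix rows must each sum to 1")
        if (m.to_numpy() < 0).any():
            raise ValueError("propensity_matrix entries must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded alongside a generated genome."""

    realized_gc: float
    expected_cp: ConformationalParams | None  # closed form; persistence 0 only
    lambda_tilt: float


class GCTargetError(ValueError):
    """Requested GC outside what the codon alphabet can reach, or no convergence."""


def _expected_body_length(mean: float, dispersion: float) -> float:
    """E[max(NB(mean, dispersion), MIN)] — the truncation matters for short genes."""
    n = dispersion
    p = n / (n + mean)
    ks = np.arange(_MIN_BODY_CODONS)
    pmf = stats.nbinom.pmf(ks, n, p)
    return float(mean + np.sum((_MIN_BODY_CODONS - ks) * pmf))


def _tilted(weights_gc: np.ndarray, lam: float) -> np.ndarray:
    w = np.exp(lam * weights_gc)
    return w / w.sum()


_SENSE_GC = np.array([c.count("G") + c.count("C") for c in SENSE_CODONS], dtype=float)
_STOP_GC = np.array([c.count("G") + c.count("C") for c in _STOPS], dtype=float)


def solve_lambda(
    target_gc: float,
    mean_body_codons: float,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> float:
    """Bisection for the exponential codon tilt hitting the target GC.

    The objective is the expected GC fraction of the whole codon stream:
    body codons at their tilted distribution, plus one ATG and one tilted
    stop codon per gene at their expected share 2/(mean + 2) of codons.
    """
    nbar = mean_body_codons

    def expected_gc(lam: float) -> float:
        body = float(_tilted(_SENSE_GC, lam) @ _SENSE_GC) / 3.0
        stop = float(_tilted(_STOP_GC, lam) @ _STOP_GC) / 3.0
        return (nbar * body + 1.0 / 3.0 + stop) / (nbar + 2.0)

    lo, hi = -60.0, 60.0
    glo, ghi = expected_gc(lo), expected_gc(hi)
    if not (glo <= target_gc <= ghi):
        raise GCTargetError(
            f"target GC {target_gc} outside achievable range [{glo:.4f}, {ghi:.4f}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g = expected_gc(mid)
        if abs(g - target_gc) <= tol:
            return mid
        if g < target_gc:
            lo = mid
        else:
            hi = mid
    raise GCTargetError(f"tilt bisection did not converge in {max_iter} iterations")


def _draw_states(
    aa_indices: np.ndarray,
    cum_prop: np.ndarray,
    persistence: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-residue states: Markov copy with prob ``persistence``, else P(state|aa)."""
    n = aa_indices.size
    u = rng.random(n)
    proposals = (u[:, None] > cum_prop[aa_indices]).sum(axis=1)
    if persistence == 0.0 or n == 0:
        return proposals
    copy = rng.random(n) < persistence
    states = proposals.copy()
    for i in range(1, n):
        if copy[i]:
            states[i] = states[i - 1]
    return states


def generate_genome(spec: SyntheticSpec) -> tuple[GenomeRecord, SyntheticTruth]:
    """Generate one organism: genes, translated proteins, H/E/C annotations.

    Deterministic: identical specs (including seed) produce identical
    records byte for byte.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    nbar = _expected_body_length(spec.mean_gene_length, spec.length_dispersion)
    lam = solve_lambda(spec.target_gc, nbar)
    codon_p = _tilted(_SENSE_GC, lam)
    stop_p = _tilted(_STOP_GC, lam)
    codon_aa = np.array([_CODON_TO_AA[c] for c in SENSE_CODONS])
    sense_arr = np.array(SENSE_CODONS)
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    aa_of_codon = np.array([aa_index[a] for a in codon_aa])
    prop = spec.propensity_matrix.loc[list(STANDARD_AA), list(SS_STATES)].to_numpy()
    cum_prop = np.cumsum(prop, axis=1)[:, :2]  # thresholds for 3 states
    ss_letters = np.array(list(SS_STATES))

    n = spec.length_dispersion
    p = n / (n + spec.mean_gene_length)
    lengths = np.maximum(
        rng.negative_binomial(n, p, size=spec.n_genes), _MIN_BODY_CODONS
    )

    genes: list[CodingGene] = []
    proteins: list[ProteinRecord] = []
    for i, L in enumerate(lengths):
        body_idx = rng.choice(len(SENSE_CODONS), size=int(L), p=codon_p)
        stop = _STOPS[int(rng.choice(3, p=stop_p))]
        seq = "ATG" + "".join(sense_arr[body_idx]) + stop
        gid = f"{spec.organism_id}_g{i + 1:05d}"
        genes.append(CodingGene(gene_id=gid, sequence=seq))
        aa_idx = np.concatenate(([aa_index["M"]], aa_of_codon[body_idx]))
        protein = "M" + "".join(codon_aa[body_idx])
        states = _draw_states(aa_idx, cum_prop, spec.persistence, rng)
        ss = "".join(ss_letters[states])
        proteins.append(ProteinRecord(protein_id=gid, sequence=protein, ss_string=ss))

    genome = GenomeRecord(
        organism_id=spec.organism_id,
        genes=genes,
        proteins=proteins,
        taxon_label="synthetic",
    )
    realized_gc = compute_coding_gc(genes)
    expected = (
        expected_cp_from_spec(spec, aa_frequencies(proteins))
        if spec.persistence == 0.0
        else None
    )
    return genome, SyntheticTruth(
        realized_gc=realized_gc, expected_cp=expected, lambda_tilt=lam
    )


def expected_cp_from_spec(
    spec: SyntheticSpec, aa_freq: AAFrequencyTable
) -> ConformationalParams:
    """Closed-form conformational parameters under the independent-residue model.

    CP(aa, ss) = P(ss|aa) / sum_aa' f(aa') P(ss|aa') with f the supplied
    amino-acid frequencies.  Only valid for persistence 0 — state copying
    breaks the per-residue independence the closed form assumes.
    """
    if spec.persistence != 0.0:
        raise ValueError("closed-form CP requires persistence = 0")
    prop = spec.propensity_matrix.loc[list(STANDARD_AA), list(SS_STATES)]
    f = pd.Series({aa: aa_freq.frequency[aa] for aa in STANDARD_AA})
    f_ss = prop.mul(f, axis=0).sum(axis=0)  # P(ss) under f
    table = pd.DataFrame(index=prop.index)
    counts = pd.Series({aa: aa_freq.count[aa] for aa in STANDARD_AA}, dtype=float)
    for ss in SS_STATES:
        table[f"f_{ss}"] = prop[ss]
        table[f"cp_{ss}"] = prop[ss] / f_ss[ss]
        table[f"n_{ss}"] = counts * prop[ss]  # expected occurrences
    table["n_total"] = counts
    return ConformationalParams(
        table=table, f_ss=f_ss, total_residues=int(counts.sum())
    )


def gc_gradient_specs(
    n_organisms: int,
    gc_min: float = 0.25,
    gc_max: float = 0.70,
    seed: int = 0,
    coil_coupling: float = 0.0,
    **kwargs,
) -> list[SyntheticSpec]:
    """Specs for a panel of organisms with GC linearly spaced on a gradient.

    ``coil_coupling`` > 0 couples each organism's coil propensity to its
    GC target via :func:`coil_tilted_propensity`; each organism gets a
    distinct sub-seed derived from ``seed``.
    """
    kwargs.setdefault("n_genes", 100)
    targets = np.linspace(gc_min, gc_max, n_organisms)
    specs = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_organisms)]
    for i, (gc, sub) in enumerate(zip(targets, child_seeds)):
        extra = dict(kwargs)
        if coil_coupling > 0:
            extra["propensity_matrix"] = coil_tilted_propensity(
                float(gc), strength=coil_coupling
            )
        specs.append(
            SyntheticSpec(
                target_gc=float(gc),
                seed=sub,
                organism_id=f"org{i + 1:03d}",
                **extra,
            )
        )
    return specs
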
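"""End-to-end orchestration: load or simulate organisms, run every analysis
stage, and write TSV tables plus a run manifest.

A run is configured either from synthetic-panel parameters or from an
organism manifest TSV (columns: organism_id, genes_fasta, proteins_fasta
and optionally ss_fasta) plus an optional COG membership table.  Stages
run in order — load/generate, composition, structure statistics,
GC regressions, COG analysis — and each stage only consumes inputs or
earlier outputs.  The manifest records the resolved configuration, the
seed, the package version and a SHA-256 per output, so a rerun with an
identical configuration is verifiably identical for deterministic
stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import call_cog_bias, cog_bias_table, fit_linear, regression_table
from .composition import aa_frequencies, compute_coding_gc
from .io import (
    SS_STATES,
    STANDARD_AA,
    GenomeRecord,
    attach_ss,
    read_cog_table,
    read_fasta,
    write_fasta,
)
from .cog import align_ss, build_groups, cog_gc_table, filter_audit_frame, select_representatives
from .structure import SS_NAMES, conformational_params, ss_composition
from .synthetic import gc_gradient_specs, generate_genome

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Exactly one of ``organisms_tsv`` (real inputs) or ``synthetic``
    (generator parameters) must be set.
    """

    outdir: Path
    organisms_tsv: Path | None = None
    cog_table: Path | None = None
    synthetic: dict | None = None
    run_structure: bool = True
    run_regression: bool = True
    run_cog: bool = True
    regression_degree: int | str = 1  # 1, 2 or "auto"
    cog_min_members: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.organisms_tsv is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of organisms_tsv / synthetic must be configured"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("outdir", "organisms_tsv", "cog_table"):
            if d[k] is not None:
                d[k] = str(d[k])
        return d


def load_config(path: str | Path) -> RunConfig:
    """Parse a plain ``key: value`` config file into a RunConfig."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value'")
        k, v = line.split(":", 1)
        raw[k.strip()] = v.strip()

    def pop_bool(key: str, default: bool) -> bool:
        v = raw.pop(key, None)
        return default if v is None else v.lower() in ("1", "true", "yes")

    synth_keys = {
        "n_organisms": int, "gc_min": float, "gc_max": float, "n_genes": int,
        "mean_gene_length": float, "length_dispersion": float,
        "persistence": float, "coil_coupling": float,
    }
    synthetic = {
        k: conv(raw.pop(k)) for k, conv in synth_keys.items() if k in raw
    } or None
    degree_raw = raw.pop("regression_degree", "1")
    return RunConfig(
        outdir=Path(raw.pop("outdir", "gcstruct_out")),
        organisms_tsv=Path(raw["organisms_tsv"]) if raw.get("organisms_tsv") else None,
        cog_table=Path(raw["cog_table"]) if raw.get("cog_table") else None,
        synthetic=synthetic,
        run_structure=pop_bool("run_structure", True),
        run_regression=pop_bool("run_regression", True),
        run_cog=pop_bool("run_cog", True),
        regression_degree=degree_raw if degree_raw == "auto" else int(degree_raw),
        cog_min_members=int(raw.pop("cog_min_members", "10")),
        seed=int(raw.pop("seed", "0")),
    )


def _load_organisms(config: RunConfig) -> list[GenomeRecord]:
    if config.synthetic is not None:
        params = dict(config.synthetic)
        n_org = int(params.pop("n_organisms", 10))
        coil = float(params.pop("coil_coupling", 0.0))
        specs = gc_gradient_specs(
            n_org, seed=config.seed, coil_coupling=coil,
            gc_min=float(params.pop("gc_min", 0.25)),
            gc_max=float(params.pop("gc_max", 0.70)),
            **params,
        )
        return [generate_genome(s)[0] for s in specs]

    table = pd.read_csv(config.organisms_tsv, sep="\t", dtype=str)
    organisms: list[GenomeRecord] = []
    for row in table.itertuples(index=False):
        genes = read_fasta(row.genes_fasta, "nucleotide")
        proteins = read_fasta(row.proteins_fasta, "protein")
        ss_path = getattr(row, "ss_fasta", None)
        if isinstance(ss_path, str) and ss_path:
            ss = read_fasta(ss_path, "ss")
            proteins, missing = attach_ss(proteins, ss)
            if missing:
                logger.warning(
                    "%s: %d proteins lack annotations", row.organism_id, len(missing)
                )
        organisms.append(
            GenomeRecord(organism_id=row.organism_id, genes=genes, proteins=proteins)
        )
    return organisms


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all configured stages; returns the map of written outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t")
        outputs[name] = path

    organisms = _load_organisms(config)
    if config.synthetic is not None:
        for g in organisms:
            write_fasta(g.genes, outdir / f"{g.organism_id}_genes.fna")
            write_fasta(g.proteins, outdir / f"{g.organism_id}_proteins.faa")
            write_fasta(g.annotated_proteins, outdir / f"{g.organism_id}_ss.fasta", what="ss")

    # --- composition stage
    gc_rows, freq_rows = [], []
    for g in organisms:
        gc = compute_coding_gc(g.genes)
        gc_rows.append({"organism_id": g.organism_id, "coding_gc": gc})
        freqs = aa_frequencies(g.proteins)
        freq_rows.append(
            {"organism_id": g.organism_id, **{aa: freqs.frequency[aa] for aa in STANDARD_AA}}
        )
    gc_table = pd.DataFrame(gc_rows).set_index("organism_id")
    emit("gc_table", gc_table)
    aa_freq = pd.DataFrame(freq_rows).set_index("organism_id")
    emit("aa_freq", aa_freq)

    # --- structure stage
    annotated = {g.organism_id: g.annotated_proteins for g in organisms}
    have_ss = config.run_structure and all(len(v) > 0 for v in annotated.values())
    if config.run_structure and not have_ss:
        logger.warning("structure stages skipped: not all organisms carry annotations")
    cp_frames, ss_rows = [], []
    if have_ss:
        for g in organisms:
            cp = conformational_params(annotated[g.organism_id])
            frame = cp.table.copy()
            frame.insert(0, "organism_id", g.organism_id)
            for s in SS_STATES:
                frame[f"F_{s}"] = cp.f_ss[s]
            cp_frames.append(frame)
            comp = ss_composition(annotated[g.organism_id], scope="proteome")
            ss_rows.append(
                {
                    "organism_id": g.organism_id,
                    "frac_helix": comp.frac_helix,
                    "frac_sheet": comp.frac_sheet,
                    "frac_coil": comp.frac_coil,
                    "total_residues": comp.total_residues,
                }
            )
        emit("cp_table", pd.concat(cp_frames).rename_axis("amino_acid"))
        ss_comp = pd.DataFrame(ss_rows).set_index("organism_id")
        emit("ss_composition", ss_comp)

    # --- regression stage
    if config.run_regression and len(organisms) >= 3:
        gc = gc_table["coding_gc"].to_numpy()
        fits = {}
        for aa in STANDARD_AA:
            fits[f"aa_freq:{aa}"] = fit_linear(
                gc, aa_freq[aa].to_numpy(), degree=config.regression_degree
            )
        if have_ss:
            for col, name in (
                ("frac_helix", "helix"), ("frac_sheet", "sheet"), ("frac_coil", "coil"),
            ):
                fits[f"ss_comp:{name}"] = fit_linear(
                    gc, ss_comp[col].to_numpy(), degree=config.regression_degree
                )
            cp_all = pd.concat(cp_frames).rename_axis("amino_acid").reset_index()
            for aa in STANDARD_AA:
                sub = cp_all[cp_all["amino_acid"] == aa].set_index("organism_id")
                sub = sub.reindex(gc_table.index)
                for s in SS_STATES:
                    y = sub[f"cp_{s}"].to_numpy()
                    if pd.isna(y).any():
                        continue
                    fits[f"cp:{aa}:{SS_NAMES[s]}"] = fit_linear(
                        gc, y, degree=config.regression_degree
                    )
        emit("regressions", regression_table(fits))

    # --- COG stage
    if config.run_cog and config.cog_table is not None:
        proteins = {
            p.protein_id: p for g in organisms for p in g.proteins
        }
        gene_gc = {
            gn.gene_id: compute_coding_gc([gn]) for g in organisms for gn in g.genes
        }
        memberships = read_cog_table(config.cog_table, list(proteins.values()))
        groups = build_groups(memberships, proteins, gene_gc)
        calls, audits = [], []
        for cog_id in sorted(groups):
            group = select_representatives(groups[cog_id])
            audit = filter_audit_frame(group)
            audit.insert(0, "cog_id", cog_id)
            audits.append(audit)
            if len(group.members) >= config.cog_min_members:
                calls.append(
                    call_cog_bias(cog_id, cog_gc_table(group), config.cog_min_members)
                )
            annotated_members = [
                m for m in group.members if m.protein.ss_string is not None
            ]
            if len(annotated_members) >= 2:
                aln = align_ss(group)
                with open(outdir / f"{cog_id}_ss_alignment.fasta", "w") as fh:
                    for rid, row in zip(aln.ids, aln.rows):
                        fh.write(f">{rid}\n{row}\n")
        if calls:
            emit("cog_bias", cog_bias_table(calls))
        if audits:
            emit("cog_filter_audit", pd.concat(audits, ignore_index=True))

    # --- manifest
    manifest = {
        "package": "gcstruct",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(outputs.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    return outputs
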
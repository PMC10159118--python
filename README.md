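# gcstruct

Prokaryotic genomes span an enormous range of genomic GC content
(roughly 20–75% in coding regions). Because the GC content of a codon
constrains which amino acids it can encode, genome-wide GC pushes on the
amino-acid composition of the whole proteome — and, since amino acids
differ in their propensity to form alpha-helices, beta-sheets and random
coils, potentially on the secondary-structure composition of the
proteome itself. `gcstruct` is a library and command-line pipeline for
quantifying that chain of effects in panels of coding genomes with
per-residue three-state structure annotations (H = helix, E = sheet,
C = coil). It is aimed at comparative genomicists and protein-evolution
researchers who have per-gene CDS FASTA, protein FASTA and an H/E/C
annotation per protein (from any three-state predictor), or who want a
fully synthetic test bed with known ground truth.

## What it computes

For a genome *G* with protein-coding genes *g* and proteome *P(G)*:

* **Coding GC content**: GC_G = Σ_g GC(g) / Σ_g |g|, pooled over genes.
* **Codon-GC classes**: each amino acid's unweighted mean synonymous-codon
  GC fraction; > ½ is *high* (A, G, P, R, W), exactly ½ *neutral*
  (V, H, D, T, Q, C, E, S), < ½ *low* (L, M, F, Y, K, N, I) — a 5/8/7
  partition of the standard code.
* **Amino-acid frequencies**: aa_G = Σ_p |p(aa)| / |P(G)| for the proteome,
  and aa_ss^G per structure state.
* **Chou–Fasman conformational parameters**: F_ss^aa (share of an amino
  acid's residues in state ss), F_ss (share of all residues in ss) and
  CP = F_ss^aa / F_ss. CP > 1 marks a former of the state, CP < 1 a
  breaker.
* **Secondary-structure composition**: helix/sheet/coil residue fractions
  per proteome and per protein.
* **GC regressions**: OLS of any of the above on GC content, with slope,
  p-value, R² and R-style significance codes (`***` ≤ 0.001 < `**`
  ≤ 0.01 < `*` ≤ 0.05 < `.` ≤ 0.1 < ` `).
* **Orthologous groups (COGs)**: representative filtering (members within
  1 SD of the mean protein length whose domain span covers ≥ 80% of the
  mean domain length), per-member composition vs gene GC, the
  "GC-biased COG" call (≥ 2 of the 3 structure slopes at p < 0.001), and
  progressive multiple alignment of the H/E/C strings.
* **Synthetic genomes**: codon sampling under an exponential GC tilt with
  solvable target GC, negative-binomial gene lengths, translated
  proteins, and structure states drawn from a known propensity matrix
  P(state | aa) with optional run-length persistence — ground truth for
  every statistic above.

## Worked example

Simulate one organism at 55% GC, then ask the pipeline what it sees:

```
$ gcstruct simulate --gc 0.55 --n-genes 50 --seed 1 --outdir demo
realized_gc	0.550809

$ gcstruct gc --genes demo/genes.fna
0.550809

$ gcstruct sscomp --proteins demo/proteins.faa --ss demo/ss.fasta
	frac_helix	frac_sheet	frac_coil	total_residues
0	0.3432634198364735	0.22047635975826518	0.4362602204052613	14065
```

The realized coding GC lands within sampling noise of the 0.55 target,
and the 14,065-residue proteome splits into ~34% helix, ~22% sheet and
~44% coil — the background the generator's default propensity matrix
encodes. Conformational parameters per amino acid:

```
$ gcstruct cp --proteins demo/proteins.faa --ss demo/ss.fasta | cut -f1-3 | head -3
amino_acid	f_H	cp_H
A	0.5258701787394168	1.5319726727361012
C	0.24780701754385964	0.7219150169333857
```

Alanine sits in helices in 53% of its occurrences, 1.53× the overall
helix share — a strong helix former — while cysteine's CP of 0.72 marks
a helix breaker. A multi-organism run (`gcstruct all --config run.cfg`)
writes per-organism TSV tables (`gc_table`, `aa_freq`, `cp_table`,
`ss_composition`, `regressions`, `cog_bias`) plus a manifest with
per-output SHA-256 hashes for reproducibility.

## Layout

* `src/gcstruct/io.py` — FASTA dialects (CDS, protein, H/E/C), COG table
* `src/gcstruct/composition.py` — GC_G, codon classes, aa frequencies
* `src/gcstruct/structure.py` — per-state frequencies, CP, composition
* `src/gcstruct/association.py` — OLS vs GC, significance codes, COG bias
* `src/gcstruct/cog.py` — representative filters, H/E/C aligner
* `src/gcstruct/synthetic.py` — generator and closed-form CP oracle
* `src/gcstruct/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for the statistical model, parameter defaults and
limitations.
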
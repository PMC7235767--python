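# digestor

Analysis toolkit for chemically stressed anaerobic-digester microbiomes:

- **`digestor.process_chemistry`** — stoichiometric and operational accounting:
  Buswell–Boyle theoretical methane potentials from C/H/O/N composition,
  organic loading rates (organic vs inorganic stressors), hydraulic retention
  time, digestion efficiency, expected surplus methane, ideal-gas volume
  normalization to 273 K / 1013 hPa, and stressor molarity.
- **`digestor.amplicon_profiles`** — FASTQ length/mean-quality filtering
  (≥ 400 bp, mean PHRED ≥ 7 by default), OTU tables with QIIME-style lineages
  (TSV and BIOM-JSON readers), relative abundances, rank aggregation, top-N
  taxon selection and cross-condition intersection, Bray–Curtis
  dissimilarities and principal-coordinates ordination.
- **`digestor.differential_shifts`** — Benjamini–Hochberg adjustment, strict
  `padj < alpha` significance filtering, the 3-stressor Venn classification of
  increased/decreased/conflicting taxa versus a control, and a clearly-labeled
  CLR + Welch fallback test for when no external differential-abundance table
  is available.
- **`digestor.glv_core`** — generalized Lotka–Volterra simulation
  (`dx_i/dt = x_i (r_i + Σ_j a_ij x_j)`, adaptive RK with blow-up detection),
  parameter inference by gradient matching (finite-difference or spline
  derivatives of log abundances, ridge-regularized regression over one or
  several trajectories, leave-one-out ridge selection), sign classification
  with an optional scale-free neutrality threshold, and interaction counting /
  shared / unique comparisons across conditions.
- **`digestor.synthetic_data`** — study-shaped synthetic inputs: persistent
  random gLV communities, noisy multinomial count tables on the
  4-condition × 4-day × 3-replicate design with step perturbations, and an
  11-week feeding-schedule fixture.
- **`digestor.pipeline` / `digestor.cli`** — stage orchestration with a run
  manifest, plus the `digestor` command-line interface.

## Tests

```sh
python -m pytest -q tests/
```

The suite covers unit behavior, property-based invariants (hypothesis), and a
dedicated `tests/test_acceptance.py` with the end-to-end acceptance criteria
(closed-form simulator checks, noiseless round-trip recovery, stochastic sign
recovery under observation noise, brute-force oracle agreement, full-pipeline
run).

## CLI

```sh
digestor simulate --seed 1 --out fixtures/            # synthetic study
digestor chem --schedule fixtures/schedule.yaml --report chem.tsv
digestor profile --counts fixtures/counts.tsv --metadata fixtures/metadata.tsv --out prof/
digestor diff --da nal=da1.tsv --da gaba=da2.tsv --da phos=da3.tsv --out venn/
digestor glv --infer trajectory.tsv --ridge 1e-3 --out glv/
digestor glv --simulate model.json --x0 0.1,0.2 --times 0,1,2,3 --out sim/
digestor run --config config.yaml                     # full pipeline + manifest
```

`digestor run` reads a YAML config (`out_dir`, `seed`, stage toggles, `alpha`,
`ridge`, `epsilon`, `top_n`, optional external `counts`/`metadata`/`schedule`
paths) and writes every stage output plus `manifest.json`; identical configs
reproduce identical outputs.

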
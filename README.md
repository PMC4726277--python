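# venomics

An integrated transcriptomic–proteomic pipeline for identifying parasitoid
venom proteins, plus the downstream comparative analysis of venom-protein
sets. A transcript becomes a venom candidate when three independent evidence
streams agree: tissue-enriched expression (FPKM filter + exact two-library
differential-expression test with Benjamini–Hochberg correction), a
secretion-signal call (annotation transfer, a built-in heuristic, or external
predictions), and proteomic confirmation (charge-aware PSM score filtering
and tryptic peptide-to-protein mapping). Candidate sets are then compared
against two reference venom sets by dual e-value/bit-score homology cutoffs:
three-set Venn partitioning, paired better-score fractions, exact Wilcoxon
matched-pairs signed-rank tests, Fisher exact enrichment, and a cutoff
sensitivity sweep.

A synthetic-data module generates every input the pipeline consumes —
transcripts with constructed signal peptides, negative-binomial count tables,
PSM tables with sub-threshold decoys, and similarity tables engineered to a
chosen Venn design — with planted ground truth, so the whole pipeline is
testable end to end without external downloads.

## Package layout

| module | contents |
|---|---|
| `venomics.synthetic_data` | `SimulationConfig`, `GroundTruth`, generators, `simulate_all` |
| `venomics.seq_utils` | translation, ORF prediction, tryptic digestion, N50/N80/N20 statistics, greedy redundancy clustering |
| `venomics.expression` | FPKM, exact conditional binomial DE test, BH adjustment, the DE filter, qPCR 2^-ddCt |
| `venomics.signal_peptide` | transfer / local-heuristic / external signal calls, concordance |
| `venomics.proteomics` | PSM filtering, peptide mapping, protein inference |
| `venomics.integration` | three-evidence intersection, keyword categorisation, `run_pipeline` |
| `venomics.venom_compare` | best hits, homology calls, Venn partition, signed-rank and Fisher tests, cutoff sweep |

The packaged fixture `venomics/data/candidate_fpkm_table.tsv` holds the
70-row candidate table (gene, tissue FPKM pair, printed log2 ratio,
section, description) used by the arithmetic checks.

## CLI

```bash
venomics simulate --outdir sim --seed 7           # synthetic inputs + truth
venomics fpkm --counts sim/counts.tsv --out fpkm.tsv
venomics de --counts sim/counts.tsv --out de.tsv
venomics sigp --fasta sim/transcripts.fasta --out calls.tsv
venomics psm-filter --psms sim/psms.tsv --out passing.tsv
venomics map-peptides --psms passing.tsv --fasta sim/transcripts.fasta --out confirmed.tsv
venomics integrate --indir sim --outdir results   # full pipeline on a directory
venomics compare --nv pp_vs_nv.tsv --oep pp_vs_oep.tsv \
    --queries ids.txt --outdir cmp
venomics run-all --outdir everything --seed 7     # simulate + integrate
```

`simulate` and `run-all` accept `--config cfg.yaml` whose keys override
`SimulationConfig` fields, e.g.

```yaml
n_transcripts: 500
n_venom: 20
fold_change_venom: 8.0
psm_depth: 3.0
venn_design: [5, 5, 5, 5]
```

An input directory for `integrate` needs `transcripts.fasta`, `counts.tsv`
(transcript_id, count_vg, count_carcass, effective_length) and `psms.tsv`
(peptide, charge, xcorr, delta_cn, slice); optional `pp_vs_nv.tsv` /
`pp_vs_oep.tsv` (12-column tab-separated hit tables) enable the comparative
stage.

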
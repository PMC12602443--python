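# ieireprog

Fold-change distribution thresholding and treatment "reprogramming" of an
immunodeficiency gene panel in bulk RNA-seq.

## The problem

In a preclinical sepsis study, mice receive a sham challenge, a septic
challenge (cecal microbiome inoculum, CM), or the septic challenge plus a
cell-penetrating nuclear transport checkpoint inhibitor peptide (NTCI).
Bulk RNA-seq of spleen and lungs (three replicates per arm) yields two
contrasts against sham — sepsis and treated sepsis. The scientific
questions are: which of the ~485 human inborn-errors-of-immunity (IEI)
gene orthologs respond to sepsis, in which direction, and how many of
those responses does the treatment shift ("reprogram")?

This package implements that analysis as a tested, reusable pipeline for
anyone with a gene-level count matrix and a gene panel:

1. **Differential expression** — median-of-ratios size factors, per-gene
   moment dispersion, two-group negative-binomial Wald test,
   Benjamini–Hochberg FDR (padj < 0.05). Externally produced DE tables
   can be ingested instead.
2. **Classification** — each contrast's log2 fold changes are rounded
   down to the nearest 0.1 and equal values added up; a Gaussian
   A·exp(−(x−μ)²/2σ²) or Lorentzian A·γ²/((x−μ)²+γ²) is least-squares
   fitted to the binned counts, and significant genes are called
   *increased* (log2FC > μ + σ), *decreased* (log2FC < μ − σ) or
   *unchanged*.
3. **Panel intersection** — human panel symbols map to mouse orthologs
   (explicit entry → curated exception → ALL-CAPS → Title-case
   convention); unmapped symbols are reported, never guessed.
4. **Reprogramming** — per panel gene, the fold-change ratio between
   contrasts, fc_ratio = 2^(log2FC_cm − log2FC_ntci), with
   *suppressed*/*enhanced* calls when the treated log2FC moves beyond the
   background width δ of the treated contrast's fit.
5. **Synthetic data** — a negative-binomial simulator with known ground
   truth at study scale (15,500 genes, 3×3 design), including a preset
   that spikes the study's headline genes (an Il10-like gene 170-fold up,
   attenuated 6.5-fold by treatment; an Nlrp12-like gene 40-fold down,
   relieved 4-fold).

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

Simulate a study-scale dataset and run every stage:

```
ieireprog simulate --seed 2 --out-dir demo/
ieireprog de --counts demo/counts.tsv --sample-sheet demo/sample_sheet.csv \
    --contrast cm --out demo/de_cm.tsv
```

which prints

```
wrote 15500 genes x 9 samples to demo
cm: 15500 genes, 282 significant at padj<0.05
```

— 15,500 genes tested in the sepsis contrast, 282 passing the padj < 0.05
gate. The numbered drivers under `analysis/` run the same stages as a
narrative (simulate both organs, DE, fit + classify, panel intersection,
reprogramming), writing tables under `results/analysis/`. Step 05 ends,
for the spleen dataset:

```
spleen: 53 significant panel genes (29 up, 24 down, 0 unchanged); 52 reprogrammed (25 enhanced, 27 suppressed)
  Il10: reduced 5.3-fold [estimated ratio 5.34, true 6.50] -> suppressed
  Nlrp12: reversed 2.8-fold [estimated ratio 0.36, true 0.25] -> enhanced
```

The Il10-like spike (truth: 170-fold induction attenuated 6.5-fold) is
recovered as *increased* then *suppressed*, with the ratio estimated from
three replicates per arm (hence 5.3 against a truth of 6.5 — at this
replication an estimated log2FC difference carries ≈ 0.37 log2 units of
sampling noise). `ieireprog run-all --config run.yaml` performs the whole
sequence per organ from a YAML configuration and writes per-stage
artifacts plus a `summary.json`; reruns are byte-identical.

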
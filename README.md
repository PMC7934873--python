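# enhancerkit

Regulatory-genomics computations anchored on enhancer RNA (eRNA) origins,
for analysts studying how transcription factor activity, chromatin
accessibility, and gene expression organize around active enhancers — the
kind of question raised by disease-associated regulatory variants such as
the *MUC5B* promoter-region SNP in pulmonary fibrosis.

Active enhancers produce short divergent transcripts: in strand-specific
nascent-transcription data (e.g. PRO-seq), RNA polymerase II loading appears
as a minus-strand pileup just upstream and a plus-strand pileup just
downstream of a point **origin**. `enhancerkit` provides:

- **`enhancerkit.origins`** — a bidirectional origin caller: smooth each
  strand with a centered moving sum, pair each minus-strand maximum with its
  nearest downstream plus-strand maximum, place the origin at the
  mass-weighted mean of the paired peaks.
- **`enhancerkit.pwm`** — a PWM scanner (MEME minimal format in, BED6 out)
  whose hit threshold is calibrated to a target p-value by an exact dynamic
  program over the null score distribution, p = P(score ≥ s | background) ≤
  1e-5 by default.
- **`enhancerkit.md`** — the **motif displacement (MD) score**: for one
  motif, the proportion of instances within r = 150 bp of the nearest
  origin among those within R = 1500 bp,

  $$\mathrm{md} = h/H,\quad h = \#\{|d|\le r\},\quad H = \#\{|d|\le R\},$$

  which is r/R = 0.1 under uniform placement and rises with
  motif–enhancer co-localization; conditions are compared per motif with a
  pooled two-proportion z-test (significance at α = 1e-4), plus barcode
  distance histograms.
- **`enhancerkit.sn`** — pseudo-bulk single-nucleus contrasts on labeled
  nuclei: locus accessibility via logistic regression of the binarized
  response with a log-depth covariate, gene expression via negative binomial
  regression with a log-depth offset, likelihood-ratio p-values, Bonferroni
  adjustment, and pseudo-bulk coverage tracks.
- **`enhancerkit.mnase`** — nucleosome protection from tiled MNase-qPCR via
  the ΔΔCt model, protection = 2^-(ΔCt − ΔCt_ref).
- **`enhancerkit.synthetic`** — seeded generators with ground truth for all
  of the above (planted origins, co-localized motifs, divergent read
  pileups, two-group nucleus tables with known fold changes, tiled Ct
  profiles).

See `docs/methods.md` for the models, parameter defaults, and numerical
conventions.

## Worked example

Run the seeded end-to-end demo (simulate → scan → call origins → MD →
differential MD → single-nucleus contrasts → MNase):

```sh
enhancerkit demo --seed 0 --out demo_out
```

which prints (abridged):

```
n_origins_A                     12
md_A                            0.6893617021276596
md_B                            0.08484848484848485
diff_md_z                       11.9903360932417
diff_md_p                       3.9928180313338786e-33
accessibility_fold_change       1.6138374019647115
accessibility_p_adj             4.246480350379954e-05
expression_fold_change          1.9381721398497864
expression_p_adj                2.3131167800268495e-10
mnase_min_protection            0.3104268657903548
```

Reading these numbers: all 12 planted origins were recovered from the
divergent coverage; the planted motif's MD score in the co-localized
condition (0.69) towers over the null condition (0.085, near the uniform
expectation 0.1), and the two-proportion z-test flags it at p ≈ 4e-33, far
past the α = 1e-4 threshold. The single-nucleus stage (400 nuclei/group in
the demo) recovers the planted accessibility ratio 1.52 as 1.61 and the
expression ratio 1.91 as 1.94, both Bonferroni-significant; the MNase stage
maps the planted open region (protection ≈ 0.31, i.e. threefold *less*
protected than the reference) between the flanking protected amplicons.
`demo_out/` holds every intermediate file (FASTA, BED, bedGraph, TSV, SVG)
plus `manifest.json` with SHA-256 checksums — byte-identical across runs at
a fixed seed.

The same stages are available as library calls (`simulate_genome`,
`threshold_from_pvalue`, `scan`, `call_origins`, `md_table`, `diff_md`,
`diff_accessibility`, `diff_expression`, `relative_protection`, ...) and as
CLI subcommands (`scan`, `call-origins`, `md`, `diff-md`, `barcode`,
`sn-compare`, `mnase`).

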
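# mirmech

Infer the mechanism of miRNA-mediated gene repression — mRNA decay versus
translational repression — from matched miRNA, mRNA and protein expression
measured across a panel of cell lines.

## The problem

miRNAs silence their targets in two ways: by destabilizing the transcript
(mRNA decay) and by reducing protein output per transcript (translational
repression). Transcriptomics alone sees only the first. Given expression
of miRNAs, mRNAs and proteins (label-free spectral counts) across the same
samples, `mirmech` computes, for every miRNA–gene pair, three correlations
across samples:

* **miRNA–mRNA** `r(m, t)` — sensitive to mRNA decay,
* **miRNA–protein** `r(m, p)` — sensitive to the combined effect,
* **miRNA–ratio** `r(m, p − t)` — with log₂ abundances, `p − t` is the
  protein-to-mRNA ratio, a proxy for translational efficiency.

A layer is *significant* when `r < −0.8` and the one-sided (negative-tail)
`p < 0.005` with `p` from `t = r√(n−2)/√(1−r²)` on `n−2` df. A pair with at
least one significant inverse correlation **and** at least one
sequence-based binding prediction (e.g. TargetScan / miRanda / MirTarget2
tables) is called an interaction, and the significance pattern over
(mRNA, protein, ratio) assigns one of six mechanism categories:

| pattern (S/NS) | category | reading |
|---|---|---|
| S, S, NS | `RD`   | mRNA decay |
| S, NS, NS | `RD_o` | decay + compensating mechanisms |
| NS, S, S | `TR`   | translational repression |
| NS, NS, S | `TR_o` | repression + compensating mechanisms |
| S, S, S | `B_s`  | both strong |
| NS, S, NS | `B_w`  | both weak |

(The remaining pattern S, NS, S is logically inconsistent and is flagged.)

Around this core the package provides: spectral-count quantification
(decoy FDR `2R/(F+R)`, two-peptide/ten-spectra filters, total-count
normalization, IQR gene representatives), canonical seed-site detection
(6mer, 7mer-A1, 7mer-m8, 8mer) with distance-weighted local AU-context and
3′-supplementary-pairing scores, one-sided Kolmogorov–Smirnov
feature-efficacy tests, per-miRNA mechanism-preference Fisher tests with
Benjamini–Hochberg correction, offset-Poisson differential expression for
two-condition spectral counts, and a synthetic-data generator with planted
mechanisms for end-to-end validation.

## Worked example

Simulate the reference study (9 samples × 3 replicates, 10 miRNAs, 200
genes, 100 planted interactions) and fit:

```python
from mirmech import MirnaTargetModel
from mirmech.synthdata import reference_config

model = MirnaTargetModel.from_simulation(reference_config(seed=0))
results = model.fit()
print(results.summary())
```

```
miRNA-target mechanism analysis
==================================
miRNAs analysed: 10 (0 removed by variance filter)
genes analysed:  200
thresholds:      r < -0.8, p < 0.005 (pearson, one-sided)

predicted interactions: 98
  RD=36  RD_o=17  TR=25  TR_o=16  B_s=0  B_w=4
  transcriptomics_only    54%
  proteomics_benefit      46%
  tr_major                42%
  concordant               4%
  tr_involved             46%

strongest TR preference: miR-010 (6/9 TR-major, Fisher p=0.11, FDR=0.874)
paired 3'-pairing t-test: t=0.123 p=0.904 over 12 combinations
```

98 of the 100 planted interactions are recovered with a mechanism-compatible
category; `results.confusion_matrix()` shows, e.g., all 24 planted
decay-only targets landing in `RD` and all 24 translation-only targets in
`TR`:

```
                         RD  RD_o  TR  TR_o  B_s  B_w  anomalous  unassigned
decay_only               24     0   0     0    0    0          0           0
translation_only          0     0  24     0    0    0          0           0
...
```

The same analysis is available from the shell:

```sh
mirmech run --synthetic --out run1 --seed 0      # full pipeline
mirmech simulate --out inputs --seed 0           # just the synthetic data
mirmech sites --mirna-fasta inputs/mirnas.fasta \
              --regions-fasta inputs/regions.fasta --out sites.tsv
```

`mirmech run` writes per-stage TSVs (correlations, sites, interactions,
efficacy, preference), a `summary.json`, a `report.txt` and a `run.log`
echoing every threshold and seed.

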
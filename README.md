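# promoterz

Promoter-level analysis of H2A.Z positional hierarchy and chromatin
accessibility.

## The problem

H2A.Z is a histone H2A variant enriched at the nucleosomes flanking gene
promoters. Its deposition is hierarchical: the +1 nucleosome (first
nucleosome downstream of the TSS) fills first, and the −1 nucleosome
acquires H2A.Z only once the +1 position nears capacity. Loss of the
chaperone ANP32E shifts H2A.Z targeting genome-wide and moves promoters up
this hierarchy, with consequences for accessibility of the
nucleosome-depleted region (NDR) between the two nucleosomes.

`promoterz` implements the quantitative pipeline for studying this
hierarchy from standard text-format genomics data (BED/BEDPE/bedGraph),
for researchers analysing ChIP-seq of histone variants together with
paired-end ATAC-seq:

* **Flank-window signal** — strand-aware mean signal in the −1 window
  (−600..−100 bp) and +1 window (+100..+600 bp) around each TSS
  (`window_signal`), or in the 500 bp windows immediately flanking the TSS
  for change analysis.
* **Positional classes** — promoters are classified by a top-quantile
  rule (default: top 25 % of all flank scores, both sides pooled):
  `Two` (H2A.Z at −1 and +1), `One` (+1 only), `MinusOnly` (−1 only,
  rare), `Zero` (neither). Cross-condition comparisons reuse the
  thresholds established in the reference condition, and class
  transitions (e.g. One→Two gains vs One→Zero losses) are tabulated
  (`hierarchy`).
* **Fragment-size stratification** — paired-end accessibility fragments
  shorter than 150 bp are non-nucleosomal fragments (NNFs), the readout
  of NDR accessibility; fragments of 150 bp and above are
  nucleosome-protected (`genomic_io.split_by_size`).
* **Association statistics** — quartile partitioning with pairwise
  two-sided Wilcoxon rank-sum tests (Hochberg-adjusted), and any-overlap
  peak intersection with a hypergeometric enrichment test
  (`association`).
* **Synthetic data with ground truth** — a generator encoding the
  +1-before-−1 installation model (saturating targeting with spillover to
  the −1 position) renders ChIP-like coverage and two-component ATAC
  fragment mixtures, with every latent state recorded (`synthetic`).

## Worked example

```python
from promoterz import (SimulationConfig, simulate_experiment,
                       loss_response)

cfg = SimulationConfig(n_promoters=2000, seed=1)   # chaperone loss triples
bundle = simulate_experiment(cfg)                  # targeting at regulated promoters
r = loss_response(bundle)                          # WT thresholds, both conditions
print(r.classifications["WT"].counts().to_dict())
print(len(r.gain_one_to_two), len(r.loss_one_to_zero))
print(float(r.comparisons["p_adj"].iloc[0]))
```

prints

```
{'Zero': 1226, 'One': 541, 'Two': 233, 'MinusOnly': 0}
97 67
4.6947439629342374e-14
```

meaning: in the reference condition 233 promoters carry H2A.Z at both
flanks, 541 at the +1 flank only and none at the −1 flank only — the
near-absence of −1-only promoters is the signature of hierarchical
installation. After chaperone loss, 97 promoters gain H2A.Z at the −1
position (One→Two) against 67 that lose it at +1 (One→Zero), and the gain
group shows a significantly larger increase in non-nucleosomal
accessibility (Hochberg-adjusted rank-sum p ≈ 5e-14).

The same pipeline is available from the shell:

```
promoterz simulate --seed 1 --n-promoters 2000 --out fx/
promoterz classify --tss fx/tss.bed --track fx/h2az_WT.bedgraph \
    --genome fx/genome.tsv --condition WT --out wt.tsv
promoterz classify --tss fx/tss.bed --track fx/h2az_ANP32E_KO.bedgraph \
    --genome fx/genome.tsv --thresholds-from wt.tsv --condition KO --out ko.tsv
promoterz transitions --ref wt.tsv --alt ko.tsv \
    --tss fx/tss.bed --genome fx/genome.tsv --out-prefix trans
promoterz nnf --fragments fx/atac_WT.fragments.bed --tss fx/tss.bed \
    --genome fx/genome.tsv --out-prefix wt_acc
```

## Model notation

For targeting intensity `T ~ LogNormal(μ, σ)` (zero for untargeted
promoters), saturation constant `S` and per-promoter spillover capacity
`c_i`:

    occ₊₁ = T / (T + S)
    occ₋₁ = max(0, T − c_i) / (max(0, T − c_i) + S)

so `occ₋₁ < occ₊₁` whenever positive, and the −1 nucleosome is occupied
only after the +1 position is near capacity. Chaperone loss multiplies
`T` by `α` (default 3) at a regulated subset of promoters. See
`docs/methods.md` for the full model, parameter table and limitations.
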
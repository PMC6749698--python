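# prsascreen

Analysis pipeline for chaperone–amylase co-expression screens in *Bacillus
subtilis*. When a heterologous α-amylase is co-expressed with a candidate
extracytoplasmic foldase (a PrsA homolog), the questions a screen must
answer are quantitative: how much PrsA reached the membrane, how divergent
are the protein families involved, does the *prsA* promoter region carry
regulatory motifs, how much amylase activity ended up in the supernatant,
and which chaperone–amylase pairings improve yield significantly. This
package implements the computational side of that screen for researchers
working on secretion optimization in Gram-positive cell factories.

## What it computes

- **`prsascreen.hi3`** — label-free Hi3 (top-3) protein quantification from
  a search-engine peptide intensity table. Modified peptides are discarded;
  each biological replicate is normalized by division through its median
  peptide intensity; a protein's Hi3 value in a replicate is the sum of its
  three most intense normalized peptides (requiring ≥ 3 reported peptides);
  a protein is quantifiable only with values in ≥ 2 of 3 replicates; and
  its relative abundance is its Hi3 value divided by the summed Hi3 of all
  quantifiable proteins in the replicate.
- **`prsascreen.identity`** — mature-sequence (signal peptide removed)
  percent-identity matrices from Smith–Waterman local alignment with affine
  gap penalties (BLOSUM62, gap open 10, extend 0.5 by default), plus a
  neighbor-joining tree on d = 1 − identity/100 with Newick output.
- **`prsascreen.motifs`** — degenerate motif scanning on both strands:
  CssR operator boxes (canonical `TTTTCACA`, reported at ≥ 7/8 matched
  bases) and paired σ^A promoter boxes (`TTGACA` … 16–18 nt … `TATAAT`,
  ≥ 5/6 per box), with offsets relative to an anchor such as a start codon.
- **`prsascreen.assays`** — amylase activity units from kinetic A405
  traces (1 unit = 1 absorbance unit/min), calibration curves with inverse
  prediction, and β-galactosidase Miller units
  (1000·(A420 − 1.75·A550)/(t·v·OD600)).
- **`prsascreen.relyield`** — yield ratios normalized to the no-chaperone
  reference strain, Welch t-tests per cell vs reference, Bonferroni
  correction within each amylase row, and significance classes
  (p < 0.05 significant, 0.05 ≤ p < 0.10 marginal).
- **`prsascreen.synthetic`** — generators for every input above with
  ground-truth manifests, so the whole pipeline is testable without any
  instrument data.

## Worked example

Spike a target protein at a twofold abundance difference between two
strains and recover the fold change from the simulated peptide table:

```python
import numpy as np
from prsascreen import hi3
from prsascreen.synthetic import ProteomeTruth, SimulationConfig, generate_peptide_table

rng = np.random.default_rng(0)
truth = [ProteomeTruth("TARGET", 5, 80.0, {"A": 2.0, "B": 1.0})] + [
    ProteomeTruth(f"BG{i}", int(rng.integers(3, 7)),
                  float(rng.uniform(20, 300)), {"A": 1.0, "B": 1.0})
    for i in range(49)
]
table, _ = generate_peptide_table(truth, SimulationConfig(intensity_cv=0.1, seed=0))
out = hi3.run_pipeline(table, n_replicates=3)
ra = hi3.relative_abundance(out, "TARGET", "A")
rb = hi3.relative_abundance(out, "TARGET", "B")
fold, sd = hi3.strain_fold_change(ra, rb)
print(f"relative abundance A: {ra.mean:.4f}")
print(f"relative abundance B: {rb.mean:.4f}")
print(f"recovered fold change: {fold:.3f} +/- {sd:.3f}")
```

prints

```
relative abundance A: 0.0243
relative abundance B: 0.0117
recovered fold change: 2.080 +/- 0.202
```

The target occupies about 1% of the quantifiable proteome in strain B and
about 2% in strain A, and the recovered ratio of 2.08 agrees with the true
spike of 2 within its replicate spread. Two effects keep single-run
recoveries off the exact truth: measurement noise (cv = 0.1 here), and the
composition effect inherent to relative quantification — the spiked target
itself enlarges strain A's denominator, biasing the recovered ratio
slightly low on average. The acceptance script quantifies both: the median
recovery over 20 simulations lands within a few percent of the truth.

Motif scanning on a synthetic promoter region:

```python
from prsascreen.motifs import CSSR_BOX, MotifModel, scan_motif
from prsascreen.synthetic import MotifImplant, generate_promoter_region

region, manifest = generate_promoter_region(
    200, [MotifImplant(CSSR_BOX, 120, "+", 1)], seed=4)
hits = scan_motif(region, MotifModel("CssR box", CSSR_BOX, min_matches=7), anchor=180)
print(hits[0])
```

prints

```
MotifHit(motif='CssR box', start=120, end=128, strand='+', n_matches=7, offset_to_anchor=-60)
```

— a 7-of-8 operator match 60 nt upstream of the anchor, exactly as planted.

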
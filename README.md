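# gpspbs

Prediction of phosphoprotein-binding-domain (PPBD)-specific binding
phosphosites from protein sequence.

Phosphorylated serine, threonine and tyrosine residues (p-sites) are read
out by modular domains — 14-3-3, SH2, BRCT, PTB, WW, FHA, PBD and others —
that recognize the phosphoresidue together with its flanking sequence.
Knowing *which* domain family can bind a given p-site turns a raw
phosphoproteome into hypotheses about signaling: this package implements
the GPS-PBS approach, which scores candidate sites by their similarity to
known binding peptides and classifies them hierarchically (two groups →
domain families → single-domain clusters) with transfer learning, so that
even clusters with a handful of known sites get a usable predictor.

## The method

A candidate site is the window PBP(*m*, *n*): the central S/T/Y with *m*
residues upstream and *n* downstream (default 10/10, length *K* = 21),
`*`-padded at protein termini.

1. **Group-based scoring.** The similarity of a query window *A* to the
   *N* known positive windows *P₁…P_N* is

   *S* = (1/*N*) Σⱼ ( Σᵢ M(Aⱼ, Pᵢⱼ) ) · *W*ⱼ,

   with M = BLOSUM62 extended by the `*` row/column and *W*ⱼ a per-position
   weight.

2. **Position weight determination (PWD).** Weights start at 1, are fitted
   by L1-penalized (LASSO) logistic regression on the per-position
   similarity features, then refined by a hill climb alternating random
   ±1 mutation and random zeroing of single weights, accepting a step only
   when the 10-fold cross-validated AUC of *S* rises.

3. **Peptide-to-vector transformation (PVT).** The scalar score expands
   into a 231-dimensional vector indexed by the unordered pairs of the
   21-symbol alphabet: *S*<sub>ab</sub> = Σⱼ *D*ⱼ M(a,b) *W*ⱼ / Σⱼ *D*ⱼ,
   where *D*ⱼ counts the query–positive residue pairings realizing {a, b}
   at position *j* (21·22/2 = 231 components).

4. **Classifier.** A seven-layer network (input, five ReLU hidden layers
   with dropout, two sigmoid output units) maps the PVT vector to the
   probability that the window is a genuine binding site; trained by SGD
   with momentum and L2 weight decay. Family models are fine-tuned from
   their group model, cluster models from their family model.

5. **Calibration.** Score cutoffs are anchored to false-positive rates on
   random background windows: 20 draws of 10,000 windows, cutoffs at
   2/6/10% FPR (pS/pT group) or 4/9/15% (pY group) for the high/medium/low
   stringencies, averaged across draws; an `All` option returns every
   score.

6. **Co-regulation analysis.** A doubly regulated p-site (DRP) is bound by
   a PPBD family and phosphorylated by a kinase family. Association of a
   PPBD family *K* (*m_K* sites) with a kinase family *L* (*n_L* sites) on
   a universe of *T* sites is tested by 10,000-round permutation of the
   kinase assignments (the null overlap is hypergeometric), plus
   hypergeometric term enrichment for annotated site sets.

A seeded synthetic-data module generates motif-structured benchmarks
(positives drawn from consensus patterns such as the 14-3-3 R-x-R-S-x-pS-x-P
or the SH2 Y-x-N / Y-x-x-M motifs), proteomes with planted sites, and
nested group/family/cluster hierarchies, so the whole pipeline is testable
without any external data.

## Worked example

```python
import numpy as np
from gpspbs import (PredictorRegistry, calibrate_thresholds, scan_fasta,
                    train_node)
from gpspbs.calibration import candidate_background_windows
from gpspbs.data_model import PSPT_GROUP
from gpspbs.synthetic import motif_14_3_3, generate_benchmark, generate_proteome

bench = generate_benchmark(motif_14_3_3(), n_pos=100, neg_ratio=10.0, seed=1)
predictor = train_node(bench, pwd="full", seed=1)
print(np.round(predictor.weights.values, 2))

proteome, _ = generate_proteome(700, 500, seed=2)
background = candidate_background_windows(proteome, PSPT_GROUP.center_classes)
predictor.thresholds = calibrate_thresholds(predictor, background, seed=3)

target, truth = generate_proteome(3, 200, planted_sites=[(motif_14_3_3(), 2)],
                                  seed=4)
print(scan_fasta(target, PredictorRegistry({"14-3-3": predictor}),
                 level="high").to_string(index=False))
```

prints

```
[0.  0.  0.  0.  0.  1.  0.  0.91 0.89 0.  0.  0.  0.76 0.  0.  0.  0.
 0.  0.  0.  0. ]
 protein_id  position residue               peptide   node level    score  passed
SYNPROT0001        41       S KDVVYRVNTHSSPTQFCHEWM 14-3-3  high 0.986383    True
SYNPROT0001       142       S ATNGNAERLVSWPDTQEDHTI 14-3-3  high 1.000000    True
SYNPROT0001       166       S AVVRSGNRFRSMPAIHIWWCN 14-3-3  high 0.999996    True
```

The learned weights single out exactly the four constrained motif offsets
(−5, −3, −2, +2 of the 21-position window; the rest are driven to zero by
the LASSO and the zeroing moves). The scan at the high threshold (2%
background FPR) recovers the planted site at `SYNPROT0001:142`; the other
two rows are the background false calls expected at that stringency over
~90 candidate S/T residues.

The same workflow is scriptable: `gps-pbs simulate | train | calibrate |
predict | evaluate | drp` (site coordinates are 1-based throughout).

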
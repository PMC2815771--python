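# motifbench

Benchmark machinery for *phylogenetic footprinting* motif discovery: a
simulator that builds promoter datasets with transcription-factor
binding sites evolved along explicit phylogenies, and an evaluation
engine that scores any motif finder's predictions against the embedded
ground truth.

De novo discovery of transcription-factor binding sites can draw on two
kinds of evidence: **coregulation** (many promoters in one species bound
by the same factor) and **orthology** (the same promoter across related
species).  Tools differ in how they exploit the second kind, and
comparing them fairly requires datasets where the true sites are known
and the amount of each kind of information is controlled.  `motifbench`
generates exactly such datasets and implements the standard performance
and quality measures, so any finder that can emit site predictions can
be benchmarked under controlled signal-to-noise conditions.

## The model

A motif is a position weight matrix (PWM) `W` of width `w`; its
information content is the total relative entropy to the background,

    IC(W) = Σ_{i=1..w} Σ_b W_ib log2(W_ib / π_b)   [bits],

and the generator produces PWMs at any target IC (a "high-IC" motif is
well conserved, a "low-IC" motif degenerate).  An ancestral promoter is
i.i.d. background of length `L` (default 500 bp) with one sampled site
overwriting a uniform random window.  It evolves down a tree whose
branches carry a *proximity* `q ∈ (0,1]` under the copy-or-redraw kernel

    P(a→b) = q δ(a,b) + (1−q) π_b ,

Jukes–Cantor for background positions (uniform π) and an F81-style
kernel for motif positions, whose equilibrium at motif column `i` is the
PWM column `W_i`.  Proximities compose multiplicatively along paths:
`T(q1)T(q2) = T(q1 q2)`.

Datasets come in three spaces — coregulation (10 reference promoters),
orthologous (one promoter plus orthologs), combined (both) — with
controlled manipulations: motif degeneracy (target IC), site dropout in
the coregulation direction, and motif loss in one species or in whole
orthologous sets.

Evaluation: a predicted site is a **true positive** when it covers at
least half the length of an embedded site on the same sequence.  From
TP/FP/FN come PPV and sensitivity, their reference-species-restricted
variants spPPV/spSens, the **recovery rate** (fraction of outputs whose
predicted PWM matches the embedded one, with a 50%/80% quality rescue
rule), `D1`/`R1` output counts, and the **F-value**, the harmonic mean
of spPPV and spSens.  A baseline Gibbs site sampler is included so the
whole simulate → find → evaluate loop runs without external tools.

## Worked example

```python
from motifbench import (FinderConfig, correct_model, gibbs_find,
                        match_sites, quality_measures, recovery,
                        simulate_from_config)

ds = simulate_from_config({"space": "coregulation", "target_ic": 24.0},
                          seed=7, dataset_id="demo")
run = gibbs_find(ds.records, FinderConfig(width=13, seed=11))
tp, fp, fn = match_sites(run.sites, ds.sites)
q = quality_measures(tp, fp, fn)
print(len(tp), len(fp), len(fn), q.ppv, q.sens,
      recovery(run, correct_model(ds), ds))
```

Run as `python examples/02_find_and_evaluate.py`, this prints

```
predicted sites:  10
TP / FP / FN:     10 / 0 / 0
PPV:              100.0%   (true sites among predictions)
Sens:             100.0%   (embedded sites recovered)
recovery:         1        (1 = predicted model matches the embedded motif)
mean site score:  21.8 bits per site
```

i.e. on a ten-gene coregulation dataset with a 24-bit motif the baseline
finder locates every embedded site exactly, and the PWM it estimates
matches the embedded motif model.  Lowering `target_ic` toward 14 bits
makes recovery drop — coregulation alone stops being sufficient for
degenerate motifs.  The other scripts in `examples/` show dataset
simulation with motif loss, scoring external predictions from the TSV
interchange format (including a MEME text adapter), and running a
benchmark grid with F-value comparisons between search spaces.

A thin CLI wraps the same functions:

```sh
motifbench simulate --config cfg.yaml --seed 5 --out DIR
motifbench findmotif --dataset DIR --width 13 --out pred.tsv
motifbench evaluate --dataset DIR --predictions pred.tsv --out report.tsv
motifbench bench run --grid grid.yaml --seed 0 --out OUT
```

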
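# sigreverse

Transcriptional signature-reversal analysis for drug repurposing.

Connectivity mapping rests on a simple hypothesis: a drug that drives gene
expression changes *opposite* to those seen in a disease may oppose the
disease biology. `sigreverse` implements the full analysis pipeline for
testing that hypothesis on bulk expression data — it is written for
computational biologists who want to build disease expression signatures
from case/control or disease-stage series (e.g. post-mortem Alzheimer brain
studies), turn drug-perturbation screens (CMAP-style rank databases or
plate-based vehicle-controlled assays such as iPSC-derived neuron cultures)
into filtered gene-level profiles, and rank compounds by how strongly they
reverse the disease signature.

Every input the pipeline consumes can also be *simulated* with planted
ground truth (`sigreverse.simulate`), so the whole analysis is testable
end to end: planted signature genes and planted "reverser" drugs are known,
and recovery is measurable.

## The statistics at the core

**Disease signatures.** A case/control contrast uses the bounded scaled
fold over intensity-scale group means,

    f = (⟨d⟩ − ⟨c⟩) / (⟨d⟩ + ⟨c⟩)  ∈ (−1, 1),

filtered by a two-sample Student *t*-test (p < 0.05) and a minimum |f| of
0.20. Ordinal disease-stage series (e.g. Braak staging, cognitive scores)
are handled by per-gene least squares, expression ~ stage + categorical
covariates, with the stage coefficient's two-sided p converted to a signed
Z score (capped at ±8.2); scales that fall with progression are sign-
reversed. A *representative* signature over P studies keeps genes whose net
regulation fraction (n↑ − n↓)/P exceeds 0.20 with a significant one-sample
*t* on the senses.

**Drug profiles.** CMAP-style per-sample ranks R are mapped linearly to
[−1, 1] via 1 − 2(R − R_min)/(R_max − R_min), averaged over replicates with
a one-sample *t* filter, and collapsed probe→gene by the largest
significant change. Plate screens are contrasted against their vehicle
controls either as *t*-filtered scaled folds or as Z scores,
Z = (m_t − m_c)/(SD_c · √(1/n_t + 1/n_c)), retained at |Z| > 3.

**Connectivity scoring.** A query signature and a drug profile are compared
over their gene overlap by the sense-concordance score

    score = (n↑↑ + n↓↓ − n↑↓ − n↓↑) / (n↑↑ + n↓↓ + n↑↓ + n↓↑),

with significance from the exact Poisson-binomial tail of the match (or
mismatch) count — per-gene match probabilities either uniform (1/2) or
scaled by each gene's regulation frequency across the profile database.
Rank lists are assessed with the KS running-sum statistic (maximal
deviation of the cumulative hit curve from the diagonal) against a seeded
Monte-Carlo null; continuous profile pairs by the regression Z of one
profile on the other. Hit compounds (≥ 2 significant anti-correlations)
are then summarised by the sum-sense-change ratio (1/P)Σ sign(g_i) > 1/3,
UPGMA clustering, and hypergeometric gene-set over-representation with
Benjamini–Hochberg control.

## Worked example

Simulate and analyse a complete screen — 4 disease studies (1000 genes,
50 up + 50 down planted at 3 noise-SD, 5 vs 5 samples) and 50 drugs in
triplicate on 5 plates, 5 of them planted reversers at reversal fraction
0.8:

```python
from sigreverse.pipeline import run_reversal_screen

screen = run_reversal_screen(seed=1)
print(f"planted reversers : {sorted(screen.reversers)}")
print(f"selected hits     : {screen.hits}")
for drug, res, rank in screen.ranking[:7]:
    flag = "*" if drug in screen.reversers else " "
    print(f"  {rank:2d} {flag} {drug}  score={res.score:+.3f}  "
          f"enrichment_p={res.enrichment_p:.2e}  overlap={res.overlap}")
ks = screen.reverser_enrichment
print(f"reverser rank enrichment: D={ks.D:.2f}, p_mc={ks.p_mc:.1e}")
```

prints

```
planted reversers : ['drug009', 'drug015', 'drug030', 'drug033', 'drug040']
selected hits     : ['drug009', 'drug015', 'drug030', 'drug033', 'drug040']
   1 * drug009  score=-1.000  enrichment_p=1.03e-11  overlap=63
   2 * drug015  score=-1.000  enrichment_p=1.62e-10  overlap=59
   3 * drug033  score=-1.000  enrichment_p=2.22e-10  overlap=60
   4 * drug040  score=-0.932  enrichment_p=1.04e-07  overlap=59
   5 * drug030  score=-0.930  enrichment_p=2.63e-07  overlap=57
   6   drug026  score=-0.455  enrichment_p=6.14e-01  overlap=11
   7   drug005  score=-0.429  enrichment_p=7.31e-01  overlap=7
reverser rank enrichment: D=0.90, p_mc=1.0e-04
```

The five planted reversers occupy the top five anti-correlation ranks with
near-perfect reversal scores and vanishing enrichment probabilities; hit
selection (≥ 2 significant anti-correlations against two independent
representative signatures) returns exactly the planted set, and the KS
statistic of their ranks is as extreme as the Monte-Carlo null ever gets.

The same pipeline is scriptable from the shell — see `sigreverse --help`
(`simulate`, `signature`, `profile`, `query`, `enrich`, `hits`,
`consensus`, `ora`).

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic-data
generators and their defaults, numerical choices and known limitations.
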
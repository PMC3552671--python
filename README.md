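# bidipol

Identification of the regulatory regions of **bidirectional (head-to-head)
gene pairs** from RNA polymerase II (RPol II) ChIP-seq binding profiles.

More than 10% of human protein-coding genes sit head-to-head on opposite
strands with transcription start sites (TSSs) less than 1,000 bp apart.  The
region between the two TSSs may hold a single shared promoter or two distinct
promoters, and RPol II occupancy resolves the two cases: two promoters leave a
*bi-peak* fragment-density profile (one peak per TSS with a valley between),
a shared or one-sided promoter leaves a single peak.  `bidipol` implements the
complete analysis for users with aligned RPol II ChIP-seq reads and a gene
annotation: binned TSS-anchored coverage, bi-peak detection, a generative
two-promoter Poisson model fitted by particle swarm MAP estimation,
regulatory-region extraction, and four-way promoter categorization, plus a
ground-truth simulator so the whole stack is testable without external data.

## Method

**Bi-peak statistics.** For a divergent pair, with `P1` and `P2` the fragment
counts in the 20-bp bins holding the plus- and minus-strand TSSs and `V` the
lowest count strictly between them,

```
Sig = min(P1, P2) / V          Dif = max(P1, P2) / min(P1, P2)
```

A window is called bi-peak when `Sig >= 1.2` and `Dif <= 4` (cutoffs
calibrated on simulated shape sets at FDR <= 0.2, built by arranging real or
simulated single-gene profiles head-to-head and summing them).

**Two-promoter Poisson model.** Each promoter contributes an
exponential-decay expected profile with five parameters — background `B`,
transcript level `T`, TSS level `S` (counts/bin) and decay scales `Kp`
(upstream) and `Kt` (downstream, bp):

```
promoter side    lambda(D) = B + (S - B) exp(-D / Kp)
transcript side  lambda(D) = T + (S - T) exp(-D / Kt)
```

Observed bin counts are Poisson with mean equal to the **sum** of the two
genes' curves; which side of each curve applies follows the bin's region
(minus-gene transcript / inter-TSS / plus-gene transcript).  Genome-wide,
each parameter family is gamma-distributed across expressed genes; the gamma
(shape, scale) hyperpriors are estimated by method of moments from
maximum-likelihood fits of isolated single genes, and the ten pair parameters
`{B1, B2, T1, T2, S1, S2, Kp1, Kp2, Kt1, Kt2}` are then obtained by
maximizing log-likelihood + log-prior with a seeded particle swarm.

**Regions and categories.** A promoter's regulatory region is the interval
where the fitted signal has decayed less than 90% relative to the TSS bin
(closed-form boundary `K ln 10` on each side, snapped to bin edges).  Bi-peak
pairs yield two regions (a *double* promoter, with their overlap width);
single-peak pairs yield one region and are *left*, *right* or *centre*
promoters according to which TSSs the region covers.  Downstream read-outs
tally gene expression per category and assign transcription-factor peak
centers to left-body / middle / right-body zones.

## Worked example

```python
import bidipol as bp
from bidipol.pipeline import categorize_pair_profile

theta = bp.default_theta()
cfg = bp.SimConfig(seed=1, n_genes=0, n_pairs=3, unexpressed_fraction=0.34)
cohort = bp.simulate_cohort(cfg)
for i, rec in enumerate(cohort.pairs):
    f = bp.extract_peak_features(rec.profile)
    call = categorize_pair_profile(rec.profile, theta, seed=11 + i)
    r = call.regions[0]
    print(f"pair{i}: d={rec.distance:4d} bp  P1={f.P1:3d} P2={f.P2:3d} V={f.V:2d} "
          f"Sig={f.sig:5.2f} Dif={f.dif:5.2f} -> {call.shape:6s} {call.category:6s} "
          f"region {r.start}-{r.end}  truth={rec.label}")
```

prints

```
pair0: d= 140 bp  P1= 38 P2= 68 V=32 Sig= 1.19 Dif= 1.79 -> single centre region 1300-2400  truth=single_true
pair1: d= 720 bp  P1= 65 P2= 23 V= 8 Sig= 2.88 Dif= 2.83 -> bipeak double region 1280-2680  truth=bipeak_true
pair2: d= 720 bp  P1= 87 P2=106 V=21 Sig= 4.14 Dif= 1.22 -> bipeak double region 1720-2280  truth=bipeak_true
```

Pairs 1 and 2 show the bi-peak signature (Sig well above 1.2, balanced
peaks) and are resolved into two promoters; pair 0, simulated with one
unexpressed gene at a 140-bp TSS separation, shows a single merged peak whose
regulatory region spans both TSSs — a centre promoter.

A `bidipol` command-line tool exposes the same stages (`bin`, `pairs`,
`classify`, `simulate`, `simulate-roc`, `fit`, `annotate`); see
`bidipol --help`.

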
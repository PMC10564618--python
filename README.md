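# mudcod

Community detection for **multi-subject dynamic gene co-expression
networks**: spectral clustering with eigenvector smoothing across both
the time dimension and the subject dimension, together with the
multi-subject dynamic degree-corrected block model (MuS-Dynamic-DCBM)
simulator used to validate it.

## Who this is for

Single-cell RNA-seq cohorts increasingly yield one co-expression network
*per donor per time point* over a common gene set. Gene modules in these
networks are expected to change smoothly along time and to be broadly
shared across donors, while each individual network is noisy. Detecting
communities independently per network wastes that shared signal;
detecting them jointly on a pooled network erases individual variation.
This package infers a separate partition for every (subject, time) slice
while borrowing strength across both dimensions.

## The model

For subject `s = 1..S` and time `t = 1..T`, let `A_{s,t}` be a symmetric
binary adjacency matrix over `G` genes, `L_{s,t} = D^{-1/2} A_{s,t}
D^{-1/2}` its degree-normalized Laplacian and `U_{s,t} = V V^T` the
projection onto its `K` leading eigenvectors. The smoothed projections
minimize

```
Σ_{s,t} ‖U_{s,t} − Ū_{s,t}‖²_F
  + β Σ_{s,t}   ‖Ū_{s,t} − μ_s(Ū_{·,t})‖²_F
  + α Σ_{s,t<T} ‖Ū_{s,t} − Ū_{s,t+1}‖²_F
```

over rank-`K` projections, where `μ_s` is the mean projection of the
*other* subjects at time `t`. The solution is computed by a fixed-point
iteration that applies the spectral truncation `Π_K` to the weighted sum
of each slice's data term, temporal neighbors, and subject mean.
`α` controls time smoothing, `β` subject smoothing:

* `β = 0` — time-only smoothing per subject (the PisCES algorithm);
* `α = β = 0` — static spectral clustering per network.

`K` can be fixed or selected per slice from the largest eigengap of the
spectrum; `(α, β)` are tuned by node-pair network cross-validation
scored with a degree-corrected block model likelihood. Labels are
extracted from each smoothed projection by row-normalized k-means on its
leading eigenvectors.

## Worked example

```python
from mudcod import MuDCoD, MuSDynamicDCBM, SimulationConfig

sim = MuSDynamicDCBM(SimulationConfig(
    n_nodes=120, n_communities=3, n_subjects=4, n_times=2,
    r_time=0.1, r_subject=0.1, setting="SSoS", seed=7,
))
networks, truth = sim.generate()

res = MuDCoD(networks, alpha=0.1, beta=0.2, n_communities=3).fit(seed=0)
print(res.summary())
print("mean ARI vs truth:", round(res.score(truth)["mean"], 3))
```

prints

```
MuDCoD fit
==============================================
subjects: 4   time points: 2   nodes: 120
alpha (time): 0.1   beta (subject): 0.2
model order: fixed K=3
iterations: 8   converged: True   final delta: 4.897e-07
communities per slice (K): min 3, median 3, max 3
mean between-subject NMI: 0.536
mean ARI vs truth: 0.853
```

The fit converged in 8 sweeps; each of the 8 slices was partitioned into
3 communities; the partitions agree with the simulated ground truth at
mean ARI 0.85, and donors agree with each other at mean NMI 0.54
(truth-level agreement is imperfect because `r_time = r_subject = 0.1`
resamples ~10% of gene labels between adjacent slices).

The same pipeline is scriptable from the shell:

```bash
mudcod simulate --genes 120 --communities 3 --subjects 4 --timepoints 2 \
    --seed 7 --out nets/
mudcod fit --networks nets/ --alpha 0.1 --beta 0.2 --k 3 --out labels.tsv
mudcod evaluate --pred labels.tsv --truth nets/truth.tsv --metric ari \
    --out scores.tsv
```

plus `mudcod tune` (cross-validation for `α, β`), `mudcod benchmark`
(simulation sweeps comparing mudcod / pisces / static) and
`mudcod binarize` (top-quantile thresholding of correlation matrices).

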
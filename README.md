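# syncnet

Whole-brain phase-synchrony network analysis of memory encoding and
retrieval for intracranial EEG, with a ground-truth synthetic cohort
generator that makes every stage testable without patient data.

## Who this is for

Electrophysiologists and methods developers who want a tested, reusable
implementation of the trial-label-permutation phase-locking framework:
given multichannel iEEG recordings, an electrode table with atlas (ROI)
labels, and a trial-event table (word onsets and recalled flags; for
retrieval, vocalization onsets), the package builds z-scored ROI × ROI
connectivity networks that quantify how phase synchronization differs
between successfully and unsuccessfully encoded (or retrieved) items, and
relates those networks to spectral power and narrowband oscillations.

## The statistic

For each electrode pair (p, q), frequency f, and time window t, the
phase-locking value R̄ is the mean resultant vector length of the
across-trial phase-difference distribution (Morlet wavelets, wave number
5; phase differences circular-averaged within 200 ms windows). The core
statistic is

    D_pq(f, t) = R̄_rem − R̄_nrem

— positive when phase coupling is tighter for later-remembered items.
Because R̄ is biased by sample size, D is z-scored against 500
label-shuffle permutations that preserve group sizes. Electrode-pair
statistics are pooled (pair mean within ROI pair, replicate-wise null
mean, then subject mean) into a 74-ROI adjacency matrix; pairs sampled by
fewer than 7 subjects are masked. Downstream, the same null-network
machinery drives summed-weight tests, node-strength hub tests
(k_i = Σ_j w_ij, Benjamini–Hochberg across ROIs), strength timecourses,
Welch-t spectral-power contrasts, power–synchrony correlations with a
cyclic-shift significance test, and BOSC / P_episode narrowband
oscillation detection. See `docs/methods.md` for the full treatment.

## Worked example

Simulate a cohort of 8 subjects in which one ROI pair (left hippocampus ↔
left middle frontal) carries injected 6 Hz phase coupling that is tight on
remembered trials (von Mises κ = 8) and nearly uniform otherwise
(κ = 0.5), then run the full encoding contrast:

```python
import numpy as np
from syncnet import pipeline, studies

cfg = pipeline.RunConfig(sim=studies.theta_pair_config(seed=21),
                         n_perm=500, min_subjects=7, seed=21)
bundle = pipeline.run_encoding(cfg)

net = bundle.banded["theta"]          # band/time-averaged theta network
z = net.zscores()[0][:, 0, 0]
for e in np.argsort(-z)[:3]:
    a, b = net.pairs[e]
    print(f"{a:24s} {b:24s} z={z[e]:6.2f}")
print(bundle.hubs[("theta", "+")][["roi", "strength", "p_fdr", "hub"]]
      .round(3).to_string(index=False))
```

prints

```
L-hippocampus            L-middle-frontal         z= 14.57
L-fusiform               L-middle-frontal         z=  0.82
L-fusiform               L-hippocampus            z=  0.76

                roi  strength  p_fdr   hub
         L-fusiform     2.241  0.739 False
      L-hippocampus    15.504  0.006  True
   L-middle-frontal    15.386  0.006  True
        L-precuneus     0.885  0.918 False
        R-cingulate     1.229  0.918 False
R-superior-temporal     0.260  0.918 False
```

The injected pair is recovered as the top theta edge (z = 14.6, against
z ≲ 1 for uncoupled pairs), and exactly its two member ROIs emerge as
synchronous hubs after FDR correction. The network-wide summed positive
theta weight is likewise significant (z = 4.98, permutation P = 0.002)
while the other band/sign combinations stay at chance.

The same `RunConfig` drives the retrieval contrast
(`pipeline.run_retrieval`, 500 ms pre-vocalization vs. unsuccessful-search
epochs, two 250 ms windows) and the oscillatory-subnetwork analysis
(`pipeline.run_oscillation_subnet`, BOSC-selected electrodes). A thin CLI
wraps these: `syncnet simulate|encode|retrieve|subnet --config run.yaml
--out DIR`.

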
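# slidekin

Kinetic analysis of ATP-dependent nucleosome sliding by ISWI-family
chromatin remodelers (SNF2h), for single-molecule biophysicists and enzyme
kineticists. The package covers three experimental readouts of the same
reaction — an enzyme repositioning a nucleosome along DNA — and ships a
synthetic-data module that generates every input it consumes, so the entire
pipeline is testable end to end without raw experimental data.

## What it computes

**Single-molecule FRET trajectories.** An immobilized, end-positioned
nucleosome carries a donor on histone H3 and an acceptor on one DNA end;
remodeling moves the nucleosome away from the labeled end and FRET decays in
alternating constant-FRET *pauses* and brief *translocation* phases (the
first pause is the "wait" pause, then p1, p2, ...). The pipeline is:

1. FRET computation (proximity ratio, optional leakage / direct-excitation /
   gamma corrections) and QC: traces with two-step donor photobleaching
   (doubly labeled H3) are excluded; traces whose fitted initial FRET is
   below 0.775 (distally labeled population, mid-FRET cluster at 0.57 vs
   0.95 for the proximal one) are excluded; the analysis window ends at the
   earliest photobleach; everything from a backtracking event (FRET
   increasing) onward is removed.
2. Segmentation with a discrete-state Gaussian HMM under a sticky
   (self-transition-biased) transition matrix, state count by BIC; an exact
   dynamic-programming least-squares changepoint fit serves as an
   independent oracle in the tests.
3. Statistics: pause-duration means per label, inter-pause FRET changes
   converted to base pairs through a monotone calibration curve
   (`fret_to_bp`), step-size ECDFs, and trajectory-level bootstrap errors.

**Ensemble kinetics.** Nonlinear least-squares fits of

- single exponential: `y(t) = (y0 − p) e^(−k_obs t) + p`, optionally with
  y0 and the plateau p shared across a concentration series;
- cooperative binding: `k_obs = k_max X^h / ((K_m^app)^h + X^h)`;
- competition binding: `k_obs = k0 / (1 + X / K_I)`;
- two-phase decay:
  `y = p + (y0 − p)[f_fast e^(−k_fast t) + (1 − f_fast) e^(−k_slow t)]`;
- ATPase initial rate: OLS slope over the first 10% of inorganic phosphate.

**Crosslinking mass spectrometry.** Semi-quantitative domain-level
differential analysis of zero-length (EDC) crosslinks between nucleotide
conditions: linear-SVM target/decoy classification of crosslink spectral
matches on five search-engine features (retained if SVM score > 1, score
difference > 5, spectral count ≥ 1), decoy-based FDR with a
10-copy-randomized decoy database, fractional spectral counting of ambiguous
site localizations (each spectrum awards exactly one count), aggregation to
domain pairs, and pseudocounted, NA-masked, median-centered log2 ratios.

## Worked example

```python
import numpy as np
from slidekin import (simulate_titration, fit_single_exponential, fit_hill,
                      TrajectorySimConfig, simulate_trajectory_set,
                      default_calibration, analyze_set, summarize_pauses)

# --- ensemble titration: two-stage fit (shared-plateau exponentials -> Hill)
concs = np.array([7.8, 15.6, 31.2, 62.5, 125, 250, 500, 1000, 4000, 16000.0])
t = np.concatenate([[0.0], np.geomspace(0.05, 60.0, 24)])
courses = simulate_titration({"k_max": 2.5, "K_m_app": 61.0, "h": 1.5},
                             concs, t, noise_sd=0.02, seed=0)
fits = fit_single_exponential(courses, share={"y0", "p"})
res = fit_hill(concs, np.array([f.params["k_obs"] for f in fits]))
# k_max  = 2.545 /min (SE 0.028)
# K_m^app = 62.3 nM (SE 2.5)
# h      = 1.50 (SE 0.08)

# --- smFRET: simulate, QC, segment, summarize
calib = default_calibration()
cfg = TrajectorySimConfig(n_frames=1110, noise_sd=0.04)
sims = simulate_trajectory_set(cfg, calib, 60, seed=3)
out = analyze_set([tr for tr, _ in sims], calib)
summary = summarize_pauses(out["pauses"], n_boot=500, seed=0)
# wait: 28.9 +/- 7.6 s  (n=13)     p1: 6.2 +/- 1.0 s     p2: 11.9 +/- 3.5 s
# step 1: median 8.0 bp            step 2: median 6.1 bp
```

The titration fit recovers the generating parameters (k_max = 2.5 min⁻¹,
K_m^app = 61 nM, h = 1.5) within the noise. In the smFRET run, 13 of 60
simulated traces survive QC — the 2:1 unlabeled:labeled H3 mixture puts 4/9
of nucleosomes in the dark "none" class and 2/9 in the excluded distal
class, so small simulated sets retain few traces (real datasets pool ≥100
trajectories); the surviving traces reproduce the ~8 bp first and ~5 bp
second step. Errors are standard deviations over trajectory-level bootstrap
resamples.

A thin CLI mirrors the library:
`slidekin simulate {traces|titration|inhibition|atpase|xlms}`,
`slidekin qc`, `slidekin segment`, `slidekin kinetics`,
`slidekin fit {exp1|hill|competition|exp2|atpase}`, `slidekin xlms`.

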
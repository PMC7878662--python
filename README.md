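# prlstat5

Mechanistic modeling of prolactin-receptor JAK2–STAT5 signaling in
pancreatic beta cells.

Prolactin (PRL) signaling through the prolactin receptor drives the
expansion of insulin-producing beta cells during pregnancy. In INS-1 beta
cells, a constant PRL stimulus produces a *biphasic* STAT5 response: an
early phosphorylation peak (~30 min), attenuation below 70% of that peak,
and a second, equal-or-larger peak after 3 h, ultimately inducing the
pro-survival protein Bcl-xL. This package is for systems biologists who
want to ask which regulatory wiring can generate that behavior and what it
implies for enhancing beta-cell survival.

## The model

A mass-action ODE network (nM, minutes). One PRL bridges two preformed
receptor:JAK2 complexes (RJ); the activated complex PRL:RJ2\* phosphorylates
STAT5A and STAT5B, which dimerize (AA, BB, AB at rates k8A/k8B/k8AB), enter
the nucleus (k14A/k14B/k14AB), and drive transcription. Phosphatases act at
the receptor (SHP-2), in the cytosol (PPX, binding k11 / catalysis k12) and
in the nucleus (PPN); unphosphorylated nuclear STAT5 is exported
(k17A/k17B). Three regulatory modules toggle independently, giving eight
model structures:

* **a** — STAT5-induced SOCS, binding ligand-bound receptor complexes
  competitively and targeting them for degradation (negative feedback);
* **b** — STAT5-induced receptor up-regulation (maximal transcription rate
  k30a; positive feedback);
* **c** — ligand-induced receptor internalization (`deg_ratio` × faster
  degradation of ligand-bound complexes).

The core network has 24 species and 31 reactions; the full network 32 and
47. On top of the simulator the package provides:

* **Ensemble modeling** — log-uniform Monte Carlo sampling (±2 decades
  around baseline) of all rates and initial values per structure, peak
  detection (20-min minimum distance, 0.1%-of-pool prominence), five
  time-course characteristics, and a qualitative shape classifier built
  from the thresholds 1% (weak activation), 70% (attenuation), 1 h (first
  peak) and 3 h (reactivation).
* **eFAST** global sensitivity analysis (first- and total-order indices
  with a dummy-input selection floor) and the multiplicative-factor
  reparameterization mult8B = k8B/k8A, mult14B = k14B/k14A, ….
* **Bayesian calibration** — Metropolis–Hastings in log10-parameter space
  with the observation variance marginalized under an inverse-gamma prior
  (the marginal likelihood is a closed form in the SSE), multi-chain
  protocol, best-chain selection by retained-window median SSE, and AIC
  structure comparison, AIC = n·log(SSE/n) + 2k.
* **Predictions** — posterior-predictive dose–response of nuclear STAT5B
  (normalized to the unstimulated level) and two-parameter perturbation
  heatmaps (k2 × k12, RJ × PPX).
* **Synthetic data** — noisy 37-point observation sets with the exact
  structure of the study's six streams (pJAK2, pSTAT5A, pSTAT5B, nuclear/
  cytosolic ratios of STAT5A and STAT5B, Bcl-xL fold change), enabling
  parameter-recovery experiments without any external download.

## Worked example

```python
from prlstat5.network import ModelStructure, build_network, structure_report, default_parameters
from prlstat5.simulate import compile_network, simulate, total_pstat5, observables
from prlstat5.ensemble import detect_peaks, classify_detailed, compute_features

full = ModelStructure.from_label("abc")
print(structure_report(build_network(full)))

params = default_parameters(full)
traj = simulate(compile_network(full), params, dose_ng_ml=200.0, horizon_min=1440.0)
series = total_pstat5(traj)[:361]          # six-hour window, 1-min grid
times, heights = detect_peaks(series, pool=1000.0)
print("peaks (min, nM):", [(float(t), round(float(h), 1)) for t, h in zip(times, heights)])

feats = compute_features(series, pool=1000.0)
print("activation strength:", round(feats.activation_strength, 4))
print("negative feedback strength:", round(feats.negative_fb_strength, 3))
print("label:", classify_detailed(series, pool=1000.0).value)

obs = observables(traj)
print("Bcl-xL fold at 12/18/24 h:",
      [round(float(obs.bclxl_fold[h * 60]), 2) for h in (12, 18, 24)])
```

prints

```
structure abc: 32 species, 47 reactions (core: 31, socs: 12, upregulation: 4)
peaks (min, nM): [(36.0, 59.2), (320.0, 64.5)]
activation strength: 0.0645
negative feedback strength: 0.339
label: DESIRED
Bcl-xL fold at 12/18/24 h: [2.23, 2.3, 2.13]
```

The full model at its baseline produces the experimentally observed shape:
a first pSTAT5 peak at 36 min (59 nM, 6.5% of the 1000 nM STAT5 pool),
attenuation to 66% of the peak, reactivation to a higher second peak at
5.3 h, and a Bcl-xL fold change that rises through ~18 h before declining —
so the trajectory is classified `DESIRED`.

A thin CLI mirrors the library (`prlstat5 report|simulate|ensemble|synth|
calibrate|predict|run`); `prlstat5 run config.yaml` executes a multi-stage
pipeline and writes CSV artifacts plus a manifest with seeds, versions and
artifact hashes.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the main computation from scratch — structure assembly for all
eight networks, the default full-model simulation and observables, a
classified Monte Carlo ensemble, synthetic-data generation, a short
Metropolis–Hastings calibration and a posterior dose–response — with all
randomness derived from `--seed`, and writes the results JSON to `--out`.
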
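# hrdquant

Quantitative analysis of protein retention in heterochromatin compartments.

Constitutive heterochromatin in mouse nuclei clusters into bright
chromocenter foci. Some chromatin proteins — the motivating case is the
histone methyltransferase KMT5C and its heterochromatin retention domain
(HRD) — show a paradoxical kinetic state there: they diffuse and remix
*within* a chromocenter in tens of seconds, yet exchange with the
surrounding nucleoplasm over hours. `hrdquant` implements the full
measurement pipeline used to characterize that behavior, plus a synthetic
data layer so every stage is testable without microscope data:

* **FRAP / iFRAP quantification** (`hrdquant.frap`) — background
  correction, scanning-photobleach normalization
  `NormI(t_n) = I(t_1)_nuc / I(t_n)_nuc · I(t_n)_ROI`, relative
  fluorescence, double-term exponential fits
  `F(t) = F_0 + a_1(1−e^{−t/τ_1}) + a_2(1−e^{−t/τ_2})` with mobile
  fraction `(plateau − F_0)/(1 − F_0)`, fractional recovery at 5 and
  100 s, kymographs, and inverse-FRAP efflux rates with turnover
  extrapolation.
* **Partition coefficients** (`hrdquant.partition`) — three-class
  intensity segmentation (chromocenter / nucleoplasm / background, with a
  DNA-counterstain fallback for non-partitioning proteins) and
  `PC = (Ī_cc − Ī_bg) / (Ī_np − Ī_bg)` per nucleus, plus normalized
  scatter and expression-saturation binning.
* **Construct panels** (`hrdquant.panel`) — per-construct medians of
  PC and recovery metrics, hierarchical clustering on z-scored features,
  Kruskal–Wallis and pairwise Wilcoxon rank-sum tests with Holm
  adjustment.
* **Sequence features** (`hrdquant.seqfeat`) — a motif-grammar scanner
  for the HRD short linear motifs (Φ1 = [VI]-x-L, His-Cys =
  H-x₄-C-x₃₋₄-C, Φ2 = L-x₅₋₆-V-x-L, Φ3 = L-x₅-V-x-L, and the canonical
  HP1 chromoshadow ligand PxVxL), CR1–linker–CR2 architecture calling
  under spacing constraints, and linker physicochemistry (NCPR, FCR,
  disorder-promoting fraction, per-residue charge profile,
  conformational class and functional length).
* **Synthetic data** (`hrdquant.simulate`, `hrdquant.seqgen`) — a
  deterministic continuum reaction–diffusion–binding simulator of a 2D
  nucleus (free diffusion, mass-action binding to a finite chromocenter
  site pool, bound-state site-to-site hopping), noisy two-channel nucleus
  renderings with ground-truth masks, expression series, and an
  HRD-sequence generator with planted motifs and composition-controlled
  linkers.

## Worked example

Simulate the "retentive" kinetic preset (dense chromocenter binding
sites, slow unbinding, fast on-lattice hopping), then run the analysis
chain on it:

```python
import dataclasses
from hrdquant import simulate as sim, frap, partition

params = sim.preset("retentive", bleach_depth=0.1)

# partial vs total bleach of one chromocenter, 100 s
roi_half = sim.chromocenter_roi(params, 0, half=True)
_, s_partial = sim.simulate_frap(params, roi_half, t_end=100, frame_interval=2.0)
t_eq = frap.internal_equilibration_time(frap.process_series(s_partial))

roi_full = sim.chromocenter_roi(params, 0)
_, s_total = sim.simulate_frap(params, roi_full, t_end=100, frame_interval=2.0)
r100 = frap.recovery_at(frap.process_series(s_total), 100.0)

# 30-minute inverse FRAP: bleach all but one chromocenter
_, s_inv = sim.simulate_ifrap(dataclasses.replace(params, bleach_depth=0.0),
                              t_end=1800, frame_interval=30.0)
res = frap.ifrap_efflux(frap.process_ifrap(s_inv), window=1800.0,
                        internal_equilibration=t_eq)
```

This prints:

```
steady-state partition coefficient : 9.55
internal remixing time (partial)   : 26 s
total-bleach recovery at 100 s     : 0.14
apparent efflux rate (iFRAP)       : 0.52 %/min
extrapolated complete turnover     : 3.2 h
equilibration-rate ratio           : 443
```

Read: the protein is ~10-fold enriched in chromocenters; a half-bleached
focus remixes internally in under half a minute, while a fully bleached
focus recovers only 14% in 100 s; extrapolating the inverse-FRAP loss
rate, complete compartment turnover takes hours — two to three orders of
magnitude slower than internal remixing. That scale separation is the
retention phenotype.

A command-line interface wraps the same stages:

```
hrd simulate frap --preset retentive --mode partial --out out/
hrd frap quantify --series out/frap.csv --out out/
hrd seq scan --fasta sequences.fasta
hrd run --seed 1 --out run_out/
```

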
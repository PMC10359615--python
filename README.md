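# apekin

Quantitative analysis of AP-endonuclease 1 (APE1) cleavage kinetics, tight
binding, RPA exchange and complex stoichiometry at DNA substrates that mimic
a stalled replication fork.

Abasic sites stall replicative polymerases at a 3′ dsDNA–ssDNA
primer-template junction (PTJ); APE1 can incise abasic sites in the exposed
single-stranded region, with major consequences for fork stability. This
package implements, as a tested and reusable pipeline, the complete
quantitative workflow used to characterize that activity:

* **Pre-steady-state kinetics.** Multiple-turnover time courses are biphasic
  and fit to `product = A(1 − e^(−k_obs·t)) + v_ss·t`, where the burst
  amplitude `A` is the concentration of actively engaged enzyme, `k_obs` the
  cleavage rate, and `k_ss = v_ss/A` the steady-state (product-release) rate.
  Single-turnover data are fit to one or two rising exponentials, with the
  larger-amplitude component defining the major population.
* **Tight binding.** EMSA titrations at 5 nM DNA are fit to the Morrison
  quadratic `AB = ((A_T + B_T + K_D,app) − √((A_T + B_T + K_D,app)² −
  4·A_T·B_T))/2` (evaluated in a cancellation-free form), because free and
  total enzyme cannot be equated near the probe concentration.
* **FRET exchange and competition.** Proximity ratios
  `E_FRET = I_665/(I_665 + I_563)` from donor/acceptor traces, plateau
  averaging, Y-Max/Y-Min normalization against the predicted no-interaction
  value (channel-wise spectral sum), and 50%-inhibition midpoints of
  competition titrations by linear interpolation.
* **Mass photometry.** Landing-event histograms decomposed with the mixture
  `f(x) = Σ aₙ·exp(−((x − bₙ)/cₙ)²)` (note: no ½ factor, so `c = σ√2`) and
  area-based population fractions `aᵢcᵢ/Σaⱼcⱼ` that resolve 1-RPA vs 2-RPA
  complexes on a DNA substrate.
* **Mechanistic oracle.** A minimal two-step turnover scheme
  (ES →(k_chem) EP →(k_rel) E + P) with closed-form burst parameters, a
  stiff ODE integration, and an exact Gillespie simulation — an independent
  check that the empirical burst model measures what it claims
  (`k_obs = k_chem + k_rel`, `A = E0·(k_chem/(k_chem+k_rel))²`).
* **Synthetic data.** Seeded generators for every experiment above at the
  standard designs (multiple turnover: DNA 100 nM / enzyme 30 nM; single
  turnover: enzyme 500 nM / DNA 50 nM; EMSA: DNA 5 nM, enzyme 0–2000 nM;
  FRET: DNA 25 nM), with proportional Gaussian noise, so every stage is
  validated by parameter recovery without instrument data.

Intended users: enzymologists and biophysicists analyzing rapid-quench,
gel-shift, ensemble-FRET or mass-photometry experiments, and anyone who
wants a fully seeded reference pipeline for burst-kinetics inference.

## Worked example

Generate three noisy multiple-turnover replicates at the standard design
from the published junction-substrate truth (k_obs = 10 s⁻¹,
k_ss = 2.7 s⁻¹, A = 30 nM) and recover the parameters:

```python
from apekin import fitkit, presets, synthgen

noise = synthgen.NoiseModel(seed=1)              # 3% cv, 0.5 nM floor
tc = synthgen.gen_timecourse(presets.mt_truth("PTJ"), noise=noise)
res = fitkit.fit_burst(tc, sigma=noise.sigma(tc.product))
p = res.params
print(f"kobs = {p.kobs:.2f} ± {p.se_kobs:.2f} s^-1")
print(f"kss  = {p.kss:.2f} ± {p.se_kss:.2f} s^-1")
print(f"A    = {p.A:.1f} ± {p.se_A:.1f} nM")
print("warnings:", res.warnings)
```

prints

```
kobs = 10.12 ± 0.46 s^-1
kss  = 2.74 ± 0.13 s^-1
A    = 29.5 ± 1.2 nM
warnings: ['low-separation']
```

The recovered rates match the generating truth within their standard
errors. The `low-separation` warning is the fitter noting that
k_obs/k_ss < 10 for this substrate, so the exponential and linear phases
overlap and k_obs is intrinsically harder to pin down — exactly the regime
where single-turnover confirmation experiments are warranted.

The same workflow is available from the shell:

```bash
apekin simulate --kind timecourse --truth-from table1:PTJ --seed 1 --out tc.csv
apekin fit --kind burst --in tc.csv --out fit.json
apekin report --preset table1 --out report.md
apekin recover --kind morrison --kd 22 --seed 1 --out recovery.json
```

`report --preset table1` reproduces the published wild-type fold-change
table (k_obs folds 12.9, 4.3, 64.5 and k_ss folds 1.6, 3.5, 11.3 relative
to duplex DNA) from the central rates.

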
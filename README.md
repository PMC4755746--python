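# tactilenp

Modeling how primary somatosensory cortex (S1) integrates input from two
mechanoreceptive channels — rapidly adapting (RA) and Pacinian (PC)
afferents — during high-frequency skin vibration.  The package
implements the full computational chain for this question and is aimed
at researchers in tactile neural coding who want a tested, reusable
version of it:

1. **Stimuli** — sinusoids, diharmonics, frozen band-limited noise
   (50–800 Hz), and texture-analog vibrations with power-law spectra
   (`tactilenp.stimulus`).
2. **Periphery** — integrate-and-fire models of RA and PC afferents
   driven by rectified position/velocity/acceleration features, plus
   population rates, the van Rossum spike distance and an afferent
   fitting routine (`tactilenp.periphery`).
3. **Cortex** — a linear-nonlinear-Poisson (LNP) model of single S1
   neurons: per 1-ms bin,

       p(s_t) = r( k_RA · s_RA,t + k_PC · s_PC,t ),

   with 100-ms filters `k_RA`, `k_PC` over the z-scored population
   rates and a piecewise-linear rectifier `r(x) = b1` for `x < 0`,
   `min(b1 + b2·x, 1)` otherwise.  Filters are estimated by
   reverse correlation with a ridge correction,
   `k = (SᵀS + aI)⁻¹ Sᵀ s_C`, and each neuron's input class (RA, PC,
   both, or none) is decided by a bootstrap-calibrated test
   (`tactilenp.cortex_lnp`).
4. **Metrics** — filter magnitude, width and excitation/suppression
   index, explained variance at 3/5/13/66-ms resolutions, predictable
   variance across repeats, and vector strength
   (`tactilenp.metrics`).
5. **Efficient coding** — filters optimized to maximize the mutual
   information `I(S, V) = Σ p(s,v) log2 p(s,v)/(p(s)p(v))` between LNP
   spiking and texture-vibration amplitude under a firing-rate
   constraint, with an analytic gradient (`tactilenp.infomax`).
6. **Synthetic ground truth** — generator for LNP neuron populations
   with known filters and a 243-neuron filter-recovery validation
   experiment, since the original recordings are not public
   (`tactilenp.synthetic_data`).

See `docs/methods.md` for the models, assumptions and numerical
choices in detail.

## Worked example

Generate a small ground-truth population, simulate its spiking
responses to frozen bandpass noise through the afferent models,
re-estimate every neuron's filters, and classify each neuron's input
(the 2-minute "fast" profile; the full profile uses 16 minutes of
noise per neuron):

```python
from tactilenp.synthetic_data import ValidationConfig, validation_experiment

config = ValidationConfig.fast(n_neurons=12)   # 2 minutes of noise per neuron
report = validation_experiment(config, seed=0)
print(f"dual-input neurons detected:  {report['pct_both_detected']:.1f}%")
print(f"single-input called dual:     {report['pct_single_as_both']:.1f}%")
print(f"filter shape recovery (r):    {report['mean_neuron_filter_correlation']:.3f}")
print(report["table"][["true_class", "label", "target_rate_hz", "p_ra", "p_pc"]]
      .to_string(index=False))
```

prints

```
dual-input neurons detected:  50.0%
single-input called dual:     0.0%
filter shape recovery (r):    0.873
true_class   label  target_rate_hz     p_ra     p_pc
   RA_only RA_only       25.622572 0.006623 0.894040
   PC_only PC_only       44.174703 0.549669 0.006623
   RA_only RA_only       11.318695 0.006623 0.536424
   PC_only PC_only      100.000000 0.304636 0.006623
   PC_only PC_only       76.159581 0.894040 0.006623
   RA_only RA_only       14.861814 0.006623 0.410596
      both    both       33.643269 0.006623 0.006623
   PC_only PC_only        8.620271 0.801325 0.006623
      both    both       58.002818 0.006623 0.006623
      both RA_only        5.000000 0.006623 0.125828
      both RA_only        6.565162 0.006623 0.735099
   PC_only PC_only       19.514044 0.390728 0.006623
```

Reading the output: every single-input neuron is labelled with its
true class (`p` is the bootstrap p-value of each input channel's
contribution; 0.0066 is the resolution floor of 150 bootstrap draws).
The dual-input neurons firing at 34 and 58 spikes/s are detected, while
at this short 2-minute profile the 5–6.6 spikes/s dual-input neurons
are missed — their weak PC drive (a third of the RA magnitude) needs
the full 16-minute sessions, under which detection reaches the
90%-plus range with essentially no false dual-input calls.

A thin CLI wraps the same entry points, e.g.:

```
tactilenp stim make --kind noise --rms 20 --out noise.txt
tactilenp synth validate --fast --n-neurons 12 --seed 0 --out report.json
tactilenp infomax run --n-textures 3 --seed 1 --out opt
```

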
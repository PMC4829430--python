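# ebcap

Quantitative analysis of microtubule **tubulin-washout experiments**: how
long does a microtubule survive after its supply of tubulin is suddenly cut
off, and what does that delay say about the protective cap at its growing
end?

Growing microtubule plus-ends carry a stabilising cap of GTP/GDP-Pi tubulin
that EB-family proteins (EB1, Mal3) bind; the EB-decorated region therefore
reports the cap's size in fluorescence time-lapse data. When soluble
tubulin is washed out, growth stops and the cap decays by two first-order
processes — conformational maturation of binding sites everywhere in the
cap (rate `k_m`) and slow shrinkage of the end (speed `v_s`) — until a
kinetic threshold is crossed and catastrophe (fast depolymerisation) sets
in. `ebcap` implements this analysis end to end:

- **cap_models** — closed-form cap kinetics. The cap (lattice-subtracted EB
  intensity) decays at `k_cap = k_m (v_s / v_g + 1)`; the delay between
  washout and catastrophe follows from a threshold on the terminal site
  *density* (`T = -ln(f_crit) / k_cap`), the *total* site number, or the
  number of sites within a window `L` of the end, each with a two-step
  maturation variant (extra fast step `k_1`).
- **trace_analysis** — per-track extraction: washout time from an
  error-function fit to the background drop, growth speed `v_g` by OLS over
  the 10 s before washout, catastrophe from an erf-smoothed speed-transition
  fit with a 25% criterion (`t_cat = t0 - 2 sigma erfinv(0.5)`), shrinkage
  and intensity metrics, and catastrophe-aligned cohort averaging.
- **comet_analysis** — averaged EB comet profiles fitted with the
  exponential-convolved-Gaussian closed form; comet length `L_comet` gives
  the maturation rate `k_m = v_g / L_comet`.
- **model_fitting** — speed-sorted, sem-weighted threshold-model fits and
  the global window-`L` fit with reduced-chi-square model comparison.
- **cohort_stats** — Spearman correlations of delay with momentary speed /
  cap size, their decay for measurement windows shifted away from washout
  (the seconds-scale "memory" of stability), and the relative variance `D`.
- **synthetic** — a seeded generator of washout cohorts with ground truth,
  so every stage is testable by parameter recovery.
- **io / pipeline / cli** — plain-CSV track tables, a one-call pipeline,
  and an `ebcap` command line (`simulate`, `analyze`, `comet`, `fit`,
  `correlate`, `report`).

## Worked example

```python
from ebcap import KineticParams, cap_decay_rate, delay_from_intensity_ratio
from ebcap.synthetic import SyntheticConfig, generate_cohort
from ebcap.trace_analysis import analyze_cohort
from ebcap.model_fitting import speed_sort, vs_vg_relation, fit_threshold

# closed-form prediction from measured kinetic parameters
p = KineticParams(v_g=33.0, v_s=40.0, k_m=0.16)
k = cap_decay_rate(p)
print(f"cap decay rate k_cap = {k:.3f} 1/s")
print(f"predicted delay at 29% cap remaining = {delay_from_intensity_ratio(1.0, 0.29, k):.2f} s")

# parameter recovery on a synthetic 210-track cohort (end-density model)
cfg = SyntheticConfig(n_tracks=210, vg_dist="uniform", vg_lo=20, vg_hi=80,
                      f_crit=0.20, cap_scale_sd=0.3, seed=1)
tracks, truth = generate_cohort(cfg)
res = analyze_cohort(tracks)
a, b = vs_vg_relation(res.frame)
groups = speed_sort(res.frame, 7)
for model in ("end_density", "total_number"):
    fit = fit_threshold(groups, 0.16, (a, b), model=model)
    name, val = next(iter(fit.params.items()))
    print(f"{model}: {name} = {val:.3f}, reduced chi2 = {fit.chi2_red:.2f}")
```

prints

```
cap decay rate k_cap = 0.354 1/s
predicted delay at 29% cap remaining = 3.50 s
end_density: f_crit = 0.183, reduced chi2 = 3.27
total_number: N_crit = 88.453, reduced chi2 = 66.75
```

The decay rate 0.354 1/s is the theoretical cap-loss rate for a microtubule
growing at 33 nm/s that shrinks at 40 nm/s after washout while maturing at
0.16 1/s; with 29% of the cap left at catastrophe it predicts a 3.5 s mean
delay. On the synthetic cohort the end-density threshold generating the
data (0.20) is recovered at 0.183 (the slow-shrinkage speed measured
between washout and catastrophe is slightly inflated by the smoothed
transition, see `docs/methods.md`), and the end-density model fits far
better than the total-number alternative — the model-discrimination
signature the speed-sorted fit is designed to expose.

The same sequence from a shell:

```sh
ebcap simulate --n-tracks 210 --seed 1 --out cohort/
ebcap analyze cohort/ --out metrics.csv
ebcap fit metrics.csv --k-m 0.16 --n-groups 7
```

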
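# noddisim

Simulation study of NODDI model fitting on multi-shell HYDI diffusion
MRI acquisition schemes.

## The problem

Hybrid diffusion imaging (HYDI) acquires diffusion MRI on several
b-value shells (here b = 375–9375 s/mm², 126 measurements) so that one
dataset supports many analysis methods. NODDI (neurite orientation
dispersion and density imaging) models each voxel with three
compartments — Watson-dispersed intracellular "sticks", a
tortuosity-linked hindered extracellular tensor, and isotropic free
water — and was proposed with its own two-shell acquisition. The
question this package answers by simulation: **do HYDI shell
combinations support NODDI fitting as well as the purpose-built
two-shell scheme?**

For a measurement with b-value b and unit gradient g the signal is

    E = (1 − f_iso)·[f_ic·E_ic + (1 − f_ic)·E_ec] + f_iso·e^(−b·d_iso)

    E_ic = ∫ W(n; μ, κ) e^(−b·d∥ (g·n)²) dn          (dispersed sticks)
    E_ec = e^(−b·gᵀ⟨D⟩g),  d⊥ = d∥(1 − f_ic)          (tortuosity tensor)

with Watson orientation distribution W(n; μ, κ) ∝ exp(κ(μ·n)²),
dispersion index ODI = (2/π)·arctan(1/κ), and fixed diffusivities
d∥ = 1.7×10⁻³, d_iso = 3.0×10⁻³ mm²/s. The pipeline synthesizes these
signals on any scheme, adds Rician magnitude noise at a b0-referenced
SNR, estimates (ICVF = f_ic, ODI, FISO = f_iso, μ) by grid-initialized
nonlinear optimization (Gaussian least squares or Rician maximum
likelihood), and compares protocols with paired tests. See
`docs/methods.md` for the numerics and design choices.

Audience: diffusion-MRI methods researchers designing or validating
multi-shell acquisition schemes for compartment modelling.

## Worked example

```python
from noddisim import (build_protocol, TissueParams, synthesize_signal,
                      add_rician_noise, NoiseSpec, fit_noddi, FitOptions)

scheme = build_protocol("p12345", seed=7)        # full 5-shell HYDI
truth = TissueParams(f_ic=0.7, kappa=4.0, f_iso=0.1, mu=(0.0, 0.0, 1.0))
clean = synthesize_signal(truth, scheme)
noisy = add_rician_noise(clean, NoiseSpec(snr_b0=30, seed=7))
fit = fit_noddi(noisy, FitOptions(objective="rician-likelihood",
                                  sigma=1/30, seed=0))
print(f"truth:    ICVF=0.700  ODI={truth.odi:.3f}  FISO=0.100")
print(f"estimate: ICVF={fit.params.f_ic:.3f}  ODI={fit.odi:.3f}  "
      f"FISO={fit.params.f_iso:.3f}")
```

prints

```
truth:    ICVF=0.700  ODI=0.156  FISO=0.100
estimate: ICVF=0.736  ODI=0.150  FISO=0.159
```

— a single noisy voxel at SNR_b0 = 30: the estimates scatter around the
truth (here +0.04 in ICVF, +0.06 in FISO); averaged over orientations
and trials they converge to it, and on noise-free input the fit
recovers the truth to ~10⁻⁹.

The scheme-comparison experiment (a few minutes; 4,000 fits):

```python
from noddisim import desk_preset, run_experiment, compare_schemes

table = run_experiment(desk_preset(master_seed=1))
for metric in ("odi_est", "icvf_est"):
    res = compare_schemes(table, "NODDI-p14", "p12345", metric, snr=20.0)
    print(metric, round(res["p_value"], 4), round(res["mean_difference"], 5))
```

prints

```
odi_est 0.8129 -0.00043
icvf_est 0.0072 -0.00347
```

ODI estimates from the two-shell reference scheme and the full 5-shell
HYDI scheme are statistically indistinguishable. For ICVF the paired
test *does* detect a difference — but its size is 0.003 (≈0.6% of the
true value, a tenth of the single-fit scatter): with 1,000 matched
pairs the test resolves a scheme-dependent estimator bias that is far
too small to matter in practice. See `docs/methods.md` for where that
bias comes from.

A CLI mirrors the library: `noddisim scheme`, `noddisim snr-report`,
`noddisim fit`, `noddisim experiment`, `noddisim report`,
`noddisim validate` (brute-force oracle audits). See `--help`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the study's headline numbers from scratch by running the
package: the pooled per-direction SNR on the outermost (b=9375) shell at
SNR_b0 = 20 and 50, the noise-free ICVF/FISO recovery on the full HYDI
protocol at the extreme ICVF grid levels, and the paired-test p-value
comparing NODDI-p14 against p12345 ICVF estimates on the scaled-down
noisy run. Takes a few minutes on one CPU; all randomness derives from
`--seed`.
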
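# sceit — multi-frequency time-difference EIT with spectral constraints

Electrical impedance tomography (EIT) images the conductivity inside a body
from currents injected and voltages measured at surface electrodes.
Time-difference EIT (tdEIT) reconstructs the *change* in conductivity
between a background and a foreground frame, which cancels much of the
modeling error and is what clinical EIT systems run in practice.  Classical
tdEIT uses data at a single frequency; measurements taken at several
frequencies cannot simply be appended, because the unknown conductivities
(and hence the unknowns of the linearized problem) change with frequency.

This package implements a tdEIT algorithm that makes multi-frequency data
usable in a single linear reconstruction by re-parameterizing each mesh
element as a convex combination of a few known tissues.  With tissue
conductivity spectra `σ_ij = ε^{t_j}(ω_i)` the element conductivities are

    σ_n(ω_i) = Σ_j f_nj σ_ij ,   0 ≤ f_nj ≤ 1,  Σ_j f_nj = 1,

and the volume fractions `f_nj` are frequency independent.  Writing the
linearized forward map at frequency `ω_i` as `J(ω_i) Δσ(ω_i) = Δυ(ω_i)` and
the fraction-to-conductivity map as a sparse coefficient matrix
`A(ω_i) F = σ(ω_i)`, the per-frequency systems stack into one system for
the fraction change ΔF:

    S ΔF = Δυ,   S = [J(ω_1)A(ω_1); … ; J(ω_M)A(ω_M)].

The unit-sum constraint is folded in by eliminating the background tissue
(`f_n1 = 1 − Σ_{j≥2} f_nj`), the damped solution
`ΔF = (S′ᵀS′ + λ diag(S′ᵀS′))⁻¹ S′ᵀ Δυ` is clamped element-wise to the
feasible fraction set, and up to two linear Gauss–Newton steps are run
(re-linearizing the Jacobians at the updated background, which raises the
rank of the stacked system).  The single-frequency damped-least-squares
baseline (DLS, `R = diag(JᵀJ)`) is provided for comparison, along with:

* a deterministic ring-structured triangular disk mesher that reproduces
  exact element/node counts (800/441 forward, 512/289 inverse),
* a first-order FEM forward solver and adjoint (compensation-theorem)
  Jacobian for the 16-electrode opposite-drive / adjacent-measurement
  protocol (192 measurements per frequency),
* L-curve and conditioning-based selection of the damping weight λ,
* SVD rank / effective-condition-number diagnostics of the stacked system,
* image scoring: region of perturbation (RP), position error (PE), shape
  deformation (SD), image noise (IN = inverse CNR), total error
  (TE = PE + SD + IN),
* scenario drivers for the five-target two-SNR validation study, the
  spectral-error robustness study, and a three-tissue (ischemia + blood)
  variant with per-tissue image extraction.

## Worked example

```python
import numpy as np
from sceit import *

spectra = brain_spectra()                  # normal vs ischemic tissue, 3 freqs
print(mean_relative_contrast(spectra))     # 24.045  (% contrast between tissues)

protocol = opposite_adjacent_protocol()    # 16 electrodes, 192 measurements
scene = make_two_tissue_scene(2, snr_db=60.0)        # target 120 px off-center
inverse_mesh = build_circular_mesh(300, 16, 512)     # 512 elements, 289 nodes

clean_bg, clean_fg = simulate_clean_frames(scene, protocol)   # 800-elem mesh
v_bg, v_fg = simulate_noisy_frames(clean_bg, clean_fg, 60.0, (0, 2, 600, 0))

sc = sc_reconstruct(v_bg, v_fg, spectra, inverse_mesh, protocol,
                    num_steps=2, lam=0.016)
dls = dls_reconstruct(v_fg[1] - v_bg[1], inverse_mesh, protocol,
                      sigma_background=0.155, num_steps=2, lam=0.0173)

for name, res in (("SC", sc), ("DLS", dls)):
    img = res.delta_sigma[1] if res.delta_sigma.ndim == 2 else res.delta_sigma
    m = compute_metrics(img, inverse_mesh, scene.target)
    print(name, round(m.pe, 4), round(m.sd, 4), round(m.in_, 4), round(m.te, 4),
          [d.rank for d in res.diagnostics])
```

prints

```
24.045330159408344
SC 0.0008 0.0997 0.1648 0.2653 [76, 228]
DLS 0.0111 0.1257 0.2416 0.3784 [76, 76]
```

Reading: both one-step systems have numerical rank 76; the second spectral-
constraints step re-linearizes at an inhomogeneous background and the
stacked rank jumps to 228, while DLS stays at 76.  The SC image has lower
position error, tighter shape, and markedly lower image noise (inverse
contrast-to-noise), so its total error is ~30% smaller on this scene.

The same pipeline is scriptable from the shell:

```bash
sceit simulate    --config cfg.yaml --out run/
sceit reconstruct --config cfg.yaml --frames run/ --algorithm sc --out run/sc.h5
sceit evaluate    --result run/sc.h5 --scene run/scene.h5 --out run/metrics.csv
sceit reproduce-study --out study/
```

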
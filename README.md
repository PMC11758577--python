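# nanoscint

Nanoscale X-ray energy-deposition Monte Carlo and radioluminescence (RL)
spectral decomposition for porphyrin-functionalized SiO₂/ZnO hybrid
nanoscintillators.

## The problem

Hybrid nanoscintillators for X-ray-activated photodynamic therapy couple a
dense inorganic scintillator (here ZnO nanoparticles on a Stöber silica
support) to an organic photosensitizer (the porphyrin TCPP). Whether the
photosensitizer lights up under keV X-rays depends on **where the beam's
energy is deposited** at the nanometre scale. This package provides the two
computational stages of that analysis:

1. **Transport + scoring** — a Monte Carlo simulator of photon–electron
   transport through two assemblies:
   * *code A*: one 80 nm SiO₂ sphere decorated with up to 215 ZnO
     nanoparticles (5 nm diameter) in air;
   * *code B*: many ZnO-shelled SiO₂ spheres (0.69 nm equal-volume shell)
     packed in an air-filled micro-cylinder (8.5 µm × 1 µm), the downscaled
     powder sample holder.

   Monochromatic parallel beams at 3.3 / 6.6 / 10 keV are transported with
   photoelectric absorption (K-shell resolved, fluorescence vs.
   non-radiative relaxation), Klein–Nishina Compton scattering, Thomson
   Rayleigh scattering, and condensed-history electron transport with 1 nm
   steps down to a 250 eV cutoff. The scored observables are the
   **per-medium energy partition** E_dep(SiO₂)/E_dep(ZnO)/E_dep(air) and
   **radial deposition profiles** E_dep(r) conditioned on the medium of the
   first photon interaction. A forced-first-interaction variance-reduction
   mode makes nanoparticle-scale targets tractable: the primary's first
   interaction is sampled conditionally on hitting a solid, and the history
   carries the interaction probability
   w = 1 − exp(−Σᵢ μᵢ lᵢ) of its ray as statistical weight.

2. **RL spectral decomposition** — a Levenberg–Marquardt fitter that
   decomposes RL spectra into positive Gaussian emission components (ZnO
   defect band ~2.22 eV, excitonic band ~3.09 eV, porphyrin red bands
   1.5–2 eV) **plus four negative-area Gaussians** at the porphyrin Q-band
   energies (2.01, 2.2, 2.34, 2.5 eV) that describe re-absorption of the
   ZnO luminescence by the dye. Components are area-parameterized
   Gaussians, A/(σ√2π)·exp(−(E−c)²/2σ²), with sign constraints enforced by
   a signed-log parameterization and box bounds by smooth sigmoid
   transforms.

A small Beer–Lambert utility (c = A/(ε·d), ε₅₂₀ = 8900 M⁻¹cm⁻¹, d = 0.1 cm)
quantifies the dye loading, and a synthetic-data module generates every
fixture the pipeline needs (toy cross-section tables, benchmark geometry
grids, RL spectra with known ground truth).

## Worked example

```python
from nanoscint.geometry import AssemblyConfig, build_code_a
from nanoscint.transport import BeamConfig, RunConfig, Simulator
from nanoscint.scoring import partition_from_run

model = build_code_a(AssemblyConfig(code="A", n_zno=215, seed=1))
sim = Simulator(model)
run = RunConfig(seed=7, mode="forced")
for energy in (3.3, 6.6, 10.0):
    res = sim.run(BeamConfig(energy=energy, n_histories=30_000), run)
    t = partition_from_run(res)
    print(energy, {m: round(f, 1) for m, f in t.fraction_pct.items()})
```

prints

```
3.3 {'SiO2': 91.8, 'ZnO': 7.5, 'air': 0.7}
6.6 {'SiO2': 90.2, 'ZnO': 9.3, 'air': 0.5}
10.0 {'SiO2': 20.8, 'ZnO': 78.4, 'air': 0.8}
```

i.e. below the Zn K edge (9.66 keV) the silica support receives most of the
deposited energy, while a 10 keV beam — just above the edge — deposits
roughly three quarters of the energy in the ZnO nanoparticles despite their
~20× smaller volume. That is the microscopic rationale for the porphyrin
sensitization observed at the highest tube voltage.

The same pipeline is scriptable from the shell:

```bash
nanoscint simulate run.yaml --out out/        # partition + profiles + manifest
nanoscint fit-spectrum spectrum.txt --variant functionalized --out fit/
nanoscint synth --out fixtures/               # synthetic spectra + truth
nanoscint quantify absorbances.csv conc.csv   # Beer-Lambert
```

Every output directory receives a `manifest.json` (config snapshot, master
seed, output hashes) sufficient for bit-identical replay.

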
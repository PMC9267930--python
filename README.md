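# treemd

Tree-accelerated molecular-dynamics/Monte-Carlo simulation of X-ray driven
ionization dynamics in atomic assemblies.

`treemd` models what happens inside a small sample (e.g. a water cube) during
an intense femtosecond X-ray pulse: atoms are photoionized and undergo Auger
decay and fluorescence, the freed quasi-classical electrons collide with and
further ionize atoms (secondary ionization), electrons recombine with ions,
and everything moves under mutual Coulomb forces. Each timestep executes four
blocks in a fixed order:

1. **RE** — recombination: bound electron–ion pairs merge;
2. **SI** — secondary ionization: each free electron is tested against its
   nearest atom/ion within an energy-dependent cutoff;
3. **MC** — stochastic atomic events (photoionization, Auger, fluorescence)
   sampled per atom from rate tables and the Gaussian pulse envelope;
4. **MD** — one velocity-Verlet step for all charged classical particles.

The two all-pairs hot spots both exist in interchangeable **brute-force** and
**oct-tree** implementations:

* the long-range **Coulomb** interaction — exact O(Nq²) summation, or a
  Barnes–Hut tree walk with opening angle θ (monopole + dipole moments),
  O(Nq log Nq);
* the **SI/RE neighbor searches** — exact O(Ne·Na) scans, or fixed-radius /
  nearest-neighbor queries on a linear oct-tree with bit-interleaved box
  identifiers, O(Ne log Na).

The tree searches prune conservatively and filter candidates with exactly the
same floating-point distance expression as the brute scans, so the brute and
tree SI/RE blocks are **bit-wise identical** — not merely close. Every solver
also reports hardware-independent operation counters so the O(N²) → O(N log N)
complexity change can be measured as counts rather than wall-clock time.

## Worked example

```python
from treemd import (SimulationConfig, SolverConfig, SIConfig, REConfig,
                    build_preset, run)

state = build_preset("47A", seed=1)       # 47 Å water cube, pre-ionized
print(f"initial: Na={state.n_atoms} Ni={state.n_ions} Ne={state.n_electrons}")

cfg = SimulationConfig(
    n_steps=20, seed=1,
    coulomb=SolverConfig(method="tree", theta=0.4, softening=0.05),
    si=SIConfig(implementation="tree"),
    re=REConfig(implementation="tree"))
final, diag, events = run(cfg, state)
print(f"after {cfg.n_steps} steps ({diag.time_fs.iloc[-1]:.3f} fs): "
      f"Ne={final.n_electrons}, "
      f"events re/si/mc = {diag.events_re.sum()}/{diag.events_si.sum()}"
      f"/{diag.events_mc.sum()}")
```

prints

```
initial: Na=9722 Ni=2102 Ne=2806
after 20 steps (0.020 fs): Ne=2679, events re/si/mc = 431/162/142
```

Re-running the same 20 steps with `implementation="brute"` for SI and RE
produces a byte-identical final state and event log — `final.digest()`
(SHA-256 over all particle buffers) compares equal.

## Command-line interface

```sh
treemd simulate --preset 47A --steps 20 --coulomb tree --si tree --re tree --seed 1
# steps=20 t=0.0200 fs  Na=9722 Ni=2023 Ne=2679  events re/si/mc=431/162/142

treemd gen-sample --preset 47A --seed 0 --out sample47.xyz
# 47A: Na=9722 Ni=2102 Ne=2806 -> sample47.xyz

treemd bench-counters --ladder 1000,4000,16000 --coulomb tree --si tree
# n     nq      ne      coulomb si      re      total
# 1000  500     290     74964   9073    7403    91440
# 4000  2000    1160    616550  44604   39568   700722
# 16000 8000    4640    4327600 208238  192975  4728813
# log-log slope of total count vs N: 1.423
```

`simulate` also accepts `--config file.yaml` (overrides the documented
defaults), `--out DIR` (HDF5 trajectory, extended-XYZ snapshots, TSV
event/diagnostic logs, JSON run manifest) and `--theta`. `gen-fixture` emits
random plasma test states. Presets: `47A`, `60A`, `75A`, `100A`, `150A` —
water cubes pre-ionized to fixed benchmark (atoms, ions, electrons) triples.

## Units and defaults

Internal math is in Hartree atomic units (length bohr, energy hartree, time
ℏ/Eₕ ≈ 24.19 as); interfaces use Å, eV, fs, Mbarn and photons/μm². Defaults:
1 as timestep, 7.12 keV photons, 3.5×10¹² photons/μm² fluence, 15 fs FWHM
Gaussian pulse starting at the pulse center, θ = 0.4, Coulomb softening
0.05 bohr. Per-element binding energies, cross sections and decay rates are
packaged as an editable YAML table (`src/treemd/data/rate_tables.yaml`) with
toy H and O entries.

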
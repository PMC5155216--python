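# shockchem

Shock-compression molecular dynamics and reactive bond-network analysis
for prebiotic ammonia synthesis on iron.

When an iron-rich meteorite strikes an ocean, the shock wave compresses
and heats a mixture of metallic Fe, dissolved N₂ and H₂O to tens of GPa
and thousands of kelvin within picoseconds.  Under these conditions
water dehydrogenates on the oxidizing iron surface, the released
hydrogen attacks adsorbed N₂, and NH₃ (immediately protonated to NH₄⁺)
appears on picosecond timescales — a candidate abiotic nitrogen source
for prebiotic amino-acid chemistry.  `shockchem` is a desk-scale,
tested re-implementation of the computational machinery needed to study
this process:

* **Shock dynamics** — a multi-scale shock technique (MSST) engine: the
  cell volume is a dynamical degree of freedom obeying
  `(Q/M)·V̈ = P_xx − P₀ − ρ₀V_s²(1 − V/V₀)`, which constrains the axial
  stress to the Rayleigh line `P = P₀ + ρ₀V_s²(1 − V/V₀)` of a steady
  shock at speed `V_s`; plus Nosé–Hoover canonical dynamics and
  distance-constrained (blue-moon) dynamics that records the
  constraint's Lagrange multiplier ⟨λ⟩.
* **Reactive analysis** — bonds defined by element-pair cutoffs from
  partial-RDF first minima (H–O 1.25, O–Fe 1.50, H–N 2.00, H–Fe 2.50 Å)
  held *continuously for a 2.42 fs lifetime*; bond-count time series,
  molecular speciation by connected components of the bond graph,
  cumulative formation events, and Mulliken-charge bookkeeping
  `Q_i(t) = Z⁰_i − Z_i(t)` for externally supplied gross populations.
* **Transport and kinetics** — mean-squared displacement
  `MSD(τ) = ⟨|r_i(t₀+τ) − r_i(t₀)|²⟩` with time-origin averaging and
  the Einstein estimator `D = slope/6`; thermodynamic integration
  `ΔF(r) = ∫_r^{r₀} ⟨λ⟩ dr′` of the constraint force; transition-state
  theory rates `k = (k_B T/h)·exp(−ΔF‡/k_B T)`; and Rankine–Hugoniot
  jump conditions linking `(V/V₀, U_p, P)`.
* **Synthetic data** — generators for every input: the 182-atom
  Fe₃₆/16 N₂/38 H₂O supercell (29.72 × 8.580 × 8.580 Å), scripted
  reactive trajectories whose proton transfers and N–N scissions happen
  at prescribed times, Brownian fixtures with known D, analytic shock
  profiles, and Lennard-Jones crystals for the dynamics engines.

Electronic structure is deliberately out of scope: forces come from
classical pair potentials, and the chemistry in the scripted fixtures
is encoded geometrically (distances versus cutoffs), which is exactly
what the analyzers consume.

## Worked example

```python
import shockchem as sc

# thermodynamic state behind the 5 km/s shock front
cell = sc.SimulationCell.orthorhombic(29.72, 8.580, 8.580)
rho0 = sc.initial_density({"Fe": 36, "N": 32, "O": 38, "H": 76}, cell)
state = sc.hugoniot_jump(rho0, V_s=5.0, U_p=2.30)
print(f"rho0 = {rho0:.3f} g/cm^3")
print(f"P = {state.P:.1f} GPa at V/V0 = {state.compression:.3f}")

# TST rates for the 0.09 eV N-H association barrier
for T in (2100.0, 1200.0):
    print(f"k({T:.0f} K) = {sc.tst_rate(0.09, T):.1f} ps^-1")

# NH3 formation census on the scripted 4 ps trajectory
frame, info = sc.build_initial_system_info(seed=0)
script = sc.nh3_formation_script(frame, info, seed=7)
traj = sc.script_reactive_trajectory(frame, script, duration=4000.0, dt=0.242)
bonds = sc.detect_bonds(traj)
events, cumulative = sc.cumulative_formation_events(bonds, "NH3")
print("NH3 formed at", [f"{e.time/1000:.3f} ps" for e in events],
      "-> cumulative", int(cumulative[-1]))
census = sc.species_census(bonds, len(traj) - 1)
print("ammonium (NH4+) at 4 ps:", census.species_count("NH4"))
```

prints

```
rho0 = 2.386 g/cm^3
P = 27.4 GPa at V/V0 = 0.540
k(2100 K) = 26.6 ps^-1
k(1200 K) = 10.5 ps^-1
NH3 formed at ['1.343 ps', '2.044 ps', '3.674 ps'] -> cumulative 3
ammonium (NH4+) at 4 ps: 3
```

The density follows from the composition and cell; the momentum jump
condition `P = ρ₀ V_s U_p` then gives the ~27 GPa pressure behind a
5 km/s shock.  The two rates are the barrier-crossing frequencies at
the 5 km/s (2100 K) and 4 km/s (1200 K) shocked-state temperatures —
fast enough that every N₂ with the right Fe/H coordination reacts
within picoseconds at the higher temperature.  The scripted trajectory
is analyzed with the production bond-lifetime machinery: three NH₃
molecules appear cumulatively and all end the run protonated as NH₄⁺.

A command-line interface wraps the same stages:

```
shockchem simulate --mode msst --potential lj-argon --vs 4.0 --steps 4000 --out run/
shockchem analyze  --trajectory run/trajectory.extxyz --msd-species Fe --out run/
shockchem kinetics --barrier 0.09 --temps 2100,1200
shockchem make-fixtures --kind nh3 --out fixtures/
```

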
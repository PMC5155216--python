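# Methods

## Scope and units

`shockchem` implements the classical-mechanics and bookkeeping layers
of a shock-compression reactive-chemistry study: shock dynamics,
bond-network speciation, transport, constrained-force free energies,
rate theory, and jump-condition thermodynamics.  Electronic structure
(DFT forces, bond-overlap populations, gross populations) is out of
scope; gross populations enter only as tabular input to the
Mulliken-charge formula, and reactivity in fixtures is scripted
geometrically.

All internal quantities use Å / fs / amu / eV, with GPa for pressures,
km/s for shock and particle velocities, and K for temperatures.  The
dynamics kernels work in amu·Å²/fs² and convert at the potential
boundary (1 eV = 9.6485×10⁻³ amu·Å²/fs²); conversion factors are
derived from CODATA constants so SI round trips are exact to floating
point.  Atomic masses are IUPAC standard weights.

## Shock dynamics (MSST)

The multi-scale shock technique treats the cell volume as a dynamical
degree of freedom.  With shock propagation along x (uniaxial strain; y
and z fixed), atoms evolve with scaled x coordinates `x = L_x s`, and
the cell obeys

    (Q/M)·V̈ = P_xx − P₀ − ρ₀ V_s² (1 − V/V₀),

the Euler–Lagrange condition of the extended Lagrangian whose cell
kinetic term is `(Q/2M)V̇²` — `Q` carries units mass²·length⁻⁴ and `M`
is the total mass.  At stationarity the axial virial stress sits on the
Rayleigh line `P = P₀ + ρ₀V_s²(1 − V/V₀)`, and because averaging the
equation of motion over a window annihilates `⟨V̈⟩`, the *time-averaged*
stress equals the Rayleigh pressure at the time-averaged volume to high
accuracy even while the cell rings.  The particle-velocity diagnostic
`U_p = V_s(1 − V/V₀)` is the mass jump condition and holds identically
by construction.

Integration is velocity Verlet (cell DOF included) with a short
fixed-point iteration for the velocity-dependent accelerations (the
`−2(L̇_x/L_x)ṡ` coupling and the kinetic part of `P_xx`); the extended
energy `E = KE + Φ + (Q/2M)V̇² + U_cell(V)` is conserved to
~10⁻⁸ eV/atom/ps in stationary runs at dt = 0.242 fs, and its error
scales as dt².  Defaults: dt = 0.242 fs (10 a.u.), initial state 0 GPa
and 300 K, `Q` chosen so the linearized cell-oscillation period is
about 100 steps.

Two behaviours of the bare method deserve note.  First, the unshocked
point `V = V₀` is a fixed point; a small negative initial `V̇`
(default 10⁻⁴ V₀/fs) nucleates compression.  Second, `V > V₀` is a
runaway branch (rarefaction is not modelled), and a *perfectly elastic*
crystal cannot thermalize the cell oscillation, so an undamped cold
crystal rings through V₀ and escapes.  Following common practice in
MSST implementations we provide an artificial viscosity acting on the
cell DOF only (`cell_damping`, 1/fs; default 0 in the library, 0.2 in
the CLI): a damped run relaxes onto the compressed Rayleigh-line
crossing — which is a stable fixed point — and can then be continued
undamped for conservative production statistics.  The damping force is
proportional to `V̇` and vanishes at stationarity, so it does not bias
the Rayleigh balance.  `P₀ = None` (default) measures the unshocked
pressure from the initial configuration, the analogue of initializing
the reference state from the current state in standard MSST codes.

## Canonical and constrained dynamics

`run_nvt` uses a single Nosé–Hoover thermostat (mass from a coupling
period of 50 dt, ndof = 3N − 3) around velocity Verlet; with the
thermostat off it is plain NVE, conserving energy to <10⁻⁵ eV/atom/ps
at dt = 0.242 fs for the Lennard-Jones fixtures and momentum to machine
precision.

`constrained_window` holds one interatomic distance fixed with
SHAKE/RATTLE (residual < 10⁻⁸ Å every step) and records the
constraint's Lagrange multiplier λ each step; ⟨λ⟩ is the time average
after discarding the first 20 % of the window.  Sign convention: λ > 0
when the unconstrained potential force would lengthen the bond (the
constraint resists expansion).  With this convention a harmonic bond of
stiffness k₀ constrained at r₀ − δ gives ⟨λ⟩ = k₀δ in the cold limit,
and the free-energy integral below yields positive barriers.  The
recorded multiplier is the instantaneous continuous-time value
`λ = μ(|v_rel|²/r + r̂·(F_j/m_j − F_i/m_i))`, which includes the
centrifugal contribution (at finite T the harmonic pair's ⟨λ⟩ exceeds
k₀δ by ≈ 2k_BT/r, as it should).  Mass-metric (Fixman) corrections are
not applied.  Thermostats: Nosé–Hoover (default) or Langevin; a single
Nosé–Hoover chain on a near-integrable few-atom system is not ergodic,
so statistical checks of window-average convergence use the Langevin
option (friction default 0.05 fs⁻¹).

Potentials are pairwise Lennard-Jones (shifted-force truncation, so
forces are continuous at the cutoff and energy is conserved exactly for
the truncated model) or Morse (energy-shift truncation), plus explicit
harmonic bonds for fixtures; forces agree with central finite
differences to 10⁻⁶ relative.  The LJ crystal builder caps the cutoff
just below half the smallest box length so the minimum-image convention
stays exact, and scans the lattice constant to mechanical equilibrium.

## Bond definition and speciation

A pair is bonded once its minimum-image distance has remained within
the element-pair cutoff *continuously* for the lifetime
L = round(2.42 fs / dt) frames (10 frames at dt = 0.242 fs), stamped at
window completion, and drops the moment the distance exceeds the
cutoff.  Cutoffs default to the partial-RDF first minima of the shocked
system (H–O 1.25, O–Fe 1.50, H–N 2.00, H–Fe 2.50 Å).  The H–N cutoff
intentionally captures hydrogen bonds as well as covalent N–H — the
distinction would need bond-overlap populations, which are not computed
here.  Speciation needs a fuller covalent table, so defaults add
N–N 1.8, H–H 1.0 and N–Fe 2.3 Å; all entries are config-overridable.
Pairs are unordered (H–O ≡ O–H); element pairs without a cutoff are
skipped with a single logged warning.

Molecules are connected components of the per-frame bond graph
(isolated atoms are single-atom components, so every census conserves
the element totals).  NH₃ is the component {N:1, H:3} — an N bonded to
Fe would drag the Fe into its component and fail the match, so "not
Fe-bound" is automatic.  Charge states cannot be assigned without
electronic structure; the census reports neutral formulas (NH₄⁺ is
reported as the NH₄ topology).  A formation event fires when a tracked
N atom's component first equals the target formula; the cumulative
count is a latch, so subsequent protonation of NH₃ to NH₄ never
decrements it.  RDF first minima are located after a 5-bin moving
average, between the first peak and the next.

## Transport, free energy, rates, jump conditions

* MSD uses unwrapped coordinates, time origins every 10 frames
  (default), and a maximum lag of 25 % of the trajectory;
  `D = slope/6` by least squares over the 20–80 % lag window,
  converted Å²/fs → cm²/s (×0.1).
* `ΔF(r) = ∫_r^{r₀} ⟨λ⟩ dr′` by the trapezoidal rule on the λ table as
  given, with r strictly decreasing from the equilibrium distance r₀
  (where ⟨λ⟩ = 0) toward the product distance; ΔF‡ is the profile
  maximum.  The integral is linear in a uniform scaling of ⟨λ⟩ and
  matches the harmonic closed form to the trapezoid-rule error bound.
* `k = (k_B T/h)·exp(−ΔF‡/k_B T)` in ps⁻¹, strictly increasing in T
  and decreasing in the barrier; a negative barrier warns (the rate
  then exceeds the attempt frequency).
* `hugoniot_jump` closes the three steady-shock relations from either
  V/V₀ or U_p: mass `U_p = V_s(1 − V/V₀)`, momentum
  `P = P₀ + ρ₀V_sU_p` (ρ₀ in g/cm³ and velocities in km/s give GPa
  directly), energy `Δe = ½(P + P₀)(v₀ − v)` per unit initial mass
  (MJ/kg).  The three outputs satisfy all relations to machine
  precision because they are constructed jointly.  Note one
  inconsistency inherited from the reference state values: the quoted
  (V/V₀, U_p) = (0.58, 2.30 km/s) at V_s = 5 km/s violates the mass
  condition (which gives 2.10 km/s); both diagnostics are reported and
  no agreement is forced — the jump solver accepts either closure.

## Synthetic data: what it emulates and what it does not

The 182-atom builder reproduces the composition, cell and topology of
the reference system: a 2×3×3 bcc Fe₃₆ slab (a = 2.86 Å) centred in x
with two free surfaces, surrounded by 54 molecule sites on a regular
lattice of which 16 interior sites hold N₂ (seeded random choice) and
38 hold H₂O.  Site geometry guarantees every unintended pair distance
clears its bond cutoff by a safety band, and the minimum interatomic
distance is ≥ 0.7 Å.  It is a topological stand-in, not the optimized
DFT geometry: water structure, surface disorder and adsorbate
configurations are idealized.

Scripted reactive trajectories relocate atoms instantaneously at
planned frames: bond-forming events are applied L − 1 frames before
their nominal time so the lifetime window completes exactly on time;
scissions are applied at the nominal time.  The planner validates every
destination against each atom's full position timeline (original and
relocated, with exact application frames), so interleaved formations
cannot clash, and rejects geometrically impossible events.  Per-frame
Gaussian jitter (default 0.05 Å) sits on top; baseline margins are a
few σ of the relative jitter, so single-frame cutoff crossings can
occur in long runs but can essentially never persist for the 10-frame
lifetime — the same robustness the lifetime criterion provides against
thermal vibration in real trajectories.  The reference story
(hydrogenation of one N by three water hydrogens, N–N scission
coincident with N–Fe contact — the associative pathway — and immediate
protonation to NH₄⁺) reproduces formation times to the frame
(±0.12 fs).  These fixtures exercise the analyzers; they contain no
dynamics, energetics or emergent chemistry, so passing them validates
the bookkeeping, not any force model.

Brownian fixtures draw independent Gaussian displacements with per-axis
step variance 2·D·dt and store unwrapped coordinates; the bond
inventory fixture realizes an exact per-type bond census from isolated
pairs held at 80 % of their cutoffs on a 6 Å grid; shock-profile tables
follow a sigmoid V/V₀(t) with P and U_p derived row-by-row from the
jump conditions.  All generators are bit-reproducible under a fixed
seed.

## Numerical choices and problem sizes

Default test/acceptance problem sizes: 108-atom LJ crystals for the
shock engine (4000 damped + 4000 conservative steps), 64 atoms for
thermostat statistics, the full 182-atom / 16 530-frame scripted
trajectory for the NH₃ census, 132 isolated pairs over 4 ps for the
bond inventory, and 20 replicates of 36 walkers for diffusion recovery.
Tolerances asserted in the suite: Rayleigh-line deviation < 2 %,
extended-energy drift < 10⁻⁴ eV/atom/ps (measured ~10⁻⁸), NVE drift
< 10⁻⁵ eV/atom/ps, constraint residual < 10⁻⁸ Å, D recovery within 3
standard errors over 20 seeds.

## Known limitations

* No electronic structure: charge transfer, bond orders and true
  reactivity are outside the model; scripted chemistry is kinematic.
* The minimum-image convention (with 3³ refinement for skewed cells) is
  exact only for cells where the shortest lattice vector exceeds twice
  the largest cutoff; the builders enforce this, but user-supplied
  degenerate cells are not rejected.
* MSST models a single steady shock; multi-shock, ramp loading and
  rarefaction are not supported (the engine aborts on sustained
  expansion).
* TST rates apply a 300 K free-energy barrier at shock temperatures,
  exactly as in the reference analysis; no quantum or variational
  corrections.
* The sigmoidal shock-profile fixture reproduces jump-condition
  consistency and timescales, not the oscillatory transients of a real
  MSST run.
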
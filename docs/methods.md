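# Methods

This note documents the model equations, parameters, discretisation and
design choices behind `myofield`, and what the test suite does and does
not establish.

## Model and assumptions

The package solves the quasi-static (electrostatic + magnetostatic)
approximation of Maxwell's equations for a muscle at rest mechanically:
field dynamics enter only through the millisecond-scale membrane kinetics,
so the electric problem is a sequence of elliptic solves driven by the
transmembrane potentials, and the magnetic field is a memoryless
post-processing of the instantaneous currents.

**Multi-domain muscle.**  The muscle is a homogenised continuum in which
an extracellular space and one intracellular space per motor unit coexist
at every point.  Charge exchanged across the fibre membranes couples the
domains; f_r^k (the local fraction of fibres belonging to unit k) weights
each intracellular domain.  Intracellular conductivity is rank-one along
the fibre direction (σ_i^t = 0): homogenised fibres conduct only along
their axis, so the transmembrane diffusion reduces to independent 1-D
problems along fibre lines.  Note one consequence the simulations make
very visible: passive (non-recruited) intracellular domains still carry
currents −σ_i∇(V_m^k + φ_e), because the extracellular field drives
current through fibres wherever the membrane admits it; at action-potential
frequencies the membrane RC time (~1.5 ms) makes this coupling strong.
Together with the extracellular anisotropy this channels return currents
along the fibre axis (combined axial conductivity 15.63 mS/cm against
3.35 mS/cm transverse), which in turn makes the external magnetic field of
deep sources cancel much more strongly than an isotropic-volume intuition
(primary-current wire field plus weak volume-current correction) suggests.
This is a genuine prediction of the fully coupled multi-domain equations,
not a numerical artefact: the solver machinery reproduces the classic
weak-cancellation result when fed an isotropic medium, and the behaviour
sharpens (does not vanish) under grid refinement.

**Membrane.**  Classic squid-axon Hodgkin–Huxley kinetics in the
physiological-voltage convention (rest −75 mV, E_Na +40, E_K −87,
E_L −64.387 mV; g_Na 120, g_K 36, g_L 0.3 mS/cm²), the standard basis
model for sarcolemma excitability.  Fatigue, temperature, t-tubules and
calcium dynamics are out of scope.

**Inactive tissue and air.**  The fat layer is a source-free isotropic
volume conductor (σ_b = 0.4 mS/cm) continuous with φ_e at the interface.
For the magnetic problem, uniform vacuum permeability everywhere makes
interfaces trivial (A and ∇A continuous by construction); air is
source-free and the far-field decay condition is truncated to A = 0 on a
finite padded box.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| σ_i^l / σ_i^t | intracellular conductivity ∥ / ⊥ fibre | 8.93 / 0.0 | mS/cm |
| σ_e^l / σ_e^t | extracellular conductivity ∥ / ⊥ fibre | 6.7 / 3.35 | mS/cm |
| σ_b | fat conductivity (isotropic) | 0.4 | mS/cm |
| C_m | membrane capacitance | 1 | µF/cm² |
| A_m | fibre surface-to-volume ratio | 500 | 1/cm |
| f_r^k | recruitment density of unit k | 1 on territory | – |
| µ0 | vacuum permeability | 4π·10⁻⁷ | T·m/A |
| L×W×H | muscle box | 4.0×1.5×2.0 | cm |
| d_fat | fat thickness | 0 / 0.2 / 0.4 | cm |
| stimulus | single pulse at the NMJ nodes | 700, 0.1 ms | mA/cm² (tissue) |
| duration | simulated window | 30 | ms |
| sampling | output rate | 10 | kHz |

The stimulus amplitude is a homogenised per-tissue-volume current; the
membrane-level current is amplitude/A_m = 1400 µA/cm², depolarising the
junction by ≈140 mV over the pulse.  Applying 700 mA/cm² directly as a
membrane current density would drive V_m to ~7·10⁴ mV — outside any
physical range — whereas any robustly suprathreshold pulse produces the
same propagating action potential, which is what the experiments need.
The simulated window (30 ms, onset 1 ms) covers the full traversal of the
4 cm fibre at the model's ≈2 m/s conduction velocity plus repolarisation.

## Reference experiment geometry

Two motor units: the recruited unit MU1 is the single fibre-parallel line
of nodes at cross-section (x_t∥, x_t⊥) = (0.75 cm, H − d) — activation
depth d below the recording surface — with its neuromuscular junction at
x_l∥ = 1 cm; the passive unit MU2 is every other muscle node.  Because
MU1 is literally one grid line, its cross-sectional area is one grid cell:
absolute signal amplitudes scale with the grid and only amplitude *ratios*
are physically meaningful outputs.  The single reference channel sits at
(x_l∥, x_t∥) = (2.5, 0.6) cm on the recording surface; the channel line
spans x_t∥ ∈ [0, W] at the grid's transverse pitch.

## Discretisation and numerics

* **Grid.**  Regular structured grid, default spacing (0.1, 0.075, 0.1) cm.
  The anisotropic transverse pitch is a geometric-fidelity choice: it puts
  the MU1 cross-section (0.75 cm) and the reference channel (0.6 cm)
  exactly on grid lines, which a uniform 0.1 cm lattice cannot do (it
  would snap the fibre by 0.05 cm, a ~7 % bias in source–sensor distance
  for shallow sources).  Finer uniform spacing (0.05 cm) is available via
  configuration for convergence studies; territory and channel coordinates
  snap to the nearest grid line in general.
* **Elliptic operator.**  7-point finite differences in divergence form
  with harmonic face averaging; muscle nodes carry σ_e + Σ_k f_r^k σ_i^k
  (the recruitment fields partition the muscle), fat nodes σ_b; shared
  unknown at the interface; zero-Neumann closure outside; one corner node
  (farthest from the recruited line) pinned to 0 mV to fix the nullspace.
  The matrix is symmetric, time invariant, and factorised once (sparse LU)
  per run.
* **Splitting.**  Per 0.1 ms PDE step: (i) ten 0.01 ms Rush–Larsen /
  forward-Euler membrane reaction substeps, (ii) elliptic solve for φ with
  right-hand side −Σ_k f_r^k σ_i^l ∂²V_m^k/∂x² (zero-flux ends), (iii)
  backward-Euler 1-D fibre diffusion of each V_m^k with the φ_e coupling
  term, all fibre lines sharing one banded Cholesky factorisation.  Fields
  are recorded after (ii), consistent with the post-reaction membrane
  state.  Gating updates are unconditionally stable; the explicit
  potential update requires dt ≤ 0.02 ms (enforced).  Halving both steps
  moves the surface-channel RMS by < 2 % (self-convergence test).
* **Currents.**  Ohm's law on centred-difference gradients per region box
  (one-sided at region boundaries); intracellular currents use
  φ_i^k = V_m^k + φ_e and are weighted by f_r^k when superposed.
* **Magnetics.**  Componentwise scalar Poisson problems on the air-padded
  box (default padding 4 cm ≈ one body diagonal; doubling the padding
  moves sensor fields by < 2 %).  The discrete operator is the plain
  7-point Dirichlet Laplacian; production solves diagonalise exactly that
  operator with fast DST-I transforms, and a sparse assembly of the same
  operator backs the small-grid tests.  B = curl A with centred
  differences (one-sided at box boundaries); the stencil pair satisfies
  div curl = 0 and curl grad = 0 to machine precision.  Membrane
  (transmembrane) currents are never added as magnetic sources: for
  cylindrical fibres their macroscopic contributions cancel.
* **Channel fields.**  Because the Laplacian is symmetric, the field at a
  sensor is a linear functional of the sources; the experiment driver
  precomputes discrete Green's rows (one spectral solve per sensor-adjacent
  node, shared between sensors and cached per geometry) and evaluates
  per-step, per-domain sensor fields as dot products.  Tests verify this
  path equals the full solve + curl + sampling to ~10⁻⁹ relative.
* **Units.**  mV, ms, cm, mS/cm, µA/cm² internally for the electric stage;
  SI (m, A/m², T) inside the magnetic stage; B is reported in pT.

## Signal analysis choices

RMS over the full simulated window; PSD as a single boxcar periodogram of
the zero-padded window (transient signals, no averaging), Parseval-exact;
mean frequency on the unnormalised spectrum; coefficient of variation with
the population standard deviation; null-to-maximum distances resolved to
the channel pitch with the minimum-|RMS| channel marking the source
position.  The first output sample is taken after the first completed PDE
step (t = 0.1 ms); fields are identically zero until stimulus onset.

## What the tests show — and what they do not

Unit and property tests pin every building block to an independent oracle:
literal 1952 rate transcriptions and a high-accuracy adaptive ODE solve
(< 1 mV waveform error) for the membrane; a hand-assembled two-conductor
cable matrix, the anisotropic infinite-medium dipole kernel (< 5 % on a
distant probe ring) and the 1-D heat kernel (< 1 %) for the electric
stage; Ampère's law for a straight wire (< 5 %), exact superposition,
machine-precision vector identities and far-field box insensitivity
(< 2 %) for the magnetic stage; closed-form signal-metric identities for
the analysis layer.  Determinism is exact: re-running a configuration, or
restarting from a state snapshot, reproduces outputs bit-identically.

The synthetic protocol idealises real muscle heavily: a single straight
fibre line as the recruited unit, two motor units, axis-aligned fibres, a
cuboid geometry, idealised noiseless point sensors and a single basis
membrane model.  Passing tests therefore demonstrate correctness of the
stated model and numerics — not that real surface recordings will show the
same selectivity figures.  In particular, the strong far-field
cancellation of the magnetic components for deep sources (see the
multi-domain discussion above) is a property of this fully coupled
homogenised model; published in-silico studies with different coupling or
discretisation choices report notably weaker cancellation, so
magnetic-field depth-decay figures should be treated as model dependent.

## Known limitations

Curved anatomies, fibre curvature, multiple fat/skin layers, mesh import,
conduction-velocity distributions, electrode/sensor physics, noise, and
motor-unit decomposition are out of scope.  Absolute amplitudes depend on
the grid through the one-cell fibre cross-section; compare ratios, not
amplitudes.  The desk-scale default grid under-resolves the action
potential's upstroke (~0.1 cm at 0.1 cm pitch); production studies should
use 0.05 cm spacing and expect several-percent shifts in ratio metrics.
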
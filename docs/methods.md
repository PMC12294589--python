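# Methods

## The model

`fklpi` computes approximate quantum time-correlation functions (CFs)

    C_AB(t) = (1/Z) Tr[ e^{-beta H} A B(t) ],    B(t) = e^{-iHt/hbar} B e^{+iHt/hbar},

and their Kubo-transformed counterparts, for systems where exact quantum
dynamics is out of reach.  The classical Wigner / linearized path-integral
approximation replaces the trace by a phase-space average: initial points
(q, p) are drawn from the Wigner transform of the Boltzmann operator and
then propagated by classical mechanics,

    C_AB(t) ~ (1/2 pi hbar Z) \int dq dp (e^{-beta H} A)_W[q,p] (B)_W[q_t, p_t].

The approximation is exact for harmonic potentials and in the high-
temperature limit; for anharmonic systems it neglects quantum coherence
(tunneling oscillations, interference) and introduces artificial dephasing.

The hard part is the Boltzmann-Wigner distribution itself.  We use the
Feynman-Kleinert (FK) variational effective-frequency construction: the
Boltzmann operator is decomposed into Gaussian quasi-density operators
(QDOs) centered on centroid phase points (xc, pc), weighted by the
classical-like centroid density exp(-beta pc^2/2M - beta W1(xc)).  The QDO
Wigner transform is an analytic Gaussian with per-mode variances

    var_q = hbar*alpha / (2 M Omega),      var_p = M*Omega*alpha*hbar / 2,
    alpha = coth(hbar*Omega*beta/2) - 2/(hbar*Omega*beta),

where Omega(xc) is the variational effective frequency, found by iterating

    a^2(Omega)   = [ (x/2) coth(x/2) - 1 ] / (M Omega^2 beta),  x = hbar*Omega*beta,
    Omega^2(a^2) = (1/M) E[ V''(xc + y) ],   y ~ N(0, a^2),

to self-consistency, and the centroid potential is

    W1(xc) = kT ln[ sinh(x/2)/(x/2) ] + V_{a^2}(xc) - (1/2) M Omega^2 a^2.

The smeared Hessian can be evaluated by Gauss-Hermite quadrature (1D) or,
"black-box" style, by Monte Carlo gradient sampling of
(1/M a^2) E[V'(xc+y) y] — an integration-by-parts identity that needs only
force calls and is what makes the method applicable to arbitrary force
routines.

At a potential barrier Omega^2 < 0 and all expressions are analytically
continued (coth -> cot).  The continued width and centroid potential are
real and positive for hbar*|Omega|*beta < 2*pi; the QDO momentum Gaussian
however acquires a negative variance, and sampling is only possible after
integrating the centroid momentum out, leaving a combined momentum variance
M/beta + var_p that is positive exactly for hbar*|Omega|*beta < pi.  The
samplers enforce the pi bound; the wider 2*pi window is used only for
evaluating W1.

## Planetary dynamics

Ordinary classical propagation of the Wigner ensemble does not preserve the
quantum canonical ensemble: expectation values such as <x^2>(t) drift, and
in molecular systems zero-point energy leaks between modes.  The planetary
variant repairs this by moving each QDO as a rigid object: the centroid
(xc, pc) follows classical dynamics on W1 (so the centroid density is
conserved exactly), while the physical point orbits the centroid in
dimensionless coordinates

    q~ = sqrt(M Omega/hbar alpha) (q - xc),  p~ = (p - pc)/sqrt(hbar alpha M Omega),
    dq~/dt = Omega(xc(t)) p~,   dp~/dt = -Omega(xc(t)) q~,

with physical coordinates recovered using Omega and alpha evaluated at the
instantaneous centroid position.  Centroid-only output of the same
propagator is centroid molecular dynamics on the FK centroid potential
(FK-CMD), available as the `fk_cmd` method.

Numerics: each step advances the centroid by velocity Verlet on a cubic-
spline cache of W1 and rotates (q~, p~) by the exact 2x2 rotation through
Omega(xc_mid)*dt with Omega frozen at the drift midpoint.  This conserves
the planet radius q~^2 + p~^2 to machine precision and the centroid energy
to ordinary Verlet tolerance.  If a centroid crosses into a barrier region
(Omega^2 <= 0) mid-trajectory — a situation the underlying theory does not
define — a configurable policy either raises (`error`, default) or clamps
the local frequency at a small positive floor (`clamp`); the choice is
recorded on the call.  The planetary propagator is implemented for one mode
(1D); multi-dimensional planetary dynamics would require re-diagonalizing
the effective-frequency matrix along the path and is out of scope for this
release (multi-D *statics* and classical propagation are supported).

## Estimator conventions

With the time convention B(t) = e^{-iHt/hbar} B e^{+iHt/hbar} used for the
exact reference, and trajectories propagated forward, the A-side estimator
is the complex conjugate of the bare Moyal product of the QDO Gaussian with
the operator:

    position:  q - i hbar (p - pc) / (2 var_p)   ( = q - i(p-pc)/(M Omega alpha) )
    momentum:  p + i hbar (q - xc) / (2 var_q)   ( = p + i M Omega (q-xc)/alpha )

The signs are pinned by two oracles in the test suite: the numeric Wigner
transform of e^{-beta H} x (whose ratio to the Boltzmann-Wigner function is
q + i tanh(beta hbar w/2) p/(M w) for the harmonic oscillator — the bare
Moyal form), and the exact harmonic CF, which the sampled CF must reproduce
including the sign of its imaginary part.  Kubo-flavor estimators are the
centroid variables themselves (xc, pc, pc/M); this convention is validated
against the closed harmonic Kubo forms.  The B side always uses the bare
Wigner symbol (q_t, p_t, p_t/M) — all operator-product structure lives on
the A side.

The standard-flavor estimators are undefined on barrier modes (var_p < 0).
When a mixed ensemble contains barrier centroids, the pipeline samples those
centroids from the pc-integrated marginal branch and excludes them from
standard-flavor CFs with a logged count; Kubo-position and density-type
observables use the full ensemble.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `hbar` | 1 | unit convention, declared once in `ThermalSystem` |
| solver `tol` | 1e-8 (rel. on Omega^2) | fixed-point tolerance; 1e-12 absolute floor near Omega^2 = 0 |
| solver `max_iter` | 200 | anharmonic fixtures converge in <= 10; damping 0.5 on oscillation |
| Gauss-Hermite order | 40 | exact for polynomial V'' up to degree 79; self-check vs order 80 at 1e-8 |
| `n_force_samples` | 2500 | gradient-sampling batch, the working value for liquid-scale use |
| MCMC step | auto | tuned to 30-50% acceptance during burn-in, then frozen |
| burn-in / thinning / chains | 500 / 5 / 10 | error bars from block averages over the independent chains |
| profile grid | 401 points | W1/Omega spline cache; grows transparently when queried outside |
| planetary `dt` | 0.02/max(omega) | resolves both planet rotation and centroid motion |
| LJ core regularization | r < 0.6 sigma | quadratic continuation: the Gaussian smearing of a bare r^-12 core is a divergent integral; the core is never visited thermally |

## Built-in benchmarks and what they emulate

The 1D fixtures are the standard testbeds of this method family:

* harmonic oscillator (beta = 0.1, 1, 8): every stage of the pipeline must
  be *exact* here — effective frequency, centroid potential, reconstructed
  Boltzmann-Wigner distribution, standard/Kubo/planetary CFs, and the
  variance identity Var(xc) + Var(q-xc) = (hbar/2Mw) coth(beta hbar w/2);
* quartic oscillator (beta = 1): a clean anharmonic fixed point,
  Omega^2 = 3 a^2(Omega);
* double well V = -x^2/2 + x^4/4 at beta = 8 (M = hbar = 1): the
  low-temperature regime where 99.7% of the Boltzmann weight sits in the
  ground state.  Here ordinary classical-Wigner propagation visibly
  violates ensemble conservation (<x^2>(t) drifts by ~70% over ten well
  periods in our runs) while the planetary ensemble stays stationary
  within Monte Carlo error, and the planetary position CF tracks the exact
  grid-diagonalization CF more closely than standard propagation does;
* parabolic barrier with hbar*|Omega|*beta = 0.9 pi: just inside the
  momentum-sampling validity window;
* a 16-particle periodic 1D Lennard-Jones chain for the liquid observables
  (g(r), intermediate scattering, Green-Kubo diffusion).

What passing these tests does *not* show: accuracy for real molecular
liquids (which needs literature pair potentials and force fields, long
trajectories and large boxes), the quality of the local harmonic
approximation for strongly anharmonic multi-dimensional systems, or any
deep-tunneling observable — the linearization has no mechanism for coherent
tunneling, and the barrier branch is restricted to hbar*|Omega|*beta < pi.

## Problem sizes

The shipped validation runs use 10^4 centroids x 10 planets for the
harmonic CF checks, 2000 centroids x 5 planets and ten well periods
(t in [0, 44]) for the double-well ensemble-conservation study, and 10^5
Gaussian samples for the gradient-sampling identity.  These sizes give
3-sigma discrimination for every claim tested while keeping the whole suite
at the scale of a coffee break; they are defaults, not limits.

## Known limitations

* The effective-frequency solve fails (by design, with a flagged result)
  where the barrier continuation leaves hbar*|Omega|*beta < 2*pi — e.g.
  near the top of a deep double well at very low temperature.  The profile
  then splits into disjoint valid segments and Monte Carlo proposals into
  the gap are rejected and counted.
* Gradient sampling assumes the smearing integral exists; steeply divergent
  cores (bare r^-12) must be regularized, as the pair-liquid model does.
* The multi-dimensional solver smears the Hessian by Monte Carlo with
  common random numbers (the same Gaussian draw across iterations), making
  the fixed point deterministic at fixed seed; constant-Hessian problems
  are exact irrespective of the sample count.
* Kubo-momentum estimators are biased for barrier centroids (pc is
  integrated out there); such centroids are rare in well-posed runs and
  are reported in the log when present.
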
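# Methods

This note records the models behind each analysis stage, the tunable
parameters and their defaults, what the synthetic generators do and do not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Spin relaxation

Peak heights versus relaxation delay are fit to a two-parameter single
exponential, h(t) = A·e^(−Rt), by unweighted nonlinear least squares
(Levenberg–Marquardt via `scipy.optimize.curve_fit`, xtol/ftol 1e-12). The
initial guess comes from a log-linear regression on the positive heights.
Delays are supplied in ms and converted to s, so rates are s⁻¹. A baseline
offset term is available (`with_offset=True`) but off by default: peak-height
decays are conventionally fit without one. A fit is flagged unconverged when
the optimizer fails or returns a non-positive rate; unconverged estimates are
excluded from downstream profiles.

Default delay schedules are the standard inversion-recovery list (20, 60,
100, 200, 600, 800, 1200 ms) and CPMG list (1, 2, 4, 8, 10, 12 ms).

**Uncertainties from replicates.** Points sharing a delay form replicate
groups; the per-point noise sd is pooled over groups,
sqrt(Σ within-group SS / Σ(n_g − 1)), which reduces to the paired-difference
estimator d/√2 for duplicate pairs. The rate sd is the sd of rates refit on
`n_draws` (default 200) copies of the observed heights perturbed by Gaussian
noise of the pooled sd, seeded for determinism. When no delay is replicated
the sd is reported missing with a warning; the covariance-based sd from the
fit remains available.

**hetNOE.** noe = h_sat/h_unsat with first-order propagation
sd = |noe|·√((σ_sat/h_sat)² + (σ_unsat/h_unsat)²). Records whose unsaturated
height is below 3× its noise sd are flagged unreliable and excluded from
profiles.

**R1R2.** The product is formed only where both rates exist;
sd = R1R2·√((σ₁/R1)² + (σ₂/R2)²), exactly zero when both inputs are exact.

## Chemical-shift perturbations

Combined shift Δδ = √(ΔδH² + (α·ΔδN)²) with α = 0.14, the standard ¹⁵N
scaling for backbone amides (configurable; echoed in output headers, since
different groups use 0.10–0.20). Residues present in the reference but
absent from the variant are broadened beyond detection: they carry no Δδ,
never enter the threshold statistics, and are always reported as
significant-by-broadening.

The significance cutoff is trimmed_mean + k·σ with k = 1.5 and a 10% trim,
interpreted as ⌊n·0.10⌋ values dropped from *each* tail. σ defaults to the
sample sd of the **full** (untrimmed) Δδ set. This choice is deliberate: with
σ taken over the trimmed set, the cutoff on a pure-jitter baseline sits near
1.3–1.7 noise sd and flags 10–18% of unperturbed residues (the folded-normal
tail), which is not how the rule behaves in practice — published CSP plots
flag a handful of residues, not a fifth of the protein. Computing σ over all
shifts lets genuine hotspots inflate σ and push the cutoff above the jitter
baseline, giving near-zero false positives while real perturbations (an
order of magnitude above jitter) remain far above the cutoff.
`sigma_mode="trimmed"` selects the alternative. Significance is a strict
comparison (Δδ > cutoff), so a degenerate all-equal table flags nothing.

## Dynamics correlation

Two per-residue profiles are compared by ordinary least squares of B on A
over residues carrying the metric in both (≥ 10 required). Residuals are
vertical (the band is drawn around the regression line, not orthogonal to
it); the residual scale is the sd with the regression n−2 denominator, with
a 1.4826·MAD robust option. A residue is an outlier when
|y − (a·x + b)| > k·σ_resid, k = 1.5 by default. Under the null (common
truth, independent Gaussian noise) this flags 2·(1−Φ(1.5)) ≈ 13.4% of
residues; outlier lists must be read against that base rate, which is why
the pipeline also reports which residues were deliberately perturbed in
synthetic runs. σ_resid = 0 (identical profiles) yields no outliers.

## Channel geometry

The 3-fold axis direction is the rotation axis of the Kabsch superposition
of chain A onto chain B; the A→C rotation must agree within 5° and both
rotation angles must be 120° ± 15°, otherwise the model is rejected as not
C3-symmetric. The axis anchor is the three-chain centroid. The direction
sign follows the third moment of the atom distribution along the axis
(largest-component fallback for symmetric models), making profiles
reproducible under arbitrary rigid motion of the input coordinates.

The channel is profiled with an axial probe: at each z sample (step 0.2 Å),
the free radius is min over atoms within a slab (half-width 1.0 Å, with a
1e-9 Å tolerance so boundary atoms are retained under floating-point
rotation error) of (perpendicular distance to axis − vdW radius), clamped at
zero. Van der Waals radii are the Bondi (1964) set, keyed by element, with
1.70 Å for unknown elements. Alternate conformers contribute independently,
so the most restrictive altloc governs the radius. This axial probe is valid
because the MIF channel is coincident with the symmetry axis; it makes no
attempt at general (non-axial) tunnel tracing, for which Voronoi-based tools
exist. The gate is the local profile minimum nearest the plane of the
nominated gate residue's side-chain tip atoms (SG for Cys, OH for Tyr, CB
for Ala, ...), or the global minimum when no residue is nominated.

Superposition RMSD pairs atoms by (chain mapping, residue number, atom name)
on Cα by default — which also keeps mutated side chains out of the
comparison — keeping one altloc per atom. For trimers all three cyclic chain
mappings are tried and the best kept; reflective mappings are non-physical
for a C3 assembly. Author residue numbering from the PDB is authoritative.

## Assembly and assays

Species mass: k·m_tagged + (3−k)·m_untagged. Default monomer masses are one
third of the intact trimer masses (96.1/3 and 37.9/3 kDa) rather than the
apparent SDS-PAGE band masses (31.8, 12.4 kDa), which are gel-calibrated
apparent values and inconsistent with the intact species masses; both are
accepted wherever masses are parameters. Assembly follows a binomial in the
tagged monomer fraction, optionally conditioned on k ≥ 1 to model Ni-affinity
retention. Expected band ratios assume Coomassie stain intensity
proportional to the mass of protein in the band — a standard approximation,
not a measured property.

Michaelis–Menten fits are unweighted least squares of v = Vmax·S/(Km+S);
kcat = Vmax/E₀ and efficiency kcat/Km, with relative efficiency in percent
against a reference fit (invariant to the units of v). Rates from raw
absorbance slopes use Beer–Lambert with ε₃₀₆ = 11 400 M⁻¹cm⁻¹. A fit is
flagged when Km lands outside 100× the substrate range.

Melts use a two-state van 't Hoff model with linear folded/unfolded
baselines: θ(T) = (θ_f + θ_u·K)/(1+K), K = exp[−(ΔH/R)(1/T − 1/T_m)],
temperatures in kelvin internally (R = 8.314 J mol⁻¹ K⁻¹), I/O in °C.
Initialisation: baselines from the outer ~15% of the temperature range, T_m
from the half-unfolded crossing. Curves spanning < 30 °C, baselines closer
than 5% of the signal range (no transition), edge-pinned T_m or ΔH ≤ 0 are
rejected.

## Synthetic data: what it emulates, and what it does not

All generators draw Gaussian noise with sd expressed as a fraction of the
noiseless initial height or signal span (one knob per generator), from a
`numpy` generator seeded explicitly — fixed seed, bit-identical output.

- **Decays**: every delay is measured twice by default, emulating a fully
  interleaved replicate series (the acquisition mode that underlies
  replicate-based uncertainty estimates); replication can be restricted to
  designated delays. Default truth rates: R1 ~ N(1.1, 0.12) s⁻¹ (slow
  trimer tumbling) and R2 ~ N(55, 7) s⁻¹, centred where the 1–12 ms CPMG
  list samples about one half-life (ln 2 / 12 ms ≈ 58 s⁻¹) — the regime
  that schedule is designed to measure. Real MIF R2 values at moderate
  fields are lower (~20–30 s⁻¹); recovery there is proportionally less
  precise because the series decays only ~25% over the schedule, and the
  recovery figures quoted by the tests should not be extrapolated to that
  regime. No lineshape, exchange or frequency-domain structure is
  simulated — peak heights only.
- **Shift tables**: variant = reference + hotspot offsets + jitter
  (0.005 ppm), hotspots at 0.06–0.15 ppm (¹H) and 0.3–1.0 ppm (¹⁵N) —
  realistic interface-scale perturbations an order of magnitude above
  jitter. Broadened residues are deleted outright; partial intensity loss
  is not modelled.
- **Trimer shell**: rings of carbon pseudo-atoms (Bondi 1.70 Å) stacked
  along z with one constricted gate ring, exactly C3-symmetric by
  construction, so the true free radius is analytic:
  ring_radius − offset − vdW. Optional SG sulfurs at a prescribed
  inter-chain separation. It is a geometric fixture, not a protein: no
  packing, no sequence, no side-chain detail.
- **Kinetics**: 8 substrate levels over 0–2 mM in triplicate, 50 nM enzyme,
  proportional noise. **Melts**: 20–100 °C in 0.5 °C steps, noise as a
  fraction of the folded/unfolded span.

Passing recovery tests on these generators demonstrates correctness of the
estimators under their stated noise models; it does not validate peak
picking, assignment, phasing or any upstream spectral processing, which this
package deliberately does not perform.

## Known limitations

- The axial probe reports the channel radius only along the symmetry axis;
  off-axis pockets and side tunnels are invisible to it.
- CSP significance with the default full-set σ depends on real perturbations
  being present; on a spectrum pair that differs only by noise the cutoff
  tightens toward the jitter scale and the ~13% tail-rate caveat of the
  trimmed-σ variant applies.
- The Monte-Carlo rate uncertainty assumes homoscedastic per-point noise
  estimated from replicates; intensity-dependent noise is not modelled.
- Relative catalytic efficiencies are ratio-recoverable; absolute kcat/Km
  values depend on accurate enzyme concentration, which is taken at face
  value.
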
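# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate. It is the package's own
account of its science; all quantitative statements below are reproduced by
the test suite or the worked example, not asserted from memory.

## Units and data model

All internal computation is SI (Pa, m, s, N, Hz). The CSV readers are the
only place unit conversion occurs (`pressure_kpa`/`pressure_psi` column
suffixes are scaled on read). Missing metadata fields are errors rather
than defaults, with two exceptions that have protocol-stated values:
Poisson's ratio ν = 0.42 and the SAOS reference frequency 0.1 Hz.
Needle radii are shaft inner radii (inner diameter / 2); bevel-tip
geometry is not modeled, and which effective radius a beveled tip
contributes is an open question of the cavitation model itself.

## Cavitation rheology

Model: P_c = 1.05 E_eff + 2.1 γ / r for a neo-Hookean solid. The fit is
unweighted OLS of P_c on 1/r (statsmodels), replicates entering as
separate points, with ≥ 3 distinct radii required. Negative intercepts or
slopes are reported with a warning flag, never clamped: they are
informative about model misfit.

Event detection. The protocol specifies Butterworth filtering but not its
parameters; the defaults are order 2, cutoff min(10 Hz, 0.1 × Nyquist),
applied forward-and-backward (zero phase) so the event time is not
delayed. A cavitation event is the first sample where pressure has fallen
by ≥ 10% of (trailing-window maximum − baseline) within a 0.25 s window;
the baseline is the median of the first 5% of samples, which makes
detection invariant to constant sensor offset. Two numerical guards matter
in practice:

- **Noise floor.** Early in the ramp the running height is of the order of
  the sensor noise and a pure fraction-of-height rule would fire on noise;
  the drop must additionally exceed 6× the noise scale estimated from the
  linearly detrended baseline segment. For clean signals the floor is ~0.
- **Peak reading.** A zero-phase IIR filter overshoots at the
  near-discontinuous pressure cliff (order-2 filtfilt overshoots the peak
  by ~2–3%), and the raw maximum is biased upward by extreme-value
  statistics of the noise near the peak (~+4% at 2% noise). The pipeline
  therefore detects the event on the filtered trace and reads P_c as the
  median of the raw signal over the trailing 0.15 s at the peak, which is
  unbiased to within ~0.2% at the default noise level. The plain
  "maximum before the drop" estimator remains the default of
  `detect_cavitation_event` (it is exact on clean signals and is what the
  zero-noise identity tests exercise).

Strain rate: the protocol's value of 0.028 s⁻¹ at 5000 μL/min is stated
without a formula, so the default convention ("protocol-constant") reproduces
it and scales linearly in injection rate; a dimensional alternative
("volumetric", Q/(4πr³/3)) is available and clearly labeled. The returned
value carries its convention name.

## Micro-indentation

Contact is the first force sample exceeding baseline mean + 3 SD that
stays above for 5 consecutive samples (baseline = first 10% of samples,
≥ 20 required). The reported contact displacement is refined to
sub-sample accuracy by extrapolating the post-contact
displacement-vs-force line back to the baseline force. Compliance is the
least-squares slope of sample deflection (stage displacement minus F/k)
versus force over the 20–80% band of the post-contact force range.

The confinement-corrected modulus relation is evaluated with the grouping

    E = 3/(8 a C) * (1 + {0.75/((a/h)+(a/h)^3) + 2.8(1-2nu)(a/h)}^-1)^-1

chosen because it restores the incompressible half-space flat-punch limit
E → 3/(8 a C) as a/h → 0 and matches the confinement-correction structure
of the bonded-layer indentation literature. The typeset source formula is
ambiguous about this grouping; the literal reading is available behind
`grouping="literal"` for sensitivity checks but is not dimensionally
anchored to the punch radius. At ν = 0.5 the 2.8(1−2ν)(a/h) term vanishes
exactly and the configuration layer warns. A quoted maximum force of 2 nN
in the source protocol is treated as a typo (inconsistent with a 0.5 mm
steel punch on kPa-scale tissue); maximum force is a free input.

Strain rate: indentation speed / sample thickness (20 μm/s on 0.5 mm
gives 0.04 s⁻¹).

## SAOS

|G*| is computed by quadrature from G′ and G″ (the magnitude computation
is not specified by the source; quadrature is the standard definition).
Interpolation between measured frequencies is linear in log–log space,
where power-law materials are straight lines; extrapolation outside the
sweep is an error. The power law |G*| = A ω^β is fit on |G*| (not G′
alone — another unstated choice; at the default loss tangent the two
differ only in A, not β). Temperature is metadata only; no correction is
applied. The linear-regime check takes parallel
(strain amplitude, G′) arrays — the sweep container carries a single
amplitude — and reports the largest amplitude contiguously within 10% of
the low-strain plateau (mean of the 3 smallest amplitudes), plus whether
the protocol's 0.5% amplitude is inside it.

## Uniaxial tension

The toe/linear boundary procedure is not defined by the source; the
package uses continuous two-segment least squares: every interior strain
value in the central 10–90% of the strain range is a breakpoint
candidate, each candidate is fit in closed form
(stress ≈ c + m₁·min(ε, ε_b) + m₂·max(ε − ε_b, 0)), the minimum-SSE
candidate is refined continuously (bounded Brent within the bracketing
interval), and the intersection of independently fit segment lines is
admitted as a final candidate (this is exact on clean bilinear data,
where the SSE surface is numerically flat near its zero). Points after
the global stress maximum (rupture tail) are truncated first. When the
two slopes differ by < 10% the curve is flagged unidentifiable and both
moduli are set to the single-line slope. The returned SSE is never worse
than the best single line, which lies in the search space's closure.

Strain rate: displacement rate / gauge length (1% of starting length per
second gives 0.01 s⁻¹).

## Cross-platform normalization and statistics

Rate adjustment uses E·(r_ref/r)^β with β from the mean of the fitted
SAOS power laws when sweeps are present, else the default 0.11; the
reference rate is the SAOS reference frequency. Records that lack a
computable rate fall back to the protocol rates (cavitation 0.028,
indentation 0.04, uniaxial 0.01 s⁻¹). Comparisons are two-tailed
Student's t-tests: pooled variance unpaired, difference-based paired,
with p-values from the t distribution (scipy). Degenerate zero-variance
cases define t = 0, p = 1 when the means agree (and p = 0 otherwise)
rather than NaN. No multiple-testing correction is applied by default,
mirroring the source statistics; the freeze/thaw report exposes a
Bonferroni flag that corrects only the verdict, never the reported
p-value. Paired and unpaired modes are both exposed because the pairing
structure of the source comparison is not fully specified.

## Synthetic data: what it emulates, and what it does not

Each generator is seeded (`numpy.random.default_rng`) and deterministic.

- Cavitation traces ramp smoothly (saturating exponential, shape
  configurable) to exactly P_c, drop within one sample to 20% of P_c, and
  carry additive Gaussian noise of 2% of P_c. Only the peak and the sharp
  drop carry information for the analysis; real pre-cavitation ramp
  shapes, bubble growth dynamics and poroelastic air escape are not
  modeled.
- Force curves have a pre-contact baseline, sample compliance from the
  closed-form inverse of the confinement relation, cantilever compliance
  in series, and 1% (of max force) Gaussian noise. No adhesion, no
  Hertzian contact, no creep.
- Sweeps follow |G*| = A ω^β with a constant loss tangent of 0.2 — a free
  synthetic parameter (the source reports G′ and G″ but no numeric
  ratio) — and one multiplicative log-normal factor per frequency (5%),
  preserving the loss tangent.
- Stress–strain curves are exactly bilinear plus additive noise of 2% of
  peak stress. Because the toe stress is ~6% of peak stress at the
  default geometry, this implies a large *relative* noise on the toe
  segment, which is why the frozen toe-recovery tolerance is much wider
  than the others.
- Study generation draws per-sample true moduli log-normally (5%) around
  the technique truth, emulating between-sample heterogeneity; the
  presets carry per-technique generating moduli (lung: cavitation
  6.1 kPa, indentation 1.4 kPa, SAOS 3.3 kPa at 0.1 Hz, uniaxial toe
  3.4 kPa over a 30 kPa linear regime; hydrogel: 19.1/13.9 kPa) and the
  protocol needle radii (16/18/22/26 G for lung, 24/27/30 G flat needles
  for hydrogel).

Passing recovery tests therefore demonstrates that the analysis chain is
correct and unbiased under these idealized signal models — not that it is
robust to drift, viscoelastic creep, heterogeneous contact, or the
fracture-vs-cavitation ambiguity of real tissue.

Replicate counts in the presets (8 cavitation regions, 6 indentation
samples × 3 indents, 7 sweeps, 4 tensile samples) are desk-scale
stand-ins chosen so a full study generates and analyzes in about one
second while keeping every group large enough for SD/SEM and t-tests.

## Tolerances

Zero-noise forward/inverse identities are asserted at 1e-8 relative.
Monte-Carlo recovery tolerances are frozen from an independent pilot run
(100 replicates per modality, pilot seed recorded in
`tests/fixtures/mc_tolerances.json`) with a fixed rule — 1.5× the pilot
95th percentile of |relative error|, rounded up to 2 significant digits —
and the tests require ≥ 90/100 replicates within tolerance at a different
seed base. The breakpoint estimator is checked for statistical
consistency (mean error shrinks with sample size) rather than a fixed
bound, since single noisy curves at 200 points leave the breakpoint
genuinely uncertain.
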
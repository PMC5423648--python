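# Methods

## Binding model

All binding math uses the exact 1:1 mass-balance quadratic for the complex
concentration. The implementation uses the algebraically equivalent
cancellation-free form 2·[P]t[L]t / (s + sqrt(s² − 4[P]t[L]t)) with
s = [P]t + [L]t + K_d, which stays accurate in the weak-binding corner
where the textbook "s − sqrt(...)" form loses digits; at K_d = 0 it reduces
exactly to the stoichiometric limit min([P]t, [L]t). The quadratic is
property-tested against an independent iterative solve of the two mass
balances (Brent root-find on the free-ligand concentration) to 1e−10
relative tolerance.

Units are fixed to μM (concentrations), ppm (shifts), μL/μcal (ITC) and
kelvin internally; any conversion happens at the file boundary.

## Global shared-K_d fit

The fast-exchange CSP trajectories of all usable residues are fitted
simultaneously: one shared K_d (bounded to [1e−3, 1e5] μM) and one
Δδ_max ≥ 0 per residue, by trust-region least squares (lmfit /
`least_squares`). Residuals are unweighted by default — per-residue weights
are accepted but optional. K_d is initialised by a midpoint heuristic (the
ligand total at which the largest trajectory reaches half of its final
CSP, corrected for depletion by −[P]t/2), falling back to [P]t; the
objective is smooth and unimodal in K_d for this model, so the fit is not
initialisation-sensitive, which the exhaustive grid-search oracle in the
tests confirms. Missing or broadened points (NaN) are dropped from the
residual, never imputed.

Standard errors are curvature-based (from the covariance of the
least-squares solution). A `converged` flag is false when the optimizer
fails or the shared K_d lands on a bound. `fit_single` is the one-residue
special case, intended as a QC companion: residues whose lone-fit K_d
deviates more than ~3× from the global value likely report a second event
and should be excluded from the pool (`kd_deviates`).

## CSP statistics and classification

The combined CSP uses the ¹⁵N scaling constant 5; it is overridable only
through an explicit argument because the value is a community convention,
not a tuning knob. Endpoint CSPs are last-versus-first titration point.
Mean and sample SD (ddof = 1) are computed over quantified residues only —
broadened residues never contribute — in a single pass, with no iterative
outlier trimming. Thresholds are inclusive (Δδ ≥ mean, Δδ ≥ mean + SD), so
the degenerate all-equal profile classifies every residue into both upper
classes; an SD below 1e−12 of the mean is snapped to zero to keep that
boundary convention stable against float round-off.

## Peak tracking

Fast-exchange assignments are transferred point-to-point by optimal
assignment (Hungarian algorithm) in combined-shift distance, gated at
`max_jump` (default 0.05 ppm): a residue with no candidate within the gate
is marked missing at that point and tracking resumes from its last known
position. Optimal assignment rather than greedy nearest-neighbour keeps
identities correct when trajectories cross, which the tests check against
a brute-force permutation oracle on small peak sets. Slow-exchange series
are handled as fixed free/bound positions exchanging intensity; the peak
lists carry a per-peak state label for this purpose.

## Exchange-broadening detection

A residue is flagged as broadened beyond detection when its intensity,
normalised to the median intensity trend of all residues at that point
(which absorbs global effects such as dilution), falls below
`alpha` × its own first-point intensity, or when its peak disappears
outright; the earliest such point is recorded. `alpha` defaults to 0.1:
"beyond detection" operationally means the peak has dropped to the
noise-floor neighbourhood, and a 10 % cutoff separates the attenuated
residues from intensity scatter at the default 5 % intensity CV. The
flagged set grows monotonically with `alpha` (property-tested).

## ITC model and fit

Injections displace cell volume proportionally (single-step dilution
recursion); the per-injection heat corrects for complex carried out with
the displaced volume. This convention differs from other displacement
bookkeepings by well under 1 % for v_i ≪ V₀. Heats are integrated
per-injection values; baseline handling of raw power traces is out of
scope. The fit floats (n, K_d, ΔH) with K_d parameterised on a log scale
(bounds 10⁻⁴–10⁶ μM), initialised by a coarse K_d grid at n = 1 with ΔH
from the total heat; the first (priming) injection is excluded by default;
a constant heat-of-dilution offset is available as an optional fourth
parameter, off by default. c = n[P]₀/K_d outside [1, 1000] marks the
result unreliable (with a stronger flag below 0.1); at c ≈ 0.2 the K_d
standard error exceeds 25 % of the estimate, which is the quantitative
face of "too shallow to fit". The default cell volume of 1400 μL is
typical for the instrument class these designs come from. 1 cal = 4.184 J
exactly.

## Thermodynamic comparisons

ΔΔG = RT ln(K_d,a/K_d,b) with R = 8.314 J mol⁻¹ K⁻¹; temperatures come
from experiment metadata, never hard-coded (cofactor titrations are run at
303.15 K, acceptor titrations at 295.15 K, and mixing the two raises a
validation error unless explicitly overridden). Fold-changes are reported
both exactly and rounded to one significant figure for presentation.
Ligand/state pairs with no detectable binding use an explicit `NO_BINDING`
sentinel: included in reports, excluded from free-energy arithmetic.

## Synthetic-data generator

The generator emulates the titration designs the analysis targets:

- fast exchange: 250 μM protein, small-increment schedule to 1.75 mM
  (13 points, dense through the K_d region), true K_d 28 μM, 20 residues;
- slow exchange: two peaks per residue with intensities (1 − f) and f and
  a 5 % detection floor, for tight binders titrated to a few equivalents;
- ITC: 40 μM cell protein, a 0.2 μL priming injection plus 11 × 25 μL
  injections of 400 μM titrant (≈2 equivalents, c ≈ 61 at K_d 0.66 μM).

Free-state shifts are drawn uniformly from realistic amide windows
(¹H 7.0–9.5, ¹⁵N 105–130 ppm) so tracking is non-trivial; endpoint changes
are Gaussian in magnitude (¹H 0.08 ± 0.04, ¹⁵N 0.4 ± 0.2 ppm) with random
signs. Default noise is 0.005 ppm ¹H / 0.025 ppm ¹⁵N and 5 % intensity CV
— typical HSQC precision; ITC heat noise defaults to 2 % of the largest
model heat. Broadening is modelled as exp(−k·f) in the bound fraction f
(k = 12 by default), the simplest attenuation monotone in occupancy.
A single integer seed drives all randomness; identical configurations and
seeds are bit-identical.

What the generator does **not** emulate: lineshapes and intermediate
exchange, peak overlap beyond coincidental proximity, temperature or pH
drifts, baseline/integration artefacts in ITC, and systematic
concentration errors. Passing tests therefore demonstrate correctness of
the estimators under the stated noise model, not robustness to every
pathology of real spectra.

## Problem sizes

The test suite and the acceptance script use 25-replicate recovery studies
(20 residues × 13 titration points for NMR; 12 injections for ITC), small
enough to run in seconds while leaving the Monte-Carlo error of the mean
recovered K_d well inside the quoted uncertainties (±3 μM NMR,
±0.03 μM ITC).

## Known limitations

- Single-site 1:1 binding only; no Hill/multi-site or competitive models.
- Fast- and slow-exchange limits only; no intermediate-exchange lineshape
  fitting, no k_on/k_off.
- The ITC forward model consumes integrated heats; it does not integrate
  raw thermograms.
- Curvature-based uncertainties assume a locally quadratic objective; a
  seeded residual bootstrap is the fallback for ill-conditioned fits.
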
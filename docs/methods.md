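# Methods

This note documents the models and procedures `qssr` implements, the defaults
and why they were chosen, the numerical details, and what the test suite's
synthetic data does and does not establish about real campaigns.

## Problem setting

A ligand-parametrization campaign characterizes a set of chiral ligands
(here on the order of n = 22) by continuous descriptors computed from two
kinds of structures — the free preligand (FL) and the metalated complex
(CMC) — plus experimental outcomes per ligand: an enantiomeric ratio and a
percent yield. Descriptors split into steric quantities the package computes
itself from geometry (%V_bur, sterimol) and electronic quantities consumed as
given (NBO partial charges, probed interaction energies), since
electronic-structure computation is out of scope. The analysis then asks two
questions: which descriptor combination best predicts enantioselectivity
(regression), and which single descriptors gate yield (classification).

## Percent buried volume

%V_bur at a metal center is computed by laying a regular cubic grid of pitch
h over the probe sphere of radius R centered on the metal and counting the
fraction of in-sphere grid points that fall inside at least one scaled vdW
sphere of the surrounding atoms. The center atom never occupies; arbitrary
further atoms can be excluded (e.g. a bound substrate) and hydrogens can be
dropped by flag.

Defaults follow common practice for metal-center buried volumes: R = 3.5 Å,
radii scale 1.17, h = 0.05 Å, hydrogens included, Bondi (1964) radii. The
probe sphere is centered exactly on the metal atom, with no offset along a
metal–ligand axis. None of these conventions is universal across published
campaigns, so every result object carries its full settings (and the radii
provenance label), `attach_computed_descriptors` stamps a settings hash into
the column provenance, and all knobs are exposed — a reproduction of someone
else's numbers is a matter of matching their recorded settings, not of code
changes. Radii lookups of elements absent from the active table are hard
errors; the Bondi set ships as a packaged CSV and custom tables load from the
same format.

Accuracy: at h = 0.05 Å the integrator agrees with a 10⁶-point Monte-Carlo
integration to better than 0.1 percentage points on random 20-atom complexes
(the acceptance script measures this), and halving the grid pitch moves
results by ~0.01 points (`buried_volume_convergence` reports this estimate
per molecule). The integrand is monotone in the radii scale and in adding
atoms, which the tests assert.

## Sterimol

Sterimol describes a substituent attached along an axis: the unit vector from
the attach atom to the substituent root atom. Membership of the substituent
is an explicit atom-index list — the package never infers connectivity, so a
wrong selection fails loudly instead of silently producing a descriptor of
the wrong fragment.

With positions p_i relative to the attach atom, projections t_i = p_i·axis,
perpendicular offsets q_i = p_i − t_i·axis and vdW radii r_i:

- L  = max_i (t_i + r_i) — exact, no discretization;
- B5 = max_i (‖q_i‖ + r_i) — exact;
- B1 = min over in-plane unit directions u of max_i (q_i·u + r_i).

B1 is found by a coarse scan (default 1° pitch, vectorized) followed by
bounded scalar minimization inside the ±1° bracket to 1e-4°. The extent
function is a maximum of sinusoids in the scan angle, so within a 2° window
it is effectively unimodal; against a dense 0.01° reference scan the
production B1 is accurate to well under 0.005 Å on random substituents.
When several directions tie within tolerance the smallest extent found wins
and the first such direction in scan order is reported. All three values are
invariant under rigid motion and atom reordering (asserted); only B1 carries
the angular-scan error.

## Selectivity response

Enantiomeric ratios are converted to the transition-state free-energy
difference ΔΔG‡ = RT·ln(er_major/er_minor) with
R = 1.98720425864083e-3 kcal mol⁻¹ K⁻¹ and default T = 298.15 K
(room-temperature catalysis; configurable). The response is a magnitude —
the major enantiomer is whichever is in excess, and its identity is metadata
rather than a sign. The map and its inverse are mutually inverse bijections
(round trip asserted to 1e-9); 50:50 maps to exactly zero, and er_minor = 0
is rejected rather than mapped to infinity.

## Descriptor table

One row per ligand, unique `ligand_id`, numeric descriptor columns named
`<property>_<site>_<FL|CMC>` (the shorthand forms `s_C2_L`, `nbo_C2`,
`nbo_C6`, `IE` are accepted via an alias map), optional `response`
(kcal/mol), `yield_percent` and `split` columns. With ~22 rows a silently
dropped or imputed ligand can flip the selected model, so the table fails
loudly on duplicates, non-numeric cells, out-of-range yields and missing
values in modeled columns; no operation reorders or drops rows implicitly.
Column provenance (e.g. the steric settings hash) is serialized in a sidecar
JSON next to the delimited file.

## Exhaustive subset regression

Every subset of the candidate descriptors of size 1..cap (default cap 6) is
fitted by OLS on z-scored features. Standardization parameters come from the
training rows only — a metamorphic test perturbs the test rows and asserts
train metrics are unchanged — and coefficients are reported on both the
standardized scale (comparable magnitudes) and the raw scale. Rank-deficient
designs are errors naming the collinear features; subsets containing a
feature that is constant within the training rows are skipped with a logged
reason so the sweep completes. An enumeration guard (default 500k subsets)
prevents accidental combinatorial explosions.

Metrics: R² = 1 − SS_res/SS_tot about the evaluated rows' own mean (flagged
undefined, never silently NaN, when the evaluated response has zero
variance); MAE in response units. LOO CV is defined as the naive loop —
refit on n−1 rows, re-standardize, predict the held-out row — and the
implementation offers both that loop and a hat-matrix closed form
e_i/(1−h_ii). Because OLS predictions are invariant to affine rescaling of
the features, per-fold re-standardization does not change held-out
predictions and the two paths are mathematically identical; tests assert
agreement to 1e-10 and the sweep uses the fast path.

Ranking policies (always logged): `r2_test` (default; descending test R²,
ties by LOO MAE, then fewer features, then lexicographic subset order),
`mae_loo`, `r2_train`. Candidates are sorted before enumeration, so the
leaderboard is invariant to the order in which the caller lists descriptors.
The train/test split is taken from the table's `split` column; a seeded
80/20 random splitter is provided for synthetic runs.

## Yield-threshold classification

Yields are binarized at an explicit cutoff (a row equal to the cutoff counts
high). Per descriptor, both directions of a single cut are scored at every
midpoint of consecutive sorted unique values, plus two boundary cuts just
outside the data range representing the trivial one-class rules. Including
the boundary rules guarantees the reported accuracy is never below the
majority-class baseline; when a boundary rule wins, the result is flagged
`degenerate` (no interior threshold helps). For non-degenerate results the
cut lies strictly between two observed values, and the full separating gap
is reported alongside the midpoint cut, because the placement of a single
printed threshold inside its gap is a convention that varies between
campaigns. Ties in accuracy are broken toward the widest gap, then the
smallest cut, then the at-or-below direction. The best threshold is
invariant (same separated rows, same accuracy) under strictly monotone
increasing transforms of the feature.

## Synthetic campaigns

`SyntheticSpec` defaults define the reference campaign used throughout the
tests: n = 22 ligands, p = 10 descriptors drawn from a zero-mean
unit-variance equicorrelated Gaussian with pairwise correlation 0.3 (one
knob for the collinearity typical of descriptor pools; moderate by design),
four active descriptors with coefficients (1.0, −0.8, 0.6, −0.5) kcal/mol —
distinct magnitudes and mixed signs spanning strong to marginal effects —
plus Gaussian noise at 0.15 × the analytic sd of the noiseless response
(var = (1−ρ)·Σβ² + ρ·(Σβ)²), i.e. a strong but not noiseless
structure–selectivity signal. Yields are a threshold mechanism, not a linear
one: 90% above the cut (default 0.0, the descriptor median) on one governing
descriptor, 20% below, with an optional independent flip rate (default 0) —
matching the assumption the classification stage makes. A seeded 80/20
train/test split is included. Everything is reproducible from the seed.

The planted-recovery study enumerates subsets up to the planted size (cap 4)
and ranks by LOO MAE. Both choices are deliberate: with ~4 test ligands,
test-set R² is far too noisy to select among 385 models (it picks the
planted subset only about two-thirds of the time), whereas LOO over the 18
training rows is stable; and capping at the planted size asks the sharp
identifiability question — among all small models, does the true one win? —
rather than competing against its own supersets, which fit the same signal
plus noise. Under these conditions the planted subset ranks first in
~100/100 seeds, and fitted coefficients recover the planted ones with mean
absolute error below 2·noise_sd/√n.

What the generator does *not* emulate: real descriptor pools are not
exactly equicorrelated (block structure from FL/CMC families is common),
real responses contain model misspecification rather than pure Gaussian
noise, yields are continuous rather than two-valued, and descriptors have
physical units and ranges. Passing the recovery tests therefore shows the
machinery is correct and that a sparse 4-descriptor signal of this strength
is identifiable at n = 22; it does not certify that any particular real
campaign's selected model is the true one.

## Pipeline and provenance

The orchestrated run (`run_pipeline` / `qssr run`) executes
simulate/descriptors → model-search → classify with validation before any
compute, writes every tabular output with the config hash, and serializes
the full effective configuration (no hidden defaults) plus a run record next
to the outputs. The hash covers reproduction-critical settings only — the
output directory and log level do not change any computed value. Logging
goes to stderr; tabular results never to stdout.

## Problem sizes

Default test-suite and acceptance-script sizes: 20 random 20-atom complexes
at 10⁶ Monte-Carlo points for %V_bur; 50 random 5-atom substituents against
a 0.01° dense scan for B1; 100 synthetic campaigns for the recovery rates;
200 random datasets for the threshold oracle. The full suite runs in a few
minutes on one CPU.

## Known limitations

- No connectivity perception anywhere: substituent membership and atom roles
  are explicit inputs (XYZ comment-line annotations or function arguments).
- No quadrant/octant %V_bur decomposition or steric maps.
- No regularized or nonlinear regression; the modeling deliberately stays in
  the plain-OLS regime the exhaustive search assumes.
- Electronic descriptors are consumed as table columns; no parsing of
  quantum-chemistry program output.
- Reproducing a specific published campaign requires that campaign's
  descriptor table, split assignment, yield cutoff and steric settings; the
  package exposes all of these as explicit inputs rather than guessing.
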
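# Methods

This note documents the models, conventions and design choices behind each
module, what the synthetic-data generators do and do not emulate, and the
numerical details a user reproducing or extending the analyses will need.

## Ligand screening

Descriptors are computed with RDKit primitives under fixed conventions:

| descriptor | convention | default rule |
|---|---|---|
| hbd | O–H/N–H hydrogens (Lipinski count); switchable to donor heavy atoms | < 7 |
| hba | number of N and O atoms | < 12 |
| mw | average-atomic-weight mass, Da | < 600 |
| logp | Crippen atom contributions; vendor-supplied value overrides | < 7 |
| rotb | non-ring single bonds between non-terminal heavy atoms, amide C–N excluded (strict) | ≤ 8 |
| aromatic_rings | SSSR rings with all atoms aromatic (RDKit perception) | ≥ 3 |
| ring_count | SSSR size | ≥ 4 |

The donor count is hydrogen-based because that is the classic rule-of-five
reading; the heavy-atom alternative is a config switch since screening
pipelines disagree. The aromaticity model is recorded in the screen summary
metadata because perception models differ between toolkits. Whether a real
vendor library's precomputed properties or freshly computed ones feed the
filter is a user choice: molecules carrying a precomputed `DescriptorSet`
are judged on it verbatim.

All seven rules are evaluated without short-circuiting so that failure
attribution is complete. Energy triage sorts ascending (most negative
binding first) with a lexicographic tie-break on molecule id, making the
selection a pure function of the set; the optional energy window is
inclusive at both ends, the conservative reading of a reported selection
range.

## Pose and trajectory geometry

Distances use heavy atoms only: docked poses frequently lack hydrogens, so
hydrogen-dependent criteria would be undefined on typical inputs. Van der
Waals radii are Bondi values. Contact classification applies the most
specific qualifying type per atom pair (hbond 3.5 Å donor/acceptor
heavy-atom pair > π–π 5.5 Å centroid–centroid > π–alkyl 4.5 Å centroid to
aliphatic carbon > vdW within the radii sum + 0.5 Å). Hydrogen-bond
detection is distance-only by default; an angular criterion would require
hydrogens. Clashes use d < 0.7·(r₁+r₂), reported by penetration depth.

χ₁ is the signed dihedral N–CA–CB–γ via the atan2 formulation, range
(−180°, 180°], positive in the IUPAC sense. Rotamer bins are gauche−
[−120°, 0°), gauche+ [0°, 120°), trans elsewhere; occupancies are exact
frequencies and sum to 1 by construction. Circular mean and resultant
length come from the unit-vector average.

RMSD supports two modes because the appropriate treatment of rotation is a
genuine modeling choice: `center-only` removes translation only (centroid
subtraction), `full` additionally applies the Kabsch optimal rotation via
SVD with a determinant correction. Full-mode RMSD is never larger than
center-only; both are exposed and neither is asserted as "the" published
convention. Center-of-mass distances are mass-weighted with standard atomic
weights by default, with a geometric-centroid flag, and support tag-based
atom exclusion (e.g. dropping a biotin linker before comparing a parent and
a biotinylated pose).

Ensemble clustering of trajectory conformers is not reproduced; where a
representative frame is needed, the frame nearest the circular-mean χ₁ of
the dominant rotamer is a documented proxy.

PDB I/O goes through biotite (fixed-column, multi-model for trajectories);
a validation pre-pass reports malformed or non-finite coordinate fields
with their line number. Only multi-model PDB trajectories are supported —
binary MD formats are out of scope.

## Rhythm and decay kinetics

Detrending subtracts a centered moving average (default window 24 h) and
trims the unsupported half-window at each end. A full-period window leaves
a sinusoid scaled by 1 + 1/width, so at 10-minute sampling a 24 h rhythm is
preserved within 1 %; commercial rhythm software uses unpublished internal
detrending, so this transparent choice is the package's own.

The damped cosine `c + A·e^(−λt)·cos(2π(t−φ)/T)` is fit by bounded
nonlinear least squares; the period is seeded from a Lomb–Scargle
periodogram peak inside the search bounds, default [16, 40] h — the
circadian range. The phase is reported on the absolute time axis, folded
into [0, T), so shifting the time axis shifts the phase and nothing else.
Rhythmicity is an F-test of the 5-parameter cosine model against a constant
at α = 0.05; published plate-reader software defines no such criterion, so
this one is explicitly ours. Non-convergence is reported as non-rhythmic
rather than raised.

One-phase decay `(y₀−p)e^(−kt) + p` defaults to a free plateau (the named
three-parameter model); `plateau_mode="zero"` pins p = 0. Flat traces and
non-positive rate estimates return an unidentifiable flag instead of a
spurious half-life. Normalized half-life divides each treated t½ by the
mean control t½ of the same batch and reports mean ± SEM.

## Quantification rules

2^−ΔΔCT: ΔCT = CT_target − CT_reference within each sample, ΔΔCT subtracts
the mean calibrator ΔCT, fold = 2^−ΔΔCT, summarized as mean ± SEM per
condition. The fold is invariant to a constant added to both genes of the
same sample (the normalization the reference gene exists for), and the
calibrator's fold is exactly 1 whenever the calibrator is a single sample.

The AP-MS retention filter keeps proteins with bait spectral count > 5 and
control count < 5 in at least 2 of 3 experiments (all three thresholds
configurable). The printed description of such filters is sometimes
self-contradictory about direction; the implemented direction is fixed by
the positive-control protein, whose control counts are zero. The 2-of-3
default tolerates a single bait dropout, which a strict 3-of-3 flag
restores. A competitor/bait mean-count ratio is attached as competition
evidence (lower = more specifically displaced). Contaminant-repository fold
changes are not reimplemented — they depend on an external database.

## Non-compartmental PK

Linear (not log-linear) trapezoids throughout, matching the plain
"trapezoidal approach"; AUC₀₋t ends at the last observed timepoint.
Terminal k_el is −slope of the OLS fit of ln C on t over the terminal set.
The default `best_fit` rule searches all tails of ≥ 3 positive points
starting after Tmax and keeps the highest adjusted r², resolving ties
toward more points; when Cmax sits at the first positive observation (an
IV-like monotone profile) the peak itself belongs to the terminal phase and
is eligible. Leading zero concentrations contribute to the AUC; trailing
zeros are excluded from the regression (below-quantification-limit
handling). When no valid terminal fit exists, extrapolated quantities are
absent and the result is flagged rather than fabricated.

Kaplan–Meier and the log-rank test are delegated to lifelines (product-
limit estimator; hypergeometric-variance two-group test, χ² with 1 df).
The median is the smallest time with S(t) ≤ 0.5 and is reported as
undefined when the curve never reaches 0.5. Plain KM is implemented; no
age adjustment or regression modeling is attempted.

## Synthetic-data generators

Each generator owns one `numpy` Generator seeded per call — fixtures are
independently reproducible and byte-identical across runs — and stores its
realized ground truth, so recovery tests compare against labels, never
against re-derived values.

- **library** — draws from a built-in catalog of hand-verified scaffolds:
  ten pass-all tetracyclic aromatics plus one single-rule failer per filter
  rule, with counts hand-tallied and masses computed from molecular
  formulas with standard atomic weights. Pass-all picks receive 0–3 methyl
  decorations (mass truth shifts by 14.027 Da each; counts are unaffected
  and every decorated scaffold keeps a wide logP and mass margin). This
  emulates descriptor diversity, not real vendor chemistry.
- **pocket** — idealized TRP/ARG/SER residues (planar indole built from
  regular polygons; zigzag side chains) spaced on a 16 Å circle, each
  oriented so its contact feature faces the pocket center, with ligand
  probe atoms placed at the requested distances. Probe directions are
  chosen (e.g. a 25° tilt off the ring normal for π–alkyl) so no incidental
  contact of another type arises; unsatisfiable requests (π interactions on
  non-aromatic residues, distances beyond the type cutoff) raise a
  generation error. The default sampling times, radii and the residue
  numbering mirror a CRY-pocket fingerprint but the geometry is synthetic.
- **trajectory** — four atoms per residue (N, CA, CB, γ) at idealized bond
  lengths (1.46/1.53/1.52 Å) and tetrahedral angles; χ₁ is realized by
  rotating the γ atom about the CA–CB axis to angles drawn from a stated
  von Mises mixture (infinite concentration = delta). Per-frame rigid-body
  motion comes from a separate child generator, so toggling it cannot
  change the angle stream — the basis of the rigid-invariance tests.
- **luminescence / decay** — closed-form damped cosine (default 30-minute
  sampling over 5 days) and one-phase decay (default 10-minute sampling
  over 24 h) plus Gaussian noise; all parameters retained as truth.
- **pk** — one-compartment first-order absorption profile sampled at the
  in-vivo design timepoints (0, 0.5, 1, 2, 4, 8, 12, 24 h), with mean-one
  multiplicative lognormal noise (concentrations are positive and
  bioanalytical error is multiplicative). Equal absorption and elimination
  rates are rejected rather than handled by the flip-flop limiting form.
- **survival** — exponential event times at rate ln 2/median_ctrl (control)
  and hazard_ratio times that (treated), with administrative censoring.

What passing these tests shows — and does not. The generators realize the
statistical structure each analysis assumes (known rotamer mixtures, exact
damped cosines, mono-exponential tails, proportional hazards). Recovery at
the tested noise levels demonstrates correctness of the estimators, not
robustness to the pathologies of real data: real traces have non-Gaussian
artifacts and drifting baselines, real libraries have correlated
descriptors, real trajectories have correlated frames, and real cohorts
violate proportional hazards.

## Problem sizes and tolerances

Recovery runs use 1000-frame trajectories (κ = 20 at a −65° mean recovers
the circular mean within ±2°), 5-day traces at 30-minute sampling (period
within ±0.2 h at 5 % amplitude noise over 20 replicates), 24 h decay traces
at 10-minute sampling (rate within 5 % at 2 % noise), and the 8-point PK
design (k_el within 1 % noiseless). Log-rank calibration uses 2000 null
replicates at 50 subjects per arm (rejection rate 0.05 ± 0.02) and 500
replicates at hazard ratio 0.5 with 100 per arm for power. These sizes keep
the full suite and the acceptance script to a couple of minutes while
leaving the Monte-Carlo error well inside each tolerance.

## Known limitations

No docking, MD integration, force fields, conformer generation or pocket
detection; no binary trajectory formats; no compartmental PK models or Cox
regression; no contaminant-database lookups; no ANOVA machinery (fits
export cleanly to standard statistics tools). The rhythmicity criterion and
the detrending window are this package's documented choices, not clones of
any commercial analysis suite.
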
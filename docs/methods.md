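# Methods

`grekin` models the initiation step shared by glycyl radical enzymes (GRE):
reversible hydrogen-atom transfer between the stable glycyl radical (Gly829 in
benzylsuccinate synthase, BSS) and the active-site cysteine (Cys493), which
generates the catalytically active thiyl radical.  Because the cysteine
sulfhydryl proton exchanges freely with solvent, this shuttle also exchanges
the Cα hydrogen of the glycyl radical with solvent isotopes — the observable
the package quantifies.

## Rate model

Every elementary step is assigned a transition-state-theory rate

    k = κ · (kB·T / h) · exp(−ΔE‡ / R·T)

with κ = 1, T = 303 K by default, CODATA 2018 constants, and ΔE‡ a
Δ(E+thermal) barrier in kJ/mol (electronic energy difference plus scaled
harmonic vibrational correction).  Tunnelling is ignored; κ is exposed for
sensitivity scans only.  At 303 K the prefactor kB·T/h is 6.31×10¹² s⁻¹ and
every 5.8 kJ/mol of barrier costs one decade of rate, so barriers printed to
0.1 kJ/mol carry an irreducible ~4% rate uncertainty — the package's
comparisons against published rates use 5% (elementary) and 10% (composite
ratios) accordingly.

Kinetic isotope effects are pure barrier-difference ratios,
KIE = exp(ΔΔE‡/RT), referenced within each transfer block (same step kind and
face/position) to the all-protium step, so reference rows have iKIE = 1,
primary substitutions give iKIE > 1, and spectator (secondary) substitutions
at the rehybridising Cα can give inverse effects < 1.

### Vibrational corrections

The `thermo` module provides the rigid-rotor/harmonic-oscillator stage that
produces such barriers from Cartesian Hessians: mass-weighted normal-mode
analysis (negative curvature reported as negative wavenumbers; optional
Eckart-style projection of rigid translations/rotations), isotope
substitution by mass replacement on an isotope-independent Hessian, and
scaled zero-point plus thermal vibrational energies

    ZPE  = Σ NA·h·c·ν̃/2,
    Evib = Σ NA·h·c·ν̃ / (exp(h·c·ν̃/kB·T) − 1).

The harmonic scaling factor defaults to 0.9806 (the B3LYP/6-31G(d) value of
Scott and Radom) and is applied to both ZPE and thermal energy; whether the
thermal term should also be scaled is a genuinely open convention, so
`scale_evib=False` restricts scaling to the ZPE.  At 303 K the choice moves a
barrier by well under 0.1 kJ/mol for typical X–H frequency changes, below the
printing precision of the tables.  Rotational/translational thermal terms are
omitted because they cancel between a transition state and a minimum of the
same system.

## The exchange network

Six glycine states: radicals GlyH•/GlyD• and closed (sp³) states GlyH2,
R-GlyHD, S-GlyDH, GlyD2 (R-GlyHD carries H at pro-S and D at pro-R, S-GlyDH
the converse).  Additions transfer the solvent isotope from the sulfhydryl to
the *re* or *si* face of the planar radical; abstractions remove the pro-R or
pro-S substituent of a closed glycine.  The sulfhydryl isotope is slaved to
the solvent deuterium fraction f_D instantly (additions carrying D are
weighted f_D, those carrying H by 1−f_D; abstractions are irreversible with
respect to the removed isotope).  This instant-equilibration assumption is
the package default; a finite SH/SD exchange rate is outside the network's
state space and would require an explicit cysteine state.

Canonical Δ(E+thermal) barrier tables are embedded for three regimes —
substrate-bound (E:S), product-bound (E:P) and apoenzyme — 16 steps each.
Two conventions deserve note:

* Where the two published tabulations of the E:S barriers disagree
  (si-face H addition to GlyD•: 61.0 vs 61.5; S-side H abstraction from
  R-GlyHD: 95.6 vs 96.1), the values consistent with the printed elementary
  rates are used.  They are also thermodynamically consistent: with 61.0 and
  95.6 the forward/reverse barrier difference of that column equals the
  intermediate stabilisation (34.6 kJ/mol) exactly, which
  `detailed_balance_check` verifies.
* The product assigned to each addition is stored as explicit data, not
  derived from a face→enantiomer rule.  For GlyH• the geometric rule
  (si→pro-S) holds, but the published pathway analysis routes re-face H
  addition to GlyD• through the state it labels "R-GlyHD" and prices its
  reverse abstraction with the S-H barrier — an enantiomer-labelling
  inconsistency in the source that the package preserves as data, because the
  rate assignments (and hence every published constant) depend on it.

The apoenzyme si face is special: reaching it requires a conformational
change priced at 86.8 kJ/mol.  The published apo exchange constants derive
from the *unpenalised* barriers, so `apo_proS_penalty` defaults to 0; setting
it to 86.8 adds the penalty to apo si-face additions.  Without the penalty
the apo network would re-protonate a deuterated radical within seconds
through the nearly barrierless S-side abstraction (2.4 kJ/mol from the
high-lying apo intermediate); with it, the apo enzyme is inert on the hour
scale in both directions, which is the physically observed situation and the
regime used for the mixed holo/apo scenarios below.

## Observed exchange constants

Isotope exchange requires a two-step pathway: reversible addition of the
solvent isotope (k1, reversed by k−1) followed by irreversible abstraction of
the *other* substituent (k2).  Two pathways exist per direction (through the
R- or S-monodeuterated intermediate).  The observed constant defaults to

    k_obs = k1·k2 / (k1 + k−1 + k2),

the small-k_obs limit of the slow eigenvalue of the three-state system.  The
exact algebraic form used by the original analysis is not published; this
variant is the one that reproduces all published observed constants
(2 s⁻¹ and 2.1×10⁻⁴ s⁻¹ for E:S H→D, 1.6 s⁻¹ for E:P, 1.6×10⁻¹⁸ s⁻¹ for the
apo S-pathway), whereas the textbook pre-equilibrium flux form
k1·k2/(k−1+k2) gives 42 s⁻¹ for the E:S S-pathway.  Both, plus the exact slow
eigenvalue, are selectable (`variant=`), and CLI output records the variant.

**Accuracy of the default.**  With S = k1+k−1+k2 and q = k1·k2/S², the exact
slow eigenvalue is λ = S(1−√(1−4q))/2 (the discriminant is non-negative for
any non-negative rates).  Writing u = √(1−4q), the relative error of the
default is (λ−qS)/λ = (1−u)/2 = q·2/(1+u), i.e. bounded by **2q** and tight
at q→1/4 (k1=k2, k−1=0).  Tests assert this exact bound; q itself is *not* an
upper bound for any q > 0.  Numerically λ is evaluated in the
cancellation-free form 2k1k2/(S+√(S²−4k1k2)).

For the enzyme pathways q is usually ≪ 1; the two exceptions are the E:S
si pathway (q ≈ 0.044, default 4.7% below λ) and the E:P si pathway
(q ≈ 0.11, default 12.5% below λ).  Time-course simulations of an isolated
pathway therefore relax at λ, not at the default k_obs, and agree with k_obs
only to within that correction.

## Time-course simulation

`simulate_exchange` propagates the master equation dp/dt = K·p of any network
by eigendecomposition of the generator, p(t) = V·e^{Λt}·V⁻¹·p(0).  Rate
spans here reach 18 decades (10⁻¹⁸–10¹³ s⁻¹ within one apo network), where
scaling-and-squaring matrix exponentials overscale and corrupt the slow
eigenmodes; eigendecomposition resolves them exactly.  Safeguards: rates
below 10⁻²⁰ s⁻¹ are clamped to zero, eigenvalue real parts are clipped at
zero (a generator cannot grow), O(eps) negative populations are clamped and
the distribution renormalised, and a dense `expm` fallback covers defective
generators (the eigenbasis condition threshold is 10¹⁰).  Results are
reported on the caller's time grid; the solution is deterministic.

A physically important feature of the *full* network, absent from the
two-step scheme: the thiyl intermediate states lie ~32–34 kJ/mol *below* the
radical states in the holoenzyme, so the radical is sequestered into the
closed states by the fast conservative-exchange steps (equilibrium constant
~8×10⁵ toward R-GlyHD in pure D₂O).  The apparent relaxation of the radical's
isotopic composition in the full E:S network is therefore ~2.6×10⁻⁴ s⁻¹
(half-time ~45 min, matching the experimental "exchange complete within the
~1 h buffer change") rather than the isolated-pathway 2 s⁻¹.  The package
exposes both views: `three_state_network` for the isolated pathway the
published constants describe, and the full six-state network for the
sequestration-limited kinetics.  Note the two-step constants remain the
correct *pathway* comparison (their ratios are what the published analysis
reports); the full network adds the conservative-trapping prefactor common to
both pathways of a direction.

`mixed_population` forms convex combinations of holo and apo trajectories to
model samples in which a fraction f_apo of the enzyme has lost its bound
substrate/product; the inverse mode recovers f_apo from a target terminal
radical composition by closed-form projection (clipped to [0,1]).  With the
holo enzyme fully relaxed after ~1 h in H₂O and the (penalised) apo enzyme
frozen, a terminal 80:20 H:D composition implies f_apo ≈ 0.20 — the
"partial loss of bound ligands" reading of a partially reverted EPR spectrum.

Sequential product deuteration (d0→d1→d2 at C3 of benzylsuccinate) uses the
closed-form Bateman solution, with the k_a = k_b degenerate case handled by
the analytic limit c0·k·t·e^{−kt}.

## EPR read-out

The protiated glycyl radical shows a 1:1 doublet with 1.5 mT hyperfine
splitting from the single Cα protium at g ≈ 2.0034 (X-band, ~9.4 GHz,
centre field h·ν/(g·μB) ≈ 335 mT); deuteration divides the coupling by
γ_H/γ_D = 6.514 and turns it into a 1:1:1 triplet that is unresolved at a
0.5 mT peak-to-peak linewidth — the spectrum "collapses".  Spectra are
simulated as first-derivative Gaussian (default) or Lorentzian multiplets,
normalised to unit peak-to-peak amplitude; g-anisotropy is deliberately
reduced to g_iso, since the decomposition is agnostic to where basis spectra
come from (measured bases work identically).

A composite spectrum is decomposed by non-negative least squares onto the two
bases (linear interpolation onto the composite's field axis; the basis axes
must cover it).  Because bases are unit-amplitude, the normalised
coefficients are the amplitude fractions directly — e.g. coefficients
0.44:0.21 are 68:32.  Spin-count (integral) fractions weight each coefficient
by the double integral of its basis: the derivative signal is integrated once
(cumulative trapezoid), a linear baseline anchored at the axis ends is
removed — standard spin-quantitation practice; the original acquisition's
baseline treatment is unpublished — and the absorption is integrated again.
A wide doublet carries more spins per unit amplitude than a narrow singlet,
so amplitude and integral fractions genuinely differ (a published 68:32
amplitude ratio becoming 80:20 on integrals is this effect); since the
original linewidths are unpublished, the package treats the exact 80:20 value
as out of reach and asserts only the qualitative width–area relation.

## MS read-out

Deuterium at C3 shifts the benzylsuccinate [M-H]⁻ ion (C11H11O4, m/z 207) to
208/209, the same channels populated by natural ¹³C/²H/¹⁷O/¹⁸O satellites of
the lighter isotopologues.  `isotope_pattern` builds the natural-abundance
pattern by per-element convolution (abundances: ¹³C 1.07%, ²H 0.0115%,
¹⁷O 0.038%, ¹⁸O 0.205% — IUPAC representative values, versioned in the
module; the original analysis does not state its table, and plausible
alternatives move the M+1/M ratio by < 1% relative).  For C11H11O4 the
pattern gives M+1/M ≈ 0.122 and M+2/M ≈ 0.015.  `deconvolute_deuteration`
inverts the lower-triangular mixing system I(M+j) = Σ d_i·a_{j−i} by forward
substitution; small negative solutions are clamped to zero with a warning.
All m/z arithmetic is nominal-mass, matching the unit-resolution SIM/MRM
channels; fragment bookkeeping covers the H₂O (−18), HDO (−19) and CO₂ (−44)
neutral losses that identify C3 as the labelled position (e.g. 208−HDO→189
alongside 208−H₂O→190).

Specific activities follow amount(µM)·V_total(mL) → nmol, divided by the
assay duration and milligrams of extract protein (V_extract·c_protein); the
default assay is 1.0 mL total, 0.2 mL extract at 39 mg/mL, 240 min.  From
the printed inputs the d1 value reproduces 1.0 pmol·min⁻¹·mg⁻¹; the printed
d2 activity (0.3) sits ~25% above the closed-form 0.235 from its own printed
inputs (0.44 µM / 240 min / 7.8 mg) — the discrepancy is recorded as
irreconcilable from printed information and the package reports the
arithmetic value.  Whether the 40% D₂O content of that assay should rescale
the exchange rates is likewise unstated; rates passed to the Bateman model
are taken as effective observed rates.

## Synthetic data

Generators produce every input class the pipeline reads, each a pure
function of an explicitly seeded RNG (fixed seed ⇒ byte-identical output):
perturbed barrier tables (Gaussian σ in kJ/mol; σ=0 returns the canonical
table object-identically), composite EPR spectra (additive Gaussian noise,
RMS quoted relative to the noiseless composite's peak-to-peak amplitude),
SIM time series (Bateman kinetics × isotope pattern × calibration slope,
multiplicative log-normal noise — detector-like), and chain-of-springs
Hessians with analytically known modes.  The emulation is deliberately
idealised: no field drift, baseline wander or lineshape asymmetry in EPR, no
chromatographic tailing or detector saturation in MS, no anharmonicity in
the Hessians.  Passing recovery tests on these inputs therefore demonstrates
correctness of the estimators under the stated noise models, not robustness
to instrument artefacts.

Default recovery-study conditions: EPR mixtures at coefficients 0.44:0.21
with 1% RMS noise, 100 replicates; MS deconvolution at (10, 2, 0.5) µM with
1% multiplicative noise, 200 replicates; rate refits from 5–9 time points
over 240 min.  Problem sizes throughout (1024-point spectra, ≤6-state
networks, ≤1000 random rate triples) are chosen so every check is exact or
statistically stable; the whole suite runs in seconds.

## Known limitations

* Barriers are inputs; nothing is fitted to observed rates, and QM/MM or MD
  stages that produced them are out of scope.
* The sulfhydryl isotope is not a dynamic state (instant solvent
  equilibration); enzyme forms are fixed regimes per run — no binding or
  release kinetics connects E:S, E:P and apo within one simulation.
* Two published iKIEs (1.12 and 8.9) were evidently computed from unrounded
  barriers; from the 0.1 kJ/mol-rounded printed barriers they can only be
  matched to ~3.3–3.8%, slightly outside the 3% reproduction bound met by the
  other fourteen.
* EPR simulation is isotropic, single-nucleus and artifact-free; MS handling
  starts from channel intensities (no peak picking or vendor formats).
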
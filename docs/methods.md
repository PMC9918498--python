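# Methods

This note documents the models, numerical choices and limitations of
each `tightknot` component, in the spirit of a statistical package's
methods appendix. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Tight-binding titration kinetics (`tightknot.kinetics`)

**Model.** Fractional residual activity of an enzyme titrated by a
reversible tight-binding inhibitor follows the Morrison equilibrium

a = 1 − ( E + I + K − √((E + I + K)² − 4EI) ) / (2E),

the physical root of K·[EI] = (E − [EI])(I − [EI]) with E, I the *total*
enzyme and inhibitor concentrations. The implementation clips the result
to [0, 1] against floating-point undershoot. All concentrations are nM
internally; CSV inputs may declare µM (`inhibitor_uM`) and are converted
on read.

**Stoichiometric estimator.** The titration's descending limb is fitted
linearly and extrapolated to zero activity. Region selection is
objective: the longest prefix of grid points whose linear fit reaches
R² ≥ 0.99 with at least 4 points (both configurable). On coarse grids —
including the default simulation design of 0.25 µM steps against 515 nM
enzyme — *no* prefix reaches that bar, because only two to three grid
points precede the equivalence point; the estimator then falls back to
the first 4-point prefix and flags the result `rectilinear=False`. The
extrapolated x-intercept is intrinsically biased upward even on
noiseless dense data (the tangent at the origin crosses at E + K, and
least-squares chords of a convex curve cross higher still), so it is
reported as a diagnostic. When the total enzyme concentration is known —
the usual situation, e.g. 12 ng/µL trypsin at 23,300 Da ≈ 515 nM via
`molar_from_mass_conc` — the equivalence point is taken at that
concentration and the residual activity there is obtained by linear
interpolation of the replicate-averaged curve. From a_eq the species
concentrations follow: [E] = [I] = a_eq·E_t, [EI] = E_t − [E], and
K_D = [E][I]/[EI]; the identity holds exactly on every returned
estimate by construction. Degenerate titrations (a_eq ≤ 0 or ≥ 1) raise
an error rather than returning a meaningless constant.

**Uncertainty.** The standard error of the stoichiometric K_D is a
nonparametric bootstrap over replicates (default 200 resamples, seeded);
with a single replicate no SE is reported. The Morrison fit reports the
asymptotic SE from the curvature of the least-squares problem
(`scipy.optimize.curve_fit`); weighting by 1/max(a, 0.05) is available
to match a multiplicative error model but is off by default.

**Plateau detection.** `preincubation_plateau` returns the earliest time
from which every consecutive change and every deviation from the final
value stays below `tol` (default 0.02); the final point alone never
qualifies, and a series that is still moving returns the sentinel
`None`.

**Group comparison** is the classical unpaired equal-variance t-test
(`scipy.stats.ttest_ind`); two constant identical groups are rejected as
degenerate.

## Envelope deconvolution (`tightknot.massspec`)

Each ion of an electrospray envelope implies M = z·(m/z) − z·m_a with
m_a the adduct mass (default the proton, 1.007276 Da; the sodium adduct
22.989218 Da is bundled for MALDI interpretation). Ascending peaks are
assigned consecutive *descending* charges; all placements with z in
[z_min, z_max] (default [1, 30]) are scored by the sample variance of
the implied masses and the minimizer is kept. The assignment is accepted
only if the relative spread (SD/mean) is below 1% (configurable);
otherwise a "no consistent envelope" error is raised. Note that almost
any *two*-peak list whose m/z ratio is close to z/(z−1) for some z in
range is internally consistent — consistency is a meaningful filter only
from three peaks up. The reported mass is the unweighted mean across
peaks (intensity weighting available via a flag) and the spread is the
sample SD. A single peak deconvolves only when the charge is pinned
(z_min = z_max).

## Sequence physicochemistry (`tightknot.seqprops`)

**Masses** are sums over residue tables (average and monoisotopic) plus
one water (18.01528 / 18.010565 Da), making concatenation exactly
additive up to one water per bond — an invariant the property tests
exercise. `X` residues are rejected unless explicitly skipped.

**Isoelectric point** is the unique root of the net-charge function
(positive Henderson–Hasselbalch terms for the N-terminus, K, R, H;
negative for the C-terminus, D, E, C, Y) found by bisection on [0, 14]
to 1e-4 pH. The default pKa table is the Bjellqvist set used by the
ExPASy Compute pI tool, including its residue-specific terminal pKa
overrides (e.g. N-terminal Ala 7.59, C-terminal Glu 4.75); the table is
plain data and swappable. The independent cross-check in the tests is
Biopython's `IsoelectricPoint`, which implements the same set but
searches only within [4.05, 12] — extremely acidic or basic peptides are
therefore compared against a fine-grid scan oracle instead.

**PEST scoring.** Candidate windows are maximal stretches between
positively charged flanks (K/R/H) with a core of ≥ 12 residues
containing at least one P, one D/E and one S/T. The score is
0.55·DEPST − 0.5·HI, where DEPST is the mass-weighted percent of
D/E/P/S/T in the core after subtracting one equivalent each of the
lightest D-or-E, one P and the lightest S-or-T (so only enrichment
beyond the qualifying minimum counts), and HI is the mole-fraction
average of Kyte–Doolittle hydropathy rescaled to 0 (Arg) … 90 (Ile) via
10·(h + 4.5). Flanks delimit the window and are excluded from the scored
core (kept in the display string). Several published variants of this
procedure exist (mole-percent instead of mass-percent weighting, flank
included, no equivalent correction); they are all reachable through
keyword arguments, and the default above was fixed by calibrating
against a published score for a known N-terminal PEST window — the
variants differ by up to ~12 score units, so the choice matters and is
documented rather than silent.

**Identity** is computed from one optimal global alignment
(Needleman–Wunsch with affine gaps; BLOSUM62, open 10, extend 0.5 —
Biopython's `PairwiseAligner`) as 100·matches/columns, columns counted
including gap columns; a "shorter-sequence" denominator is available
since the literature is inconsistent. **Coverage** is the union of all
exact substring matches of each peptide, as a percent of protein length;
unmatched peptides warn and contribute zero. **Gel mass** interpolates
log10(mass) linearly in relative migration over the marker standards.
Gel-derived masses can disagree grossly with spectrometric masses for
acidic, SDS-underbinding proteins — the toolkit reports both and does
not reconcile them.

## Disulfide scaffolds (`tightknot.cysframe`)

Cysteine ordinals C1..Cn are assigned by order of appearance,
independent of residue numbering. The family registry stores: ICK
(C1–C4, C2–C5, C3–C6), Kunitz (C1–C6, C2–C4, C3–C5), Kazal (C1–C5,
C2–C4, C3–C6), the ten-cysteine colipase-like MIT1 fold (C1–C4, C2–C5,
C3–C7, C6–C9, C8–C10), HAND (six cysteines, connectivity unspecified —
count-screening only), and DDH. The DDH pattern as printed in the
scaffold literature, (C1–C2, C2–C4), reuses C2 and cannot be a valid
pairing; whether this is a typo for a standard pattern is unresolved, so
it is stored verbatim with a `valid=False` flag and excluded from exact
matching — recorded, not guessed. Classification is exact bond-set
match, else nearest valid template by Jaccard similarity with the
mismatching bonds listed and ties reported as ambiguous. Conserved
cysteine columns of an alignment require every non-gap symbol to be C
and a gap fraction at or below the (default zero) tolerance.

## Interface geometry (`tightknot.contacts`)

Structures are parsed and written with biotite's PDB support; a light
pre-scan reports the line number of a malformed coordinate before
parsing. Models typically lack hydrogens, so hydrogen-bond detection is
heavy-atom-only in the style of protein-interaction calculators: donors
are nitrogens plus template hydroxyl oxygens (OG, OG1, OH, water),
acceptors are oxygens plus His ring nitrogens, and a bond is any
cross-chain donor–acceptor pair within the cutoff (default 3.5 Å,
configurable; looser "weak interaction" distances up to ~6 Å can be
surveyed by raising it). No angular criterion is applied — without
hydrogens an angle term would be template-guesswork. Interface residues
are all cross-chain residue pairs with any-atom minimum distance within
the cutoff (default 4.0 Å), classified main/side by the closest atoms,
with optional flagging of user-supplied catalytic or specificity-pocket
residue numbers. Residue numbering follows the input file verbatim;
serine-protease numbering conventions differ between trypsin- and
chymotrypsin-based schemes and no renumbering is attempted. Candidate
reactive-site loops are coil segments (given a secondary-structure
string) or inter-cysteine segments (without one) containing at least one
Lys/Arg — a sequence-level proxy for surface-exposed substrate-like
loops; solvent accessibility is deliberately not computed.

## Synthetic data (`tightknot.synthetic`)

The generators emulate the assay and instrument outputs the analyses
consume, with known ground truth and one explicit seed each (no global
RNG state):

* **Titrations** apply multiplicative Gaussian noise,
  a·(1 + ε), ε ~ N(0, cv), clipped to [0, 1.05] — matching
  percent-of-control fluorescence readouts where slight super-control
  readings occur. Defaults are the study conditions this package was
  built around: K_D = 30.25 nM, E_t = 515 nM, grid 0–4 µM in 0.25 µM
  steps, cv = 0.02, triplicate.
* **Envelopes** place peaks at (M + z·m_a)/z with optional Gaussian m/z
  noise; no isotope structure, profile shape or chromatographic
  dimension is simulated.
* **Framework sequences** interleave prescribed-length random non-Cys
  spacers with the template's cysteines.
* **Toy complexes** realize each requested donor–acceptor pair at its
  exact distance in an isolated 25 Å cell, so constraints cannot
  interact; duplicate atom specifications are rejected as conflicting.

Passing round-trip tests on these fixtures demonstrates estimator
correctness under the stated error models; it does not demonstrate
robustness to the structure of real data (baseline drift, peak
interference, alignment ambiguity, crystallographic disorder).

## Pipeline (`tightknot.pipeline`, CLI)

A flat YAML config toggles the five stages and carries every numeric
default. Stage failures are caught per stage and recorded in the report;
provenance includes the package version, a config hash, input SHA-256
digests and the seed — no timestamps, so a fixed config and seed
reproduce a byte-identical report.

## Validation problem sizes

The recovery studies run 200 simulated titrations (17-point grid,
triplicate) for the noisy-recovery checks and a 5 nM-step grid for the
dense noiseless checks; envelope and geometry round trips use 2–4 peaks
and 1–3 atom pairs. These sizes make the full suite complete in well
under a minute while leaving the Monte Carlo means stable to well inside
the tolerances they are compared against.

## Known limitations

* The stoichiometric estimator needs the total enzyme concentration for
  unbiased results; from the titration alone the equivalence point is
  only recoverable up to the convexity bias described above.
* Envelope consistency filtering cannot reject two-peak lists whose
  ratio happens to match z/(z−1).
* The PEST score is calibrated to one published value; other PESTfind
  implementations may differ by their variant choices.
* Hydrogen-bond detection is distance-only and heavy-atom-only.
* The MALDI-style adduct interpreter subtracts adduct masses from a
  singly charged peak; it does not reconcile monoisotopic versus average
  mass conventions between instruments.
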
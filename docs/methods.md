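# Methods

## Hydrogen-bond model

A hydrogen bond is any donor–H···acceptor triple satisfying both geometric
criteria: d(H···A) ≤ 2.7 Å and a deviation of the D–H···A arrangement from
linearity of at most 30°.  Angular cutoffs are quoted under several
conventions in this field; we use the deviation-from-linearity cone
(accept when ∠(D,H,A) ≥ 150°), the standard geometric definition for a 30°
criterion, and expose both cutoffs in `HBondCriteria`.

Chemistry is element-based: donors are N/O heavy atoms carrying at least
one hydrogen of the same residue within 1.2 Å; acceptors are all N/O heavy
atoms.  Donors without a paired hydrogen are skipped with a logged warning
rather than an error, because heavy-atom-only trajectories are common; the
reader never synthesizes hydrogens.  One hydrogen may bond to several
acceptors; counts are counts of qualifying triples, not of hydrogens —
shared contacts of the flexible arginines are a real feature of this
binding site, and triple counting keeps them visible.  No periodic-boundary
handling is applied: inputs are assumed unwrapped.

Bond energies use the empirical exponential distance–energy relation
E = −502·10³·exp(−3.6·d) kJ/mol with d = d(H···A) in Å.  The relation was
fitted for H···O contacts; we apply it to every detected bond regardless of
acceptor element, matching how a single formula is applied to a whole
network, and both constants are configurable.  Note the published prefactor
makes individual short bonds worth ~90–130 kcal/mol, far above calorimetric
hydrogen-bond strengths; network totals computed here are therefore useful
as *relative* scores between variants, and the package validates the
arithmetic against closed forms rather than against absolute experimental
energies.  Signed sums are computed internally and reported as magnitudes
in kcal/mol (1 kcal = 4.184 kJ), matching the tabular convention.

The helix-network partition scores bonds with exactly one partner (donor or
acceptor heavy atom) inside the inclusive residue range 112–133 — the
second C-terminal helix — and the other outside it; intra-helix bonds are
excluded.  Per-frame analyses discard frames before an equilibration time
(default 10 ns).

## Mg²⁺ coordination and repulsive contacts

Classification uses the minimal distances dα, dβ, dγ of the ion to the
non-bridging phosphate-oxygen groups Oα = {O1A, O2A}, Oβ = {O1B, O2B},
Oγ = {O1G, O2G, O3G}.  Bridging oxygens (O3A, O3B) are excluded because
chelation and arginine contacts involve the non-bridging oxygens.  A frame
is first-sphere Oα/Oβ when dα and dβ are both within the first-sphere
cutoff, first-sphere Oβ/Oγ analogously; otherwise second-sphere when any
group distance is within the second-sphere cutoff; otherwise unbound.  The
cutoffs (2.6 Å and 5.0 Å) are not published values: they are chosen at the
bimodal split typical of direct Mg–O coordination (~2.0–2.1 Å) versus
water-bridged separation (~4 Å), and are configurable.  If both bidentate
patterns qualify simultaneously, the pair whose larger member distance is
smaller wins; the ambiguity is logged.  Second-sphere assignment is purely
distance-based — no explicit water bridge is verified, since water may be
absent from inputs.

Repulsive contacts count binding-site cationic side chains (Arg NE/NH1/NH2,
Lys NZ) within 4.5 Å of the ion, per residue by default (a residue counts
once) with a per-atom mode available, since typical counts of one or two contacts do
not disambiguate the convention.  The binding-site residue list defaults to
Arg/Lys with a listed atom within 8 Å of any ATP atom in the frame and can
be supplied explicitly.

## Replica statistics and the results table

Each independent run is reduced to its time average first; reported values
are the mean and the sample standard deviation (n−1 denominator) across run
means — three runs are treated as a sample of replicas.  Pooling frames
would weight runs by length and is deliberately not done.  Identical run
means short-circuit to an SD of exactly 0 to avoid float round-off through
the mean.  Energy totals are formed per run (component sum) before
cross-run summarizing, so the total summary is exactly consistent with the
component summaries, and the table invariant total = protein–ATP + helix
holds to machine precision.  The binding-energy penalty is
ΔE_HB = E_HB(mutant) − E_HB(wild type), defined only between tables at the
same coordination state.

## Free-energy estimators

**BAR.**  Sign convention: `forward` holds the work of the 0→1
perturbation, `backward` the work of the 1→0 perturbation, so identical
forward and backward sample lists correspond to ΔF = 0 exactly.  The
maximum-likelihood self-consistency equation (with the ln(n_f/n_r) offset)
is solved by geometric bracket expansion around the symmetric work midpoint
followed by Brent's method; the residual at the root is required to be
below 10⁻¹⁰ per sample.  The reported uncertainty is the inverse-Fisher
asymptotic standard error of the underlying logistic likelihood.  When the
work distributions do not overlap the residual plateaus at zero over a wide
interval and the root is meaningless; this is detected by vanishing Fisher
information and raised as a convergence error with an overlap diagnostic.
β defaults to 300 K in the unit of the work values.

**TI.**  Trapezoidal quadrature of per-window mean ∂H/∂λ on a strictly
increasing λ grid in [0, 1] (85 windows by default), after discarding the
first 100 ps of each 500 ps window.  The trapezoid is exact for affine
profiles on any grid; for curved profiles the error is O(h²) — on the
85-window grid a cubic of moderate curvature is reproduced to ~3·10⁻⁵
relative.  TI uncertainty is reported as the two-point sample SD of a
forward and a backward run, |a − b|/√2.

**Slice convergence.**  The estimator is re-run on time slices of the
per-window series (default 100–500, 100–300 and 300–500 ps, half-open).
Slices further apart than 3 combined standard errors raise a drift flag;
an empty slice produces an error entry without suppressing the others.

**Snapshot subsampling** retains the first frame at or beyond each grid
target start, start+stride, …; with frame times starting at 0, a 100 ns
trajectory at 100 ps spacing subsampled from 10 ns at a 100 ps stride
yields exactly the 900 snapshots of the standard endpoint-analysis
schedule.

## Synthetic data: what it emulates and what it does not

The site generator emulates only the *geometric observables* the analyses
consume: named ATP phosphate/nucleoside atoms, a Mg²⁺ ion placed by exact
triangulation to realize a requested coordination state, cationic side
chains at chosen distances from the ion, and donor–H–acceptor triples built
to exact d(H···A) and angular deviation with the donor–hydrogen distance
fixed at 1.0 Å.  Atom groups occupy grid cells ~8 Å apart so planted
contacts are the only contacts.  Default configurations carry nine
protein–ATP bonds (mirroring the named nucleoside-site interactions of
Arg92/Arg126/Glu83/Asp89) and five helix-network bonds, matching the ~9–10
and ~5 bond scales of the real site; the mutant configuration adds one
protein–ATP bond and removes one repulsive contact, reproducing the
qualitative wild-type/mutant contrast.  Frames receive independent
isotropic Gaussian jitter per atom (default study noise σ = 0.05 Å).

This construction has no stereochemistry, force field, water, periodic box
or kinetics, and jitter is uncorrelated across frames.  Passing tests
therefore demonstrate the correctness of the *measurement* layer
(detection, classification, scoring, statistics, estimators), not the
realism of any trajectory.  One quantitative consequence of the independent
per-atom jitter: the planted 1.0 Å donor–hydrogen distance fluctuates with
σ ≈ 0.07 Å against the 1.2 Å pairing cutoff, so ~0.2% of donor–hydrogen
pairs per frame drop out at σ = 0.05 Å.  Recovery under jitter is
accordingly scored per planted bond (≥ 99% recovered); exact whole-frame
recovery is asserted only for noiseless frames.  In constrained-bond MD
hydrogens ride their donors and this channel does not exist.

Work samples are drawn from the Gaussian pair W_f ~ N(ΔF + βσ²/2, σ²),
W_r ~ N(−ΔF + βσ²/2, σ²), which satisfies the Crooks fluctuation relation
exactly, giving BAR a known target (ΔF = μ_f − σ²/2 at β = 1) and an
analytic asymptotic standard error evaluated by quadrature of the Fisher
information.  ∂H/∂λ windows follow closed-form constant/linear/cubic
profiles with known integrals.

## Problem sizes and numerical choices

Validation runs use deliberately small inputs — 3–5 frame noiseless
trajectories, 200-frame jittered trajectories, 10⁵ work samples per
direction over 20 seeds, 85-window λ grids — chosen so the whole suite and
the reproduction script each complete in seconds while leaving the
statistical margins (3 standard errors, ≥ 99% recovery) meaningful.  All
generators are deterministic under a fixed seed.  PDB coordinates carry the
format's three decimals, so round-trips are exact to 10⁻³ Å; sample-series
round-trips through the package's own writer are bit-exact (shortest float
representation).  Frame times are not stored in PDB; the reader assigns
start + index·spacing with both configurable.

## Known limitations

Only multi-model PDB input is supported (no binary trajectory formats, no
topology parsing).  The Espinosa-type scoring ignores electrostatics,
van der Waals terms and entropy; it is a network-strength score, not a
binding free energy.  No MBAR, no autocorrelation/statistical-inefficiency
estimation, no water-mediated bond chains, no bond-lifetime analysis.
Published measured quantities that require the original trajectories
(absolute bond counts, MM-PBSA energies, the solvation ΔG curves) are out
of reach by construction; the package validates its arithmetic and
estimators against closed forms, oracles and planted ground truth instead.
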
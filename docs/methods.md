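# Methods

## Model

`arraymelt` treats a microarray feature as a local two-state equilibrium
P + T ⇌ PT in which the fragmented, labeled target — not the probe — is
the species that depletes. The hybridization efficiency E = [PT]/[T]₀ then
takes the logistic form

E(FA) = {P}₀K / (1 + {P}₀K),  K = exp(−(ΔG° + m·FA)/RT),

with the formamide concentration FA in % v/v entering the free energy
linearly through the m-value. Everything downstream (melting points,
specificity scores, curve fitting) is a function of this closed form. The
melting point on the formamide axis is the exact solution of
E(FA) = E(0)/2:

[FA]₁/₂ = RT·ln(2 + C)/m,  C = {P}₀·exp(−ΔG°/RT),

which is always positive and increases with duplex stability. A
documented non-feature: real profiles often *rise* over the first few
percent formamide before the plateau (a kinetic effect); the model does
not attempt to reproduce it, and the preprocessing masks those points
instead (see below).

## Free-energy rule system

Duplex free energy is assembled additively from table lookups:

- an initiation penalty ΔG°ᵢₙᵢ = 1.96 kcal/mol, held fixed because only
  the product exp(−ΔG°ᵢₙᵢ/RT)·{P}₀ is identifiable from melting data —
  {P}₀ is the member of the pair allowed to vary in fitting;
- one nearest-neighbor stack energy per adjacent pair of Watson-Crick
  paired probe bases (10 canonical stacks under strand-reversal
  equivalence);
- one internal-loop term per run of consecutive non-Watson-Crick columns:
  - a single mismatch uses the loop value of its canonical triplet
    (closing pair, mismatch pair, closing pair; 104 classes =
    (192−16)/2+16), or optionally the linear map α·ΔG°sln+β with
    (α, β) = (0.354, 0.487);
  - a tandem mismatch splits its quadruplet into two halves scored by
    closing-pair class (A:T vs G:C) × mismatch class (G·G, G·A, G·T,
    other) — eight rule cells — and sums them; the linear alternative
    (0.198, 1.167) takes a caller-supplied solution quadruplet value;
  - a bulged base looks up one of 64 contexts (bulged base × 16 flanking
    pair combinations, keyed along the bulge-carrying strand, a reading
    invariant under viewing the duplex from the other strand) on the
    solution scale and maps it to the array with slope 0.238. In the
    ΔΔG° bookkeeping relative to the unmodified probe, a deletion-type
    bulge replaces two nearest neighbors and an insertion-type bulge one;
  - runs with no table (three or more adjacent mismatches, multi-base
    bulges, terminal mismatches) fall back to the least destabilizing
    covered analog sharing the available closing pairs, applied per event,
    and the result carries an `extended` flag. Terminal-run fallbacks are
    clamped at ≥ 0 kcal/mol: dangling-end stabilization is deliberately
    outside this framework, so an unpaired terminal feature never lowers
    the energy.

Because the assembly is absolute (stacks plus loops), the total duplex
energy is invariant under swapping which strand is called "probe"; ΔΔG°
values quoted against a perfect-match reference use the probe-strand
stacks, consistent with composing `dg_perfect + Σ ΔΔG°`.

### Positional effects: relaxed ends

A mismatch near a terminus can cost more in loop penalty than the few
clamping stacks beyond it contribute. `minimize_conformation` therefore
evaluates, besides the imposed full duplex, every relaxation that unpairs
all probe bases from a mismatch/bulge feature to either terminus (and to
just before the feature), including simultaneous relaxation at both ends
when two features flank the duplex, and returns the minimum-energy state.
Ties prefer the less relaxed conformation. At least two paired bases (one
stack) are always retained.

## Shipped parameter tables

No experimentally fitted calibration for a specific array platform is
bundled; instead the package ships a **synthetic** parameter set
(`data/microarray_params_synthetic.toml`), generated deterministically by
`parameters.build_synthetic_params` and clearly labelled as such:

- array nearest-neighbor stacks are a damped linear image of the unified
  solution-scale values (0.25·ΔG°sln − 0.046), giving a mean stack of
  −0.40 kcal/mol so that a typical 22-mer melts near 20% formamide under
  the default globals — the regime the design workflow targets;
- mismatch loops combine a mismatch-class penalty (G·G most stable at
  +0.10, C·C least at +1.50), closing-pair adjustments (−0.20 per G:C,
  +0.10 per A:T) and a key-hashed jitter of ±0.15, spanning −0.30 to
  +1.85 kcal/mol; a solution-scale copy consistent with the (α, β) map is
  included so the linear mode runs end to end;
- bulge loops sit near +3.6 kcal/mol on the solution scale, so after the
  0.238 slope a bulge destabilizes like a moderate single mismatch;
- tandem half-scores range from +0.05 (G:C closing, G·G) to +1.00 (A:T
  closing, other).

Globals: m = 0.173 kcal/mol/%, log₁₀{P}₀ = −2.0, T = 315.15 K,
R = 0.00199 kcal/(mol·K), giving exp(−ΔG°ᵢₙᵢ/RT)·{P}₀ = 4.39·10⁻⁴.
Everything is replaceable through the TOML interface; the validator
enforces canonical, complete tables (10/104/64/8 keys).

## Preprocessing and calibration

Replicate reduction: with ≥3 replicates, a replicate more than three
standard deviations (of the remaining two) from the mean of the remaining
two is dropped (at most one per cell). The mean of the Nonsense control
probes is subtracted as background and its standard error folded into each
probe SD in quadrature. A cell with no surviving replicates becomes NaN,
not an error.

Probe filters before fitting: perfect matches need I_max ≥ 1000 a.u.,
mismatched probes ≥ 500 a.u.; mismatched probes losing more than half
their signal over the first formamide increment are dropped. Points left
of the profile maximum below 80% of I_max are masked (the kinetic rise).
The experimental half-denaturation point is the linear interpolation
between the two subsequent points bracketing I_max/2 right of the maximum.

The bi-level fit normalizes each profile by its I_max and matches
I/I_max = γ·E(ΔG°, FA). The outer level is trust-region nonlinear least
squares over (m, log₁₀{P}₀) (start (0.2, −2), relative cost tolerance
1e−8, at most 500 evaluations, box bounds m ∈ [1e−4, 2],
log₁₀{P}₀ ∈ [−12, 3]); the inner level solves each γ exactly,
γ = Σ(E·y)/Σ(E²) over the probe's fitted points. γ rescales vertically
only and cannot move a melting point. Reported statistics: Σr²/n, R²,
s² = Σr²/ν with ν = n − (fitted probes + global parameters) — each fitted
γ is charged to the degrees of freedom — mean squared prediction error on
a seeded random validation split scored with per-probe closed-form γ at
the optimum, and the signed/absolute melting-point errors
err[FA]₁/₂ = [FA]₁/₂,pred − [FA]₁/₂,exp. The split seed is recorded in the
result.

## Synthetic data generator

`synthdata.generate` emulates a formamide-series hybridization: a random
GC-54% gene (1542 nt), perfect-match probes of varied length (18–26 nt at
evenly spaced sites, 250 by default) to spread melting points over the
practical range, per-probe brightness log-uniform on 500–40,000 a.u.
(standing in for the positional amplification/labeling bias of fragmented
targets; fragment lengths 25–150 nt, mean 65, are the motivation but are
not simulated explicitly), replicate features (3), additive background
around 100 a.u. measured by a Nonsense probe, sparse multiplicative
outliers (rate 0.01), and a compressive saturation response above 40,000
capped at the 65,536 pixel ceiling. A tenfold concentration mode
multiplies brightness by 10 to push profiles into saturation.

Noise is homoscedastic on the normalized scale with SD 0.078 per
replicate-averaged data point (variance 0.0061); individual replicates are
drawn √3 wider so the averages have the quoted variance. What passing
recovery tests show, therefore, is that the calibration machinery inverts
*this* generative structure — sigmoidal truth, independent Gaussian noise,
well-behaved background. Real arrays add effects the generator omits
(sequence-dependent labeling bias correlated with stability, spatial
artifacts, probe-dependent kinetics, cross-hybridization between features),
so recovery here bounds algorithmic, not experimental, error.

## Design workflow

For each target site the probe length (18–26 nt) whose predicted melting
point falls in the prescribed window (default 18–22% formamide, closest to
center preferred) is selected; sites with no admissible length are
reported unmet. The working formamide concentration defaults to 15% —
a few points below the window, trading a little stringency for target
capture. Specificity is the predicted efficiency against each non-target's
best alignment site (semi-global alignment with substitutions and
single-base indels; no alignment within ⌊L/3⌋ edits counts as zero
efficiency); a candidate is specific when every non-target efficiency is
below 0.05. OTU presence is called from a probe panel by a pass-fraction
rule (default 0.9, i.e. 9 of 10 bright); the bright threshold for
simulated readouts defaults to 1750 fluorescence units and is
configurable.

## Numerical and scale choices

- The logistic is evaluated through `scipy.special.expit` on
  log({P}₀K); no overflow for any finite ΔG°/FA.
- Melting points use log-sum-exp (`logaddexp`) for ln(2 + C).
- Test and acceptance problem sizes — 250-probe synthetic experiments,
  400-conformation oracle sweeps, 1000-point bisection comparisons — keep
  the whole suite in a few seconds while exercising every code path; the
  generator scales to full tiling sets (1380 probes) when asked.
- Deterministic ordering everywhere: probes by start then name, table keys
  sorted, seeded RNG threaded through generation, fitting splits, and the
  CLI.

## Known limitations

- The shipped tables are synthetic: absolute predictions for real arrays
  require fitting the TOML tables to platform data with `bilevel_fit`.
- Only single-base bulges and ≤2-mismatch loops are table-backed; larger
  disruptions use the conservative fallback and are flagged.
- The low-formamide kinetic signal rise is masked, not modeled.
- In-solution parameter generation (hairpins, dangling ends) is out of
  scope; solution-scale inputs for the linear modes must be supplied.
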
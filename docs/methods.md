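# Methods

This package analyzes an engineered *Escherichia coli* "growth switch": a
strain (R) in which transcription of the *rpoBC* operon — encoding the β and
β′ subunits that limit core RNA-polymerase assembly — is driven by an
IPTG-inducible promoter. Adjusting the inducer concentration adjusts the β′
pool and thereby switches growth between zero and the maximal rate the
medium supports. The pipeline estimates growth rates from microplate
kinetics, reconstructs β′ concentrations from an mCherry fusion with
maturation correction, characterizes the dose–response (threshold bracket,
Michaelis–Menten above threshold, Hill ultrasensitivity), quantifies the
instantaneous glycerol production yield of growth-arrested producer strains,
computes the flux-balance theoretical maximum yield, and analyzes
single-cell lineages through an arrest/recovery cycle.

Because the underlying measurements are wet-lab experiments, the package
ships a mechanistic simulator that generates all inputs with the statistical
structure the analysis stages assume. The simulator is a calibration device,
not a mechanistic claim: it is the minimal ODE system reproducing the
documented phenomenology, with defaults calibrated to the published
quantities (maximal rates of 0.012 / 0.016 / 0.027 / 0.009 min⁻¹ for the
four media; a switching threshold between 20 and 30 µM IPTG; a Hill
coefficient near 10 for growth vs β′; a twofold yield gain on arrest).

## The simulator model

State variables: β′ pool `c` (arbitrary units, normalized so the growth
threshold `hill_K` = 1), immature and mature reporter `i`, `m`, biomass `B`
(background-corrected absorbance units), substrate `glc` and product `gly`
(g/L). With induction `u(I) = I^h / (I^h + K_iptg^h)` and promoter activity
`p = k_tx_max · u`:

    mu(c)   = mu_max · c^n / (c^n + K^n)                (n = 10, K = 1)
    dc/dt   = p − (mu + δ) · c
    di/dt   = p − (k_mat + mu + δ) · i
    dm/dt   = k_mat · i − (mu + δ) · m
    dB/dt   = Y_abs · min(mu·B/Y_abs, q_cap)            (0 once glc = 0)
    dglc/dt = −q
    dgly/dt = f_branch · (q − biomass-directed uptake)

where `q_cap = q_max · B · glc/(glc + K_glc)` is the Monod-limited uptake
capacity. Strains carrying the glycerol pathway (GPD1–GPP2 fusion) run
glycolysis at capacity (`q = q_cap`) and the uptake not invested in biomass
overflows to glycerol with branch fraction `f_branch = 0.6`; non-producing
strains take only their biomass demand plus a small maintenance uptake
(`q_maint = 0.002 g · (absorbance·L·min)⁻¹`). This split keeps carbon
conservation exact (glucose consumed ≥ biomass-attributed glucose +
glycerol) and reproduces both the sustained post-arrest consumption of the
producer strains and the absorbance plateau of arrested plate cultures.

Observation model: absorbance `A = B + A_bg` with multiplicative lognormal
noise (σ = 0.01, matching tight replicate bands), fluorescence
`F = φ·m·B + a_auto·A` with additive Gaussian noise and an autofluorescence
coefficient `a_auto = 2.5` RFU per absorbance unit. Samples every 2 min
(plates) or 30 min (shake-flask production assays).

Key calibration choices, made once:

- **Cooperative induction (h = 5, K_iptg = 36 µM).** A pure
  Michaelis–Menten induction term cannot place the switching threshold
  between adjacent tested levels 20 and 30 µM: at steady state the
  production `P(I)` must rise by a factor ≥ 2.9 between those levels for a
  Hill-10 growth law, while MM induction caps the ratio at 30/20 = 1.5. The
  effective cooperativity of lac-repressor induction (tetrameric LacI, dual
  operators) motivates the Hill form; `h = 1` recovers MM. With these
  defaults the bracket (20, 30) emerges from the analysis rather than being
  hard-coded anywhere.
- **Slow depletion δ = 0.002 min⁻¹** of the β′–mCherry pool (half-life
  ≈ 5.8 h; proteolysis of unassembled subunits plus leakage). Without it the
  carried-over pool freezes just below the growth threshold in arrested
  wells and reported β′ levels at low IPTG would not be negligible relative
  to induced levels, contrary to observation. δ is treated as a known
  constant and passed to the reconstruction.
- **Preculture carry-over c0 = k_tx_max/δ = 15.** Overnight precultures are
  stationary: dilution has stopped while synthesis continues, so the pool
  accumulates to the synthesis/depletion fixed point. This yields ≈ 3 h of
  preculture-fueled growth after dilution into unsupplemented medium, as
  observed.
- **Per-medium promoter activity `k_tx_max = 2.5 · mu_max · hill_K`,** so the
  fully induced steady-state pool sits ≈ 2× above the growth threshold in
  every medium (saturation bias on the measured rate < 10⁻⁵ min⁻¹). The
  empirically observed shift of the IPTG threshold with medium richness is
  *not* emulated; the threshold bracket is calibrated for the reference
  M9-glucose medium only.
- **Medium-dependent effective biomass yields** (0.45 / 0.75 / 1.8 / 0.40 g
  biomass per g substrate): in rich media most biomass carbon comes from
  amino acids rather than glucose; a single yield would violate carbon
  conservation in LB.
- **Production runs**: inoculum A0 = 0.0015 absorbance (OD600 ≈ 0.0035) and
  2 g/L glucose so the constitutive producer exhausts glucose shortly after
  the 450-min analysis window while the switched-off producer keeps
  consuming past 700 min; assay noise 0.005 g/L (coupled enzymatic assays
  with calibration).
- **Inoculum A0 = 0.0043 absorbance** for plates (OD600 0.01 with the 2.34
  plate-to-OD factor).
- mCherry maturation `k_mat = 0.028 min⁻¹` (≈ 25 min half-time; literature
  value for mCherry, config-overridable).

Numerics: LSODA with rtol 1e-8 / atol 1e-9; glucose exhaustion handled as a
terminal integration event followed by a starved phase (growth and uptake
off, gene-expression states continuing), which keeps the biomass equation's
indicator factor exact rather than smoothed. States are clipped at zero;
undershoot beyond tolerance aborts with a diagnostic. Per-well RNG streams
derive from `SeedSequence([seed, well_index])`, so identical (config, seed)
runs are byte-identical and different wells are independent.

## Analysis stages

**Growth rates** are ordinary least squares of ln(absorbance) on time —
equivalent to a nonlinear exponential fit on noise-free data, closed-form
and reproducible. The growing-regime window is 0.05 < A < 0.2
(background-corrected): below 0.05 the preculture polymerase still
dominates, above 0.2 oxygen transfer limits growth. The arrested-regime
window is t ≥ 1000 min, with negative slopes within one standard error
floored at zero. Wells are routed to a policy by whether their corrected
absorbance ever reaches 0.2. When noise causes brief boundary crossings,
the longest contiguous run inside the band is used. Replicates are
summarized as mean ± 2 SEM. Escape from arrest (stability assays) is called
when corrected absorbance crosses 0.1 after the arrest window with a
positive local slope over the trailing 120 min; the published data report
only escape counts, so the rule is this package's operationalization.

**Reporter quantification** works on the concentration proxy ρ = F/A after
subtracting the medium blank and an autofluorescence term a·A regressed
from an untagged control strain. The maturation balance gives the immature
pool ι = (dρ/dt + (µ+δ)·ρ)/k_mat, with dρ/dt from a smoothing spline, and
the total (maturation-corrected) concentration ρ_total = ρ + ι. At steady
state with δ = 0 this reduces to ρ·(1 + µ/k_mat) exactly. Steady-state
levels are medians over the same window used for the growth fit.

**Dose–response**: the threshold is reported as a bracket of adjacent
tested levels (never interpolated): the largest level below the arrest
cutoff (0.2 × maximum rate — the published two-category description states
no cutoff) followed by a level at ≥ half-maximal rate. Michaelis–Menten is
fitted on an (I − threshold) origin shift so the curve is zero at the
threshold. The Hill fit of rate vs β′ uses natural-scale least squares with
multi-start over the exponent (n ∈ {1,2,4,8,12,16}, bounds [1,20]) because
log-linearization is ill-conditioned near a switch; vmax is fitted freely
by default (the alternative of pinning it to the wild-type rate is exposed
as an option).

**Production yield**: Y(t) = −(dx_gly/dt)/(dx_glc/dt) from the analytic
derivatives of cubic smoothing splines. The smoothing parameter minimizes
the GCV score n·RSS/(n−df)² over a wide logarithmic grid, with df the trace
of the smoother matrix; selections with df > n/2 are excluded because the
GCV denominator degenerates near interpolation, which otherwise produces
wild derivative estimates exactly where consumption rates are small.
Evaluation windows default to 250–450 min (constitutive producer) and
250–700 min (switch strain); points where |dx_glc/dt| falls below 5% of its
in-window maximum are masked rather than divided through. Samples after
substrate exhaustion are dropped before fitting, since the kink there would
otherwise be smeared into the window by the smoothing penalty. Noise-free
data can be fitted with an explicit near-zero smoothing parameter; at 30-min
sampling note that even a central finite difference of an exponential with
k = 0.012 min⁻¹ carries a sinh(kh)/(kh) ≈ 2% truncation bias, so derivative
cross-checks use finer sampling. Biomass
normalization cancels algebraically in the ratio and is omitted. Replicate
profiles are averaged pointwise with 2-SEM bands on the intersection of
open masks.

**FBA**: linear programming (cobrapy, GLPK — the solver family used for the
original computation) maximizing the glycerol exchange flux subject to
S·v = 0 and bounds, with glucose exchange fixed at −1 mmol gDW⁻¹ h⁻¹,
non-growth-associated maintenance pinned at 6.75 mmol gDW⁻¹ h⁻¹,
growth-associated maintenance zero, and oxygen unconstrained. Mass yield
uses MW 92.09 (glycerol) and 180.16 (glucose) g/mol. The biomass flux is
left free by default (matching the stated constraint set literally); a flag
can pin it to zero. Unit tests run on a bundled 7-metabolite, 9-reaction
toy network whose optimum is hand-solvable (2 glycerol per glucose without
cofactor costs, mass yield 184.18/180.16 ≈ 1.0223; the default maintenance
diverts exactly half a triose, mass yield 0.7667). A genome-scale model
(e.g. iAF1260) can be supplied as SBML or COBRA JSON by path; it is not
bundled.

**Single-cell lineages**: divisions are called at frame-to-frame length
ratios < 0.7 (robust to ~10% length noise for symmetric division);
generations are maximal runs between divisions with first/last segments
censored. Elongation rates are OLS slopes of ln(length). The population
curve weights each generation's rate by the frames it contributes to each
30-min bin (the published weighting is not specified in the main text;
unweighted is available). Censored generations are included by default so
filamenting cells contribute during arrest. Decline/recovery lags are the
first bin centers after inducer removal/re-addition crossing 90% of the
pre-removal mean. In the simulator, division additionally requires the β′
pool to be above the growth threshold (c ≥ 1.0), which reproduces
filamentation during depletion and the ≈ 1–2 h recovery lag after
re-addition (division-protein pools must be rebuilt before cytokinesis
resumes).

## What the synthetic data do and do not show

The generator reproduces: preculture carry-over growth (~3 h), the sharp
IPTG threshold, Hill-10 coupling of growth to β′, maturation-lagged
fluorescence, medium-dependent maximal rates, arrest plateaus at low
absorbance, escaper kinetics, filamentation and recovery, and the
doubling of the instantaneous glycerol yield upon arrest. It does not
model: growth on post-glucose by-products (the observed biphasic growth;
deliberately omitted rather than guessed), the medium dependence of the
IPTG threshold, stochastic single-cell gene expression, spatial effects in
microfluidic channels, the mechanism of filamentation, or the slower,
more gradual growth-rate decline seen in the producer strain (the
single-pool washout arrests in ~2.5–3.5 h of culture time). Passing tests
therefore validate the estimators under the stated noise and sampling
structure, not the biology of any particular dataset.

Problem sizes used by the test suite and the reproduction script — five
replicate wells per condition, eight IPTG levels, six production
replicates, 100 cells at 10-min framing — are the published experimental
designs.

## Known limitations

- The threshold bracket calibration is specific to the reference medium.
- GCV smoothing is selected per curve; derivative-based yields remain the
  most noise-sensitive quantity in the pipeline (the max-over-window
  statistic is biased upward by residual derivative noise at low
  consumption rates — with default noise this bias is ≈ +5–15% on the
  yield ratio).
- The arrested-regime rate floor (zero below one standard error) means
  very slow residual growth (< ~5·10⁻⁵ min⁻¹) is reported as zero.
- Amount-level (rather than concentration-level) reporter deconvolution is
  mathematically equivalent but noisier and is not implemented.
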
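# Methods

## Study design being modelled

Each animal contributes a matched pair of uterine-horn samples — the
inseminated side carrying embryos and the contralateral non-inseminated side
carrying unfertilized oocytes — hybridized to one array each. With three
animals that is six arrays. Because both horns share one animal's hormonal
milieu, any expression difference is attributable to the local presence of
the embryo; the price is very small replication (n = 3 pairs), which shapes
several choices below.

## Synthetic expression data

`tlr4sim.synthetic` generates probe-level intensities as
2^(baseline + probe offset + animal effect + array effect + planted
log2FC·[inseminated] + noise). All random components are Gaussian on the
log2 scale: measurement noise (default SD 0.25), per-animal shifts (SD 0.2)
and per-array shifts (SD 0.1) chosen as typical magnitudes for two-channel
normalized single-dye array data; per-probe baseline offsets (SD 1.5)
spread probes across the intensity range so the lowess stage has support.
Planted effects are expressed as the log2 fold change of the inseminated
side, so a planted value of −1 makes the inseminated/non-inseminated ratio
0.5 for every probe of that gene. The default table size is 2,000 probes —
ample for the statistical properties tested while keeping the suite fast;
the generator accepts the full platform size (24,123) unchanged.

What the generator does *not* emulate: probe-sequence-specific affinity
biases, intensity-dependent (nonlinear) dye effects, spatial artefacts, and
correlated probe behaviour within a transcript beyond the shared gene
effect. Passing tests therefore demonstrate the statistical machinery under
the model's own assumptions, not robustness to platform artefacts.

Two read-only fixtures ship as packaged CSVs: the six published MAL probe
ratios (two probes × three animals) and the 20-row pathway scenario table
(species, base abundance, sensitivity, scenario multipliers/concentrations).

## Normalization and differential expression

Raw intensities are log2-transformed and each array is lowess-normalized
against a median pseudo-reference array on the (A, M) scale; the fitted
intensity-dependent bias is subtracted. The span defaults to 0.3 — a common
middle ground between tracking genuine intensity-dependent bias and
overfitting — since no span is dictated by the analysis being reproduced.

Each probe set is then fit with y = μ + treatment + probe + array + ε, the
array intercept random, by REML (statsmodels MixedLM), and the treatment
contrast (non-inseminated minus inseminated, "N − Y") is Wald-tested. Two
documented degenerate paths drop to ordinary least squares: a single-probe
probe set (one observation per array makes the array effect unidentifiable)
and an array-variance estimate collapsing to zero, which is common at
n = 3 arrays per group. The OLS path uses the t distribution with the
model's residual degrees of freedom; with six arrays and one probe that is
4 df, which is deliberately conservative — exact mixed-model small-sample
df corrections (Kenward–Roger style) are not implemented, and p-values from
the REML path use the Wald normal approximation. A vectorized OLS path
(`fit_single_probe_table`) computes the identical statistic for whole
tables of single-probe sets; equality with the per-set fit is tested.

Multiplicity is controlled family-wise by Bonferroni at α = 0.05 (the
analysis being reproduced used Bonferroni; no FDR alternative is offered).
Zero residual variance is flagged `degenerate` with p = 1 for a zero
contrast and p = 0 otherwise.

ΔΔCT quantification: ΔCT = CT(gene) − CT(β-actin) per group,
ΔΔCT = ΔCT(inseminated) − ΔCT(non-inseminated), fold change 2^(−ΔΔCT); the
orientation matches the down-regulation convention of the validation
experiments.

## Scenario construction

For each pathway species the (probe, animal) ratios inseminated /
non-inseminated are summarized as minimum, maximum and geometric mean. The
extremes are routed by the species' sensitivity sign: a positive-sensitivity
species contributes its maximum ratio to the maximum-response scenario and
its minimum to the minimum-response scenario; a negative-sensitivity
(inhibitory) species contributes them swapped, so the scenarios bound the
*response*, not the expression. The average-response scenario always takes
the geometric mean. Species with no mapped probe stay at multiplier 1.00
(inferred from the neutral TRIF and IRAK4 rows). Zero sensitivity is mapped
as positive with a warning; it does not occur in the shipped data.

Complexes have no transcript; assuming equilibrium with their constituents,
candidate ratios are products over constituents — all minima, all maxima,
all geometric means — routed by the complex's own sensitivity sign.
Multipliers are rounded to two decimals *before* being multiplied into
concentrations (and constituent extremes are rounded before the product);
this is the only convention that reproduces the published table cell-for-cell
(e.g. 10000 × 1.51 = 15100 and 9970 × 9.85 = 98204.5).

Two documented discrepancies in the source table are preserved rather than
smoothed over. First, the printed minimum of the six MAL ratios is 0.7956
(rounds to 0.80) but the table's maximum-response cell uses 0.74; the
fixture stores both, and computation from the raw ratios yields 0.80.
Second, the triple complex IRAK1_IRAK4_MyD88 follows the product rule only
in its minimum-response cell (8900 × 0.08 = 712); its printed max/avg
multipliers equal IRAK1's own. Both behaviours are available via
`triple_complex_rule=` ("product", the default, or "largest_constituent").

## The TLR4 network

The published full model behind the original analysis (76 species, 203
reactions) is not public in this codebase's sources, so `tlr4sim.network`
ships a reduced elementary mass-action network (~34 species) over exactly
the 20 scenario-table species plus explicit intermediates. Signal flow:
LPS binds CD14, acquires MD2, engages TLR4 into an active receptor; TRAM
engagement produces the signalling receptor while MAL competes for the same
receptor and sequesters it (a topology choice that gives MAL its net
inhibitory effect); the signalling receptor activates IRAK1 out of the
IRAK1–IRAK4–MyD88 complex and TRAF6 out of the RP1–TRIF–TRAF6 complex;
active TRAF6 → TAK1 → IKK; active IKK degrades IκB both free and in the
IκB·NF-κB complex, releasing and activating NF-κB; activated NF-κB drives
TNF synthesis and IκB resynthesis. Units are molecules per cell and
minutes throughout.

The IκB resynthesis feedback is promoter-mediated: NF-κB occupies a small
fixed pool of gene copies (2) whose occupancy saturates, so resequestration
capacity is bounded. This is the standard transcriptional mechanism and it
matters qualitatively: with bounded shut-off capacity, scenarios that
release more NF-κB produce *longer* as well as taller TNF responses, which
is the observed behaviour of the full model. Only IKK-activated NF-κB
transcribes, so an unstimulated system (LPS dose 0) produces no TNF at all.

Rate constants are a version-pinned default set (`DEFAULT_RATE_CONSTANTS`)
chosen once so that the base scenario yields a single transient TNF peak
within the default 360-minute horizon at the default LPS dose of 1,000
molecules/cell; none of these three numbers is dictated by the reproduced
analysis. Absolute peak heights and sensitivity magnitudes therefore carry
no meaning against the published values — only signs, rankings and
scenario orderings are asserted anywhere. An externally parameterized model
can be supplied through the same YAML/JSON schema
(`PathwayModel.from_yaml`) and run through the identical simulation,
sensitivity and comparison code.

Integration uses scipy's LSODA with rtol 1e-6 / atol 1e-8 by default
(1e-8/1e-10 inside the sensitivity analysis, where peaks are differenced);
states are clipped at zero inside the rate law and a post-hoc check rejects
trajectories more negative than 1e-6 of the solution scale. Peak height is
refined with a local quadratic through the three samples around the grid
maximum; the peak interval is the full width at half maximum of the
contiguous half-height interval containing the peak, with linearly
interpolated crossings ("peak interval" has no formal definition in the
source analysis; FWHM is this package's definition). A trajectory still
rising at the horizon is flagged non-transient and reports no FWHM.

## Sensitivity analysis

The coefficient is a forward finite difference at exactly +1 % — the
quantity's definition, not an approximation choice — normalized per 1 % so
other `delta` values remain comparable; a central-difference scheme is
available but non-default. Species with zero initial abundance are reported
not-applicable. Near-linearity (δ = 0.01 vs 0.005 within 10 %) and sign
stability under 10× tighter tolerances are tested. With the default
network the sign pattern matches the published table where the topology
promises it: IκB-α and MAL negative; TLR4, TRAF6, TAK1, IKK complex and
NF-κB positive; the IκB·NF-κB complex, IKK complex and TAK1 at the top of
the |s| ranking. The negative signs printed for TRIF and RP1 are not
promised by the reduced topology (they emerge from details of the full
model that are not public) and are not asserted.

## Pipeline and problem sizes

`run_pipeline` chains the stages deterministically from a single seed and
writes every intermediate table, the resolved configuration, and the
scenario comparison (peak ratio in percent of base, FWHM ratio in fold).
The scenario stage defaults to summaries recovered from the packaged
reference table (`summary_from_multipliers` inverts the sign-routing), so
the simulated scenarios are the published ones; ratio-derived construction
from an annotated intensity table is available through the library
(`ratios_from_table` → `build_scenario_table`).

Test problem sizes were chosen for statistical adequacy at interactive
runtimes: 2,000-probe tables, a 200-replicate × 1,000-probe null
simulation for family-wise error (binomial tolerance at that replication),
and an 11-probe-per-set layout for the power check, mirroring the actual
array's probe-set size.

## Known limitations

- The reduced network is a qualitative stand-in: it reproduces sign
  patterns and scenario orderings, not the published percentage changes in
  peak height or interval.
- Mixed-model p-values use Wald tests (normal for REML fits, t for the OLS
  fallback); small-sample df corrections are not implemented.
- The lowess reference scheme (median pseudo-array) and span are
  package choices; the original normalization details are unrecorded.
- No MAS5/RMA summarization, detection calls, or annotation enrichment;
  expression status enters through the synthetic generator or user tables.
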
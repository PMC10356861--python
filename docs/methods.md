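# Methods

## Tracer mass balance

The analysis treats every measured pool (whole-tissue biomass, extracted
nucleic acids, dissolved NH₄⁺ and NO₂⁻) as a two-component isotopic mixture
of natural-abundance background and labeled-substrate-derived atoms. With
atom fractions expressed in at% throughout (never fractions of 1), the
tracer-derived elemental amount is

n_tracer = n_total · (a_sample − a_ctrl) / (a_source − a_ctrl).

The source at% is computed from the composition of the label mixture by an
atom-weighted average: each molecular species contributes its labeled
positions at their isotopic purity and its remaining positions at natural
abundance. For the default equimolar ¹³C₂-taurine (99 at%) / ¹⁵N-taurine
(98 at%) mixture this gives 50.035 at% ¹³C and 49.183 at% ¹⁵N. Because every
pulse of the pulsed-addition design uses the same mixture, the source at% is
constant in time; unlabeled pulses, when present, dilute it via the
cumulative nominal additions.

Control values: measured unlabeled-substrate control explants take precedence
(their mean at% per element); when none are supplied the natural-abundance
constants 1.07 at% ¹³C and 0.366 at% ¹⁵N are used. Both constants are
overridable in the run configuration. Dissolved-pool attributions use the
natural-abundance constant for nitrogen, since control incubations carry no
measurable dissolved ¹⁵N enrichment.

Negative enrichment (sample at% below control) can arise from measurement
noise near natural abundance. The signed value is always computed; the
default policy clips it to zero for downstream per-weight amounts and rates
and logs a warning. Net ammonium release may legitimately be negative and is
reported signed with a warning.

Rates are end-point based: the total tracer-derived amount at the final
sampling time divided by the elapsed incubation time, matching a
single-interval 48-h design; no regression over intermediate time points is
attempted. Rates are computed per replicate first and summarized as
mean ± SE across explants (n = 3 by default). Amounts are carried in µmol
internally; conversion to nmol min⁻¹ g⁻¹ happens only at reporting.

## Incubation accounting

Net concentration changes subtract each vessel's own t = 0 value, which
absorbs carryover (e.g. residual sulfate leaching from tissue into
sulfate-free medium) without an external constant. Sponge-vessel signals are
additionally corrected by the mean net change of no-sponge control vessels of
the same treatment. Per-biomass normalization is conc × volume / wet weight;
the tissue-molarity conversion multiplies µmol g⁻¹ by an assumed tissue
density of 1.2 g wet weight per cm³ (µmol cm⁻³ ≡ mM). Sampling times are
matched exactly within ±0.01 h; no interpolation is performed. Hypothesis
testing across treatments is deliberately left to standard statistical
routines (scipy/statsmodels) and is not part of this package's surface.

## Abundance estimators

FISH densities divide each field's count by the field volume (ocular grid
area × optical section thickness, µm³ → cm³ with the exact factor 10⁻¹²) and
report the mean and SD of per-field densities rather than pooled counts over
pooled volume — the SD then retains its per-field meaning; the two estimators
coincide for uniform geometry and equal counts. Fields with a zero
general-probe count are excluded from the relative-fraction estimate with a
warning. qPCR copies g⁻¹ convert to copies cm⁻³ through the same 1.2 g cm⁻³
density. Read-recruitment relative abundance is mapped fragments over total
fragments.

## NSAF

NSAF divides each protein's spectral count by its length and normalizes to
the sample sum, so per-sample values sum to 1; replicate aggregation averages
per-sample NSAF (never pooled counts). Contaminant proteins remain in the
sample-level normalization by default — mirroring common NSAF practice of
normalizing over all identified proteins — but are reported as their own bin
and can be excluded, which rescales the remaining shares. Within-bin shares
renormalize a protein set against its bin's summed NSAF.

## The simulator

The generator emulates the batch design the analysis assumes: stirred 1-l
vessels, triplicate explants (wet weight ~ N(9.14 g, 2.4 g) truncated at
0.5 g), taurine pulses of 1 mM at t = 0 and 0.6 mM at 36 h (1.6 mM total),
48-h duration with sampling at 0/12/48 h, and three vessel groups — labeled
sponges, unlabeled-control sponges, and labeled no-sponge medium controls.

Dynamics are explicit-Euler with Δt = 0.05 h (≤ 0.1 h enforced). Per step:
uptake U = k·[taurine]·Δt (first-order default, k = 0.05 h⁻¹; a zero-order
mode and a configurable lag-onset hour, default 0, are available); biomass
gains f_C·2U carbon and f_N·U nitrogen; the dissimilated remainder releases
(1−f_N)·U ammonium and efficiency·U sulfate (taurine is C₂N₁S₁; dissimilated
carbon is respired and tracked but not resolved as CO₂); ammonia oxidation
converts min(rate·Δt, NH₄⁺) to nitrite at 3 µM h⁻¹ unless NH₄⁺ is at or
above the 100 µM substrate-inhibition threshold. A step that would drive any
pool negative raises an error suggesting a smaller Δt. Heavy-isotope atoms
are book-kept alongside every pool: pools produced from taurine inherit the
taurine pool's current at%, and nitrite inherits the ammonium pool's current
at% — the choice that keeps the ¹⁵N inventory exactly conserved when a
natural-abundance ammonium background exists (the two coincide at the default
zero initial NH₄⁺). Conservation of C, N, S and of labeled atoms holds to
floating-point accuracy in the noiseless state, which is retained as a
separate truth object.

Uptake is modeled per vessel, not per gram of explant, so true per-gram rates
vary across replicates with wet weight; the analysis equations cannot
distinguish host and symbiont compartments, and neither does the simulator.
`calibrated_labeled_experiment` calibrates f_C and f_N in closed form against the
drawn wet weights so that the replicate-mean true rates equal requested
targets (defaults 1.38 and 0.74 nmol min⁻¹ g⁻¹) — biomass gain is linear in
the assimilated fractions while total uptake is independent of them.

Explant elemental composition is not a measured quantity here; defaults of
5800 µmol C g⁻¹ and 1250 µmol N g⁻¹ wet weight (≈20% dry-mass fraction with
35% C and 7.5% N of dry mass, typical for demosponge tissue) put simulated
bulk enrichments at the ~1.1–1.2 at% ¹³C / ~0.5 at% ¹⁵N scale the analysis
is designed for.

Measurement noise is applied only to reported tables: multiplicative
Gaussian with CV 10% on concentrations and elemental totals (truncated at
zero; per-analyte overrides possible) and additive Gaussian with SD
0.001 at% on atom fractions (EA-IRMS precision scale, truncated to
[0, 100]). All randomness flows from one seeded generator, so identical
parameters give byte-identical output tables.

The fixture generators draw FISH field counts from a zero-truncated normal
(defaults 260.6 ± 73 per 146.25 × 146.25 × 1 µm field) with general-probe
counts scaled by a target:EUB ratio (default 0.24), and spectral-count
tables with uniform 50–2000 aa lengths, negative-binomial counts, and bin
labels assigned to realize a requested target-bin NSAF share (default
35.7%, within ~2 percentage points at ≥500 proteins).

What the simulator does *not* emulate — and hence what passing tests do not
demonstrate about real incubations: sorption of labeled substrate to tissue,
host (as opposed to symbiont) uptake, isotope fractionation, denitrification
or N₂O losses under hypoxia, DMSP co-metabolism, autocorrelated instrument
drift, and any kinetic structure beyond first-/zero-order uptake with an
optional lag. The kinetic constants are synthetic choices that qualitatively
reproduce the observed trajectory shapes (late sulfate acceleration, early
nitrite rise, nitrite decline once ammonium accumulates), not inferred
parameters.

## Numerical choices and degenerate inputs

Mixing attribution requires source at% strictly above control at%
(degenerate-denominator error otherwise); empty pools report the natural
abundance so attribution yields zero rather than 0/0; an all-zero
spectral-count sample and an empty normalization base are undefined and
raise; mixed-element sample/control pairs are type errors. SE across
replicates uses the n−1 denominator; a single replicate reports SE = NaN.
Simulation pool checks use a 10⁻⁹ µmol slack to tolerate rounding.

## Problem sizes

Default test and acceptance runs use 3 replicates per vessel group, 960–1920
Euler steps per vessel, 10-field FISH fixtures and 400–600-protein proteome
fixtures — sizes chosen to keep the full suite in the low seconds while
leaving all statistical checks well-powered.
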
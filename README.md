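# tauflux

Stable-isotope tracer mass balance for taurine metabolism in sponge
holobionts.

Marine sponges host dense microbial symbiont communities that process
dissolved metabolites such as taurine (2-aminoethanesulfonic acid, C₂H₇NO₃S).
In batch incubations of sponge explants with dual-labeled taurine
(¹³C₂-taurine + ¹⁵N-taurine), the fate of the substrate is read out from bulk
atom-fraction (at%) enrichments of biomass and dissolved nitrogen pools, from
dissolved sulfate, ammonium and nitrite time series, and from symbiont
abundance and metaproteome measurements. `tauflux` implements this analysis
as a tested, reusable pipeline, together with a seeded forward simulator of
the whole experiment so that every stage can be exercised — and its parameter
recovery verified — without any external data.

## The model

The amount of an element E ∈ {C, N} in a pool that derives from the labeled
substrate follows from a standard two-pool mixing model:

```
n_E,taurine = n_E,total · (a_E,sample − a_E,ctrl) / (a_E,taurine − a_E,ctrl)
```

where *a* is the heavy-isotope atom fraction (at%), *ctrl* an
unlabeled-substrate control, and the source term `a_E,taurine` is the
atom-weighted at% of the label mixture: for an equimolar ¹³C₂-taurine
(99 at%, 2 of 2 C labeled) + ¹⁵N-taurine (98 at%, 1 of 1 N) addition,

```
a_C,taurine = (2·99 + 2·1.07) / 4  = 50.04 at%
a_N,taurine = (98 + 0.366) / 2    = 49.18 at%
```

with 1.07 at% ¹³C and 0.366 at% ¹⁵N natural abundance. Net tracer-derived
ammonium release corrects both the NH₄⁺ and the NO₂⁻ pool (taurine-derived
ammonium already oxidized to nitrite by the ammonia-oxidizing symbiont) by
their no-sponge seawater controls:

```
n_NH4,released = (n_NH4,sponge − n_NH4,SW) + (n_NO2,sponge − n_NO2,SW)
```

Amounts are normalized to explant wet weight (µmol g⁻¹) and converted to
end-point assimilation rates (nmol min⁻¹ g⁻¹). Supporting modules cover
incubation accounting (net changes, control subtraction, the
1.2 g wet wt = 1 cm⁻³ tissue-molarity conversion), FISH cell densities from
ocular-grid field counts, qPCR copy numbers, read-recruitment fractions, and
NSAF (normalized spectral abundance factor) metaproteome shares,
NSAFᵢ = (SpCᵢ/Lᵢ) / Σⱼ(SpCⱼ/Lⱼ).

## Worked example

Simulate the pulsed labeling design (1 mM taurine at t = 0 plus 0.6 mM at
36 h, triplicate ~9 g explants in 1-l vessels, 10% CV measurement noise) and
run the analysis:

```sh
$ tauflux simulate -o demo --seed 1
$ tauflux analyze -i demo/incubation.tsv -a demo/atom_fractions.tsv -o demo/out
C rate: 1.79 ± 0.43 nmol min-1 g-1 (n=3); N rate: 0.88 ± 0.11 nmol min-1 g-1 (n=3)
```

The printed rates are the mean ± SE across the three explants of the
taurine-derived carbon and nitrogen assimilated into whole-holobiont biomass.
`demo/out/summary.json` additionally reports the source at% values used
(50.035 / 49.183), the net tracer-derived ammonium release and the net
sulfate production per gram wet weight; `demo/out/attributions.tsv` holds the
per-replicate attribution (µmol, µmol g⁻¹, nmol min⁻¹ g⁻¹). The noiseless
truth for the same run is written to `demo/truth.json`, so recovered and true
rates can be compared directly. In library code,
`tauflux.simulate.calibrated_labeled_experiment(seed)` produces the same design with
the assimilated fractions calibrated so that the true mean rates equal chosen
targets (defaults 1.38 and 0.74 nmol min⁻¹ g⁻¹).

Other subcommands: `tauflux abundance` (FISH densities, qPCR conversion),
`tauflux nsaf` (per-bin NSAF shares) and `tauflux report` (bundle the JSON
outputs).

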
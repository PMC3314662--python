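# tlr4sim

Tools for asking whether a pre-implantation embryo locally modulates the
maternal innate-immune system of the uterine horn, by chaining a paired-design
microarray analysis into a dynamic model of TLR4 → NF-κB → TNF signalling.

The experimental design it serves is a within-sow comparison: one uterine
horn is inseminated (embryos present), the contralateral horn receives
diluent only (oocytes present), and both horns are profiled on separate
arrays for each of three animals. The package provides, as a library and a
`tlr4sim` command-line tool:

1. **Synthetic paired-design expression data** with log-normal intensities,
   animal and array random effects, and planted treatment fold changes, plus
   packaged fixtures (the six published MAL probe ratios and the 20-row
   pathway scenario table).
2. **Differential expression**: per-array lowess normalization against a
   median pseudo-reference, then the per-probe-set linear mixed model

   *y<sub>ijk</sub>* = μ + *T<sub>i</sub>* + *P<sub>j</sub>* + *A<sub>k</sub>* + ε<sub>ijk</sub>

   (treatment and probe fixed effects, random array intercept), reporting the
   least-squares-mean treatment difference oriented N − Y and
   Bonferroni-adjusted p-values; plus comparative-CT (ΔΔCT) quantification
   for qPCR validation.
3. **Scenario construction**: per pathway species, the
   inseminated/non-inseminated probe ratios are summarized as (min, max,
   geometric mean) and routed into minimum-, average- and maximum-response
   abundance scenarios by the species' sensitivity sign; complex abundances
   follow the constituent-product rule.
4. **A mass-action ODE model of TLR4 signalling** (LPS → CD14/MD2/TLR4 →
   TRAM/MAL branch point → IRAK/TRAF6/TAK1/IKK cascade → IκB degradation →
   NF-κB release → TNF, with promoter-mediated IκB resynthesis as negative
   feedback), scenario-configurable initial abundances, and peak metrics
   (height, time to peak, FWHM).
5. **Sensitivity analysis**: for each species the coefficient
   *s* = 100 · (H(1.01·c₀) − H(c₀)) / H(c₀), i.e. the percentage change in
   peak TNF per 1 % increase in initial abundance.

## Worked example

```python
from tlr4sim import (mal_fixture, summarize_ratios, assign_scenarios,
                     build_default_network, simulate, peak_metrics)

summ = summarize_ratios(mal_fixture()["ratio"])
print(round(summ.max, 2), round(summ.geomean, 2))
# 1.51 1.08            <- extremes of the six MAL probe ratios

mult = assign_scenarios(summ, sensitivity=-1.16e-2)
print(10000 * mult.r_min_resp)
# 15100.0              <- MAL abundance in the minimum-response scenario:
#                         MAL inhibits the response, so its *maximum*
#                         expression ratio feeds the *minimum*-response case

tc = simulate(build_default_network())
m = peak_metrics(tc)
print(f"peak TNF {m.peak_height:.0f} molecules/cell at {m.time_to_peak:.0f} min,"
      f" FWHM {m.fwhm:.0f} min")
# peak TNF 116963 molecules/cell at 103 min, FWHM 106 min
```

The full pipeline (synthetic data → differential expression → scenarios →
simulation of all four scenarios → sensitivity → comparison table):

```sh
tlr4sim run-all --seed 3 --outdir runs/demo
```

writes `scenario_comparison.csv` with each scenario's peak height, FWHM, and
ratios against the base (oocyte-presence) run; with the default network the
peak ordering is min-response < base < avg-response < max-response and the
maximum-response peak interval is ~2.6× the base interval.

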
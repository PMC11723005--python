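# popgrowth

Growth analysis and early selection for clonal tree progeny trials.

Long-term progeny trials of vegetatively propagated trees — here
modelled on reciprocal poplar hybrids (*Populus deltoides* ×
*P. maximowiczii*, direct cross `DxM` and reciprocal `MxD`) measured
annually from age 2 to 18 — pose a chain of standard growth-and-yield
questions that this package answers in one coherent toolkit:

1. **Derived stem traits.** From annual DBH (cm) and height H (m):
   height–diameter ratio `HDR = H / DBH`, basal area
   `G = π·DBH²/4` (DBH in m), and stem volume `V = G · H · F` with a
   fixed breast-height form factor `F = 0.44`.
2. **Quantitative maturity age (QMA).** Mean annual increment
   `MAI(t) = V(t)/t` versus periodic annual increment
   `PAI(t) = V(t) − V(t−1)`; the age where the falling PAI curve
   meets MAI is the maximum-sustained-yield harvest age of a clone.
3. **Path analysis.** The correlation of each trait with volume is
   decomposed into a direct path coefficient
   `DPC_i = B_i·S_i/S_y` (standardized partial regression
   coefficient) and indirect paths `IPC_ij = r_ij·DPC_j` routed
   through the other traits, over pooled age windows
   (2–3, 4–6, …, 16–18) — identifying DBH as the best volume
   predictor.
4. **Early selection efficiency.** Age–age correlations `Rp` of DBH
   against a mature reference age (default 14) are scaled by the
   years saved, `ESE = Rp · t_e / t_l`, and the earliest run of ages
   with strong, significant correlations in both populations is the
   optimal early-selection window.
5. **Clone selection.** Survival-rate filtering (≥ 60 % of cuttings),
   ranking on mature clone-mean volume, selection of the top
   `floor(rate·n)` clones (minimum 1), and stability reporting via
   the volume coefficient of variation `CV = 100·sd/mean`.

Because per-tree data from such trials are rarely deposited, the
package ships a calibrated trial simulator (`synthetic_data`):
logistic DBH/height growth with per-clone random effects, additive
measurement noise and Bernoulli mortality, whose noise-free curves
provide an analytic QMA oracle for validating the detectors. The
published summary tables of the reference trial (survival counts,
mature trait means, age–age correlations) are included in
`popgrowth.datasets` as worked-example inputs.

## Worked example

```python
from popgrowth import (GrowthSimConfig, simulate_trial, derive_traits,
                       qma_table, age_age_table, optimal_window,
                       select_top_clones)

table, truth = simulate_trial(GrowthSimConfig(seed=1))
traits = derive_traits(table)            # HDR, basal area, volume

print(qma_table(traits).head(4).to_string(index=False))
rows = age_age_table(traits, late_age=14)
win = optimal_window(rows)
report = select_top_clones(traits, rate=0.25)
```

prints

```
clone_id  qma_age  volume_at_qma flag  crossing_interp
   DM-01       14       1.153876   OK        13.671315
   DM-02       14       0.752334   OK        13.414609
   DM-03       14       0.909210   OK        13.758541
   DM-04       15       1.118346   OK        14.128590
```

Each simulated clone reaches quantitative maturity around 13–15
years at roughly 0.8–1.2 m³ of stem volume — a 17-clone trial of
this scale should be harvested near age 14, and
`crossing_interp` gives the sub-year MAI/PAI crossing for
diagnostics. The age–age table shows the accuracy/time trade-off
(correlations rise with age while ESE falls):

```
cross_type  early_age  late_age     r  n  p_value stars   ese
       DxM          2        14 0.531 10    0.114    ns 3.720
       DxM          3        14 0.594 10    0.070    ns 2.774
       DxM          4        14 0.725 10    0.018     * 2.537
       DxM          5        14 0.636 10    0.048     * 1.782
```

and the selection stage reports
`selected 4/17: ['MD-02', 'MD-01', 'DM-06', 'DM-01']` with
population volume CVs of 23 % (DxM) and 27 % (MxD) against ≤ 4 % for
the selected clones — selection improves uniformity as well as yield.

The same chain is available from the shell:

```sh
popgrowth all --seed 1 --outdir run/
popgrowth ese --in run/traits.csv --late-age 14 --out ese.csv
```

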
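# platec50

IC50 estimation from 96-well plate screening assays.

`platec50` is for scientists running absorbance- or luminescence-based
proliferation assays (SRB, MTT and kin) who need inhibitory concentrations
computed reproducibly from raw plate-reader output. It parses plate files,
normalizes every well to percent inhibition against in-plate controls,
estimates IC50 three ways, attaches bootstrap confidence intervals, and
emits a report from which the entire analysis can be re-run.

## Plate layout

One row of the plate holds the controls: wells 1–9 contain untreated cells
(cell control, CC) and wells 10–12 contain medium without cells (CM). Every
other analyzed row holds one compound at 4 concentrations × 3 wells,
concentrations descending left to right. Percent inhibition of proliferation
for a treated well with absorbance $A_p$ is

$$IP = 100\left(1 - \frac{A_p - A_{cm}}{A_{cc} - A_{cm}}\right)$$

where $A_{cc}$ and $A_{cm}$ are the mean cell-control and medium-control
absorbances. IP is not clamped: negative values (growth stimulation) and
values above 100% propagate and are flagged.

## Estimators

* **Two-point** (Reed–Muench style): linear interpolation, in transformed
  coordinates, between the two adjacent triplicate-mean inhibitions
  bracketing 50%. Absolute IC50 only, no confidence interval, and it refuses
  (with an explicit reason) when no bracket exists, a bracketing mean is
  exactly 0%/100%, or a bracketing mean falls in the near-50% band
  (48–52% by default).
* **Linear regression**: ordinary least squares through the individual well
  points with 0 < IP < 100, on a log2/log5/log10/linear dose axis and a
  linear/probit/logit/log10 inhibition axis; reports r².
* **Nonlinear regression** (default): least-squares fit of the zero-baseline
  Hill curve $IP(C) = I_{max}\,C^h/(C^h + K^h)$ by Nelder–Mead, using all
  points; reports R² and $I_{max}$.

**Absolute** IC50 is the concentration giving 50% inhibition on the
control-defined scale ($C = K\,(50/(I_{max}-50))^{1/h}$, refused when
$I_{max} \le 50$). **Relative** IC50 is the concentration giving half the
compound's own maximal effect — exactly $K$ for the Hill fit. Regression
IC50s carry 95% CIs from a semi-parametric (residual-resampling) bootstrap,
and IC50s from repeated assays aggregate by geometric mean with a t-based CI.

## Worked example

```python
from platec50 import (AnalysisConfig, BootstrapConfig, HillParams, RowSpec,
                      analyze_plate, simulate_plate, single_row_truth)

# a synthetic plate with known truth: I_max=80%, h=1, K=10 ug/ml
truth = single_row_truth(HillParams(i_max=80, h=1, k=10),
                         noise_sd=0.02, seed=7)
plate, record = simulate_plate(truth)

config = AnalysisConfig(
    control_row="H",
    row_specs=(RowSpec(row="A", compound_name="compound-A",
                       doses=(1000.0, 100.0, 10.0, 1.0)),),
    method="nonlinear", ic50_type="relative",
    bootstrap=BootstrapConfig(n_replicates=1000, seed=1))
report = analyze_plate(plate, config)
est = report.compounds[0].estimate
print(f"relative IC50 = {est.value:.2f} ug/ml, "
      f"95% CI [{est.ci_95[0]:.2f}, {est.ci_95[1]:.2f}], "
      f"I_max = {est.i_max:.1f}%, R^2 = {est.gof:.4f}")
```

which prints

```
relative IC50 = 10.62 ug/ml, 95% CI [9.86, 11.49], I_max = 78.8%, R^2 = 0.9986
```

the fitted half-maximal concentration (truth 10), its bootstrap interval,
the fitted plateau (truth 80%) and the goodness of fit.

The same pipeline runs from a shell:

```
platec50 simulate --config truth.yaml --seed 7 --out plate.txt
platec50 convert --delimiter ';' --decimal auto export.csv plate.json
platec50 analyze --data plate.txt --config analysis.yaml --out-dir results/
```

`analyze` writes `report.json` (canonical, embeds the plate and config — the
analysis can be restored and repeated from it alone), `report.txt`, and one
dose-response plot per compound.

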
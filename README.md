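# vbpricing

Simplified **value-based pricing (VBP)** of high-tech medical devices, as
practised by regional health-technology-assessment (HTA) committees that must
set reimbursed prices for risk class IIb/III devices without the evidence base
a full cost-effectiveness analysis needs. The package is for HTA analysts and
health economists: it prices a cohort of devices from a short evidence table,
classifies the devices the model cannot price, and quantifies how well the
estimated prices agree with the prices actually paid.

## The model

For each new device, three parameters are extracted from its mini-HTA report:
the per-patient price of the current standard of care (SOC), the percent
relative improvement of the device on the primary clinical endpoint, and the
per-patient health-care cost delta (positive for a saving). The price is

```
VBP = P_SOC * (1 + I/100) + ΔC
```

where `I > 0` when the device improves the endpoint (`I < 0` if it worsens
it). When the benefit is a QALY gain `g` instead of a percentage, it is
monetised at a willingness-to-pay threshold `λ` (default 60 000 EUR/QALY, the
regionally recognised value) and enters additively: `VBP = P_SOC + ΔC + λ·g`.
The relative improvement derived from endpoint rates `r_new`, `r_soc` is
`100·(r_new − r_soc)/r_soc` for a higher-is-better endpoint and
`100·(r_soc − r_new)/r_soc` for a lower-is-better one.

A decision algorithm runs before the equation: a published full
cost-effectiveness analysis supplies the price directly; devices without an
adequate comparator, with an unvaluable benefit, or without comparative data
(and no committee-accepted supportive evidence) are classified as failures of
the simplified model; devices with supportive evidence only are priced at the
SOC price plus the cost delta (the 0%-improvement rule).

Cohort-level concordance between estimated VBPs and real prices is summarised
by Pearson's r with a Fisher z-transform confidence interval
(`tanh(arctanh r ∓ z_crit/√(n−3))`), a two-sided t-test with n−2 df, and the
ordinary-least-squares line of VBP on real price.

## Worked example

The package bundles `tuscany17.csv`, the 17-device cohort evaluated by the
Tuscany regional committee in the first semester of 2024 (see
`vbpricing.fixture_path()`; schema documented in `vbpricing/model.py`,
including the optional `supportive_evidence` column that records the
committee judgment enabling the 0%-improvement rule).

```bash
vbpricing report --cohort src/vbpricing/data/tuscany17.csv
```

prints (abridged):

```
  code  name                                          real price  status                             VBP
--------------------------------------------------------------------------------------------------------
   276  Flow Triever                                     8000.00  computed                       1402.81
   303  Hot Spaxus                                       5000.00  computed                      10674.00
   ...
   296  Tricvalve                                       24000.00  failed_no_comparator
   305  Cardiomems                                      12000.00  external_cea                   8475.00
   315  Neovasc Reducer                                  6350.00  computed                       3000.00

Priced 13/17 devices (4 failures, 23.5% failure rate)
Concordance over n=13 priced devices: r=0.929 (95% CI 0.7749 to 0.9790, p=4.41e-06); VBP = 0.9662 x real price -556.0396
WARNING: device 301: stated improvement 56% differs from rate-derived 56.4%; stated value used
WARNING: device 289: stated improvement 57.6% differs from rate-derived 54.7%; stated value used
```

Reading the output: 13 of the 17 devices could be priced (the other four lack
the data the simplified model needs and would go to a full economic
analysis); across the priced devices the estimated VBPs track the real prices
closely (r = 0.929, slope ≈ 0.97), i.e. the committee's empirically set
prices were close to value-based ones. Warnings flag devices whose stated
improvement percentage disagrees with the one derivable from the endpoint
rates; the stated value drives the price.

Other commands: `vbpricing evaluate` (per-device results CSV + JSON summary),
`vbpricing concordance` (statistics JSON, optional scatter plot),
`vbpricing simulate` (synthetic cohorts with known ground truth). The same
functionality is available as a library (`evaluate_cohort`,
`analyse_concordance`, `generate_cohort`, ...).

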
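# Methods

## The pricing model

The package implements the simplified added-therapeutic-value pricing rule
used for high-tech medical devices (risk class IIb/III): the value-based
price (VBP) anchors on the per-patient price of the standard of care (SOC),
scales it by the percent relative improvement on the primary clinical
endpoint, and adds the per-patient health-care cost delta,

    VBP = P_SOC * (1 + I/100) + ΔC .

Sign conventions: `I` is positive when the new device improves the endpoint
and negative when it worsens it (so a worse device prices below the SOC);
`ΔC` is positive when the new device saves non-device health-care cost.
When the clinical benefit is expressed as a QALY gain `g` rather than a
percentage, it is monetised at a willingness-to-pay threshold `λ` and enters
additively, `VBP = P_SOC·(1 + I/100) + ΔC + λ·g` with `I = 0` unless a
percentage is also stated. This is the only use of a willingness-to-pay
threshold in the model; everywhere else it is a plain cost-benefit rule.
The model deliberately ignores trial quality, device-acquisition cost
asymmetries, and committee discretion — it is a screening estimate, not a
substitute for a full cost-effectiveness analysis.

### Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `wtp_threshold` | EUR/QALY | 60 000 | regionally recognised threshold for innovative devices |
| `rounding` | — | two decimals | reported VBP only; internals stay at full precision |
| `ci_level` | — | 0.95 | concordance confidence level |

### The decision algorithm

Branches are evaluated in a fixed order; data-availability failures come
before any computation:

1. **external full CEA** — a published full cost-effectiveness VBP (in EUR)
   takes precedence over the simplified rule;
2. **no adequate comparator** → failure;
3. **unvaluable benefit** — a benefit is claimed but no data allow valuing
   it → failure;
4. **no comparative study and no quantified benefit** — with
   committee-accepted supportive evidence the device is priced at
   `P_SOC + ΔC` (the 0%-improvement rule); without it → failure;
5. otherwise the equation applies.

Whether "supportive evidence" exists is an explicit boolean input
(`supportive_evidence`), not inferred from other fields: it encodes a
committee judgment. Precedence among benefit representations: an external
CEA beats everything; a QALY gain is exclusive of endpoint rates and of a
stated percentage (their joint presence is a validation error); a stated
percentage beats the rate-derived one, and a disagreement beyond 0.1
percentage points (the printing precision of improvement values) is logged
and reported as a warning. A comparative study that quantifies no usable
benefit is priced at 0% improvement with a note. When several alternative
comparators are priced, the SOC price is their arithmetic mean unless the
worksheet documents the exact value used (an override field, which also
exists for the cost delta).

### Numerical choices and degenerate inputs

- The VBP is computed at full double precision; rounding (default: euro
  cents) applies to the reported value only.
- A zero SOC price (sham or no-treatment comparator) makes the percent term
  vanish; only QALY monetisation plus the cost delta can then price the
  device. A zero comparator *event rate* makes the relative improvement
  undefined; a stated percentage must be supplied.
- An empty CSV cell is "not available" and feeds the failure branches; an
  explicit 0 is a measured zero. Currency is EUR throughout; thousands
  separators are not accepted (strict dot-decimal, comma-separated CSV).

## Concordance analysis

Each priced device contributes a (real price, VBP) pair, in cohort order;
failures are excluded and fewer than three pairs is an error. Agreement is
summarised by Pearson's r (via `scipy.stats.pearsonr`), the Fisher
z-transform interval `tanh(arctanh r ∓ z_crit/√(n−3))` (implemented from
the closed form), the two-sided t-test `t = r√(n−2)/√(1−r²)` with n−2
degrees of freedom, and the ordinary-least-squares line of VBP (y) on real
price (x). The t-test is the conventional companion to Pearson's r; at very
small n it is anti-conservative relative to the exact permutation null
(whose smallest attainable two-sided p at n = 3 is 1/3), which the test
suite checks explicitly alongside a null-calibration simulation. The
correlation is reported both as r and r²: on the bundled cohort the
published headline value (0.929) is consistent with r, jointly with its
confidence interval and regression line, and the package surfaces both to
avoid the ambiguity.

### The bundled cohort and one preserved discrepancy

`tuscany17.csv` transcribes the published 17-device cohort cell-by-cell.
Two rows carry stated improvements that the endpoint rates do not reproduce
(devices 289 and 301); the stated values drive pricing, with warnings,
because the published VBPs follow from the stated percentages. Device 301
is a genuine discrepancy: its published VBP (22 800) does not follow from
its own row (14 640 × 1.56 = 22 838.4). The pipeline reports the formula
value; tests assert the difference explicitly (relative margin 0.2%) rather
than matching it silently. Consequently the concordance statistics exist in
two variants: on the pairs exactly as published, every printed statistic is
reproduced at printed precision; on the fully recomputed pairs the results
differ only within the margin that single row induces (slope 0.9662 vs
0.9653; intercept −556.0 vs −552.9).

## Synthetic cohorts

The generator emulates the structure the concordance analysis assumes:
prices and VBPs linked by a linear law `VBP = a·price + b` with additive
Gaussian scatter, a configurable fraction of unpriceable devices (split
across the three failure kinds), and occasional externally priced ones.

Per priced device, a SOC price, a relative improvement (endpoint direction
drawn uniformly, comparator rate bounded so the derived new-device rate
stays in [0, 100] and round-trips the improvement exactly) and an optional
saving are drawn; the real price is the noiseless inverse law of the
resulting structural VBP, truncated at zero; the Gaussian scatter is then
absorbed into the health-care cost delta so that the *computed* VBP equals
`a·price + b + ε` exactly. Placing the scatter on the VBP side of the
regression is a deliberate design choice: scatter on the price side would
make ordinary least squares inconsistent for `a` (errors-in-variables
attenuation, worsened by truncation at zero — a few percent at realistic
noise), whereas this construction keeps the generator–estimator pair
consistent, makes the noiseless limit exact (r = 1, slope and intercept
recovered to numerical precision), and attributes the noise to the
ingredient of the model that is least precisely measured in practice.

The `tuscany_like_scenario` preset fixes the study-like conditions: 17
devices, failure probability 4/17 split 2:1:1 across the failure kinds as
observed, one external-CEA device in 17, SOC prices uniform on
300–22 000 EUR, improvements uniform on 0–90%, savings of 800–1800 EUR with
probability 2/13, scatter sd 3000 EUR (the residual scale of the published
scatter), and the published line (a = 0.9653, b = −552.9477). A single
seeded `numpy` generator drives everything; identical seed and config give
bitwise-identical cohorts.

What the generator does *not* emulate: manufacturer pricing strategy,
committee discretion, heteroscedastic or heavy-tailed pricing errors,
QALY-driven synthetic devices, and correlation between failure status and
price level. Tests passing on synthetic cohorts therefore demonstrate
internal consistency of the pipeline and estimator, not external validity
on real pricing data.

Problem sizes used in the test suite: the recovery check runs 500
replicates of 200-device cohorts (chosen to make the Monte-Carlo error of
the mean slope ≈0.01%, far below the 1% consistency margin); property
suites use 1000 randomised cases each.

## Known limitations

- The model is a screening tool; its precision is bounded by the quality of
  the three inputs, which the package validates syntactically but cannot
  audit clinically.
- The Fisher interval and t-test are large-sample approximations; at n
  below ~10 the interval is approximate and the t-test anti-conservative.
- The 0%-improvement rule and the supportive-evidence flag encode committee
  judgments; the package records and applies them but cannot derive them.
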
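# toxvoi

Value-of-information (VOI) analysis for comparing chemical toxicity-testing
strategies.

Tens of thousands of chemicals in commerce have never been tested for
toxicity. When a regulator considers testing one before deciding whether to
mitigate exposure, three things trade off against each other: how much a
test **reduces uncertainty** about toxicity, how long it **delays** the
decision (during which health costs keep accruing), and what it **costs**.
`toxvoi` quantifies this trade-off with a preposterior Bayesian decision
analysis, for risk assessors, regulatory economists, and anyone designing or
prioritising toxicity-testing programmes.

## The model

Inter-individual tolerance and exposure are lognormal, so on the log10 dose
scale the population average risk has a probit closed form:

```
R = Φ((μ_exp − μ_tox) / √(σ_exp² + σ_tox²))
```

A mitigation cutting mean exposure by *k*% shifts `μ_exp` by
`log10(1 − k/100)`. Prior uncertainty about the locations `μ_tox`, `μ_exp`
is normal on the log10 scale, quoted in orders of magnitude (OM; an OM span
divided by 7.325 gives the normal sd). A test is characterised by the
posterior width it achieves; the conjugate normal update then fixes both the
implied observation noise and the preposterior distribution of the
posterior mean.

Costs are tracked in $M over a discounted multi-year horizon: an annual
control cost ramping exponentially from 0 at *k* = 0 to `ACC_max` at
*k* = 100, plus a health cost `N · B_y · V · R` per year. Two decision
makers act on this model:

* **TRDM** (target-risk): regulates when the 5th percentile of the risk
  distribution exceeds a target risk level (TRL), stands down when the 95th
  falls below it, and is otherwise undecided; regulation cuts exposure 90%.
* **BRDM** (benefit-risk): picks the mitigation level minimising expected
  total social cost; it always decides.

For each decision maker the package computes the full metric ladder:
EV|CI (baseline value under current information), EVIPI / EVIPPI (value of
perfect / partial-perfect information), EVISI / **EVDSI** (value of an
actual test without / with the delay its duration imposes), CoD (cost of
delay, EVISI − EVDSI), ENBS (EVDSI minus the cost of testing), ROI
(ENBS per dollar of testing), and preposterior decision probabilities.

## Worked example

Six presets pair a fatal outcome (lifetime risk, $8.8M per statistical
life) and an acute outcome (daily-risk airway event, $50 per case) with
three prior-uncertainty scenarios. Scenario 1 puts 7 OM of prior
uncertainty on toxicity and compares Test A (1 year, $5K, posterior width
4 OM) with Test B (5 years, $5M, 2 OM):

```
$ toxvoi run --preset fatal-s1 --dm brdm
scenario decision_maker      metric    test         value
fatal-s1           brdm       ev_ci    None  1.950497e+04
fatal-s1           brdm       evipi    None  1.161551e+04
fatal-s1           brdm         ore    None  7.300000e+01
fatal-s1           brdm       evisi       A  9.814161e+03
fatal-s1           brdm         cod       A  2.857883e+03
fatal-s1           brdm       evdsi       A  6.956278e+03
fatal-s1           brdm         roi       A  1.391255e+06
fatal-s1           brdm       evisi       B  1.126969e+04
fatal-s1           brdm         cod       B  1.353088e+04
fatal-s1           brdm       evdsi       B -2.261187e+03
fatal-s1           brdm         roi       B -4.532373e+02
...
```

Read: acting today, the benefit-risk decision maker would cut exposure by
73% (the ORE) at an expected total social cost of $19,505M (EV|CI). Perfect
toxicity information would be worth $11,616M. Test B's sharper result would
be worth more than Test A's if it arrived instantly (EVISI $11,270M vs
$9,814M), but its five-year delay costs $13,531M, so waiting for it
*destroys* $2,261M of value (negative EVDSI, ROI −453), while the fast,
cheap Test A nets $6,956M and an ROI of 1.39 million. Timeliness beats
sharpness here.

The same library surface is available in Python:

```python
import toxvoi as tv

result = tv.run_application("fatal-s1")
print(result.brdm.ore_prior)          # 73.0
print(result.brdm.tests["B"].roi)     # -453.2...
```

`toxvoi surface` maps EVDSI over testing time × uncertainty reduction, and
`toxvoi sweep` re-runs a scenario across values of one economic or policy
parameter (discount rate, maximum control cost, cost-curve steepness, TRL).

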
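# zoipanc

Zero-and-One-Inflated Poisson (ZOIP) regression pipeline for counts of
skilled antenatal care (SANC) visits.

## The problem

In household surveys from Bangladesh, many mothers report zero SANC visits
for their last birth, and many others stop after a single visit. A count
of visits therefore carries probability mass at 0 and at 1 far beyond what
a Poisson model implies, and Poisson or negative-binomial regression gives
distorted estimates. This package is for analysts of Demographic and
Health Survey (DHS)-style maternal-health data who need the full analysis
chain around such counts: covariate recoding, complete-case filtering,
descriptive and nonparametric screening, a formal test for simultaneous
zero/one inflation, the ZOIP regression itself, and trend contrasts for a
residence-by-survey-year interaction. Because the underlying survey
microdata are restricted-access, the package includes a synthetic
generator that emulates the pooled four-wave sample (2011, 2014, 2017-18,
2022; pooled n = 20,791) with known generating truth, so the whole
pipeline is testable end to end.

## The model

A ZOIP outcome is a three-component mixture: structural zeros with mass
φ₀, structural ones with mass φ₁, and a Poisson(λ) component with mass
φ₂ = 1 − φ₀ − φ₁:

    P(Y = 0) = φ₀ + φ₂ e^{−λ}
    P(Y = 1) = φ₁ + φ₂ λ e^{−λ}
    P(Y = y) = φ₂ λ^y e^{−λ} / y!,   y > 1

Covariates enter through a log link on the Poisson mean,
log λᵢ = xᵢᵀβ; the masses carry no covariates. A coefficient βⱼ is
reported as the **mean ratio** exp(βⱼ), the multiplicative change in λ per
unit change in xⱼ. The survey year is coded 1–4 and interacts with the
rural indicator, so the rural-vs-urban ratio in year t is
exp(β_rural + t·β_int) and the per-year trend is exp(β_year) (urban) or
exp(β_year + β_int) (rural), with delta-method standard errors and
log-scale 95% intervals.

Estimation maximises the full mixture likelihood by quasi-Newton search
with analytic gradients, with (φ₀, φ₁) kept inside the simplex by a
multinomial-logit transform; standard errors come from the observed
information. Before fitting, a partial score test checks for simultaneous
zero/one inflation against the Poisson null (χ² with 2 df, validated
against a parametric bootstrap).

## Worked example

```python
from zoipanc import (SyntheticConfig, generate_pooled_dataset,
                     build_design_matrix, fit_zoip, score_test_zero_one)
from zoipanc.fit import mean_ratio_frame
from zoipanc.trends import rural_urban_trend_table

records, truth = generate_pooled_dataset(SyntheticConfig(seed=1))
st = score_test_zero_one(records["sanc_visits"].to_numpy())
print(f"score test: statistic={st.statistic:.1f}, df={st.df}, p={st.p_value:.3g}")

fit = fit_zoip(build_design_matrix(records))
print(mean_ratio_frame(fit).round(3))
for c in rural_urban_trend_table(fit)[0]:
    print(f"{c.description}: ratio={c.ratio:.3f} "
          f"(95% CI {c.ci_low:.3f}-{c.ci_high:.3f})")
```

prints (abridged):

```
score test: statistic=7920.0, df=2, p=0
                       label  estimate    se  mean_ratio  p_value
            residence[rural]    -0.495 0.024       0.609      0.0
        maternal_edu[higher]     0.602 0.022       1.826      0.0
                 survey_year     0.031 0.007       1.032      0.0
survey_year:residence[rural]     0.110 0.008       1.116      0.0
                        phi0     0.169 0.003         NaN      0.0
                        phi1     0.011 0.003         NaN      0.0
rural vs urban, year code 1: ratio=0.680 (95% CI 0.659-0.702)
rural vs urban, year code 2: ratio=0.759 (95% CI 0.744-0.776)
rural vs urban, year code 3: ratio=0.848 (95% CI 0.831-0.866)
rural vs urban, year code 4: ratio=0.947 (95% CI 0.918-0.976)
```

The score test overwhelmingly rejects the plain Poisson null on the
synthetic pooled data (as expected: it was generated with 17.2% structural
zeros and 1.1% structural ones). The fit recovers the generating masses
(φ̂₀ = 0.169, φ̂₁ = 0.011) and the rural deficit shrinking over time: rural
mothers average 32% fewer visits than urban mothers at the first wave but
only 5% fewer by the fourth.

The same pipeline runs from the shell on any conforming CSV:

```sh
zoipanc simulate --out data.csv --truth truth.json --seed 1
zoipanc report --input data.csv --output-dir out/
```

which writes `table1.csv` … `table4.csv`, `fig1.csv`, `fig2.csv` and a
machine-readable `report.json`. Raw DHS-style extracts (five-level wealth
index, media-use frequencies, empowerment indicators) are accepted with
`--raw-mode`, which applies the documented recoding first.

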
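# svdose

Precision modelling of small-volume versus whole-kidney SPECT dosimetry.

## The problem

In molecular radiotherapy (e.g. [¹⁷⁷Lu]Lu-DOTATATE of neuroendocrine
tumours) the kidneys are the dose-limiting organ, and their absorbed dose
is estimated from quantitative SPECT images. Two estimates of the same
kidney dose are in common use: the mean dose over the segmented **whole
kidney parenchyma (WKP)**, and the mean dose inside one or more **small
spherical volumes (SVs)** (typically 2 ml or 0.6 ml) placed in the
parenchyma. SV doses are quick to obtain but noisy and systematically
biased; the WKP estimate is the reference but carries its own residual
noise from segmentation, partial-volume correction and sampling.

`svdose` is for physicists and dosimetrists who want to *quantify* that
trade-off: how fast does precision improve when k SVs are averaged, and
what is the best precision any SV strategy can reach?

## The model

Each kidney has a true dose D. Measurements are multiplicative
perturbations,

    D_WKP  = D (1 + ε_WKP),     D_SV,i = D · b (1 + ε_i),

with jointly Gaussian, possibly correlated noise (σ_SV, σ_WKP, ρ) and a
systematic SV bias b, estimated by the **normalization factor**
NF = mean(D_SV/D_WKP) over a stratum. The precision statistic is the
relative difference

    RD(k) = 100 · (SV_mean(k) − WKP) / WKP,

in which D cancels, so its spread measures pure measurement imprecision.
The empirical precision curve U(k) = sd(RD(k)) is modelled by the power
law

    U(k) = α · k^(−β) + γ,

where β = ½ is the ideal central-limit regime and the asymptote **γ** is
the residual relative imprecision of the WKP reference itself
(≈ 100·sd(ε_WKP)/D) — the best achievable precision no matter how many
SVs are averaged. Because patient dose tables are not public, the package
ships a synthetic-cohort generator calibrated to the observed study
design (18 patients × 2 kidneys, 5 SVs, two SV volumes, five Gaussian
post-filters) so every estimator is testable end to end.

## Worked example

```python
import svdose as sd

config = sd.default_config(seed=7)          # calibrated 18-patient design
records = sd.generate_cohort(config)
stratum = sd.split_strata(records)[(2.0, 0.0)]   # 2 ml SVs, unfiltered

nf = sd.normalization_factor(stratum)
print(f"NF = {nf.nf:.3f} +/- {nf.sem:.3f} (n={nf.n})")

normalized = sd.normalize_records(stratum, nf.nf)
curve = sd.precision_curve(normalized, [1, 2, 3, 4, 5])
print("U(k):", [f"{u:.2f}" for u in curve.u_percent])

fit = sd.fit_power_law(curve)
print(f"alpha={fit.alpha:.2f} beta={fit.beta:.2f} gamma={fit.gamma:.2f} R2={fit.r2:.4f}")
print(f"floor = {sd.asymptotic_floor(fit):.2f}%, U(100) = {sd.evaluate(fit, 100):.2f}%")
```

prints

```
NF = 1.122 +/- 0.009 (n=180)
U(k): ['11.33', '9.28', '8.50', '8.09', '7.92']
alpha=4.58 beta=0.87 gamma=6.75 R2=0.9996
floor = 6.75%, U(100) = 6.84%
```

Reading: the 2-ml SVs overestimate the WKP dose by 12.2% (the NF); a
single SV agrees with the WKP estimate to within ±11.3% (1 sd); averaging
five SVs improves that to ±7.9%; and the fitted power law (R² = 0.9996)
says precision plateaus at γ ≈ 6.8% — the imprecision of the WKP
reference itself, which no amount of SV averaging can beat.

The same pipeline is available from the shell:

```sh
svdose simulate --seed 42 --out cohort.csv
svdose analyze --in cohort.csv --volume 2.0 --filter 0 --kmax 5 --out curve.csv
svdose fit --in curve.csv --out fit.json
svdose report --in fit.json
```

```
alpha     3.896 %
beta      0.951
gamma     8.329 %   (asymptotic precision floor)
R^2      0.9993
U(100)    8.378 %   (extrapolated)
```

`cohort.csv` is a long-format dose table (one row per SV) that can also
hold real measurements; `analyze` then runs on them unchanged.

The power-law fit is a scikit-learn estimator
(`svdose.PowerLawDecay().fit(k, u)`), so it composes with sklearn
pipelines and model selection.

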
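# purist

Computational purification of bulk tumour mRNA abundance profiles.

Bulk tumour samples are mixtures of cancer and normal cells, so any
expression-based biomarker built on them reflects a blurred, composition-
dependent signal. `purist` estimates, for each tumour sample in a cohort
of one cancer subtype, (1) the fraction of cancer cells and (2) a
personalized, purified cancer expression profile — using only the bulk
tumour profiles and a panel of *unmatched* healthy-tissue profiles from
the same tissue. No paired normal sample, cell-type signatures, or known
proportions are required. It is aimed at bioinformaticians preprocessing
expression cohorts (microarray intensities or normalized RNA-seq gene
counts; linear scale, never log-transformed) ahead of biomarker or
survival analyses.

## Model

Patient *n*'s tumour profile decomposes as

```
t_n = alpha_n c_n + sum_r theta_{n,r} b_r + e_n ,   alpha_n + sum_r theta_{n,r} = 1
```

with cancer fraction `alpha_n`, personalized cancer profile `c_n`, and
healthy references `b_1..b_R`. Profiles are treated as probability
distributions over transcripts and the discretized tumour column `x_n` as
a multinomial draw from the mixture `xhat_n = B theta_n + alpha_n c_n`,
with Dirichlet priors tying the model together:

```
x_n     ~ Multinomial(depth_n, xhat_n)
theta_n ~ Dirichlet(nu)
c_n     ~ Dirichlet(kappa_n m)          # patients cluster around a shared profile m
m       ~ Dirichlet(kappa' B omega)     # the shared profile resembles healthy tissue
```

MAP estimation runs in two stages of block coordinate descent, each block
minimized by a conjugate-gradient routine with a Wolfe-Powell line search:
**CPE** (cancer profile estimation) fits the shared profile `m`, all
mixing weights (hence every `alpha_n`), and the hyper-parameters; **PPE**
(patient profile estimation) freezes each `alpha_n` and fits the
personalized `c_n`, reported both as probabilities and rescaled to the
intensity scale of the input (per-sample totals conserved). See
`docs/methods.md` for assumptions, reparametrizations, and limitations.

## Worked example

The package ships a seeded generator that draws ground-truthed cohorts
from the model's own generative process, so recovery can be measured
directly:

```python
import numpy as np
from purist import (FitOptions, generate, run_cpe, run_ppe,
                    score_recovery, to_probability_panel)

# a cohort drawn from the generative model at the reference conditions
tumour, healthy, truth = generate(G=2000, N=20, R=5, depth=10**6, seed=42)
panel = to_probability_panel(healthy)

opts = FitOptions(seed=42)
cpe = run_cpe(tumour, panel, opts)       # stage 1: fractions + shared profile
ppe = run_ppe(tumour, panel, cpe, opts)  # stage 2: per-patient profiles

print("sample      true alpha   estimated alpha")
for sid, a, ahat in list(zip(tumour.sample_ids, truth.alpha_true,
                             cpe.alphapurities))[:6]:
    print(f"{sid}    {a:10.3f} {ahat:17.3f}")

report = score_recovery(truth, cpe, ppe)
print(f"alpha MAE           {report.alpha_mae:.3f}")
print(f"alpha Spearman rho  {report.alpha_spearman:.3f}")
print(f"mean r(log c_n)     {report.logc_pearson_mean:.3f}")
```

Output (about 8 s on one CPU):

```
sample      true alpha   estimated alpha
tumour001         0.365             0.391
tumour002         0.459             0.492
tumour003         0.457             0.487
tumour004         0.862             0.922
tumour005         0.383             0.411
tumour006         0.468             0.502
alpha MAE           0.040
alpha Spearman rho  1.000
mean r(log c_n)     0.934
```

The estimated fractions track the truth closely in rank (Spearman rho
1.0) with a small systematic excess — the likelihood is exactly flat
along a direction that trades healthy signal into the shared cancer
profile while inflating all fractions, so the absolute level is set by
the priors (see the limitations section of `docs/methods.md`). The
per-patient purified profiles correlate with their true log profiles at
r = 0.93 on average.

### Command line

The same pipeline is available as a CLI over TSV/CSV matrices
(transcripts in rows, samples in columns, first column = transcript IDs):

```sh
purist simulate -G 2000 -N 20 -R 5 --depth 1000000 --seed 42 -o sim/
purist cpe --tumour sim/tumour.tsv --healthy sim/healthy.tsv --seed 42 -o cpe/
purist ppe --tumour sim/tumour.tsv --healthy sim/healthy.tsv \
           --cpe-dir cpe/ --seed 42 -o ppe/
purist score --truth-dir sim/ --cpe-dir cpe/ --ppe-dir ppe/
```

`cpe/alphapurities.tsv` holds one cancer fraction per sample;
`ppe/cancerprofiles.tsv` holds the purified profiles on the input
intensity scale, same shape and gene order as the tumour matrix. Each run
directory contains a JSON manifest (version, seed, config hash); reruns
with the same seed and configuration are byte-identical.

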
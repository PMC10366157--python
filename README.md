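# famagg

Familial aggregation and family-based heritability of food-intake
phenotypes from pedigree data.

Dietary habits cluster in families: spouses share a household, parents
shape what their children eat, and genetic variation influences food
preference. `famagg` quantifies both sides of that clustering for
epidemiologists working with family cohorts and food-frequency-questionnaire
(FFQ) phenotypes:

* **Familial aggregation** — intraclass/interclass correlations (ICCs) for
  every relative-pair class a pedigree defines (parent–offspring by sex,
  siblings by sex, spouses, grandparents, avuncular, half-siblings,
  cousins), with leave-one-family-out jackknife standard errors.
* **Family-based heritability** — a kinship-covariance mixed model fitted
  by a Gibbs sampler (Gaussian and probit-liability variants) and by
  profile maximum likelihood, with split Gelman–Rubin convergence checks.

Because individual-level cohort data of this kind are not public, the
package ships a first-class synthetic-data generator that emulates the
relevant pedigree envelope (families of 3–32 members, sibships of 1–6,
singletons, three-generation extensions) and FFQ-like phenotypes with known
generative parameters, so every stage has a recovery test.

## Model

For a prepared trait $y$ over $n$ pedigreed individuals,

$$y_i = \mu + \sum_k x_{ik}\beta_k + g_i + e_i, \qquad
g \sim N(0, \sigma_g^2 A), \quad e \sim N(0, \sigma_e^2 I)$$

where $A = 2\Phi$ is the additive relationship matrix (twice the kinship
matrix $\Phi$ computed from the pedigree by the recursive tabular method),
the fixed effects are age and sex, and heritability is
$h^2 = \sigma_g^2/(\sigma_g^2 + \sigma_e^2)$. Binary traits use the probit
liability link $P(y_i = 1) = \Phi(\eta_i)$ with $\sigma_e^2 \equiv 1$ and
$h^2$ reported on the liability scale. Phenotype preparation follows FFQ
practice: exclusion of implausible energy reporters (outside 800–4200
kcal/d), servings per 1000 kcal, food-group aggregation, age adjustment,
and rank-based inverse-normal (or Box–Cox) normalization.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort:

```sh
python analysis/01_simulate_cohort.py --families 600 --seed 1
python analysis/02_prepare_phenotypes.py
python analysis/03_familial_correlations.py
python analysis/04_heritability.py
```

which prints (abridged):

```
simulated 1956 individuals in 600 families
mean family size 3.26 (max 12)
true h2=0.25, couple c2=0.2, spousal r=0.25
energy filter: 1956 -> 1818 (138 excluded, 7.06%)

ICC by pair class (trait: intake):
  spouse           icc=+0.355 (se 0.043, n=446)*
  brother-sister   icc=+0.329 (se 0.053, n=205)*
  mother-son       icc=+0.251 (se 0.055, n=382)*
  ...
  grandparent      icc=+0.008 (se 0.059, n=260)

trait        h2 (%)  post. SD  ML h2 (%)   R-hat
intake        26.91    0.0423      23.74  1.0022
```

Spouses correlate most strongly (they share the couple environment, c² =
0.2, plus assortative mating r = 0.25), first-degree relatives correlate at
roughly half the genetic variance, and second-degree classes fall off
accordingly. The fitted h² of ~27% sits above the generative 25% because
the model has no household variance component, so shared environment is
partly absorbed into the genetic term — the standard caveat for
family-based (as opposed to twin- or genotype-based) heritability. The
Gelman–Rubin statistic below 1.03 indicates the two chains agree.

The same machinery is scriptable through the `famagg` CLI (`simulate`,
`correlate`, `heritability`, `describe`, `run`) or directly from Python;
see the docstrings in `src/famagg/`.

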
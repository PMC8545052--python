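# mythcast

Epidemiological analysis of COVID-19 **myth cascades** on Twitter: how fast
do specific myths ("eating garlic prevents infection", "5G spreads the
virus") propagate through the user population, who engages with them, and
what emotions do they evoke?

The package is aimed at computational social scientists and infodemiology
researchers. It provides, as composable library modules plus a CLI:

- a transcription of the 27 WHO-Mythbuster myths in five categories
  (Prevent, Spread, Detect, Treat, Misc) with their boolean keyword
  queries, and a matcher that labels archived tweets against them;
- per-category **cascades**: daily new tweets and daily new distinct users
  over an observation window;
- **SIR diffusion fitting**: the cumulative number of distinct posting
  users is identified with the infected-plus-recovered compartment of

  ```
  dS/dt = -β S I,    dI/dt = β S I - γ I,    dR/dt = γ I
  ```

  and (β, γ, and optionally the effective population n_eff) are estimated
  by Poisson maximum likelihood on daily new-user counts with Nelder–Mead.
  The basic reproduction number **R0 = β/γ** flags an *infodemic* when
  R0 > 1;
- topic tables (Porter-stemmed top-k terms per category, with an "other"
  bucket), engagement summaries (log-scale user metadata, reaction
  statistics, long-tail CCDFs and a Hill tail index), and six-class Ekman
  emotion-profile aggregation with a pluggable classifier interface;
- a **synthetic corpus generator** (chain-binomial stochastic SIR with
  known β, γ; catalog-matching texts; log-normal engagement; Dirichlet
  emotion vectors), used throughout the test suite as ground truth.

The raw tweet corpus behind such studies is typically not redistributable,
so every quantitative claim the package makes is validated by parameter
recovery on the synthetic generator.

## Worked example

Simulate one myth's diffusion with known rates, then recover them:

```python
from mythcast import simulate_chain_binomial, SIRDiffusionModel

gt = simulate_chain_binomial(beta=0.4, gamma=0.2, N=10_000, T=120, i0=10, seed=1)
model = SIRDiffusionModel(fix_n_eff=10_000).fit(gt.new_infections)
print(f"beta = {model.beta_:.3f}  gamma = {model.gamma_:.3f}")
print(f"R0 = {model.r0_:.3f}  infodemic = {model.infodemic_}")
```

prints

```
beta = 0.381  gamma = 0.179
R0 = 2.131  infodemic = True
```

The true R0 of the generator is β/γ = 2.0 (2.21 after accounting for its
day-discretization, see `docs/methods.md`); the fit recovers it from one
noisy realization of 8,449 posting users and correctly flags the myth as
an infodemic. When the susceptible pool is unknown, `fix_n_eff` may be
omitted and n_eff is fitted within bounds — but see the identifiability
warning in the methods note before interpreting R0 from a single completed
cascade.

The same pipeline runs end to end from the shell:

```sh
mythcast simulate --seed 1 --out demo/            # synthetic 5-category corpus
mythcast report --corpus demo/corpus.jsonl \
    --emotions-csv demo/emotions.csv --out demo/report/
```

`demo/report/summary.csv` then holds one row per category with tweet and
user counts, fitted (β, γ, n_eff), R0, the infodemic flag and convergence
status; alongside it are per-category cascade, fitted-curve, top-term,
engagement and emotion-summary CSVs.

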
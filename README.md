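# pairctmc

Continuous-time Markov chain analysis of leadership and following in pairs
of foraging fish.

When two fish forage together from the safety of cover, one of them — an
*initiator* — leaves first, and its partner may or may not join. Whether
leadership is just a passive consequence of temperament, or whether the
act of initiating itself changes how the pair behaves for the rest of the
trip, is a question about the *dynamics* of the pair, and `pairctmc` is a
toolkit for asking it quantitatively. It is aimed at behavioural
ecologists and biostatisticians working with timestamped leave/return
event logs of animal dyads.

## The model

The pair is a continuous-time Markov chain observed at exact event times.
Its state combines four binary variables: the location of the bold fish,
the location of the shy fish (bold/shy assigned by temperament score), the
identity of the most recent trip initiator, and whether the partner has
joined that trip. Feasibility rules (both out ⇒ joined; an unjoined solo
excursion belongs to the initiator) leave **12 states** connected by **24
single-mover transitions** with intensities q<sub>i,j</sub>.

The scientific questions become nested constraints on those intensities:

- **memory-free** (8 classes): rates depend on the two locations only —
  no social roles;
- **initiator-only** (16 classes): roles matter, recruitment success does
  not;
- **full** (24 classes): locations, initiator and joined flag all matter;
- **one-step memory** (8 states, 16 rates, non-nested): role effects
  persist over at most one change in location.

Fitting is exact-times maximum likelihood (closed form `events/exposure`
per class without covariates; L-BFGS on the log scale with them). Pair
temperament scores enter log-linearly on each transition
(β for the bold fish's score, σ for the shy fish's). Nested variants are
compared by likelihood-ratio tests, non-nested ones by AIC, and
uncertainty comes from a pair-resampling bootstrap. Initiation sequences
are summarised with Wald–Wolfowitz runs z-scores and exact binomial sign
tests. A Gillespie-style generator produces synthetic studies with known
truth so every stage is testable without field data.

## Worked example

```python
from pairctmc import (StudyConfig, make_study, fit_session_logs, lrt,
                      aic_compare, descriptives, initiation_runs_by_pair,
                      sign_binomial_test, bootstrap)

# a synthetic study: 20 pairs, two one-hour sessions each
ds = make_study(StudyConfig(n_pairs=20, sessions_per_pair=2,
                            session_minutes=60.0, seed=7))

full = fit_session_logs(ds.logs, "full")           # 24 per-minute intensities
mf   = fit_session_logs(ds.logs, "memory_free")    # locations only
res  = lrt(full, mf)
print(f"LRT full vs memory-free: chi2_{res.df} = {res.stat:.1f}")
print(f"Delta AIC = {aic_compare(full, mf):.1f}")

d = descriptives(ds.logs)
print(f"trips/h = {d['trips_per_hour_mean']:.1f} +/- {d['trips_per_hour_se']:.1f}")

runs = initiation_runs_by_pair(ds.logs)
neg, n = int((runs.runs_z < 0).sum()), int(runs.runs_z.notna().sum())
print(f"negative runs z: {neg}/{n}, sign test P = {sign_binomial_test(neg, n):.3f}")

def resoluteness(logs):   # bold's return rate when shy led vs when bold led
    f = fit_session_logs(logs, "full")
    return {"ratio": f.rates["q_10_12"] / f.rates["q_6_7"]}
br = bootstrap(ds.logs, resoluteness, B=200, seed=1)
print(f"q_10,12/q_6,7 = {br.point['ratio']:.2f}, "
      f"95% CI ({br.ci['ratio'][0]:.2f}, {br.ci['ratio'][1]:.2f}), "
      f"P = {br.pvalue('ratio'):.3f}")
```

prints

```
LRT full vs memory-free: chi2_16 = 413.7
Delta AIC = 381.7
trips/h = 54.6 +/- 0.7
negative runs z: 17/20, sign test P = 0.003
q_10,12/q_6,7 = 1.65, 95% CI (1.41, 1.90), P = 0.010
```

Read: the data (generated with role memory) decisively reject the
memory-free model (χ²₁₆ = 413.7); fish make ~54 trips per hour; 17 of 20
pairs show clumped initiation sequences — runs of consecutive initiations
by the same fish; and the bold fish returns to cover 1.65× faster during
trips its partner initiated than during its own (the initiator is more
resolute).

The same pipeline is scriptable from the shell:

```sh
pairctmc simulate --config config.json --out data/
pairctmc fit --logs data/events.csv --model full --out fits/full.json
pairctmc fit --logs data/events.csv --model memory_free --out fits/mf.json
pairctmc compare fits/full.json fits/mf.json --out fits/cmp.json
pairctmc report --logs data/events.csv --out report/
```

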
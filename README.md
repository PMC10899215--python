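# qaopnet

Quantitative adverse-outcome-pathway (qAOP) modeling of chronic toxicity
under repeated exposure.

Most quantitative AOP models describe a single exposure at increasing
doses. Chronic toxicity is different: the apical outcome emerges only
after repeated insults, at a repetition number that varies between donors.
`qaopnet` implements a complete proof-of-concept framework for this
setting, aimed at computational toxicologists who want to prototype
repeated-exposure qAOP analyses before in vitro data exist:

* a **virtual-data simulator** for a hypothetical 19-node pathway
  (2 MIEs, 8 biomarkers, 2 acute and 6 chronic key events, 1 adverse
  outcome) over 4 doses × 8 donors × 6 exposure repetitions, with
  dose-monotone acute responses, donor-specific chronic onset, and
  lognormal replicate noise driven by dose-to-dose jumps;
* a **replicate resampler** built on exact lognormal moment matching
  (μ_v = ln(f̄²/√(f̄²+s²)), o_vv = ln(1+s²/f̄²), cross-node correlation
  ρ√(o_vv o_v'v')) and conjugate Bayesian learning of the per-node
  linear-Gaussian conditionals on the pathway DAG;
* **per-exposure static Gaussian Bayesian networks** with dose as a
  continuous root: node-wise OLS conditionals, activation probabilities
  P(node > Δ | dose ∈ [d±ε]) by logic sampling, (Δ, dose) probability
  surfaces and their volume under the surface (VUS, trapezoid rule);
* a **non-stationary dynamic Bayesian network** over exposure slices
  (first-order Markov, no within-slice edges, slice-specific
  ridge-regularized coefficients with LOOCV penalty selection) that yields
  transition probabilities P(AO > Δ at e | KE > Δ at e−τ) by likelihood
  weighting over network-resampled trajectories;
* **data-driven pruning** of the lagged wiring: LOOCV lasso subset
  selection for multi-parent nodes, a p < 0.05 slope filter for
  single-parent nodes, reachability culling on the unrolled slice graph,
  and recomputation of the transition probabilities on the refit network.

The default activation threshold is the conventional Δ = log₁₀2 ≈ 0.301 in
log fold-change units; all analyses run on the natural-log scale of the
lognormal replicate model.

## Worked example

```python
import qaopnet as q

primary = q.generate_primary(q.StudyDesign(seed=1))   # ground-truth table
reps = q.simulate_replicates(primary)                 # replicate-level data

model = q.fit_dbn(reps)                               # slice-wise DBN
row = q.transition_probability(model, reps, "KE8", tau=1, e=5,
                               n_sims=100_000, seed=1)
print(f"P(AO>Δ at e=5 | KE8>Δ at e=4) = {row['prob']:.3f}")

gbn5 = q.fit_gbn(reps, 5)                             # static network at e=5
print({v: round(gbn5.node_r2[v], 2) for v in ("KE1", "KE2", "KE8", "AO")})
```

Output for this seed:

```
P(AO>Δ at e=5 | KE8>Δ at e=4) = 0.851
{'KE1': 0.89, 'KE2': 0.28, 'KE8': 0.95, 'AO': 0.85}
```

Activation of KE8 one repetition earlier is a strong proxy for the adverse
outcome (probability 0.85 here), and the static-network node fits separate
cleanly: acute KE1 and the chronic KE8/AO conditionals are tight, while
KE2 — a chronic event regulated by an acute upstream biomarker it barely
correlates with — is an information bottleneck (R² 0.28). Activation
probabilities show the onset pattern directly: with the same pipeline,
P(AO > Δ | d ≈ 100) is 0.008 at the first exposure and 0.596 at the fifth.

The same steps are available from the shell:

```sh
qaopnet simulate --seed 1 --out primary.csv
qaopnet resample --primary primary.csv --out replicates.csv
qaopnet dbn-fit --replicates replicates.csv --out dbn.json
qaopnet transit --model dbn.json --replicates replicates.csv \
    --ke KE8 --tau 1 --e 5 --out transitions.csv
qaopnet run-all --seed 1 --out run/        # full pipeline + manifest
```

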
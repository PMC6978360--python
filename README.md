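# oadiff

Order-of-acquisition diffusion analysis (OADA) for open-diffusion
social-learning experiments, built around the two-option ("lift"/"pull")
puzzle-box design used with wild primate groups: no trained demonstrator,
free interaction with the task, and fine-grained records of who manipulated,
who succeeded with which technique, and who was watching.

It is written for behavioural ecologists and social-learning researchers who
want to (1) detect and quantify social transmission of a novel foraging
technique from the *order* in which group members first succeed, (2) ask
whether transmission is option-specific or generalizes across techniques,
and (3) test "from whom" transmission biases (rank, sex, age, kin) by
partitioning the observation network into mutually exclusive pathways.

## The model

From the event log the package builds a **dynamic observation network**
o<sub>ijl</sub>(t): the number of times individual *i* watched individual
*j* succeed with option *l* before time *t*. A naive (individual, option)
pair (*i*, *l*) then acquires at relative rate

```
R_il(t) = [ Σ_k s_k · x_k(i, l, t) ] · exp(z_i' β_social)
          + exp(z_i' β_asocial + γ · solved_i(t) + δ · 1[l = pull])
```

where `x_k` is the cumulative observation count through network component
*k* — the option-specific (OS) component counts observations of *l* itself,
the cross-option (CO) component counts the other option, and bias analyses
use rank/sex/age/kin partitions instead — `s_k ≥ 0` is the social
transmission rate per observation relative to the asocial baseline (fixed at
1), `z_i` are standardized individual-level variables (sex, age, rank),
`γ` is the asocial boost once the individual has solved the other option and
`δ` an asocial option effect. The OADA likelihood is a partial likelihood
over risk sets: at each acquisition event, the probability that the observed
learner was the one to learn is its rate divided by the summed rate of all
still-naive pairs in the group; absolute times cancel.

Constraint hypotheses on the `s` parameters (free / equal / one pathway only
/ asocial), crossed with every subset of five asocial and three social ILV
effects, give 1056 models whose AICc Akaike weights are summed per
hypothesis; parameters are reported as full-model-averaged estimates with
profile-likelihood CIs. Dominance ranks for the rank ILV come from an I&SI
ordering of agonistic win/loss data with de Vries' h′ linearity test. A
generative simulator inverts the same rate model (continuous-time competing
exponential clocks, session slicing, per-event observer sets, ground-truth
pathway labels) so every stage can be validated without field data.

## Worked example

Simulate a study-scale experiment (groups of 28 and 12, option-specific
transmission s_OS = 0.25, 30× other-option asocial boost), rebuild the
dataset and network from the event log alone, and fit the OS-only model:

```python
from oadiff import synth, event_io, obs_networks, oada

config = synth.SimulationConfig()          # two groups (28 + 12), s_OS = 0.25
exp = synth.simulate(config, seed=42)

datasets = event_io.build_diffusion_dataset(exp.events, exp.roster)
networks = obs_networks.build_dynamic_network(exp.events, exp.roster)
components = {g: oada.os_co_components(networks[g]) for g in datasets}
data = oada.prepare_oada_data(list(datasets.values()), components)

spec = oada.OadaModelSpec(
    "c_os_only", (("OS", 0), ("CO", None)),
    asocial_ilvs=frozenset({"other_option_solved"}),
)
fit = oada.fit(spec, data, oada.FitConfig(n_starts=3, seed=0))
lo, hi = oada.profile_ci(fit, "s_OS", data)
```

This prints:

```
acquisition events: 47
s_OS = 0.222  (95% profile CI 0.016-1.784)
other-option asocial boost: x27.5
AICc = 280.2
% acquisitions via OS pathway: 32.9 (asocial 67.1)
```

i.e. from the acquisition order alone the fit recovers a per-observation
transmission rate near the generating value 0.25, a ~30-fold asocial boost
for an individual's second option, and attributes about a third of the
acquisitions to option-specific social transmission — close to the
simulator's own truth labels for this seed.

The same pipeline runs from the shell: `oadiff simulate`, `oadiff fit`,
`oadiff bias --bias rank`, `oadiff dominance`, `oadiff report`, with a YAML
run config and CSV/JSON outputs (hypothesis support, model-averaged
estimates, pathway percentages, sociogram edge list, preference and rate
tables, and a reproducibility manifest).

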
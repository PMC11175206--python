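# fedlatent

A single-process simulator for **clustered federated learning with VAE
latent signatures**. Clients never share raw data. Instead, each client
trains a small variational autoencoder (VAE) on its private dataset,
encodes the data into latent space, and sends the server a compact
*latent signature*: per-dimension histograms of the latent coordinates
plus a scalar latent variance, the sample count, and the number of label
classes present. The server then:

1. computes the pairwise **Jensen–Shannon divergence** (JSD, in nats)
   between all client signatures — exactly K(K−1)/2 evaluations;
2. **groups** clients by thresholding the divergence matrix and taking
   connected components, selecting each group's *head* as the member with
   the largest latent variance;
3. updates the global model each round by **two-level aggregation**:
   within each group, local models are combined with weights built from
   three ratios — data volume, label-class count, and latent variance —
   mixed by simplex coefficients (α, β, γ) with α + β + γ = 1; the group
   models are then averaged globally with weights of the same form.

A standard **FedAvg** baseline (sample-count weighting) is included for
comparison, along with synthetic federation generators (tabular Gaussian
blobs and simple images) with planted group structure and Dirichlet label
skew, so every claim in this repository is checkable offline and
deterministically from a single seed.

## Why clustered aggregation?

When client data is non-IID — different label mixes, shifted feature
distributions, different sizes — plain FedAvg averages away the structure.
If the federation actually consists of a few latent *groups* of similar
clients, grouping first and weighting by data volume, label diversity, and
latent spread yields aggregation weights that respect that structure,
while the only information leaving a client is a low-dimensional histogram.

## Worked example

Nine clients in three planted groups, tabular features, three classes:

```python
import fedlatent as fl

cfg = fl.ExperimentConfig(
    rounds=10,
    method="proposed",
    model=fl.ModelSpec(kind="dnn", input_shape=(8,), num_classes=3,
                       hidden_width=64),
    client=fl.ClientConfig(learning_rate=0.01, batch_size=32),
    synthetic=fl.SyntheticSpec(num_clients=9, num_groups=3, num_classes=3),
    seed=7,
)
result = fl.run_experiment(cfg)
print(result.threshold, result.assignment.groups, result.assignment.heads)
```

This run suggests a JSD threshold of **0.0866 nats** from the divergence
matrix, recovers the three planted groups exactly —
`[[0, 3, 6], [1, 4, 7], [2, 5, 8]]` with heads `[0, 7, 8]` — and the global
model improves over the rounds:

```
round  0  loss 0.6901  accuracy 0.894
round  3  loss 0.4394  accuracy 0.986
round  6  loss 0.2974  accuracy 0.986
round  9  loss 0.2163  accuracy 0.982
```

The FedAvg baseline on the same federation and seed finishes at loss
0.2096, accuracy 0.986 — on this easy, well-separated synthetic task both
methods learn well; the value of the proposed pipeline here is the
recovered group structure and the audited, interpretable weights
(`result.audits` records every client and group weight per round).

The same pipeline is available from the command line:

```bash
fedlatent generate  --seed 1 --out runs/fed
fedlatent signatures --data runs/fed --out runs/sigs
fedlatent group     --signatures runs/sigs --out runs/groups
fedlatent train     --seed 1 --method proposed --out runs/proposed
fedlatent report    --run runs/proposed
```

## Reproduction

All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (data, model init, shared VAE init,
per-client VAE and training streams); the derived seeds are saved with
every run. To reproduce the headline quantities:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This writes (among others, at seed 1): the hand-checkable divergences
JSD((1,0),(0,1)) = 0.693147 nats and JSD((0.8,0.2),(0.5,0.5)) = 0.050672
nats; a maximum deviation of 0 between the proposed aggregation (single
group, α=1) and FedAvg over 5 rounds; perfect planted-group recovery
(mean adjusted Rand index 1.0 over 10 seeds); and final test accuracy
1.000 for both methods on the 20-round end-to-end task against a
majority-class baseline of 0.362.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and limitations.
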
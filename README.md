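# pairdistill

Pairwise and independent-model distillation for generative protein sequence
models.

## The problem

Generative models trained on a multiple sequence alignment (MSA) of a
protein family — autoregressive models, variational autoencoders — define a
distribution p(s) over aligned sequences s = (s₁, …, s_N) with q = 21
symbols (20 amino acids + gap).  Viewed as energy-based models with
E(s) = −log p(s), they may contain interactions of every order.  How much of
what they learn is actually *pairwise*?  This package answers that by
distilling: it fits a Potts model

    E_pw(s) = − Σ_{i<j} J_ij(s_i, s_j) − Σ_i h_i(s_i) − C

(or an independent/profile model, J ≡ 0) that minimizes the mean squared
energy error under a chosen sequence distribution D,

    L(J, h, C) = E_{s∼D} [ (E^M(s) − E_pw(s))² ],

where E^M is the original model's energy.  The choice of D is a gauge
choice: for the uniform distribution U the minimizer is exactly the pairwise
part of E^M in the zero-sum gauge, while the model's own distribution M
concentrates fidelity near the sequences the model actually generates.  The
extracted models are then scored on how well they reproduce the original
energies (range-normalized RMSE on distance-stratified test sets), rank
mutational effects (Spearman correlation against fitness measurements) and
recover structural couplings (APC-corrected Frobenius scores, PPV curves).

Intended users: computational biologists analyzing what protein sequence
models learn, and anyone who wants a cheap, interpretable pairwise surrogate
for an expensive generative model.

## What's inside

| Module | Contents |
| --- | --- |
| `pairdistill.alignment` | FASTA reading/encoding, dedup, 9:1 splits, Hamming stratification, sequence reweighting, mutational CSV |
| `pairdistill.energy` | `PairwiseModel`, `IndependentModel`, zero-sum gauge, enumeration + Möbius-expansion oracles, parameter counts |
| `pairdistill.ardca` | `ArDCA`: exact-likelihood autoregressive model (L-BFGS training, ancestral sampling) |
| `pairdistill.vae` | `SequenceVAE`: one-hidden-layer VAE, ELBO training, importance-sampling energies |
| `pairdistill.distill` | the three extraction routes: exact least squares, closed-form uniform estimators, Adam protocol |
| `pairdistill.evaluate` | NRMSE, Spearman, stratified reports, contact scores, PPV, coupling scatter |
| `pairdistill.synthetic` | planted pairwise/three-body models, Gibbs/exact samplers, synthetic mutational tables |
| `pairdistill.pipeline` / `cli` | end-to-end orchestration and the `pairdistill` command |

Models follow scikit-learn conventions (`fit` / `sample` / `score_samples`,
fitted attributes with trailing underscores) and compose with sklearn
tooling.

## Worked example

Distill a pairwise model from an autoregressive model trained on a
synthetic alignment drawn from a known Potts model:

```python
import pairdistill as pdl

cfg = pdl.PipelineConfig(
    data={"synthetic": {"kind": "pairwise", "N": 6, "q": 3,
                        "n_sequences": 2000,
                        "coupling_scale": 0.3, "field_scale": 0.5}},
    original={"kind": "ardca", "max_iter": 300},
    extractions=[
        {"distribution": "U", "family": "pairwise", "n_samples": 100_000},
        {"distribution": "M", "family": "pairwise", "n_samples": 100_000,
         "step_size": 0.01, "max_steps": 20_000},
        {"distribution": "M", "family": "independent", "n_samples": 100_000,
         "step_size": 0.01, "max_steps": 20_000},
    ],
    mutational={"synthetic": {"n_single_mutants": 12, "noise_sd": 0.1}},
    seed=1,
)
report = pdl.run_pipeline(cfg)
print(report.nrmse["PW/M"])
print(report.spearman)
```

Output from this exact configuration:

```
{'test_close': 0.0010663681356331129, 'test_distant': 0.0036069568404823757,
 'mutational': 0.002716484754859274}
{'original': 0.9580419580419581, 'PW/U': 0.9720279720279721,
 'PW/M': 0.9580419580419581, 'IND/U': 0.5104895104895105,
 'IND/M': 0.43356643356643365}
```

Reading it: the pairwise model extracted with samples from the model
distribution (PW/M) reproduces the original energies to about 0.1–0.4% of
their range on every test stratum and matches the original's mutational
Spearman exactly, while the independent models (IND/*) lose most of the
rank signal — the original model's useful structure here is pairwise, as it
must be for data generated by a Potts model.

The same machinery is exposed on the command line:

```bash
pairdistill make-fixtures --out fx --n-positions 6 --n-symbols 4
pairdistill train-ardca --msa fx/alignment.fasta --out ardca.npz
pairdistill distill --original ardca.npz --dist M --family pairwise \
    --n-samples 100000 --out pw.npz
```

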
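# acpflow

Does the training method shape how information flows through a recurrent
neural network, even when final performance is identical?  `acpflow` is an
analysis pipeline that trains small Elman networks on an active
categorical perception task by two methods — neuroevolution (a genetic
algorithm over the weights) and backpropagation through time — and then
dissects the trained networks with information theory and lesion analysis.
It is aimed at researchers in computational neuroscience and
neuroevolution who want a reproducible, tested implementation of set-wise
transfer entropy and noise-perturbation importance on recurrent networks.

## The task and model

A block with three binary attributes (small/large, bright/dark,
left/right) is flashed onto a 4-pixel retina for two consecutive
timesteps of a 4-timestep episode (early, intermediate, or late), coded
+1/−1/0.  The 8 configurations × 3 timings give n = 24 episodes over
m = 8 classes.  A 4–16–8 Elman network (tanh units, biases, zero initial
hidden state) reads out the class at the final timestep and is scored by

    E = Σ (O − A)²,   w = 1 − E/(n·m),   W = 1.5^(w·a)

where `O` are the final outputs, `A` the one-hot targets, and `a` the
number of correct classifications.  The GA evolves 100 genomes under
roulette-wheel selection on W with per-weight mutation probability 0.01
(Gaussian offsets, variance 0.1); backpropagation does full-batch
gradient descent on the MSE.  Both train networks to perfection (24/24).

On the perfect networks the pipeline measures, per training method:

* **Set transfer entropy** TE_{S→j} = I(X^j_{t+1}; X^S_t | X^j_t) in bits,
  a plug-in estimate over median-binarized hidden-state transitions, for
  random source sets S of sizes 1–15 and single targets j ∉ S — including
  the per-connection density TE/|S| and the set size where it peaks;
* **Importance** I = 1 − ⟨w̃/w⁰⟩ of the corresponding recurrent weights
  under one-sided uniform noise U[0, r] swept over r = 0…4, the lesion
  measure paired draw-for-draw with the TE values;
* Spearman correlations between the two, per set size;
* the recurrent weight distributions of the two methods (two-sample
  Kolmogorov–Smirnov).

See `docs/methods.md` for conventions, estimator bias, and sensitivity.

## Worked example

The analysis is a sequence of numbered drivers:

```sh
python analysis/01_generate_task.py   --out results
python analysis/02_train_replicates.py --out results
python analysis/03_te_importance_scan.py --out results
python analysis/04_summarize.py       --out results
```

Printed output of a run (desk profile: 10 replicates per method, 30
subset draws per size, 5 noise repeats; ~4 minutes on one CPU):

```
episodes: 24  classes: 8
BP: 10/10 replicates perfect; first-perfect iteration range 97-922
GA: 10/10 replicates perfect; first-perfect iteration range 99-755
wrote results/te_importance_pairs.tsv: 9000 paired observations (20 networks x 15 sizes x 30 draws)
per-connection information peak (argmax of mean TE/|S|): {'BP': 3, 'GA': 2}
sizes with significant TE-importance correlation (raw p<0.05): 1 of 30
recurrent-weight KS statistic 0.1648, p = 9.065e-31
```

Reading this: every replicate of both methods found a perfect classifier
well inside its budget (2000 generations / 5000 epochs).  Transfer
entropy and weight importance are essentially uncorrelated at every set
size (1 nominally significant size out of 30 method×size combinations is
chance at α = 0.05).  The per-connection information peak sits at small
interior set sizes (2–3); at this single-seed scale its exact position is
noisy — the multi-seed estimate (three master seeds, 100 draws per size,
as run by the acceptance script) places the GA peak at size 3 and the BP
peak at the 2–3 boundary.  The weight distributions of the two methods
differ statistically but only mildly in shape.  `results/report/`
contains the backing tables and figures (TE-vs-importance scatter grids,
set-size curves with standard errors, weight histograms and rank plots).

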
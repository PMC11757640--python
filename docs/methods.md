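# Methods

## The task

The stimulus set abstracts active categorical perception into a delayed
classification problem.  A block with three binary attributes — size
(small/large), shade (bright/dark), side (left/right) — is projected onto a
4-pixel retina: small blocks cover two contiguous pixels, large blocks
three; left blocks are flush with column 0, right blocks with column 3;
bright pixels read +1, dark pixels −1, empty pixels 0.  Each episode lasts
four timesteps and shows the block on two consecutive timesteps (early:
t = 0,1; intermediate: t = 1,2; late: t = 2,3), with blank frames elsewhere,
so the network must retain what it saw until the final timestep.  The full
space is 8 configurations × 3 timings = 24 episodes over 8 classes, three
episodes per class.  There is nothing to sample: the generator enumerates
the complete space deterministically, and this enumeration *is* the study's
dataset.  Because the data is the whole population rather than a draw from
it, passing tests say nothing about generalisation to unseen stimuli — the
scientific object is the trained network's internal organisation, not its
test-set skill.

## The network and its score

A 4–16–8 Elman network: sensors feed a 16-node recurrent layer through
`W_in` (16×4); the layer feeds back on itself through `M` (16×16) and
forward through `W_out` (8×16); hidden and output nodes add a bias and
apply tanh.  The hidden state starts at zero before each episode, and the
class readout is the argmax of the 8 outputs at the final timestep (ties
toward the lowest index; t = 3 is the only timestep by which every timing
condition has completed).

Performance over the n = 24 episodes and m = 8 classes:

    E = Σᵢⱼ (O − A)²ᵢⱼ        squared error over final outputs O
    w = 1 − E/(n·m)           normalised fitness
    a = #{episodes classified correctly}
    W = 1.5^(w·a)             selection fitness

`A` is one-hot: +1 at the true class and 0 elsewhere.  The off-target
value matters a great deal for neuroevolution: with 0 off-targets a
random network (outputs near zero) has w ≈ 1 − 1/m > 0, so W rewards
every correct classification from generation zero.  A −1 off-target
coding instead gives random tanh networks E > n·m, hence w < 0, so
W = 1.5^{wa} *punishes* accuracy while every a = 0 network sits at W = 1;
roulette-wheel selection then drives accuracy to zero and stalls —
populations never recover within 2000 generations.  We verified this trap
empirically before fixing the one-hot convention.

## Training

**Neuroevolution.**  A population of 100 genomes (every weight and bias,
472 parameters) is scored with W; the next generation is 100
fitness-proportional draws with replacement, each mutated: every scalar
independently gains, with probability 0.01, an offset from N(0, 0.1)
(standard deviation √0.1 ≈ 0.316).  No elitism, no recombination.  The
population evaluation is fully vectorised (population × episodes ×
timesteps in one einsum chain), which keeps a 2000-generation run at a
few seconds on one CPU.

**Backpropagation.**  Full-batch gradient descent on the mean squared
error of the final-timestep outputs, with exact gradients through all
four timesteps (verified against central finite differences at 1e−4
relative tolerance).  One epoch = one full-batch update.  The default
learning rate is 0.1; at this rate every tested seed reaches 24/24 within
~1500 epochs.  Adam is available as an alternative optimiser but is not
part of the replication profile.

**Replication profile.**  Networks are Xavier-seeded
(N(0, 2/(fan_in+fan_out)) weights, zero biases) and trained *until the
first perfect classifier appears* (caps: 2000 generations / 5000 epochs).
Both choices resolve genuine ambiguities in the study being reproduced:
its methods text names Kaiming initialisation while its weight-trajectory
figure describes Xavier-seeded networks, and its training account can be
read either as stopping each run at optimal performance or as running a
fixed budget that sufficed for every replicate.  Both init schemes and
both stopping rules are implemented and selectable.  We profiled all
four combinations and note
(see "Sensitivity" below) that the per-connection information peak is
sensitive to them; the replication profile fixes Xavier + early stopping
once, on the textual grounds above, and all shipped analyses use it.
`init_network`'s default scheme remains Kaiming, following the methods
text, for users who want a bare network outside the replication pipeline.

## Transfer entropy

Hidden states are recorded noise-free over all 24 episodes (96 samples of
16 nodes) and binarized per node at the node's pooled median, strictly
above → 1.  Ties occur structurally: episodes that share a configuration
differ only in timing, so pre-onset states repeat exactly across
episodes; tied values map to 0, which can push a node's ones-count below
half.  Transitions pair consecutive states *within* episodes only
(t → t+1 for t = 0,1,2; 72 pairs): the pre-episode zero state is a reset
artefact, not dynamics, and including it (or crossing episode boundaries)
would fabricate transitions that never occurred.  We checked the
alternative 96-transition convention that includes the reset transition;
it shifts TE magnitudes slightly and moves no headline conclusion except
flattening the per-connection peak.

TE from a source set S to a single target j ∉ S is the plug-in
conditional mutual information I(X^j_{t+1}; X^S_t | X^j_t) in bits,
estimated from the empirical distribution of the 72 transitions, with
history length 1.  Targets are always single nodes.  Two independent code
paths (a termwise sum over the joint table, and an entropy decomposition
over integer-coded samples) are held together, and against a brute-force
oracle, by the test suite at 1e−12.

The plug-in estimator is biased upward at small sample sizes — with 72
samples and 2^{|S|+2} cells the bias grows with |S| — and no correction
is applied, matching the direct estimation the analysis reproduces.  The
property suite characterises the bias instead (mean ≈ 0.02–0.1 bits at
|S| = 1 for i.i.d. traces) rather than hiding it.  Consequences to keep
in mind: set-TE is monotone in |S| by construction, and the per-node
quantity TE/|S| compares sizes on a biased scale; all size-argmax
statements are statements about this estimator at these sample sizes, as
in the original analysis.

## Importance (lesion by noise)

The importance of a weight group of M is measured by adding a fresh
one-sided uniform offset U[0, r] to each targeted weight at every
computational update, sweeping r over 21 levels 0.0–4.0 (step 0.2), and
averaging the relative fitness w̃/w⁰ over levels and repeats
(default 10; 5 in the desk profile):  I = 1 − ⟨w̃/w⁰⟩.  The scalar
averages all 21 levels uniformly, the r = 0 level contributing exactly 1.
For a set pair (S, j) the targeted entries are row j, columns S of M
(row = target convention).  Draws are independent per weight per update
by default; a shared-draw mode (one offset per update applied to the
whole group) is selectable for the reading in which a perturbed group
shares a single offset.
Fitness w rather than accuracy a is used for the ratio so the measure is
continuous; for perfect networks w⁰ ≈ 1 and the distinction is
second-order.  Networks with w⁰ ≤ 0 are rejected explicitly rather than
returning unstable ratios.

## Experiment orchestration

`run_replicates` trains n seeded replicates (seeds base, base+1, …) and
archives terminal networks and histories; only networks that re-evaluate
to 24/24 enter analyses.  `te_importance_scan` draws, per network and per
set size 1–15, random (S, j) pairs — uniformly chosen source sets, target
uniform among the rest — and feeds the *same* draws to both the TE and
the importance computation, so every row is a paired observation.
Spearman rank correlations between TE and importance are computed per
size (raw p-values, with a Bonferroni column for transparency), means and
standard errors per size per method, and pooled recurrent-weight
distributions are compared between methods with a two-sample
Kolmogorov–Smirnov test.

Scale profiles: desk (10 replicates per method per master seed, 100
subset draws per size, 5 noise repeats) and paper (50 replicates, 100
draws, 10 repeats).  The shipped analyses and the acceptance script use
the desk profile with three master seeds, i.e. 30 networks per method;
all randomness flows from per-stage seeds derived from the master seed.

## Sensitivity and known limitations

* **The per-connection peak is a near-tie.**  Mean TE/|S| differs between
  set sizes 2 and 3 by ~0.001–0.004 bits (1–3 standard errors at 30
  networks × 100 draws).  Under the replication profile the GA peak is
  consistently at size 3; the BP peak is statistically tied between 2
  and 3 and resolves marginally toward 3 as the number of networks and
  draws grows.  Under Kaiming seeding or fixed-duration training the
  assignments shift (GA moves to 2, BP varies between 2 and 3).  The
  qualitative statement that is
  robust across every profile we measured: information density peaks at
  small interior sizes (2–3), GA density is higher than BP density, and
  GA encodes in sets at least as large as BP.
* **Robustness contrast.**  GA networks transfer significantly more
  information through large source sets than BP networks (one-sided
  Welch test, p < 0.01 at 30 networks per method).  The companion claim —
  that GA networks also lose *less* performance under large-set
  perturbation — does not reach significance under the replication
  profile at desk scale (its direction reproduces under Kaiming-seeded
  fixed-duration training, p ≈ 0.05, and reverses under early stopping,
  where barely-perfect BP networks are the more noise-tolerant).  The
  pipeline computes and reports the test either way.
* **Weight-distribution KS values** depend on the replicate draw; the
  pipeline reproduces the analysis (pooled M weights, two-sample KS,
  rank-sorted per-network curves), not any particular published D or p.
* Degenerate (constant) hidden nodes binarize to all zeros and are
  flagged; TE involving them is well-defined (zero marginal entropy).
* The synthetic task has no observation noise and no train/test split;
  conclusions are about internal information organisation of perfectly
  performing networks, and transfer to noisy or generalising settings is
  untested.
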
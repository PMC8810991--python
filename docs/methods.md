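# Methods

## Model and procedure

The framework treats triage as a two-stage learning problem on a binary
diagnostic task.

**Stage one — deep ensemble.** K classifiers with identical architecture are
trained on identical rows, differing only in random initialization (member
*i* uses seed `master_seed + i`). No bootstrap resampling is applied: the
spread of independently initialized networks is the epistemic-uncertainty
signal, and resampling the rows would mix in sampling noise. Members are
ordinary cross-entropy MLP classifiers (scikit-learn `MLPClassifier`); any
object with a `fit`/`predict_proba` contract can be substituted through
`train_ensemble`'s `member_factory` hook, so larger backbones can be attached
without touching the rest of the pipeline.

**Uncertainty measures.** Two per-patient quantities in nats:

- ensemble entropy `u_e = -Σ_k P_k ln P_k` over the K member positive-class
  probabilities. The `P_k` do not form a distribution over k, so this is a
  sum of per-member terms, not a normalized entropy; it is implemented in
  exactly this form because that is how the method is defined. A normalized
  alternative (`mean_binary_entropy`, the mean of the members' full binary
  entropies) is exposed under its own name for users who want a proper
  per-member entropy; it is never the default.
- diagnostic entropy `u_d`: the entropy of the class-vote fractions, where a
  member votes positive iff its probability is ≥ 0.5. For binary tasks
  `u_d ∈ [0, ln 2]`, and `u_d = 0` exactly at unanimity. The ≥ 0.5 / ties-
  positive vote rule is shared with the majority diagnosis so the two are
  mutually consistent.

**Stage two — defer network.** A fully connected ReLU network (default two
hidden layers × 100 nodes) maps the K + 2 features (member probabilities,
then `u_e`, `u_d`) to C + 1 = 3 outputs and is trained with

    loss(x, target) = α · CE(target) + CE(defer)

No defer labels exist; the cost of deferring is taken as constant, which is
what the unconditional CE(defer) term encodes. At decision time the argmax
over the three softmax outputs is taken; a tie between defer and the best
class breaks toward defer (deferral is the conservative action for a safety
tool), and a class tie breaks positive.

**Placement of α.** The loss is sometimes written with the weight on the
defer term. The two parameterizations coincide at α = 1 (and differ only by
an overall rescaling at other α), but their *direction* differs: with the
weight on the target term, increasing α discourages deferral, which is the
behavior the coverage dial is described and used with (defer rates fall as α
rises). For a sample whose input implies class confidence q, the per-sample
optimum of this loss puts softmax mass proportional to (α(1−q), αq, 1), so
defer wins the argmax exactly when α < 1/max(q, 1−q): the deferred set grows
from "maximally ambiguous only" (α just below 2) to "everything" (α below 1)
as α decreases. The default is therefore `alpha_on="target"`; the literal
defer-weighted form remains selectable for fidelity experiments.

**Baselines.** LD widens the diagnostic architecture by one defer output and
trains it end-to-end on raw features with the same loss implementation and
decision rule (single source of truth). DT defers iff the chosen entropy
strictly exceeds a threshold and diagnoses the rest by majority vote; strict
comparison makes threshold 0 defer exactly the patients with non-zero
entropy, so DT's maximum defer rate equals the fraction of patients whose
members disagree — its structural ceiling. Diagnostic entropy is DT's
default measure; the ensemble-entropy variant is retained for comparison.
Whether DT's non-deferred patients should be classified by majority vote or
by thresholding the mean probability is not fixed by the method; majority
vote is used for consistency with the vote fractions that define `u_d`.

## Synthetic cohorts

The generator emulates the difficulty structure that makes deferral
worthwhile, not any particular clinical modality. Each class contributes
`n_per_class` rows (balanced generation stands in for the majority-class
down-sampling applied to real cohorts), split across three regimes:

- **easy** — Gaussian cluster at the class's own centroid; centroids are
  `class_separation` apart (default 6, with unit noise SD), so these are
  reliably learnable.
- **ambiguous** — both classes drawn from one shared cluster at the origin;
  within the region the Bayes error is 0.5 and an honest ensemble shows
  both vote disagreement and mid-range probabilities.
- **overconfident_wrong** — labeled y but drawn near the *opposite* class's
  easy centroid, at 0.85 of the way along the inter-centroid axis. Being
  firmly inside the opposite easy region, these draw unanimous wrong votes
  (`u_d = 0`), which is precisely the regime where threshold triage is
  blind. Sitting slightly short of the centroid leaves their member
  probabilities marginally less extreme than genuinely easy cases — a weak
  continuous signature that only a *learned* defer rule can exploit, which
  is the mechanism that separates the uncertainty-aware defer network from
  DT on this cohort.

Defaults (fractions 0.6 / 0.3 / 0.1, 10 features, separation 6, noise SD 1)
were chosen so that a desk-scale ensemble reproduces all three regimes
crisply: near-perfect easy accuracy, ~50% ambiguous accuracy, and ≥ 80% of
overconfident-wrong test samples unanimously misclassified. Subgroup tags
are carried through generation for evaluation diagnostics only; the model
interfaces accept features and labels, never tags.

What the generator does **not** emulate: text/image modalities, feature
correlations and missingness of real EHR data, label noise beyond the
flipped subpopulation, covariate shift between splits, or human-expert
error (deferred patients are scored as correctly diagnosed, the same
assumption the overall-F1 metric makes). Passing tests on these cohorts
shows the machinery behaves as designed in the regimes that matter; it does
not certify performance on any clinical dataset.

## Training defaults and numerical choices

- Ensemble members: two hidden layers (32, 32), ReLU, Adam, learning rate
  1e-3, weight decay 1e-4, 60 epochs, batch 128. This is the reference
  fully-connected design scaled to desk size; K defaults to 50 in the
  library and CLI, while tests and the acceptance script use K = 10 (all
  operations are written for arbitrary K ≥ 2).
- Defer network: hidden (100, 100), 20 epochs of minibatch Adam (β₁ = 0.9,
  β₂ = 0.999, ε = 1e-8) at learning rate 9e-4, batch 64, He initialization.
  Implemented directly in numpy (forward/backward by hand) because the
  weighted defer loss is the core of the method; training is fully
  deterministic given the spec seed. Stage-two inputs are not standardized:
  probabilities and entropies are already bounded and commensurate.
- Stage two is trained on the ensemble's predictions for the *same*
  training split used by stage one (the single 70–30 split protocol). An
  independent ensemble could be cross-fitted to avoid optimistic in-sample
  probabilities; at the fixture scale the in-sample protocol already
  reproduces the intended behavior, so the single split is the default.
- One defer network is trained per α value in a sweep; no warm starting, so
  grid points are independent.
- Degenerate metrics (0/0 divisions, empty non-deferred set) are reported
  as NaN with explicit flags (`f1_undefined`, `no_non_deferred`, …), never
  silently 0, and sweep tables keep such rows so output stays rectangular.
  Internal rates are fractions; percent formatting is a reporting concern.
- All randomness in an experiment run derives from one global seed:
  ensemble master seed `1000·seed`, defer-network seed `1000·seed + 500`,
  LD seed `1000·seed + 700`. Rerunning any stage with the same config and
  seed reproduces its output tables byte-for-byte.

## Problem sizes

Tests and the acceptance script use cohorts of 1 000 samples per class with
K = 10 members and 5 independent training seeds for the behavioral claims
(coverage monotonicity, matched-F1 comparison), and smaller cohorts with
K ∈ {2, …, 5} for unit-level contracts. These sizes give stable
seed-averaged statistics while keeping a full run around a minute on one
CPU core.

## Known limitations

- Binary tasks only (C = 2); the loss and decision rule generalize to
  C > 2 but the containers and metrics here do not.
- The matched-F1 comparison between the two learned defer methods is a
  stochastic statistic: with only five training seeds, individual seeds can
  favor either method even when the mean defer rates clearly favor the
  uncertainty-aware network.
- Expert cost is constant and expert accuracy is assumed perfect in the
  overall-F1 metric; modelling human uncertainty is out of scope.
- Ensemble members see in-sample data at stage two (see above); with very
  flexible members this could understate stage-one uncertainty.
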
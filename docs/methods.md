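# Methods

## Overview

`iistruct` computes integrated information structures (IIS) from
multichannel neural time series, following the IIT 3.0 formalism for small
binary systems observed at a fixed lag. The pipeline has five stages:

1. **Preprocessing** — bipolar re-referencing of adjacent electrodes,
   segmentation into fixed-length epochs, and a per-channel, per-epoch
   median split into binary states.
2. **System model** — a state-by-node transition probability matrix (TPM)
   estimated empirically per epoch and channel subset at lag τ.
3. **Mechanism analysis** — cause/effect repertoires, minimum-information
   partitions, mechanism-level φ, concepts, and the cause-effect structure
   (CES).
4. **System analysis** — unidirectional cuts and system-level Φ; the
   mechanism φ vector of the full system is the IIS.
5. **Decoding** — linear-SVM classification of arousal condition from φ, Φ
   or the IIS, under nested leave-one-pair-out cross-validation.

A synthetic-data module generates both ground-truth binary Markov systems
and pseudo-LFP recordings so that every stage is testable end to end
without any recorded data.

## The system model

For a set of `n` binarized channels, the TPM is the `2^n × n` matrix
`P[s, j] = p(channel j on at t+τ | system state s at t)`, estimated by
counting every lag-τ transition inside one epoch (overlapping, stride 1;
transitions never cross epoch boundaries). Nodes are assumed conditionally
independent given the past state (no instantaneous interactions), so the
state-by-state matrix is the product of per-node Bernoullis. States are
indexed little-endian: the lowest-labelled channel is the least significant
bit.

Current states never observed in an epoch are filled with the
maximum-entropy value 0.5 per node and flagged. Because every reported
quantity is a state-weighted average with occurrence counts as weights,
these filled rows receive zero weight and cannot contribute to any reported
φ or Φ; the fill only completes the matrix so the engine's marginalizations
are defined. (Whether, and how, incomplete empirical TPMs should be
completed at all is an open modelling question; the max-ent fill is this
package's choice, made so that downstream averages are provably unaffected.)

Defaults: τ = 4 samples (4 ms at 1000 Hz), with 2 and 6 supported for
sweeps; channel-set size k = 4 (configurable 2–5), giving C(15,4) = 1365
sets for a 15-channel probe, 16 states and 15 mechanisms (4/6/4/1 of sizes
1–4) per set.

## Repertoires, φ, and Φ

**Effect repertoire** of mechanism M (in its current state) over purview P:
the product over purview nodes of the node's on-probability at t+τ,
conditioning on M and marginalizing all other nodes under the uniform
distribution. **Cause repertoire**: Bayesian inversion — over purview
states z, the product across mechanism nodes of the likelihood of that
node's current state given the purview in z at t−τ (non-purview past nodes
uniform), normalized. A zero normalizer (unreachable mechanism state)
returns the uniform distribution, flagged.

**φ (mechanism level)**: all bipartitions of (mechanism, purview) are
enumerated — unordered, with possibly-empty components but no
(empty, empty) part, which also excludes the trivial partition. A
partition's repertoire is the product of the two parts' repertoires, the
severed mechanism→purview influences replaced by uniform marginalization
("noising"). φ is the raw minimum earth mover's distance between the whole
and partitioned repertoires (no per-partition normalization — IIT 3.0
selects the raw minimum, unlike IIT 2.0). The core cause/effect purview
maximizes φ; concept φ = min(φ_cause, φ_effect). Zero-φ concepts are
retained so the census is always complete.

**EMD**: ground metric is the Hamming distance between purview bit-states.
The solver is an exact successive-shortest-path min-cost transportation
solve on the excess/deficit graph (Johnson potentials + Dijkstra). Two
exact shortcuts keep the search fast without approximation:

* effect repertoires (whole and partitioned) are Bernoulli products, for
  which the Hamming EMD equals the sum of per-node marginal differences;
* total variation lower-bounds the EMD (each unit of moved mass costs at
  least one bit flip), so cause-side partitions whose TV already exceeds
  the incumbent minimum are skipped before any transport solve.

**Φ (system level)**: for each of the `2^n − 2` unidirectional cuts, all
influences from one part onto its complement are noised and the CES is
recomputed. The distance between full and cut structures is, per mechanism,

    min(φ_full, φ_cut) · [EMD(cause_full, cause_cut) + EMD(effect_full, effect_cut)]
  + |φ_full − φ_cut| · [EMD(cause_big, uniform) + EMD(effect_big, unconstrained effect)]

where "big" is the larger-φ concept of the pair and the residual mass is
moved to the maximally uninformative reference distributions. Φ is the
minimum over cuts. A completely feedforward system therefore has Φ = 0:
the cut severing the (non-existent) feedback direction changes nothing.

### Conventions the formalism leaves open

* **Common repertoire space.** Repertoires of concepts with different
  purviews are compared after expansion to the full n-node space, filling
  off-purview nodes with the uniform (maximum-entropy) distribution,
  independently per node. This is the single most consequential convention
  in the structure distance; the uniform fill is used on both cause and
  effect sides. The effect-side reference for residual mass is the
  unconstrained effect repertoire of the *full* (uncut) system; the
  cause-side reference is uniform.
* **Tie-breaking**, all deterministic: purview ties (within 1e−10) go to
  the larger purview, then the first in ascending-bitmask order; partition
  and cut ties go to the first candidate in a fixed enumeration order.
* **1-channel mechanisms** use exactly the same partition rules as larger
  ones (the only valid partitions sever the mechanism from part of its
  purview); their φ values are surfaced unchanged.
* **Numerics**: repertoire normalization tolerance 1e−10; the engine is
  validated against a brute-force enumeration + LP oracle to 1e−6; the
  transport solver against the LP itself to ~1e−11.

## Preprocessing choices

Binarization is a strict-greater comparison against the per-channel
within-epoch quantile (default the median): exactly-threshold samples go to
'off'. With tie-free continuous data and even epoch length the split is
exactly balanced, giving each channel ~1 bit of entropy. The threshold
quantile is a parameter so threshold sweeps are possible. Epoch medians are
never pooled across epochs or conditions. Binarization is invariant to
positive affine rescaling per channel. A pass-through slot is kept where a
notch filter would remove line noise in real recordings; the synthetic data
carries none, so no filter is implemented.

## The synthetic study

The pseudo-LFP generator emulates the *dimensions and coupling logic* of a
wake/anesthesia LFP experiment, not any specific physiology: 13 subjects ×
2 conditions × 8 epochs × 15 channels × 2250 samples at 1000 Hz by default.
Channels are damped stochastic oscillators — AR(2) processes with Gaussian
innovations, per-channel resonant frequencies drawn from 5–40 Hz, pole
radius 0.9 — coupled at lag 1 through a symmetric (bidirectional) random
weight matrix normalized to unit spectral norm. "Wake" scales the coupling
matrix by 0.35; "anesthesia" scales the identical matrix by 0.07, modelling
anesthesia as a uniform weakening of cross-channel communication with
self-dynamics intact. A spectral-radius guard rescales the system if a
draw lands within 0.005 of instability. Seeding is hierarchical: one study
seed fans out to per-subject dynamics and per-epoch noise streams, so
identical seeds give bit-identical studies and epochs are independent.

Ground-truth binary systems complement the AR generator: feedforward copy
chains (node i+1 copies node i with a set fidelity; node 1 is a fair coin)
for the zero-integration property, and logistic recurrent networks
(on-probability = logistic of coupling-scaled symmetric random weights on
current spins) whose state-averaged Φ grows with coupling.

What the generator does **not** model: line noise, stimulus structure,
drug pharmacokinetics, non-stationarity, channel-specific anesthetic
effects, or any claim about real fly physiology. Passing tests show the
*pipeline* recovers planted coupling differences; they are not evidence
about biological recordings.

## Decoding

The classifier is an L2-regularized squared-hinge linear SVM. Samples come
in wake/anesthesia pairs (same epoch within a subject; same subject across
subjects at one epoch), and all cross-validation leaves out whole pairs.
The nested scheme: the outer loop holds out one pair; the inner loop runs
leave-one-pair-out over the remaining pairs for each cost in the grid
{2^−50, 2^−40, …, 2^50} (11 values, decade steps of the exponent); inner
accuracy ties select the lowest cost, resolved after averaging over inner
folds; the final model retrains on all inner pairs at the chosen cost.
Features are z-scored with the training fold's mean and population SD
(ddof = 0; the convention is declared so two-point examples are exact);
zero-SD features map to 0. Per-mechanism accuracies are averaged within
mechanism size (4, 6, 4, 1 mechanisms of sizes 1–4) for reporting. The
iteration cap (2000) binds only at the extreme ends of the cost grid,
where the dual solver oscillates; results remain deterministic.

## Problem sizes for desk-scale runs

The full 15-channel × 1365-set design runs through the identical code path
but is a cluster-scale computation. The package's desk-scale study
(`desk_study_config`) uses 6 channels (C(6,4) = 15 sets), 2 subjects, and
the standard 8 epochs × 2250 samples per condition, which completes the
whole generate → binarize → Φ/IIS → decode pass in minutes on one CPU. The
equal-coupling null variant swaps no other parameter. Statistical checks
on decoding use a conservative binomial trial count (subjects × pairs × 2),
ignoring the strongly correlated channel-set replicates.

## Known limitations

* Observational TPMs only: no perturbational estimates, no background-
  condition control; spurious high-order correlations of partially
  observed systems are inherited, not corrected.
* No complex search: channel sets are fixed at k nodes; the engine scales
  to n = 5 but cost grows super-exponentially with n.
* The CES distance follows the φ-weighted formula with the conventions
  above; other operationalizations of the residual transport exist and
  would give different (though similarly behaved) Φ values.
* Mechanism φ of unobserved states is never reported (zero weight), but
  observed-state repertoires do read max-ent-filled rows of sparse
  empirical TPMs; with 2250-sample epochs and 4-channel sets this is rare.
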
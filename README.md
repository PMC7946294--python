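# iistruct

Integrated information structures from multichannel neural recordings.

`iistruct` implements the IIT 3.0 analysis chain used to ask whether the
pattern of irreducible causal interactions in a small neural system — not
just a scalar summary of it — tracks the level of arousal: continuous
voltage traces are binarized by a per-epoch median split, a state-by-node
transition probability matrix (TPM) is estimated at lag τ for every small
channel subset, and from each TPM the package computes mechanism-level
integrated information φ, system-level integrated information Φ, and the
**integrated information structure (IIS)** — the vector of all 2^k − 1
mechanism φ values of a k-channel set. A decoding stage then classifies
wake vs. anesthesia from φ, Φ, or the IIS with nested leave-one-pair-out
cross-validated linear SVMs. It is written for electrophysiologists and
computational neuroscientists who want these quantities from their own
multichannel recordings, and for methodologists who want a tested,
oracle-verified small-system IIT engine.

## The quantities

For a mechanism M (a channel subset in its current state) and purview P,
the cause/effect repertoires are the distributions M specifies over P's
past/future states, unexamined channels marginalized uniformly. Mechanism
integrated information is the irreducibility of those repertoires,

    φ(M, P) = min over bipartitions  EMD(whole repertoire, partitioned repertoire),

with the earth mover's distance taken under the Hamming ground metric and
severed influences replaced by uniform noise; a mechanism's φ is
min(φ_cause, φ_effect) at its φ-maximizing ("core") purviews. System-level
integrated information is the minimum over unidirectional cuts of the
φ-weighted distance between the full and cut cause-effect structures,

    Φ = min over cuts  Σ_M  min(φ, φ_cut)·[EMD^c + EMD^e] + |φ − φ_cut|·[EMD to unconstrained],

so a purely feedforward system has Φ = 0. All transport problems are
solved exactly (min-cost flow, validated against an LP oracle); the
mechanism census of a 4-channel set is 15 mechanisms (4/6/4/1 of sizes
1–4) over 16 states, and a 15-channel probe yields C(15,4) = 1365 sets.

Because the recordings the analysis was designed around are not bundled, a
first-class synthetic module generates ground-truth binary Markov systems
(feedforward chains, logistic recurrent networks) and pseudo-LFP studies —
coupled AR(2) oscillators, 13 subjects × 2 conditions × 8 epochs × 15
channels × 2250 samples at 1000 Hz by default, with cross-channel coupling
weakened under "anesthesia" — so the entire pipeline is testable from
nothing.

## Worked example

```python
import iistruct as ii

tpm = ii.make_recurrent_tpm(3, coupling=1.0, seed=7)   # known ground truth
res = ii.compute_big_phi(tpm, (1, 0, 1))
print(f"Phi = {res.big_phi:.4f}")
print(f"minimal cut: {res.minimal_cut.from_part} -> {res.minimal_cut.to_part}")
for c in res.full_ces.concepts:
    print(f"  mechanism {c.mechanism}: phi = {c.phi:.4f} "
          f"(cause {c.core_cause.purview}, effect {c.core_effect.purview})")
```

prints

```
Phi = 0.0831
minimal cut: (0, 1) -> (2,)
  mechanism (0,): phi = 0.0926 (cause (1,), effect (1,))
  mechanism (1,): phi = 0.1476 (cause (1,), effect (1,))
  mechanism (2,): phi = 0.1643 (cause (2,), effect (2,))
  mechanism (0, 1): phi = 0.0551 (cause (0, 1, 2), effect (0, 1, 2))
  mechanism (0, 2): phi = 0.0388 (cause (1, 2), effect (1, 2))
  mechanism (1, 2): phi = 0.0816 (cause (1, 2), effect (1, 2))
  mechanism (0, 1, 2): phi = 0.0836 (cause (1, 2), effect (1, 2))
```

Φ > 0 because the logistic network is recurrent: no unidirectional cut
reproduces its cause-effect structure. The seven concept φ values are the
IIS of this state; the minimal cut severs the influence of channels
(0, 1) on channel 2, the cheapest way to make the system feedforward.
Running the same TPM with `coupling=0.0` gives the fully unconstrained
system: every φ and Φ collapse to exactly 0.

The same computation over a whole study runs from the shell:

```bash
iis simulate --seed 1 --out study/           # pseudo-LFP epochs + manifest
iis preprocess --in study/ --epoch-seconds 2.25 --quantile 0.5 --out bins/
iis phi --in bins/ --k 4 --tau-ms 4 --out results.csv
iis decode --in results.csv --mode within --features iis --out accuracies.csv
```

`results.csv` holds one row per (subject, condition, epoch, channel set)
with Φ, the 15 mechanism φ values, and the set's spatial features (mean
location relative to the most central channel; total path distance).

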
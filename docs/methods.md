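# Methods

## Model

For a patient with events `(e_1, t_1) … (e_n, t_n)` inside the observation
window and demographics `d` (age group, gender), the network computes:

1. **Time embedding.** `t_i` is the *recency lag* — the gap in hours between
   event i and the most recent event in the window (an alternative reading,
   lag behind the previous event, is possible; recency was chosen because
   the attribution analyses emphasize how much weight the model puts on the
   most recent hours, and recency makes that information available to every
   event symmetrically). Dimension j of `v_t` is `sin(t·j/(t_m·k))` for even
   j, `cos` for odd j, with j starting at 0 (so dimension 0 is constantly 0;
   the index origin is configurable). `t_m` is the maximum lag in the
   training split; larger test-time lags are clamped.
2. **Value embedding.** The same sinusoidal map applied to
   `(v − v_min)/(v_max − v_min)`. The per-variable range is the training
   split's empirical range, widened to cover the declared normal range and
   clipped to the declared physical bounds; out-of-range values are clamped
   with a warning. Boolean events skip the value path entirely and use the
   raw event-table row as `v_e`; real events use
   `v_e = v_ev W_v + v_ee W_e + b_e`.
3. **Demographic attention.** Scores `β_j = v_j^d·W_vd + v_e·W_ve` over the
   |d| = 2 demographic rows, softmaxed into weights; the result `v_da` is
   event-specific because the score is conditioned on `v_e`.
4. **Fusion.** `q = v_e W_qe + v_t W_qt + v_da W_qd + b_q`. (The summed
   three-block projection is algebraically the same as concatenation
   followed by one dense layer.)
5. **Self-attention** (one layer, one head): `β_ij = Q_i·K_j` with *no*
   1/√k scaling, softmax over all j *including* i (both choices
   configurable; the raw-score, self-inclusive form is the default),
   `P_i = V_i + Σ_j α_ij V_j`.
6. **Pattern attention**: `γ = softmax(P W_p + b_p)`, `h = Σ γ_i P_i`; risk
   `y = sigmoid(h·W_h + b_h)`; binary cross-entropy loss with predictions
   clamped to `[1e-7, 1 − 1e-7]`.

Because every aggregation is a sum weighted by softmaxes over the event set,
the architecture is exactly permutation-invariant in the events (up to
floating-point summation order).

**Variants.** The no-time variant feeds a zero vector for `v_t` and is
therefore bit-stable under any retiming of events. The no-value variant
replaces the sinusoidal `v_ev` by `s·w_val + b_val` where `s` is the
normalized scalar value (per-variable training means are carried for
contexts that need a filled scalar); it retains magnitude information only
through a single learned direction.

**Implementation.** The network is plain numpy; the reverse-mode gradient is
written out by hand (softmax, attention and scatter-add backward rules) and
checked exhaustively against central finite differences for all three
variants in the test suite (agreement ~1e-10 at eps 1e-6). Parameters are
initialized uniform(−1/√k, 1/√k), biases zero, from a seeded generator; all
computation is deterministic given the seed.

## Training

Mini-batch Adam on the BCE. Sequences are processed one patient at a time at
their natural length and gradients are averaged over the mini-batch; this is
numerically identical to padding with masked softmaxes (the softmaxes
normalize over real events either way) and is the simpler implementation on
a single CPU at the scales used here. When a validation cohort is supplied,
training always runs the full epoch budget and restores the parameters from
the epoch with the best validation AUROC (the validation metric is AUROC
because that is the reported evaluation metric).

Two presets exist. The *paper-scale* preset is k=512, 50 epochs, batch 64,
lr 1e-4. The *desk-scale* default used throughout the tests is k=32,
20 epochs, batch 16, lr 2e-3: at k=32 with ~300 training patients the
large-scale setting yields only ~100 optimizer steps, far too few for the
attention layer to organize, so the desk preset takes proportionally more,
larger steps. One desk-scale training run (280 patients, ~190 events each)
takes about 13 s on one CPU.

Normalization statistics — per-variable value ranges and means, and `t_m` —
are always refit from the training split only (per fold during
cross-validation), so no information flows from validation or test patients
into the encoder.

**Cross-validation.** Patients are dealt into 10 label-stratified sets
(sizes within 1); fold f trains on sets f…f+6, validates on f+7 and tests
on f+8, f+9 (mod 10). Every patient is tested exactly twice; reported as
mean ± std of the 10 fold AUROCs.

## Interpretability

`C_ij = γ_i α_ij` sums to exactly 1 per patient. For cohort-level ranking,
each event is binned into five levels: inside the normal range → normal;
outside → high/low, split into high vs very-high (low vs very-low) at the
median of out-of-range values observed on that side, ties going to the
inner bin. Side medians are computed over the **whole cohort** by default
(cases-only is available): the phrase "the median of all the high values"
does not restrict the reference population, and the whole-cohort reference
is more stable when case out-of-range values are concentrated in a narrow
excursion band. Contribution mass is aggregated per *unordered*
(variable, level)-pair key (`C_ij + C_ji`); diagonal cells are tracked
under an `(event, itself)` key so mass is conserved, but excluded from the
two-event ranking. AVG-CR is each key's percent of the patient's unit
contribution mass, averaged over all case patients with absent keys
counting zero (an alternative denominator — averaging only over patients in
which the key occurs — is implemented as an option). Pattern keys ignore
event times; the per-patient explanation export retains them.

## Simulator

The generator emulates the *shape* of ICU vital-sign streams, not their
marginal distributions: eight variables with physiologic bounds and normal
ranges, collections arriving by a Poisson process (34 expected collections
per 48 h window, matching typical per-patient collection counts), values
from a mid-normal Gaussian base process (sd = normal-width/8), 30% of
(collection, variable) cells missing, demographics uniform over ICU-typical
age bins and two genders, and 1:3 exact age/gender matching (controls
inherit their case's anchor time — real cohorts never state the control
index-time convention, and case-anchored indexing is the conservative
choice).

The planted pattern works as follows (defaults): every patient, case or
control, receives with probability 0.93 three separated singleton
excursions of each planted variable (uniform over the out-of-range side,
the two variables confined to opposite halves of the window so they never
co-occur); case patients additionally receive, with probability 0.95, five
collections in which *both* planted variables are excursed simultaneously,
drawn from the upper 40% of the out-of-range span (the very-high band).
Controls show the co-timed pair with probability 0.02. Missingness is
applied after planting, so excursion cells can be lost like any others.
These rates were chosen so that (a) presence of either excursion alone is
nearly label-independent — a logistic model on the two presence indicators
scores AUROC ≈ 0.58 — while (b) same-collection co-occurrence separates the
classes at AUROC ≈ 0.95. A `late_cases` timing mode moves the co-timed
excursions to the newest third of the window for cases and the oldest third
for controls at equal rates, producing a cohort whose only signal is
timing (used to demonstrate the no-time ablation's collapse).

What passing tests on this simulator do **not** show about real data:
excursion *counts* retain some marginal signal (only presence is masked);
values are Gaussian-around-normal rather than skewed and autocorrelated;
missingness is independent rather than diagnosis-driven; there are no
boolean diagnosis-code streams; and the planted signal is a single
two-variable interaction, far cleaner than real physiology. Results here
certify the machinery (optimization, attribution, conservation), not
clinical performance.

## Numerical choices and degenerate inputs

* Softmaxes subtract the row max before exponentiation.
* Simultaneous events are ordered by (collection, variable) only for
  reproducible serialization; the model is order-independent.
* The observation window `[anchor − holdoff − obs, anchor − holdoff)` is
  closed at the older edge, so an event exactly at the window start is kept
  and one exactly at the hold-off boundary is excluded.
* Patients with empty windows are excluded from training/evaluation with a
  logged count; single-event patients are valid (all softmaxes become
  singletons and the contribution matrix is `[[1.0]]`).
* A variable with no out-of-range observations on a side maps later values
  on that side to the inner bin (high/low).
* Cross-entropy predictions are clamped at 1e-7; Adam uses eps 1e-8.

## Known limitations

* The numpy implementation targets desk-scale problems; k=512 with
  thousands of patients would want a GPU tensor library.
* AVG-CR denominators and the side-median reference population are genuine
  ambiguities of the attribution scheme; both choices are exposed as
  options and the defaults are documented above.
* The trainable-parameter inventory of the original large-scale
  configuration cannot be pinned down exactly; no claim is made about
  matching a specific parameter count.
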
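# Methods

## The model

`ss8pred` predicts, per residue, one of the eight DSSP secondary-
structure states G, H, I, E, B, T, S, C (this canonical order indexes
every 8-wide array in the package; amino-acid axes are alphabetical by
one-letter code). Three information sources are combined:

1. **Evolutionary profiles.** Each position carries a 20-vector of
   residue frequencies, read from the percentage block of PSI-BLAST
   ASCII PSSM files (log-odds are ignored), renormalized to sum 1.
   All-zero rows are replaced by the query residue's one-hot; unknown
   residues get the uniform profile.

2. **Structural templates.** A ranked hit table from a profile search
   against sequences of known structure is filtered to the top hit with
   identity below 95 % (rejecting trivial self-matches); the hit
   chain's DSSP states are copied onto the aligned query positions,
   annotated with the hit's identity fraction as the *degree of
   similarity*. Unaligned positions, and positions whose hit residue
   has undetermined structure, stay empty. Only the single best
   admissible template is used.

3. **Context-based mean-force potentials.** From a labeled corpus,
   PSSM-weighted counts are accumulated for singlets (residue R at a
   position with state C), doublets (R with its neighbour at offset k)
   and triplets (neighbours at offsets k₁ < k₂): each position
   contributes the product of profile frequencies rather than a hard
   count. By the inverse-Boltzmann relation, the potential of state C
   in context is −RT·ln(P_obs/P_ref) where the reference conditions on
   strictly less context (the corpus state distribution for singlets;
   the neighbour(s) alone, centre marginalized, for doublets/triplets);
   doublet and triplet terms are constructed so each level measures
   only the *additional* association its extra neighbour brings. The
   total pseudo-energy of residue i adopting state C sums the singlet
   term, all in-chain doublet terms and all in-chain triplet terms.

### Encoding and networks

Stage 1 encodes each residue as a window (default 15, odd) of 30-value
slots: 20 profile frequencies, a terminal flag (1 when the slot falls
off either chain end; such slots are otherwise all zero), the template
similarity degree, and 8 structure values — the template state's
one-hot where the template covers the slot, else the residue's context
scores with similarity 0. 15 × 30 = 450 inputs. Stage 2 slides a second
window (default 15) over the stage-1 output distributions, 9 values per
slot (8 probabilities + terminal flag) = 135 inputs.

Both phases are single-hidden-layer feed-forward networks (hidden
widths 225 and 68; logistic hidden units, softmax output,
cross-entropy loss; a sigmoid/squared-error variant exists behind a
flag), trained by mini-batch SGD with momentum 0.9 and optional
per-epoch learning-rate decay, early-stopped on validation Q8 with the
best weights restored. All initialization and shuffling is governed by
explicit seeds; identical seeds and data give bit-identical models. An
Adam optimizer is available but not default: in our experiments it
learned to over-trust low-similarity templates.

Final state calls are the argmax of the normalized stage-2
distribution; exact ties break by the fixed frequency-informed priority
H > E > C > T > G > S > B > I.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| window / stage2_window | 15 / 15 | residues per input window (odd; predicted residue at centre) |
| doublet offsets | ±1…±5 | neighbour separations entering doublet statistics; covers the i+3/i+4/i+5 helix hydrogen-bond partners |
| triplet pairs | all 45 ordered pairs of the above | each pair's components must also be doublet offsets (triplet potentials factor through them) |
| RT | 1 | energy unit; only relative score magnitude reaches the network |
| pseudocount α | 1 | total regularizer mass 8α per context, shrinking toward the **corpus state distribution** (see below) |
| hidden widths | 225 / 68 | stage-1 / stage-2 hidden layer sizes |
| learning rate | 0.01 (stage 1), 0.05 (stage 2) | the small refinement network needs the hotter rate to escape the smoothed majority-state optimum that erases short G/B/S segments |
| batch / patience / epochs | 256 / 10 / 300 | training loop defaults |
| template ceiling | 0.95 | hits at or above this identity are rejected |
| chain length filter | 40–1000 | chains outside this range are dropped before training |

**Pseudocount target.** The regularized conditional is
P(C|ctx) = (N(C,ctx) + 8α·q_C) / (N(ctx) + 8α) with q the corpus state
distribution. Shrinking toward the *uniform* distribution instead (the
plain additive rule, available as `pseudocount="uniform"` and used by
the scalar probability API) leaves a deterministic residual energy in
the doublet/triplet tables even when labels are independent of
sequence, because their cells have far smaller denominators than the
singlet cells and are dragged toward 1/8 harder — rare states dominate
the artifact. Background shrinkage is exactly unbiased at every context
level under independence, which is what lets the zero-information check
below measure association rather than estimator bias.

**Stacked stage-2 training.** By default `fit()` trains the refinement
network on *out-of-sample* stage-1 outputs (two temporary half-corpus
stage-1 networks each predict the other half), so stage 2 sees the
probability distribution it will face at test time instead of the full
network's overconfident training-set outputs. The experiment drivers
disable this (`stacked_stage2=False`) to keep their runtime in minutes;
at their corpus sizes the hot stage-2 learning rate is the binding fix.

**Context-score scaling.** Raw pseudo-energies are z-scored per state
against training-corpus statistics, clipped at ±3 SD and mapped to
[0, 1], so they share the bounded range of the one-hot template values.

## The synthetic generator

The generator emulates the statistical structure of a real labeled
corpus, not protein physics:

* **Labels** follow a first-order Markov chain whose self-loop mass
  sets mean segment lengths (G 3, H 10, I 5, E 5, B 1, T 3, S 2, C 4)
  and whose entry weights give protein-like stationary frequencies
  (H and C most common; I and B rarest, ~1 %).
* **Residues** are drawn from state-conditioned emissions. Emission
  centres are *grouped by structural family* — G/H/I share one
  preference block, E/B another, T/S a third — because in real proteins
  sequence propensities barely separate states within a family; the
  member is determined by segment dynamics and, when present, by the
  template. Sharpness (default 3) scales the log-preferences.
* **Profiles** are the true state's emission row perturbed by a
  Dirichlet draw (concentration `pssm_noise`, default 10) blended with
  30 % of the query residue's one-hot, emulating the substantial weight
  PSI-BLAST gives the query itself and guaranteeing the true residue
  nonzero frequency.
* **Templates** cover one contiguous region (fractional coverage) and
  copy the truth, rewriting each covered position to a uniformly chosen
  *different* state with probability `template_error_rate`, which
  defaults to 1 − similarity so that better templates are genuinely
  more informative.

The singlet Bayes rate — the best possible accuracy from one residue
identity, Σ_r max_C π_C e_C(r) — is computable in closed form from the
transition and emission matrices and anchors the learnability check.

What the generator does **not** emulate: homologous families and
alignment gaps, position-dependent conservation, physical residue-
contact constraints, and the heavy-tailed chain-length distribution of
the PDB. Tests passing on synthetic corpora therefore demonstrate that
the machinery is correct and that the method behaves as designed under
its own assumptions; they do not certify accuracy numbers on real
proteins.

## Experiments and problem sizes

All experiment drivers live in `ss8pred.experiments` and are exercised
both by the test suite and by `scripts/acceptance.py`; sizes were
chosen for single-CPU runs in minutes.

* **Learnability** — 200 template-less chains of length 100, default
  emissions/profiles, 5/1/1-proportioned chain split, stage-1 epochs
  ≤ 100 (patience 10, lr decay 0.985), stage-2 epochs ≤ 150 (lr 0.05,
  patience 15). Test Q8 must exceed the analytic singlet Bayes rate by
  ≥ 5 points; measured margins are ~20 points.
* **Template-similarity ladder** — one chain corpus (350 × 70), then
  one *independently trained model per similarity level*
  {none, 0.25, 0.5, 0.75, 0.95} with full-coverage templates and error
  = 1 − similarity, exactly as in similarity-subset benchmarking; the
  chains, the split and the seeds are identical across levels, so level
  differences are paired. Mean test Q8 must be non-decreasing in
  similarity and the 0.95 level must beat template-less by ≥ 10 points.
  Training a *single* model on mixed similarities and binning its test
  chains does not yield a reliable ordering at the low end: a
  75 %-wrong template carries little information while its one-hots
  replace the context scores, and one shared network over-trusts them.
* **Zero-information limit** — 10⁵ residues with uniform emissions
  (labels exactly independent of sequence) and broad profiles
  (pssm_noise 100, query blend 0.1), doublet offsets only. Mean |U|
  over all singlet and doublet entries must stay below 0.02; the broad
  profiles matter because with the default spiky profiles the statistic
  has a shot-noise floor (~0.027) unrelated to association.
* **Counting oracle** — 24 random micro-corpora (≤ 5 chains, length
  ≤ 10, one-hot and fractional profiles) against an independent
  position-loop counter.
* **Leakage guard** — 14 chains, 7 folds: per-fold context tables must
  differ from whole-corpus tables, fold roles must partition the
  chains, and removing a round's held-out chains and recounting must
  reproduce that round's tables exactly.

## Numerical choices and degenerate inputs

* Internal coordinates are 0-based half-open; DSSP and PSSM files are
  1-based on disk and converted at the parser boundary.
* DSSP blank structure codes (and any unrecognized code) map to C;
  gaps in DSSP residue numbering are filled with 'X'/'C' flagged
  *undetermined* — such residues stay in place but are excluded from
  count accumulation, training samples and scoring, and they break SOV
  segments.
* Potentials index unknown residues ('X') through an extra 21st slot
  holding the mean over the 20 canonical types.
* Offsets falling outside a chain simply contribute nothing; chains
  shorter than the window are fully padded and still predicted.
* SOV8 follows the 1999 revision (per overlapping pair,
  len(s_ref)·(minov+δ)/maxov with δ = min(maxov−minov, minov,
  ⌊len_ref/2⌋, ⌊len_pred/2⌋), normalized over reference segments
  including unmatched ones, pooled over all eight states). Per-state
  scores with empty reference are undefined: reported as NaN, shown as
  0.00 in tables, excluded from macro-averages. Overall Q8 is
  micro-averaged (residue-weighted); cross-validation additionally
  reports the arithmetic mean over fold scores.
* Probability rows reaching stage 2 are renormalized (with a warning)
  if they do not sum to 1; training aborts on non-finite loss.

## Known limitations

* π-helices are essentially never recovered — they are the rarest state
  and are absorbed by α-helix — matching the behaviour of 8-state
  predictors generally; isolated β-bridges (length-1 segments) are
  frequently smoothed away by the refinement stage despite its hot
  learning rate.
* The similarity degree is a single scalar per hit; per-position
  alignment quality is not modelled.
* Template transfer uses the raw hit-table identity; "positives" or
  profile-level similarity measures are not implemented.
* External search tools (PSI-BLAST and a PDB-sequence profile search)
  are consumed through their output files; the package never invokes
  them in tests.
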
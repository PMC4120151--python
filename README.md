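# ss8pred — template-based 8-state protein secondary structure prediction

Most secondary-structure predictors stop at three states (helix, strand,
coil). DSSP's full eight-state assignment — 3-10 helix (G), α-helix (H),
π-helix (I), β-strand (E), β-bridge (B), turn (T), bend (S) and
other/coil (C) — carries far more structural information: it constrains
backbone dihedrals tightly enough to prune tertiary-modelling search
spaces and to distinguish helix types when fitting cryo-EM density. The
catch is that the rare states (G, I, B, S) are nearly impossible to call
from sequence alone.

`ss8pred` is for structural bioinformaticians who want per-residue
8-state calls that exploit *homology*: when a sequence of known
structure aligns to the query, its DSSP states are transferred as a
structural template and fed to the classifier together with the
evolutionary profile. Where no template covers a residue, the package
falls back on **context-based mean-force potentials** — pseudo-energies
measuring how favourable each state *C* is for residue *R* given its
sequence neighbours at fixed offsets, derived from PSSM-weighted
singlet/doublet/triplet statistics by the inverse-Boltzmann relation

```
U_singlet(C, R)        = −RT ln [ P_obs(C | R) / P_ref(C) ]
U_doublet(C, R R₊ₖ)    = −RT ln [ P_obs(C | R R₊ₖ) P_ref(C) / ( P_ref(C | R₊ₖ) P_obs(C | R) ) ]
U(C, Rᵢ) = U_singlet + Σₖ U_doublet + Σ_{k₁<k₂} U_triplet
```

with the reference at each level conditioning on strictly less context
(the doublet/triplet offsets ±1…±5 cover the i+3/i+4/i+5 hydrogen-bond
partners that define the three helix types and short-range strand
alternation).

Each residue is encoded as a 15-residue window × 30 values per slot
(20 profile frequencies, 1 terminal flag, 1 template-similarity degree,
8 structure values — template one-hot where covered, scaled context
scores otherwise) = **450 inputs**, feeding a two-phase feed-forward
network: sequence→structure (450→225→8) then structure→structure
refinement (135→68→8). Predictions are evaluated by Q8 (per-residue
accuracy) and SOV8 (the 1999-revision segment-overlap score over all
eight states).

Real training data (PISCES-culled PDB chain sets, PSI-BLAST profiles,
DSSP output, profile-search hit tables) are parsed by `ss8pred.io` and
`ss8pred.templates`; a fully seeded synthetic generator
(`ss8pred.synthetic`) emulates all of them — Markov-chain state strings
with protein-like segment lengths, state-conditioned residue emissions,
noisy profiles, and templates with controllable similarity, coverage
and error rate — so the whole method runs and tests at desk scale with
no downloads.

## Worked example

Train on a synthetic corpus whose chains carry 60 %-similarity templates
over 80 % of their residues, then predict a held-out chain (runs in a
couple of minutes on one CPU):

```python
from ss8pred import GeneratorConfig, TemplateSS8Model, TrainingRun, generate_corpus

cfg = GeneratorConfig(n_chains=150, length_range=(60, 90),
                      template_similarity=0.6, template_coverage=0.8, seed=7)
corpus = generate_corpus(cfg)

model = TemplateSS8Model.from_corpus(corpus)
results = model.fit(
    run1=TrainingRun(epochs=100, early_stop_patience=10, lr_decay=0.985),
    run2=TrainingRun(epochs=150, learning_rate=0.05, early_stop_patience=15, lr_decay=0.99),
    seed=7,
)
print(results.summary())
print(results.evaluate().to_table().to_string())
```

prints

```
Template-based 8-state secondary structure predictor
========================================================
stage 1: 450 -> 225 -> 8  (103,283 parameters)
stage 2: 135 -> 68 -> 8  (9,800 parameters)
window 15 (30 values per slot), stage-2 window 15
corpus split: 108 train / 21 validation / 21 test chains
stage 1: 100 epochs, final loss 0.5200, best validation Q8 85.12%
stage 2: 47 epochs, final loss 0.7071, best validation Q8 84.12%

          G      H    I      E    B      S      T      C  Overall
Q8    58.14  94.40  0.0  92.00  0.0  50.36  69.46  84.92    81.00
SOV8  58.26  95.94  0.0  85.91  0.0  50.40  67.35  84.57    79.86
```

The table mirrors the standard per-state layout: overall test Q8 is
81.0 % and SOV8 79.9 %; helix and strand are called well, the short
rare states (G, S, T) benefit from the templates, and π-helix (I) and
isolated bridges (B) remain out of reach — displayed as 0.00 when the
state is absent or never recovered. Predicting one chain:

```python
cid = results.test_ids[0]
chain = corpus.chain(cid)
pred = results.predict_chain(chain, corpus.profiles[cid], model.template_for(cid))
print(pred.states[:40])
```

```
truth      EEEETTTHHGTTSSCIIIISHHHHHHHHHHCCTEEEEETH
predicted  EEEETTHHHHTTTTSHHSSSHHHHHHHHHHHTTEEEEEEH
```

The same pipeline is scriptable from the shell —
`ss8pred synth | build-scores | build-template | encode | train |
predict | evaluate` (see `ss8pred --help`) — reading and writing
FASTA, PSI-BLAST ASCII PSSM, DSSP text, tab-separated hit tables and
prediction TSVs.

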
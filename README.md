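# mcbead

Two-step Torsades-de-Pointes (TdP) risk classification from multi-channel
ion-channel block — **M**ulti-**C**hannel **B**lockage at **EAD** — with an
O'Hara–Rudy human ventricular myocyte simulation layer for pause-induced
early-afterdepolarization (EAD) analysis.

## The problem

Drug-induced block of the hERG potassium channel (IKr) is the classical
marker of torsadogenic risk, but hERG-only classifiers misjudge drugs whose
block of other channels — above all the L-type calcium current ICaV —
mitigates the danger. `mcbead` is for safety pharmacologists and modelers
who have per-drug patch-clamp panels (IC50 and Hill coefficient per
channel, plus the effective free therapeutic plasma concentration, EFTPC)
and want a transparent, mechanistically grounded risk call.

## The method

All drug effects are conductance block: `block = 100·cʰ/(IC50ʰ + cʰ)` and
`g → (1 − block/100)·g`. The classifier runs in two steps anchored at
IC60,hERG — the concentration giving 60% hERG block, the level at which
pause-induced EADs appear in the mid-myocardial O'Hara–Rudy cell:

1. **Gate.** Compute the hERG ratio `IC60,hERG / EFTPC`. A drug whose
   therapeutic exposure is far below the critical hERG-block concentration
   (ratio ≥ threshold; candidates 50/100/150/200, best training accuracy
   wins) is classified TdP− outright.
2. **Multi-channel step.** For the remaining drugs, fit a logistic model
   `P(TdP+) = 1/(1 + e^−(β₀ + Σ βᵢ·featureᵢ))` on channel-block features
   evaluated at IC60,hERG — deliberately independent of the noisy EFTPC.

The fitted model renders as a 2D risk map (hERG ratio on x, normalized
feature combination on y) whose regions reproduce the model's predictions
exactly. The biophysical layer — O'Hara–Rudy (2011) cells, original and
Dutta-rescaled variants, forward-Euler gold standard at dt = 0.001 ms —
supplies the EAD analysis behind the 60% anchor: short–long pacing
(200 stimuli at 500 ms, then a pause), EAD detection on the post-pause
beat, and (ICaV, INaL, IKs) block-space scans whose EAD+/EAD− surface
parallels the classifier's decision boundary. See `docs/methods.md` for
the full model description.

## Worked example

Generate a synthetic 60-drug panel whose ground truth follows a known rule
(TdP+ iff hERG ratio < 100 and ICaV block at IC60,hERG < 30%), fit the
two-step classifier, and cross-validate:

```sh
$ mcbead synth --n 60 --seed 11 --ratio-threshold 100 --cav-cutoff 30 \
    --out demo_panel.csv
wrote 60 drugs to demo_panel.csv

$ mcbead fit --panel demo_panel.csv --definition target3 --features ICaV \
    --out demo_model.json
threshold=100 training accuracy=100.0% -> demo_model.json

$ mcbead loo --panel demo_panel.csv --definition target3 --features ICaV
LOO accuracy: 100.0%
```

The persisted model shows the recovered rule: the selected gate is the
generative ratio threshold (100), and the step-2 boundary −β₀/β_ICaV =
31.005/0.8825 ≈ 35% ICaV block separates the classes (any boundary between
the class margins is exact here; leave-one-out accuracy 100% confirms the
rule generalizes):

```json
{ "ratio_threshold": 100.0,
  "intercept": 31.005,
  "coefficients": [-0.882],
  "feature_names": ["ICaV"] }
```

The negative ICaV coefficient is the mechanistic signature: more calcium
block is protective. `mcbead riskmap --model demo_model.json --panel
demo_panel.csv --out map.png` draws the corresponding risk map;
`mcbead simulate --variant OHR --herg-block 60 --protocol pause --out
trace.tsv` writes a post-pause voltage/calcium trace whose final beat
shows the EAD that motivates the 60% anchor, and `mcbead eadscan` maps the
(ICaV, INaL, IKs) block space.

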
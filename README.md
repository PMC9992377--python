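# groupplv

Phase-locking-value (PLV) functional connectivity from multichannel EEG,
and a small convolutional network that decodes binary emotional state —
high vs. low arousal or valence — from the resulting adjacency matrices,
at either the **individual** level (one matrix per participant, trial and
3-s window) or the **group** level (matrices element-wise averaged over all
participants watching the same stimulus window, capturing the cohort's
collective synchrony).

The package targets the layout of DEAP-style affective-EEG corpora (one
archive per participant holding a `videos x channels x samples` array of
32-channel, 128 Hz recordings plus `videos x 4` self-ratings on a 1–9
scale), and ships a synthetic EEG generator with closed-form expected
synchrony so the whole pipeline — filtering, phase extraction, PLV,
group averaging, classification, evaluation — is testable without any
external download.

## The statistic

For a real signal $s(t)$, the analytic signal
$z(t) = s(t) + i\,H\{s(t)\} = A(t)e^{i\phi(t)}$ (Hilbert transform $H$)
yields the instantaneous phase $\phi(t) \in [-\pi, \pi]$. For two
channels with relative phase $\phi_{12}(t) = \phi_1(t) - \phi_2(t)$
sampled at $N$ points,

$$
\mathrm{PLV} \;=\; \sqrt{\Big[\tfrac1N\textstyle\sum_j \sin\phi_{12}(j)\Big]^2
 + \Big[\tfrac1N\textstyle\sum_j \cos\phi_{12}(j)\Big]^2}\;\in\;[0,1],
$$

with 1 for a constant phase difference and 0 for no phase relationship.
Each 60-s trial (after discarding a 3-s pre-stimulus baseline) is cut
into twenty 3-s windows; each window is zero-phase band-passed into the
theta (4–8 Hz), alpha (8–13 Hz), beta (13–30 Hz) and gamma (30–45 Hz)
rhythms, and all-pairs PLV gives one 32 × 32 matrix per window and band.
A 32-participant, 40-video cohort therefore yields 25 600 individual and
800 group matrices per band. Matrices are labeled high/low by the strict
4.5 threshold on the (mean, for group level) self-rating, and fed to a
CNN: two blocks of conv(5 × 5, same) → batch-norm → max-pool → dropout
(32 then 64 filters, dropout 0.4), then flatten → dense(128, ReLU) →
dense(2, softmax), trained with Adam (lr 10⁻⁴, batch 32). The network is
implemented directly in NumPy (no deep-learning framework required) and
is fully seeded.

## Worked example

```python
import numpy as np
import groupplv as gp
from groupplv import model as mm

# A synthetic cohort whose two conditions differ only in gamma-band
# synchrony: 8 participants, 20 videos, 30 s of usable signal each.
cfg = gp.separable_gamma_config(n_participants=8, n_videos=20,
                                duration=33.0, seed=7)
corpus = [gp.simulate_participant(cfg, p) for p in range(cfg.n_participants)]
ds_ind, ds_grp = gp.build_datasets(corpus, "gamma", "arousal")
print(f"individual matrices: {len(ds_ind)}   group matrices: {len(ds_grp)}")

hi = gp.condition_average(ds_grp, "high").values
lo = gp.condition_average(ds_grp, "low").values
iu = np.triu_indices(16, 1)
print(f"mean within-community gamma PLV  high: {hi[:16,:16][iu].mean():.3f}   "
      f"low: {lo[:16,:16][iu].mean():.3f}")

x, y = ds_grp.to_arrays()
m = mm.train(mm.build_model(mm.ModelConfig(epochs=20, seed=0)), (x, y),
             mm.SplitSpec(seed=0))
prob = m.predict_proba(x[m.test_indices])
rep = gp.evaluate_predictions(y[m.test_indices], prob, dimension="arousal",
                              level="group", band="gamma", seeds=[0])
print({k: round(v, 3) for k, v in rep.scalars().items()})
```

prints

```
individual matrices: 1600   group matrices: 200
mean within-community gamma PLV  high: 0.963   low: 0.131
{'accuracy': 1.0, 'precision': 1.0, 'recall': 1.0, 'f_measure': 1.0, 'auc': 1.0}
```

The condition-averaged maps show what the classifier exploits: tight
gamma locking (PLV ≈ 0.96) inside each synchrony community in the
high condition against a washed-out baseline (≈ 0.13) in the low
condition, so the held-out 40 test matrices are classified perfectly.
On real data the contrast is far weaker; the command-line path
`groupplv deap-repro --data <dir-of-s*.dat>` reruns the same experiment
on a user-supplied DEAP download.

## Command line

```sh
groupplv simulate --out corpus/ --participants 8 --videos 20 --seed 0
groupplv extract  --data corpus/ --band gamma --dimension arousal --out mats/
groupplv train    --matrices mats/arousal_gamma_group.npz --out cnn --seed 0
groupplv evaluate --matrices mats/arousal_gamma_group.npz --model cnn --seed 0
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch through the library
(tone synthesis → analytic-signal phase → PLV), the two deterministic
reference values of the phase-locking statistic: the PLV of two
equal-frequency sinusoids holding a fixed π/4 offset, and the PLV of two
integer-cycle tones whose relative phase sweeps exactly one full cycle
over the window. Run it as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
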
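# beenose

Electronic-nose classification of honeybee worker biological status.

Colonies that lose their queen eventually develop *physiological laying
workers* — workers with activated ovaries that lay unfertilized eggs — and
detecting such colonies early matters in practical beekeeping. One proposed
instrument is an electronic nose: an array of six Taguchi-type metal-oxide
gas sensors (TGS823, TGS826, TGS832, TGS2600, TGS2602, TGS2603) sampling the
headspace above a caged sample of 100 workers. The joint response pattern of
the partially selective sensors characterizes the odor without separating
its chemical components.

`beenose` is a tested re-implementation of the analysis pipeline of such a
study, for researchers in chemosensory data analysis who want to reproduce,
probe, or extend the method. The original device recordings are proprietary,
so the package includes a first-class synthetic-data generator that emulates
their stated statistical structure:

- four classes of test object — 1 (empty chamber), 5 (young workers),
  6 (old workers), 7 (workers from colonies with laying workers) — with ten
  objects per class;
- two twin devices (M1, M2) with device-specific baseline offsets and two
  chamber insert materials (wooden, polystyrene) with insert-specific odor
  shifts;
- per object, a 600 s exposure phase (exponential rise to a class-dependent
  plateau) and a 600 s regeneration phase on filtered air (exponential
  decay), one reading per second, with Gaussian measurement noise.

## The method

Each object's 1200 × 6 recording is reduced to a six-descriptor feature
vector: the reading of each sensor at a fixed reference second *t* = 270,
chosen after signal stabilization. Optional **baseline differential
correction** subtracts the mean of the object's own 600-s regeneration
record, removing device and ambient offsets:

    x_s = exposure_s(270)                       (raw)
    x_s = exposure_s(270) − mean_t regen_s(t)   (corrected)

Per-class **scent signatures** (radar-chart data) min-max normalize each
attribute over all objects to [0, 1], average within class, and square:

    sig_i(c) = ( mean_{obj ∈ c} norm(TGS_i(obj)) )²

Classification uses ten simple classifiers, m1–m10: 1-nearest-neighbour and
an inverse-distance **weighted-voting rule ("811"**, each training row votes
for its own class with weight 1/(d + δ)**)** under Canberra, Euclidean,
Manhattan, and min-max-normalized Euclidean distances, plus two
**ε-indiscernibility Naive Bayes** variants that score class *c* by

    score(c) = Σ_i  |{rows of c : |row_i − x_i| ≤ ε·range_i}| / |c|

(`nb`), or that sum multiplied by the class prior |c|/N (`nb2`), with
ε = 0.01. Sums rather than products avoid zeroing.

Evaluation is Monte Carlo cross-validation ("5×MCCV5"): 25 independent
stratified 50/50 train/test splits, identical splits for all ten
classifiers, metrics averaged over splits. Reported metrics are global
accuracy, coverage (identically 1), per-class accuracy, **balanced
accuracy** (unweighted mean of per-class accuracies), and the study's
"true positive rate" (fraction of objects *predicted* as a class that truly
belong to it — a precision). The sweep covers eight options — device ×
insert × baseline correction — and five variants: all four classes together
and each class one-vs-rest (e.g. 7 vs "156").

## Worked example

```python
import beenose as bn

cfg = bn.GeneratorConfig.default(separation=0.05, seed=7)  # overlapping classes
study = bn.generate_study(cfg)                             # 160 objects
res = bn.run_option_sweep(study, options=("I",), variants=("7vsall",), seed=7)
print(res[["classifier", "acc_156", "acc_7", "acc_balanced", "tpr_7"]]
      .round(3).to_string(index=False))
```

prints

```
          classifier  acc_156  acc_7  acc_balanced  tpr_7
        canberra.1nn    0.907  0.848         0.877  0.778
        canberra.811    1.000  0.136         0.568  0.480
         eps=0.01.nb    0.640  0.968         0.804  0.484
        eps=0.01.nb2    0.997  0.296         0.647  0.820
       euclidean.1nn    0.917  0.816         0.867  0.800
       euclidean.811    1.000  0.176         0.588  0.680
       manhattan.1nn    0.915  0.800         0.857  0.793
       manhattan.811    1.000  0.168         0.584  0.600
maxminnormalized.1nn    0.928  0.824         0.876  0.836
maxminnormalized.811    1.000  0.072         0.536  0.280
```

Option I is the M1 device with a wooden insert and no baseline correction;
the variant merges classes 1, 5, 6 into the rest-label "156". Each row is
the 25-split MCCV average for one classifier: `acc_7` is the fraction of
class-7 (laying-worker) test objects recognized, `tpr_7` the fraction of
objects predicted as class 7 that really are, and `acc_balanced` the mean of
the two per-class accuracies. At this deliberately overlapping class
separation the 1-NN family clearly beats the voting rule, whose votes are
swamped by the 3:1 rest majority.

The same pipeline is scriptable from the shell:

```sh
beenose simulate --out run/ --seed 7
beenose evaluate --out run/ --signals run/ --options I --variants 7vsall --classifiers all
beenose report --results run/results.csv --metric acc_balanced
```

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic study from the
given seed, computes per-option decision tables and class signatures, and
runs the MCCV sweep over Options I/II/V/VI for the four-class and 7-vs-rest
variants with all ten classifiers, writing its JSON report to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
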
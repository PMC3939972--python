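# eegpipe

Windowed complexity and spectral features for two-group EEG discrimination,
classified per participant with a leave-one-participant-out (LOPO)
RBF-kernel support vector machine — plus a calibrated synthetic cohort
generator for testing the whole chain when no clinical recordings are
available.

## The problem

Resting EEG of patients with schizophrenia tends to be *more regular* than
that of matched controls. A practical way to quantify this is approximate
entropy (ApEn): for a window `x(1..N)`, embed it as templates
`X(i) = [x(i) … x(i+m−1)]`, count matches under the Chebyshev norm within a
tolerance `r`, form the mean log match frequency

```
Φ^m(r) = (1/(N−m+1)) Σ_i ln C_i^m(r),      ApEn(m, r, N) = Φ^m(r) − Φ^{m+1}(r)
```

and read ApEn as the negative log conditional probability that sequences
close for `m` samples stay close for `m+1`. Lower ApEn = more regular
signal. The package computes windowed ApEn (`m = 2`, `r = 0.1·SD`, 2-s
windows, 50 % overlap) on five central/temporal channels
(Cz, C3, C4, T3, T4), alongside three comparison features per window —
Burg autoregressive coefficients, Butterworth band power
(delta/theta/alpha/beta) and Higuchi fractal dimension — and feeds each
feature type to a soft-margin RBF-SVM evaluated with LOPO cross-validation,
so no subject's windows ever appear in both training and test.

Because no public recordings accompany the original clinical study, the
`synthetic` module generates surrogate cohorts: per channel a mixture of
band-limited pink noise and a drifting 8–12 Hz oscillation whose
subject-level mixing weight is calibrated (via a frozen lookup table) so
the two groups differ in mean windowed ApEn by a configurable gap
(default 0.10, controls higher).

## Worked example

```python
import eegpipe as ep

recs = ep.generate_cohort(ep.CohortSpec(seed=1))        # 10 + 10 subjects
fm = ep.extract_feature_matrix(recs, "apen")             # 2380 windows x 5 channels
folds = ep.lopo_cv(fm)                                   # 20 folds
from eegpipe.evaluation import fold_accuracy_summary, pooled_confusion
print(fold_accuracy_summary(folds))
print(ep.metrics(pooled_confusion(folds)))
```

prints

```
{'n_folds': 20, 'accuracy_mean': 0.8819..., 'accuracy_sd': 0.2884...,
 'subject_vote_accuracy': 0.9}
{'sensitivity': 0.8067..., 'specificity': 0.9571..., 'accuracy': 0.8819...}
```

meaning: averaged over the 20 held-out subjects, 88.2 % of a held-out
subject's windows are assigned to the correct group; 18 of 20 subjects are
correctly labelled by majority vote; pooled over all windows, 80.7 % of
patient windows and 95.7 % of control windows are recognised.

The same run from a shell:

```bash
eegpipe synth --n-patients 10 --n-controls 10 --gap 0.10 --seed 1 --out data/
eegpipe features --data-dir data/ --type apen --out apen.csv
eegpipe classify --features apen.csv --out report.json
eegpipe report --features apen.csv --out tables.md
```

or end-to-end with all four feature types from a TOML config:
`eegpipe run --config run.toml` (see `docs/methods.md` for the knobs).

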
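"""Monte Carlo cross-validation and the option x variant x classifier sweep.

The study design ("5xMCCV5") draws 25 independent stratified random
train/test splits of a decision table, classifies every test row from the
training rows with each of the ten classifiers — the same splits for every
classifier, so methods are compared on identical data — and averages the
per-split metrics arithmetically.

Metrics follow the study's conventions: per-class accuracy is the fraction
of a class's test objects classified correctly; balanced accuracy is the
unweighted mean of per-class accuracies; "true positive rate" of a class is
the fraction of objects *predicted* as that class that truly belong to it
(a precision); coverage is the fraction of test objects receiving any
label, identically 1 for all classifiers here.

Besides the four-class task, each class can be evaluated one-vs-rest: the
remaining classes are merged into a single rest-label (e.g. 7 vs "156").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, classify, parse_classifier
from .features import OPTIONS, DecisionTable, _label_key, build_decision_table
from .synth import DEVICES, INSERTS

__all__ = [
    "VARIANTS",
    "SplitPlan",
    "MetricsRecord",
    "relabel_one_vs_rest",
    "make_split_plan",
    "metrics_from_predictions",
    "run_mccv",
    "run_option_sweep",
    "best_classifier_table",
]

# Evaluation variants: the four-class task plus each class one-vs-rest.
VARIANTS = ("all", "1vsall", "5vsall", "6vsall", "7vsall")


@dataclass
class SplitPlan:
    """A fixed list of stratified train/test splits, reused across classifiers."""

    splits: list  # [(train_idx, test_idx)] as integer arrays
    n_groups: int = 5
    n_per_group: int = 5
    test_fraction: float = 0.5
    seed: int = 0

    def __len__(self) -> int:
        return len(self.splits)


@dataclass
class MetricsRecord:
    """Evaluation metrics, per split or averaged over splits."""

    acc_global: float
    cov_global: float
    acc: dict  # per-class accuracy (recall)
    acc_balanced: float
    tpr: dict  # per-class precision (the study's "true positive rate")
    n_splits: int = 1


def relabel_one_vs_rest(table: DecisionTable, positive) -> DecisionTable:
    """Keep the positive class; merge every other label into one rest-label.

    The rest-label concatenates the remaining labels in ascending order
    (7 vs rest in the four-class table gives classes {7, "156"}).  Applied
    to an already-binary table with its own positive class it is the
    identity.
    """
    if positive not in table.class_set:
        raise ValueError(f"positive class {positive!r} not in table classes {table.class_set}")
    rest = [c for c in table.class_set if c != positive]
    merged = "".join(str(c) for c in sorted(rest, key=_label_key))
    rows = [
        r if r.class_label == positive else dataclasses.replace(r, class_label=merged)
        for r in table.rows
    ]
    return DecisionTable(rows=rows)


def make_split_plan(
    table: DecisionTable,
    n_groups: int = 5,
    n_per_group: int = 5,
    test_fraction: float = 0.5,
    seed: int = 0,
) -> SplitPlan:
    """Draw ``n_groups * n_per_group`` stratified random train/test splits.

    Per class, ``round(test_fraction * n_class)`` rows go to test in each
    split; every class must contribute at least one row to both sides.
    Identical arguments reproduce identical plans.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(table.labels, dtype=object)
    class_idx = {c: np.flatnonzero(labels == c) for c in table.class_set}
    n_test = {}
    for c, idx in class_idx.items():
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has {len(idx)} row(s); need >= 2 to stratify")
        k = int(round(test_fraction * len(idx)))
        if k < 1 or k >= len(idx):
            raise ValueError(
                f"test_fraction={test_fraction} leaves class {c!r} with "
                f"{k} test rows out of {len(idx)}; every class needs rows on both sides"
            )
        n_test[c] = k

    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_groups * n_per_group):
        test_parts, train_parts = [], []
        for c in table.class_set:
            perm = rng.permutation(class_idx[c])
            test_parts.append(perm[: n_test[c]])
            train_parts.append(perm[n_test[c] :])
        test = np.sort(np.concatenate(test_parts))
        train = np.sort(np.concatenate(train_parts))
        splits.append((train, test))
    return SplitPlan(splits=splits, n_groups=n_groups, n_per_group=n_per_group,
                     test_fraction=test_fraction, seed=seed)


def metrics_from_predictions(truth, predicted, classes=None) -> MetricsRecord:
    """Confusion-matrix metrics for one batch of predictions.

    ``tpr`` of a class with no predicted members is 0 by convention.
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(predicted)} predictions")
    if not truth:
        raise ValueError("need at least one prediction")
    if classes is None:
        classes = sorted(set(truth), key=_label_key)

    n = len(truth)
    correct = sum(t == p for t, p in zip(truth, predicted))
    acc, tpr = {}, {}
    for c in classes:
        in_c = [p for t, p in zip(truth, predicted) if t == c]
        pred_c = [t for t, p in zip(truth, predicted) if p == c]
        acc[c] = sum(p == c for p in in_c) / len(in_c) if in_c else 0.0
        tpr[c] = sum(t == c for t in pred_c) / len(pred_c) if pred_c else 0.0
    return MetricsRecord(
        acc_global=correct / n,
        cov_global=sum(p is not None for p in predicted) / n,
        acc=acc,
        acc_balanced=float(np.mean([acc[c] for c in classes])),
        tpr=tpr,
        n_splits=1,
    )


def run_mccv(table: DecisionTable, plan: SplitPlan, spec: ClassifierSpec) -> MetricsRecord:
    """Average per-split metrics over every split of the plan."""
    classes = table.class_set
    per_split = []
    for train_idx, test_idx in plan.splits:
        train = DecisionTable(rows=[table.rows[i] for i in train_idx])
        truth = [table.rows[i].class_label for i in test_idx]
        pred = [classify(train, table.rows[i], spec) for i in test_idx]
        per_split.append(metrics_from_predictions(truth, pred, classes=classes))
    return MetricsRecord(
        acc_global=float(np.mean([m.acc_global for m in per_split])),
        cov_global=float(np.mean([m.cov_global for m in per_split])),
        acc={c: float(np.mean([m.acc[c] for m in per_split])) for c in classes},
        acc_balanced=float(np.mean([m.acc_balanced for m in per_split])),
        tpr={c: float(np.mean([m.tpr[c] for m in per_split])) for c in classes},
        n_splits=len(per_split),
    )


def _variant_table(table: DecisionTable, variant: str) -> DecisionTable:
    if variant == "all":
        return table
    if variant.endswith("vsall"):
        return relabel_one_vs_rest(table, int(variant[:-5]))
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def _plan_seed(seed: int, device: str, insert: str, variant: str) -> int:
    # Baseline-corrected options share the plan seed of their uncorrected
    # twin (the flag is deliberately absent), so correction effects are paired.
    ss = np.random.SeedSequence(
        entropy=seed,
        spawn_key=(DEVICES.index(device), INSERTS.index(insert), VARIANTS.index(variant)),
    )
    return int(ss.generate_state(1)[0])


def run_option_sweep(
    study,
    options=tuple(OPTIONS),
    variants=VARIANTS,
    specs=None,
    seed: int = 0,
    n_groups: int = 5,
    n_per_group: int = 5,
    test_fraction: float = 0.5,
    t_ref: int = 270,
    regen_stat: str = "mean",
) -> pd.DataFrame:
    """Evaluate every option x variant x classifier cell of the study.

    Returns a long-format frame keyed by (option, variant, classifier) with
    the metric fields as columns (``acc_<label>`` / ``tpr_<label>`` per
    class present in the variant).  Within each (option, variant) cell the
    classifiers attaining the column maximum of ``acc_balanced`` and of
    each ``tpr_<label>`` are flagged in ``best_for``.
    """
    if specs is None:
        specs = [parse_classifier(f"m{i}") for i in range(1, 11)]
    specs = [s if isinstance(s, ClassifierSpec) else parse_classifier(s) for s in specs]
    for opt in options:
        if opt not in OPTIONS:
            raise ValueError(f"unknown option {opt!r}; expected one of {tuple(OPTIONS)}")
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}; expected one of {VARIANTS}")

    records = []
    for opt in options:
        device, insert, baseline = OPTIONS[opt]
        base_table = build_decision_table(
            study, device, insert, baseline_correct=baseline, t_ref=t_ref, regen_stat=regen_stat
        )
        for variant in variants:
            table = _variant_table(base_table, variant)
            plan = make_split_plan(
                table, n_groups=n_groups, n_per_group=n_per_group,
                test_fraction=test_fraction, seed=_plan_seed(seed, device, insert, variant),
            )
            for spec in specs:
                m = run_mccv(table, plan, spec)
                rec = {
                    "option": opt,
                    "variant": variant,
                    "classifier": spec.name,
                    "acc_global": m.acc_global,
                    "cov_global": m.cov_global,
                }
                for c in table.class_set:
                    rec[f"acc_{c}"] = m.acc[c]
                rec["acc_balanced"] = m.acc_balanced
                for c in table.class_set:
                    rec[f"tpr_{c}"] = m.tpr[c]
                records.append(rec)

    if not records:
        return pd.DataFrame(
            columns=["option", "variant", "classifier", "acc_global", "cov_global",
                     "acc_balanced", "best_for"]
        )
    results = pd.DataFrame(records)

    flag_cols = [c for c in results.columns if c == "acc_balanced" or c.startswith("tpr_")]
    best_for = []
    for _, row in results.iterrows():
        cell = results[(results["option"] == row["option"]) & (results["variant"] == row["variant"])]
        flags = [col for col in flag_cols
                 if pd.notna(row[col]) and row[col] == cell[col].max()]
        best_for.append(",".join(flags))
    results["best_for"] = best_for
    return results


def best_classifier_table(results: pd.DataFrame, metric: str = "acc_balanced") -> pd.DataFrame:
    """Best classifier (and its value) per (variant, option) for one metric.

    Ties are reported jointly, comma-separated, mirroring the study's
    best-classifier summary tables.
    """
    if metric not in results.columns:
        raise ValueError(f"metric {metric!r} not in results columns")
    rows = []
    for (variant, option), cell in results.groupby(["variant", "option"], sort=False):
        vals = cell[metric]
        if vals.isna().all():
            continue
        best = vals.max()
        names = ",".join(cell.loc[vals == best, "classifier"])
        rows.append({"variant": variant, "option": option, "metric": metric,
                     "classifier": names, "value": best})
    return pd.DataFrame(rows)
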
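"""Agreement metrics and leave-one-out feature sensitivity.

Model assessments are compared against reference labels (expert
assessments or planted simulation truth) with exact-match accuracy and
Cohen's chance-corrected kappa, both on the full three-class alphabet and
after merging rare + fairly common into "less common" for the binary
view. The sensitivity harness drops one feature at a time, reruns the
whole modelling chain with the same seeds, and reports the relative
change of both metrics — ranking features by how much agreement their
removal costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import FAIRLY_COMMON, RARE, VERY_COMMON

__all__ = ["LESS_COMMON", "AgreementReport", "binarize", "reference_consensus",
           "accuracy", "cohens_kappa", "agreement_report",
           "leave_one_out_sensitivity"]

LESS_COMMON = "less_common"


@dataclass
class AgreementReport:
    confusion: pd.DataFrame      # rows = reference, columns = prediction
    accuracy: float
    kappa: float
    n: int


def binarize(labels):
    """Merge rare and fairly common into "less common". Idempotent."""
    mapping = {RARE: LESS_COMMON, FAIRLY_COMMON: LESS_COMMON,
               VERY_COMMON: VERY_COMMON, LESS_COMMON: LESS_COMMON}
    if isinstance(labels, str):
        return mapping[labels]
    return np.asarray([mapping[l] for l in labels], dtype=object)


def reference_consensus(ref1, ref2) -> np.ndarray:
    """Two-rater consensus: the agreed class, or fairly common on disagreement."""
    a = np.asarray(ref1, dtype=object)
    b = np.asarray(ref2, dtype=object)
    if a.shape != b.shape:
        raise ValueError("reference labelings cover different species sets")
    return np.where(a == b, a, FAIRLY_COMMON).astype(object)


def accuracy(pred, ref) -> float:
    """Fraction of exactly matching labels."""
    p = np.asarray(pred, dtype=object)
    r = np.asarray(ref, dtype=object)
    if p.shape != r.shape:
        raise ValueError("label vectors differ in length")
    if len(p) == 0:
        raise ValueError("empty label vectors")
    return float((p == r).mean())


def cohens_kappa(pred, ref) -> float:
    """Cohen's kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginals.

    When chance agreement p_e is 1 (both raters constant on one class) the
    statistic is defined as 1 for perfect agreement and 0 otherwise.
    """
    p = np.asarray(pred, dtype=object)
    r = np.asarray(ref, dtype=object)
    if p.shape != r.shape:
        raise ValueError("label vectors differ in length")
    n = len(p)
    classes = np.unique(np.concatenate([p, r]))
    p_o = float((p == r).mean())
    p_e = sum(float((p == c).mean()) * float((r == c).mean()) for c in classes)
    if p_e >= 1.0 - 1e-12:
        return 1.0 if p_o >= 1.0 - 1e-12 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def agreement_report(pred, ref) -> AgreementReport:
    """Confusion matrix (reference rows), accuracy, and kappa in one report."""
    p = np.asarray(pred, dtype=object)
    r = np.asarray(ref, dtype=object)
    classes = sorted(set(p) | set(r))
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for ri, pi in zip(r, p):
        conf.loc[ri, pi] += 1
    return AgreementReport(confusion=conf, accuracy=accuracy(p, r),
                           kappa=cohens_kappa(p, r), n=len(p))


def leave_one_out_sensitivity(table, reference, cfg,
                              run_models=None) -> pd.DataFrame:
    """Drop each feature in turn, rerun the models, and measure agreement loss.

    ``run_models(table, cfg, exclude)`` must return the per-species
    ensemble labels (the default is the pipeline's modelling chain).
    Returns one row per excluded feature with 3-class and binary accuracy
    and kappa plus their relative percentage change against the
    full-feature baseline (negative = loss). Seeds are shared with the
    full run so differences reflect the excluded feature alone.
    """
    if run_models is None:
        from .pipeline import run_models as run_models  # late import, avoids cycle
    ref = np.asarray(reference, dtype=object)
    ref_bin = binarize(ref)

    full = run_models(table, cfg, exclude=None)
    base_acc3 = accuracy(full, ref)
    base_k3 = cohens_kappa(full, ref)
    base_acc2 = accuracy(binarize(full), ref_bin)
    base_k2 = cohens_kappa(binarize(full), ref_bin)

    def rel(new, base):
        return float("nan") if base == 0 else (new - base) / base * 100.0

    rows = []
    for feat in table.feature_names:
        pred = run_models(table, cfg, exclude=feat)
        acc3, k3 = accuracy(pred, ref), cohens_kappa(pred, ref)
        pred2 = binarize(pred)
        acc2, k2 = accuracy(pred2, ref_bin), cohens_kappa(pred2, ref_bin)
        rows.append({
            "excluded_feature": feat,
            "accuracy_3class": acc3, "kappa_3class": k3,
            "rel_accuracy_3class_pct": rel(acc3, base_acc3),
            "rel_kappa_3class_pct": rel(k3, base_k3),
            "accuracy_binary": acc2, "kappa_binary": k2,
            "rel_accuracy_binary_pct": rel(acc2, base_acc2),
            "rel_kappa_binary_pct": rel(k2, base_k2),
        })
    out = pd.DataFrame(rows)
    out.attrs["baseline"] = {"accuracy_3class": base_acc3, "kappa_3class": base_k3,
                             "accuracy_binary": base_acc2, "kappa_binary": base_k2}
    return out
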
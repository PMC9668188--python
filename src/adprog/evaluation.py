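"""One-vs-rest ROC evaluation and the paired permutation test.

Discrimination is summarized per baseline group and follow-up year: for
participants who were CN at baseline the positive class is MCI (the
predicted MCI probability scores the conversion), for MCI baselines it is
AD.  ROC curves from repeated splits are averaged vertically on a fixed
false-positive-rate grid.  Two models are compared with a paired
permutation test whose statistic is the split-level, year-averaged AUC
difference averaged over repeats; the null is built by randomly swapping
the two models within each split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ovr_auc",
    "auc_table",
    "average_roc",
    "permutation_test",
    "PermutationResult",
    "POSITIVE_CLASS",
]

logger = logging.getLogger(__name__)

#: positive class (and its probability column) per baseline group
POSITIVE_CLASS = {"CN": ("MCI", "p_mci"), "MCI": ("AD", "p_ad")}

FPR_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


def ovr_auc(scores, positives) -> float | None:
    """One-vs-rest AUC: positive-class score against the binary label.

    Ties are credited 0.5 (the Mann-Whitney convention).  Returns None for
    a single-class set (mirrors sparse early follow-up years), logging the
    skip.
    """
    positives = np.asarray(positives, dtype=bool)
    if positives.all() or not positives.any():
        logger.info("single-class evaluation set skipped (n=%d)", len(positives))
        return None
    return float(roc_auc_score(positives, np.asarray(scores, dtype=float)))


def auc_table(predictions: pd.DataFrame, labels: pd.DataFrame,
              baseline: pd.DataFrame, model: str = "model") -> pd.DataFrame:
    """Per (group, year, repeat) one-vs-rest AUC from test predictions.

    ``predictions`` carries repeat/id/year and the three class probability
    columns; ``labels`` supplies the ground-truth label per (id, year);
    ``baseline`` supplies each participant's baseline diagnosis.
    """
    dx = baseline.set_index("id")["baseline_dx"]
    lab = labels.set_index(["id", "year"])["label"]
    frame = predictions.copy()
    frame["group"] = frame["id"].map(dx)
    frame["label"] = [lab.get((i, y)) for i, y in zip(frame["id"], frame["year"])]

    rows = []
    for (group, year, repeat), grp in frame.groupby(["group", "year", "repeat"]):
        pos_label, pcol = POSITIVE_CLASS[group]
        auc = ovr_auc(grp[pcol], grp["label"] == pos_label)
        if auc is not None:
            rows.append((model, group, int(year), int(repeat), auc))
    return pd.DataFrame(rows, columns=["model", "group", "year", "repeat", "auc"])


def average_roc(curves: list[tuple[np.ndarray, np.ndarray]],
                grid: np.ndarray = FPR_GRID) -> pd.DataFrame:
    """Vertical averaging of ROC curves on a fixed FPR grid.

    Each (fpr, tpr) curve is linearly interpolated onto ``grid``; the
    band is +/- one standard error across curves (zero width for a single
    curve or identical curves).
    """
    if not curves:
        raise ValueError("need at least one curve")
    tprs = np.stack([np.interp(grid, np.asarray(f), np.asarray(t))
                     for f, t in curves])
    mean = tprs.mean(axis=0)
    se = (tprs.std(axis=0, ddof=1) / np.sqrt(len(curves))
          if len(curves) > 1 else np.zeros_like(mean))
    return pd.DataFrame({"fpr": grid, "tpr": mean,
                         "lo": mean - se, "hi": mean + se})


def roc_points(scores, positives) -> tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper returning a (fpr, tpr) pair for one split."""
    fpr, tpr, _ = roc_curve(np.asarray(positives, dtype=int),
                            np.asarray(scores, dtype=float))
    return fpr, tpr


@dataclass
class PermutationResult:
    """Outcome of the paired model comparison.

    ``p_value`` is the normalized rank of the observed statistic among the
    permuted ones, one-sided on the signed statistic (testing A > B); the
    add-one rank convention keeps it strictly positive.  Swapping the two
    models negates the observed statistic, so a two-sided p is available
    by doubling the smaller tail.
    """

    observed: float
    p_value: float
    n_perm: int
    seed: int
    n_repeats: int

    def to_json(self) -> str:
        return json.dumps({
            "observed": self.observed, "p_value": self.p_value,
            "n_perm": self.n_perm, "seed": self.seed,
            "n_repeats": self.n_repeats,
        })


def _year_mean_diff(auc_a: pd.DataFrame, auc_b: pd.DataFrame) -> np.ndarray:
    """Per-repeat, year-averaged AUC difference (A - B), aligned on keys.

    Years missing an entry on either side (skipped single-class years)
    drop symmetrically from both models' year means.
    """
    a = auc_a.set_index(["group", "year", "repeat"])["auc"]
    b = auc_b.set_index(["group", "year", "repeat"])["auc"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no aligned (group, year, repeat) AUC entries")
    diff = (a.loc[common] - b.loc[common]).rename("diff").reset_index()
    per_repeat = diff.groupby("repeat")["diff"].mean()
    return per_repeat.to_numpy(dtype=float)


def permutation_test(auc_a: pd.DataFrame, auc_b: pd.DataFrame,
                     n_perm: int = 100_000, seed: int = 0) -> PermutationResult:
    """Paired permutation test for the AUC difference between two models.

    The test statistic is the mean over repeats of the year-averaged AUC
    difference.  Each null draw independently swaps the two models within
    each repeat, which flips the sign of that repeat's year-averaged
    difference.  The p-value is (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 is refused (unstable p-value)")
    d = _year_mean_diff(auc_a, auc_b)
    observed = float(d.mean())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 271]))
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = (signs * d).mean(axis=1)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return PermutationResult(observed=observed, p_value=float(p),
                             n_perm=int(n_perm), seed=int(seed),
                             n_repeats=int(d.size))
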
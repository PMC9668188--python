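"""Biomarker-contribution ablation and continuous risk trajectories.

The multi-horizon model accepts a missingness mask, so the contribution of
each biomarker modality can be measured at test time: restrict to test
participants with complete baseline data, force every variable outside a
scenario's keep-set to "missing" (placeholder value + mask bit), and
compare the resulting AUC with a clinical-data-only (CD-only) baseline
scenario on the identical subjects.  PIB is exempt from the completeness
requirement and stays masked in every scenario, since it is essentially
never acquired.

The same model also yields continuous conversion-risk curves: evaluated on
a monthly grid of horizons with baseline-only inputs, the predicted MCI
probability (CN baselines) or AD probability (MCI baselines) traces each
participant's risk over the five-year window; curves are averaged within
groups sharing the same observed conversion profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import POSITIVE_CLASS, ovr_auc
from .feature_encoder import (
    BIOMARKER_MODALITIES,
    EncoderState,
    FeatureSchema,
    PIB,
    encode_frame,
)
from .training import RepeatModels

__all__ = [
    "MaskScenario",
    "standard_scenarios",
    "complete_data_ids",
    "mask_modalities",
    "delta_auc",
    "risk_trajectory",
    "TrajectoryCurve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaskScenario:
    """Named keep-set of modalities/variables on top of clinical data.

    Clinical data (demographics, genotype, clinical and cognitive
    assessments, baseline diagnosis) is always kept; ``keep_modalities``
    and ``keep_variables`` add biomarkers.  Everything else is forced
    missing.
    """

    name: str
    keep_modalities: tuple[str, ...] = ()
    keep_variables: tuple[str, ...] = ()

    def kept_variables(self, schema: FeatureSchema) -> set[str]:
        kept: set[str] = set()
        for name in schema.maskable_names:
            modality = schema.modality_of(name)
            if modality not in BIOMARKER_MODALITIES:
                kept.add(name)  # clinical data always kept
            elif modality in self.keep_modalities and modality != PIB:
                kept.add(name)
            elif name in self.keep_variables:
                kept.add(name)
        return kept


def standard_scenarios() -> list[MaskScenario]:
    """The modality-contribution scenarios reported by the analysis."""
    return [
        MaskScenario("CD-only"),
        MaskScenario("CD+FDG", keep_modalities=("fdg",)),
        MaskScenario("CD+CSF", keep_modalities=("csf",)),
        MaskScenario("CD+AV45", keep_modalities=("av45",)),
        MaskScenario("CD+Hippocampus/ICV",
                     keep_variables=("mri_hippocampus", "mri_icv")),
        MaskScenario("CD+MRI", keep_modalities=("mri",)),
        MaskScenario("CD+All", keep_modalities=("csf", "mri", "fdg", "av45")),
    ]


def complete_data_ids(baseline: pd.DataFrame, schema: FeatureSchema) -> list:
    """Participants with no missing baseline variable (PIB exempt)."""
    required = [v for v in schema.maskable_names if schema.modality_of(v) != PIB]
    complete = baseline[required].notna().all(axis=1)
    return list(baseline.loc[complete, "id"])


def mask_modalities(rows: pd.DataFrame, scenario: MaskScenario,
                    encoder: EncoderState,
                    delta_t=None) -> np.ndarray:
    """Encode rows with everything outside the scenario's keep-set masked.

    Masked variables get the mask bit 1 and the training placeholder value
    (which z-scores to 0 for numericals), exactly as a genuinely missing
    variable would.
    """
    schema = encoder.schema
    kept = scenario.kept_variables(schema)
    masked = rows.copy()
    for name in schema.maskable_names:
        if name not in kept:
            masked[name] = np.nan
    return encode_frame(masked, encoder, delta_t=delta_t)


def delta_auc(models: list[RepeatModels], baseline: pd.DataFrame,
              labels: pd.DataFrame,
              scenarios: list[MaskScenario] | None = None,
              rounded_delta_t: bool = False) -> pd.DataFrame:
    """AUC gain of each scenario over CD-only, per (group, year).

    Every scenario is evaluated on the identical complete-baseline test
    subjects of each trained repeat, so differences are attributable to
    the masked inputs alone.  Returns columns ``scenario, group, year,
    repeat, auc, delta_auc``.
    """
    scenarios = scenarios or standard_scenarios()
    if not any(s.name == "CD-only" for s in scenarios):
        scenarios = [MaskScenario("CD-only")] + list(scenarios)
    base_ids_all = baseline.set_index("id", drop=False)

    rows = []
    for rm in models:
        schema = rm.encoder.schema
        complete = set(complete_data_ids(baseline, schema))
        ens = rm.ensemble_for(None) if rm.kind == "nmm" else None
        eligible = complete & set(rm.test_ids) if rm.test_ids else complete
        lab = labels[labels["id"].isin(eligible)]
        if lab.empty:
            logger.info("repeat %d: empty complete-data subset, skipped",
                        rm.repeat_index)
            continue
        from .training import _delta_col
        for scenario in scenarios:
            for year, ygrp in lab.groupby("year"):
                sub = base_ids_all.loc[ygrp["id"]]
                dt = _delta_col(ygrp, rounded_delta_t)
                if rm.kind == "nmm":
                    X = mask_modalities(sub, scenario, rm.encoder, delta_t=dt)
                    P = ens.predict_proba_encoded(X)
                else:
                    e = rm.ensemble_for(int(year))
                    X = mask_modalities(sub, scenario, rm.encoder)
                    P = e.predict_proba_encoded(X)
                probs = pd.DataFrame(P, columns=["p_cn", "p_mci", "p_ad"])
                for group in ("CN", "MCI"):
                    gmask = (sub["baseline_dx"] == group).to_numpy()
                    if gmask.sum() == 0:
                        continue
                    pos_label, pcol = POSITIVE_CLASS[group]
                    auc = ovr_auc(probs.loc[gmask, pcol],
                                  (ygrp["label"].to_numpy()[gmask] == pos_label))
                    if auc is not None:
                        rows.append((scenario.name, group, int(year),
                                     rm.repeat_index, auc))
    out = pd.DataFrame(rows, columns=["scenario", "group", "year",
                                      "repeat", "auc"])
    ref = out[out["scenario"] == "CD-only"].set_index(
        ["group", "year", "repeat"])["auc"]
    out["delta_auc"] = [
        auc - ref.get((g, y, r), np.nan)
        for auc, g, y, r in zip(out["auc"], out["group"], out["year"],
                                out["repeat"])
    ]
    return out


# ---------------------------------------------------------------------------
# Risk trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryCurve:
    """Mean predicted conversion risk over a monthly horizon grid.

    ``band`` is the 68% band: mean +/- one standard error of the mean
    across the participants sharing the profile.
    """

    profile: str
    months: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "profile": self.profile, "month": self.months,
            "mean": self.mean, "lo": self.lo, "hi": self.hi, "n": self.n,
        })


def conversion_profiles(labels: pd.DataFrame) -> pd.Series:
    """Profile label per participant: converter at year k, or stable
    through a last visit at year k.  Partitions the participants."""
    out = {}
    for pid, grp in labels.groupby("id"):
        conv = grp[grp["category"].str.endswith("converter")]
        if len(conv):
            out[pid] = f"converter, year {int(conv['year'].min())}"
        else:
            out[pid] = f"stable, last seen year {int(grp['year'].max())}"
    return pd.Series(out, name="profile")


def risk_trajectory(models: RepeatModels, baseline: pd.DataFrame,
                    labels: pd.DataFrame, subject_ids: list,
                    months: np.ndarray | None = None) -> list[TrajectoryCurve]:
    """Continuous risk curves of the multi-horizon model by profile.

    Inputs are baseline-only; the model never sees follow-up data.  For
    each subject the ensemble is evaluated at every grid horizon; the
    conversion channel is the MCI probability for CN baselines and the AD
    probability for MCI baselines.  Curves average subjects within a
    conversion profile; empty profiles are omitted.
    """
    if models.kind != "nmm":
        raise ValueError("risk trajectories require the multi-horizon model")
    months = np.arange(0, 61) if months is None else np.asarray(months)
    base = baseline.set_index("id", drop=False).loc[subject_ids]
    profiles = conversion_profiles(labels[labels["id"].isin(set(subject_ids))])
    ens = models.ensemble_for(None)

    # risk[subject, month]
    risk = np.zeros((len(base), len(months)))
    channel = np.where(base["baseline_dx"].to_numpy() == "CN", 1, 2)
    for j, m in enumerate(months):
        P = ens.predict_proba(base, delta_t=float(m))
        risk[:, j] = P[np.arange(len(base)), channel]

    curves = []
    prof_of = profiles.reindex(base["id"]).to_numpy()
    for profile in sorted(pd.unique(prof_of[pd.notna(prof_of)])):
        sel = prof_of == profile
        n = int(sel.sum())
        if n == 0:
            logger.info("profile %r empty, omitted", profile)
            continue
        sub = risk[sel]
        mean = sub.mean(axis=0)
        se = sub.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
        curves.append(TrajectoryCurve(profile=profile, months=months,
                                      mean=mean, lo=mean - se, hi=mean + se,
                                      n=n))
    return curves
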
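"""Baseline feature schema and leakage-free encoding.

Raw baseline rows (one per participant) are transformed into fixed-length
model input vectors.  Missing values are never dropped: a missing
categorical is substituted by the training-set mode, a missing numerical by
the training-set mean, and a binary missingness mask (1 = missing) is
concatenated so the classifier can learn to discount the placeholders.
All substitution and z-scoring statistics are fitted on the training
partition only and frozen in an :class:`EncoderState`.

Vector layout (fixed, frozen in the schema):

    [ one-hot categoricals (17) | baseline dx (1) | z-scored numericals (45)
      | missingness mask (50) | optional time-to-follow-up in months ]

which gives 113 entries for single-horizon models and 114 when the
follow-up time is an input.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CategoricalVar",
    "NumericalVar",
    "FeatureSchema",
    "EncoderState",
    "EncodedSample",
    "default_schema",
    "fit_encoder",
    "encode",
    "encode_frame",
]


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoricalVar:
    name: str
    levels: tuple[str, ...]
    modality: str


@dataclass(frozen=True)
class NumericalVar:
    name: str
    modality: str


@dataclass(frozen=True)
class FeatureSchema:
    """Frozen description of the baseline feature set.

    ``categoricals`` are one-hot encoded (their widths sum to 17 in the
    default schema); ``numericals`` are z-scored scalars (45 by default).
    The baseline diagnosis is a separate scalar (0 = CN, 1 = MCI) with no
    mask entry, so the mask covers 5 + 45 = 50 variables.
    """

    categoricals: tuple[CategoricalVar, ...]
    numericals: tuple[NumericalVar, ...]
    dx_column: str = "baseline_dx"

    @property
    def categorical_names(self) -> list[str]:
        return [c.name for c in self.categoricals]

    @property
    def numerical_names(self) -> list[str]:
        return [v.name for v in self.numericals]

    @property
    def maskable_names(self) -> list[str]:
        return self.categorical_names + self.numerical_names

    @property
    def one_hot_width(self) -> int:
        return sum(len(c.levels) for c in self.categoricals)

    @property
    def mask_width(self) -> int:
        return len(self.categoricals) + len(self.numericals)

    @property
    def vector_length(self) -> int:
        return self.one_hot_width + 1 + len(self.numericals) + self.mask_width

    def modality_of(self, name: str) -> str:
        for c in self.categoricals:
            if c.name == name:
                return c.modality
        for v in self.numericals:
            if v.name == name:
                return v.modality
        raise KeyError(name)

    def variables_in_modality(self, modality: str) -> list[str]:
        out = [c.name for c in self.categoricals if c.modality == modality]
        out += [v.name for v in self.numericals if v.modality == modality]
        return out

    @property
    def modalities(self) -> list[str]:
        seen: list[str] = []
        for name in self.maskable_names:
            m = self.modality_of(name)
            if m not in seen:
                seen.append(m)
        return seen

    def feature_names(self, with_delta_t: bool = False) -> list[str]:
        """Column names of the encoded vector, in concatenation order."""
        names: list[str] = []
        for c in self.categoricals:
            names += [f"{c.name}={lvl}" for lvl in c.levels]
        names.append(self.dx_column)
        names += self.numerical_names
        names += [f"mask:{v}" for v in self.maskable_names]
        if with_delta_t:
            names.append("delta_t")
        return names

    def to_yaml(self) -> str:
        doc = {
            "categoricals": [
                {"name": c.name, "levels": list(c.levels), "modality": c.modality}
                for c in self.categoricals
            ],
            "numericals": [
                {"name": v.name, "modality": v.modality} for v in self.numericals
            ],
            "dx_column": self.dx_column,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FeatureSchema":
        doc = yaml.safe_load(text)
        return cls(
            categoricals=tuple(
                CategoricalVar(d["name"], tuple(d["levels"]), d["modality"])
                for d in doc["categoricals"]
            ),
            numericals=tuple(
                NumericalVar(d["name"], d["modality"]) for d in doc["numericals"]
            ),
            dx_column=doc.get("dx_column", "baseline_dx"),
        )


# Modality labels
DEMOGRAPHICS = "demographics"
GENOTYPE = "genotype"
CLINICAL = "clinical_assessments"
COGNITIVE = "cognitive_assessments"
CSF = "csf"
MRI = "mri"
FDG = "fdg"
AV45 = "av45"
PIB = "pib"

#: Modalities reported with block-level missingness (demographics and
#: genotype are essentially complete in practice, but remain maskable).
BIOMARKER_MODALITIES = (CSF, MRI, FDG, AV45, PIB)


def default_schema() -> FeatureSchema:
    """The study's baseline feature schema.

    45 real-valued variables (ECog is a 14-vector, ADAS-Cog a 3-vector and
    RAVLT a 4-vector, each component separately maskable), 5 one-hot
    categoricals of total width 17, and the scalar baseline diagnosis.
    """
    categoricals = (
        CategoricalVar("sex", ("Female", "Male"), DEMOGRAPHICS),
        CategoricalVar("ethnicity", ("Hisp/Latino", "Not Hisp/Latino"), DEMOGRAPHICS),
        CategoricalVar(
            "race",
            ("Asian", "Black", "Hawaiian/Other PI", "Indian/Alaskan",
             "More than one", "White"),
            DEMOGRAPHICS,
        ),
        CategoricalVar(
            "marital", ("Divorced", "Married", "Never married", "Widowed"),
            DEMOGRAPHICS,
        ),
        CategoricalVar("apoe4", ("0", "1", "2"), GENOTYPE),
    )
    numericals = (
        [NumericalVar("age", DEMOGRAPHICS), NumericalVar("education", DEMOGRAPHICS)]
        + [NumericalVar("cdr", CLINICAL), NumericalVar("faq", CLINICAL)]
        + [NumericalVar(f"ecog_{i}", CLINICAL) for i in range(1, 15)]
        + [NumericalVar("mmse", COGNITIVE)]
        + [NumericalVar(f"adas_{i}", COGNITIVE) for i in range(1, 4)]
        + [NumericalVar("moca", COGNITIVE)]
        + [NumericalVar(f"ravlt_{i}", COGNITIVE) for i in range(1, 5)]
        + [NumericalVar("ldel", COGNITIVE), NumericalVar("trabscor", COGNITIVE),
           NumericalVar("digit", COGNITIVE), NumericalVar("pacc_digit", COGNITIVE),
           NumericalVar("pacc_trails", COGNITIVE)]
        + [NumericalVar("csf_abeta", CSF), NumericalVar("csf_tau", CSF),
           NumericalVar("csf_ptau", CSF)]
        + [NumericalVar("mri_ventricles", MRI), NumericalVar("mri_hippocampus", MRI),
           NumericalVar("mri_wholebrain", MRI), NumericalVar("mri_entorhinal", MRI),
           NumericalVar("mri_fusiform", MRI), NumericalVar("mri_midtemp", MRI),
           NumericalVar("mri_icv", MRI)]
        + [NumericalVar("fdg", FDG), NumericalVar("av45", AV45),
           NumericalVar("pib", PIB)]
    )
    return FeatureSchema(categoricals=categoricals, numericals=tuple(numericals))


# ---------------------------------------------------------------------------
# Encoder state
# ---------------------------------------------------------------------------

class EncoderFitError(ValueError):
    pass


class EncodingError(ValueError):
    pass


@dataclass
class EncoderState:
    """Training-set statistics frozen for leakage-free encoding."""

    schema: FeatureSchema
    modes: dict[str, str]
    means: dict[str, float]
    z_mean: dict[str, float]
    z_sd: dict[str, float]
    fingerprint: str = ""

    def to_json(self) -> str:
        doc = {
            "schema": yaml.safe_load(self.schema.to_yaml()),
            "modes": self.modes,
            "means": self.means,
            "z_mean": self.z_mean,
            "z_sd": self.z_sd,
            "fingerprint": self.fingerprint,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EncoderState":
        doc = json.loads(text)
        schema = FeatureSchema.from_yaml(yaml.safe_dump(doc["schema"]))
        return cls(
            schema=schema,
            modes=doc["modes"],
            means={k: float(v) for k, v in doc["means"].items()},
            z_mean={k: float(v) for k, v in doc["z_mean"].items()},
            z_sd={k: float(v) for k, v in doc["z_sd"].items()},
            fingerprint=doc["fingerprint"],
        )


@dataclass
class EncodedSample:
    """One model input row: feature vector, one-hot label, sample weight."""

    x: np.ndarray
    y: np.ndarray | None = None
    w: float = 1.0
    delta_t: float | None = None
    id: object = None
    year: int | None = None


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return pd.isna(v)


def _state_fingerprint(state: EncoderState) -> str:
    payload = json.dumps(
        [state.modes, state.means, state.z_mean, state.z_sd], sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def fit_encoder(train_rows: pd.DataFrame, schema: FeatureSchema) -> EncoderState:
    """Fit substitution and z-score statistics on the training partition.

    Every non-missing training value counts equally; mode ties break by
    lexicographic level order.  A variable missing in every training row is
    a fit error.  A zero-variance column gets sd 1 (with a warning) so
    encoding never divides by zero.
    """
    if len(train_rows) == 0:
        raise EncoderFitError("empty training partition")

    modes: dict[str, str] = {}
    for cat in schema.categoricals:
        col = train_rows[cat.name]
        observed = col[~col.map(_is_missing)].astype(str)
        if observed.empty:
            raise EncoderFitError(f"variable {cat.name!r} missing in all training rows")
        counts = observed.value_counts()
        top = counts[counts == counts.max()].index
        modes[cat.name] = sorted(top)[0]  # lexicographic tie-break

    means: dict[str, float] = {}
    z_mean: dict[str, float] = {}
    z_sd: dict[str, float] = {}
    for var in schema.numericals:
        col = pd.to_numeric(train_rows[var.name], errors="coerce")
        observed = col.dropna()
        if observed.empty:
            raise EncoderFitError(f"variable {var.name!r} missing in all training rows")
        mu = float(observed.mean())
        sd = float(observed.std(ddof=0))
        if sd <= 1e-10 * max(1.0, abs(mu)):  # constant up to roundoff
            warnings.warn(f"zero-variance training column {var.name!r}; sd set to 1")
            sd = 1.0
        means[var.name] = mu
        z_mean[var.name] = mu
        z_sd[var.name] = sd

    state = EncoderState(schema=schema, modes=modes, means=means,
                         z_mean=z_mean, z_sd=z_sd)
    state.fingerprint = _state_fingerprint(state)
    return state


def _encode_dx(value) -> float:
    if value in (0, 1):
        return float(value)
    if isinstance(value, str):
        if value.upper() == "CN":
            return 0.0
        if value.upper() == "MCI":
            return 1.0
    raise EncodingError(f"baseline diagnosis must be CN or MCI, got {value!r}")


def encode(row, encoder: EncoderState, delta_t: float | None = None) -> EncodedSample:
    """Encode one baseline row into the fixed-length input vector.

    Pure function of (row, encoder, delta_t); never mutates the encoder.
    """
    schema = encoder.schema
    one_hot: list[float] = []
    mask: list[float] = []
    for cat in schema.categoricals:
        v = row[cat.name]
        missing = _is_missing(v)
        level = encoder.modes[cat.name] if missing else str(v)
        if level not in cat.levels:
            raise EncodingError(f"unseen level {level!r} for variable {cat.name!r}")
        block = [0.0] * len(cat.levels)
        block[cat.levels.index(level)] = 1.0
        one_hot += block
        mask.append(1.0 if missing else 0.0)

    dx = _encode_dx(row[schema.dx_column])

    nums: list[float] = []
    for var in schema.numericals:
        v = row[var.name]
        missing = _is_missing(v)
        raw = encoder.means[var.name] if missing else float(v)
        nums.append((raw - encoder.z_mean[var.name]) / encoder.z_sd[var.name])
        mask.append(1.0 if missing else 0.0)

    parts = one_hot + [dx] + nums + mask
    if delta_t is not None:
        parts.append(float(delta_t))
    return EncodedSample(
        x=np.asarray(parts, dtype=np.float64),
        delta_t=None if delta_t is None else float(delta_t),
        id=row.get("id") if hasattr(row, "get") else None,
    )


def encode_frame(
    rows: pd.DataFrame,
    encoder: EncoderState,
    delta_t: np.ndarray | float | None = None,
) -> np.ndarray:
    """Vectorized :func:`encode` over a DataFrame; returns (n, 113|114)."""
    schema = encoder.schema
    n = len(rows)
    cols: list[np.ndarray] = []
    mask_cols: list[np.ndarray] = []

    for cat in schema.categoricals:
        col = rows[cat.name]
        missing = col.map(_is_missing).to_numpy()
        levels = col.astype("object").where(~missing, encoder.modes[cat.name]).astype(str)
        bad = ~levels.isin(cat.levels)
        if bad.any():
            raise EncodingError(
                f"unseen level {levels[bad].iloc[0]!r} for variable {cat.name!r}"
            )
        for lvl in cat.levels:
            cols.append((levels == lvl).to_numpy(dtype=np.float64))
        mask_cols.append(missing.astype(np.float64))

    cols.append(rows[schema.dx_column].map(_encode_dx).to_numpy(dtype=np.float64))

    for var in schema.numericals:
        col = pd.to_numeric(rows[var.name], errors="coerce")
        missing = col.isna().to_numpy()
        vals = col.fillna(encoder.means[var.name]).to_numpy(dtype=np.float64)
        cols.append((vals - encoder.z_mean[var.name]) / encoder.z_sd[var.name])
        mask_cols.append(missing.astype(np.float64))

    cols += mask_cols
    if delta_t is not None:
        dt = np.broadcast_to(np.asarray(delta_t, dtype=np.float64), (n,))
        cols.append(np.array(dt))
    return np.column_stack(cols) if n else np.empty((0, schema.vector_length + (delta_t is not None)))
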
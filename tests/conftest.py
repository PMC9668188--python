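import numpy as np
import pandas as pd
import pytest

from adprog import (
    GeneratorConfig,
    apply_exclusions,
    build_labels,
    default_schema,
    fit_encoder,
    generate_cohort,
    records_from_frames,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort():
    """A labeled synthetic cohort shared by read-only tests."""
    cohort = generate_cohort(GeneratorConfig(n_participants=500, seed=42))
    records = records_from_frames(cohort.baseline, cohort.visits)
    kept, log = apply_exclusions(records, horizon_years=5)
    labels = build_labels(kept, horizon_years=5)
    kept_ids = {r.id for r in kept}
    baseline = cohort.baseline[cohort.baseline["id"].isin(kept_ids)]
    return baseline.reset_index(drop=True), labels, log, cohort


@pytest.fixture(scope="session")
def fitted_encoder(small_cohort, schema):
    baseline, _, _, _ = small_cohort
    return fit_encoder(baseline, schema)


def make_raw_frame(schema, n, seed, missing_frac=0.0):
    """Random raw baseline frame conforming to the schema."""
    rng = np.random.default_rng(seed)
    data = {"id": [f"P{i}" for i in range(n)],
            "baseline_dx": rng.choice(["CN", "MCI"], size=n)}
    for cat in schema.categoricals:
        data[cat.name] = rng.choice(cat.levels, size=n)
    for var in schema.numericals:
        data[var.name] = rng.normal(size=n)
    frame = pd.DataFrame(data)
    if missing_frac > 0:
        for name in schema.maskable_names:
            mask = rng.uniform(size=n) < missing_frac
            frame.loc[mask, name] = np.nan
    return frame
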
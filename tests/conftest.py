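"""Shared fixtures: small synthetic cohorts and metadata builders."""

from __future__ import annotations

import numpy as np
import pytest

from ksface.landmarks import PhotoMeta
from ksface.synth import SynthConfig, generate_cohort


def make_meta(
    n_patients: int,
    photos_each: int = 3,
    seed: int = 0,
    label: str = "control",
    age_lo: float = 1.0,
    age_hi: float = 15.0,
) -> list[PhotoMeta]:
    """Metadata-only cohort helper for model-level tests."""
    rng = np.random.default_rng(seed)
    meta = []
    for i in range(n_patients):
        gender = "male" if rng.uniform() < 0.5 else "female"
        eth = rng.choice(
            ["Caucasian", "Asian", "African/Caribbean"], p=[0.8, 0.1, 0.1]
        )
        base = rng.uniform(age_lo, age_hi)
        for j in range(photos_each):
            meta.append(
                PhotoMeta(
                    patient_id=f"P{i:03d}",
                    photo_id=f"P{i:03d}_v{j}",
                    view="frontal",
                    age=float(base + j),
                    gender=gender,
                    ethnicity=str(eth),
                    label=label,
                )
            )
    return meta


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort (landmarks, images, meta)."""
    cfg = SynthConfig(
        n_controls=14, n_ks1=8, n_ks2=4, n_ks_unknown=0,
        photos_per_patient=(1, 2), seed=11,
    )
    return generate_cohort(cfg)
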
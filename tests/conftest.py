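from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from radbalance.cohort import BoundingBox, ImageRecord

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_record(
    image_id: str,
    fracture: bool = False,
    difficulty: str | None = None,
    age: float = 10.0,
    projection: str = "ap",
    uncertain: bool = False,
    boxes: list[BoundingBox] | None = None,
    **kw,
) -> ImageRecord:
    """Terse valid-record builder for tests."""
    if difficulty is None:
        difficulty = "easy" if fracture else "not_applicable"
    if boxes is None:
        boxes = [BoundingBox(10, 10, 60, 60)] if fracture else []
    return ImageRecord(
        image_id=image_id,
        patient_age=age,
        gender=kw.pop("gender", "female"),
        laterality=kw.pop("laterality", "left"),
        projection=projection,
        study_type=kw.pop("study_type", "initial"),
        fracture=fracture,
        difficulty=difficulty,
        diagnosis_uncertain=uncertain,
        image_width=kw.pop("image_width", 640),
        image_height=kw.pop("image_height", 640),
        boxes=boxes,
        **kw,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pool() -> list[ImageRecord]:
    """8 images: 2 difficult-fracture, 2 easy-fracture, 4 controls; one projection,
    ages within the 1-year caliper of each other."""
    return [
        make_record("d1", fracture=True, difficulty="difficult", age=10.0),
        make_record("d2", fracture=True, difficulty="difficult", age=10.4),
        make_record("e1", fracture=True, difficulty="easy", age=10.2),
        make_record("e2", fracture=True, difficulty="easy", age=10.6),
        make_record("c1", age=10.1),
        make_record("c2", age=10.3),
        make_record("c3", age=10.5),
        make_record("c4", age=10.7),
    ]
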
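"""Balanced (matched) and random test-set construction, overlap, stratification.

The balanced construction is a two-stage caliper matching:

* **Stage 1** — every difficult visible-fracture image becomes an anchor and
  is matched without replacement to a distinct *easy* fracture image with the
  same projection and an age difference within the caliper (nearest age
  first).
* **Stage 2** — every fracture image selected so far (anchors and their
  matches) is matched, under the same criteria, to a distinct non-fracture
  image.

With A anchors the result has exactly 4A images: 2A fractures (50%), A of
them difficult (25% of the set).  Images carrying the "diagnosis uncertain"
tag are excluded before any sampling.  An anchor that cannot be matched is a
hard error — the construction either succeeds completely or reports exactly
which anchor failed at which stage.
"""

from __future__ import annotations

import csv
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import ImageRecord

__all__ = [
    "MatchPair",
    "TestSetSplit",
    "MatchingConfig",
    "MatchingError",
    "exclude_uncertain",
    "build_balanced_set",
    "build_random_set",
    "compute_overlap",
    "stratify",
    "write_split",
    "read_split",
    "write_pairs",
]

STAGE_DIFFICULT_TO_EASY = "difficult_to_easy"
STAGE_FRACTURE_TO_CONTROL = "fracture_to_control"


class MatchingError(RuntimeError):
    """Raised when an anchor cannot be matched at some stage."""


@dataclass(frozen=True)
class MatchPair:
    """Provenance of one anchor-to-match assignment."""

    anchor_id: str
    match_id: str
    age_delta: float
    projection: str
    stage: str

    def __post_init__(self) -> None:
        if self.anchor_id == self.match_id:
            raise ValueError("anchor and match must differ")
        if self.age_delta < 0:
            raise ValueError("age_delta must be >= 0")


@dataclass
class TestSetSplit:
    """A named, ordered set of image ids with its matching provenance."""

    __test__ = False  # not a test class, despite the name

    label: str
    image_ids: list[str]
    pairs: list[MatchPair] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ValueError("image_ids must be unique")

    def __len__(self) -> int:
        return len(self.image_ids)

    def id_set(self) -> set[str]:
        return set(self.image_ids)


@dataclass
class MatchingConfig:
    """Tolerances and determinism knobs for the balanced construction.

    ``age_caliper`` is the hard upper bound on the anchor-match age
    difference in years; projections must agree exactly.  Anchors are
    processed in a random order seeded by ``anchor_order_seed`` so the
    greedy assignment is reproducible.
    """

    age_caliper: float = 1.0
    anchor_order_seed: int = 0
    replacement: bool = False

    def validate(self) -> None:
        if self.age_caliper <= 0:
            raise ValueError("age_caliper must be > 0")


def exclude_uncertain(pool: Sequence[ImageRecord]) -> list[ImageRecord]:
    """Drop images flagged diagnosis-uncertain, preserving order."""
    return [r for r in pool if not r.diagnosis_uncertain]


class _CandidatePool:
    """Per-projection candidates ordered by (age, image_id), nearest-age lookup.

    Ties in age distance are broken by lexicographically smallest image_id so
    the assignment is deterministic across platforms.
    """

    def __init__(self, records: Iterable[ImageRecord]):
        self._by_proj: dict[str, list[tuple[float, str]]] = {}
        for r in records:
            self._by_proj.setdefault(r.projection, []).append((r.patient_age, r.image_id))
        for lst in self._by_proj.values():
            lst.sort()

    def take_nearest(
        self, projection: str, age: float, caliper: float, remove: bool = True
    ) -> tuple[str, float] | None:
        """Pop the in-caliper candidate nearest in age, or None."""
        lst = self._by_proj.get(projection)
        if not lst:
            return None
        pos = bisect_left(lst, (age, ""))

        def run_start(i: int) -> int:
            # first index of the equal-age run containing i; ids ascend inside a run
            a = lst[i][0]
            return bisect_left(lst, (a, ""))

        best: int | None = None
        if pos > 0:
            best = run_start(pos - 1)
        if pos < len(lst):
            right = pos  # ids ascend within the run starting here
            if best is None:
                best = right
            else:
                d_left = age - lst[best][0]
                d_right = lst[right][0] - age
                if d_right < d_left or (d_right == d_left and lst[right][1] < lst[best][1]):
                    best = right
        if best is None:
            return None
        cand_age, cand_id = lst[best]
        delta = abs(cand_age - age)
        if delta > caliper + 1e-12:
            return None
        if remove:
            lst.pop(best)
        return cand_id, delta

    def restore(self, projection: str, age: float, image_id: str) -> None:
        insort(self._by_proj.setdefault(projection, []), (age, image_id))


def _match_stage(
    anchors: Sequence[ImageRecord],
    candidates: _CandidatePool,
    cfg: MatchingConfig,
    stage: str,
) -> list[MatchPair]:
    pairs: list[MatchPair] = []
    for anchor in anchors:
        found = candidates.take_nearest(
            anchor.projection, anchor.patient_age, cfg.age_caliper, remove=not cfg.replacement
        )
        if found is None:
            raise MatchingError(
                f"anchor {anchor.image_id!r} (projection={anchor.projection}, "
                f"age={anchor.patient_age}) has no candidate within caliper "
                f"{cfg.age_caliper} at stage {stage!r}"
            )
        match_id, delta = found
        pairs.append(
            MatchPair(
                anchor_id=anchor.image_id,
                match_id=match_id,
                age_delta=delta,
                projection=anchor.projection,
                stage=stage,
            )
        )
    return pairs


def build_balanced_set(
    pool: Sequence[ImageRecord],
    cfg: MatchingConfig | None = None,
    max_anchors: int | None = None,
) -> tuple[TestSetSplit, list[MatchPair]]:
    """Run the two-stage matched construction on an eligible pool.

    ``max_anchors`` caps the number of difficult-fracture anchors (after the
    seeded shuffle) so oversized synthetic pools can reproduce a target set
    size exactly.  Returns the split together with the provenance pairs of
    both stages (also stored on the split).
    """
    cfg = cfg or MatchingConfig()
    cfg.validate()
    eligible = exclude_uncertain(pool)
    by_id = {r.image_id: r for r in eligible}
    if len(by_id) != len(eligible):
        raise ValueError("pool contains duplicate image ids")

    rng = np.random.default_rng(cfg.anchor_order_seed)

    anchors = [r for r in eligible if r.fracture and r.difficulty == "difficult"]
    anchors = [anchors[i] for i in rng.permutation(len(anchors))]
    if max_anchors is not None:
        if max_anchors > len(anchors):
            raise MatchingError(
                f"requested {max_anchors} anchors but pool has only {len(anchors)} "
                "difficult fracture images"
            )
        anchors = anchors[:max_anchors]

    easy_pool = _CandidatePool(r for r in eligible if r.fracture and r.difficulty == "easy")
    stage1 = _match_stage(anchors, easy_pool, cfg, STAGE_DIFFICULT_TO_EASY)

    fracture_ids = [a.image_id for a in anchors] + [p.match_id for p in stage1]
    fracture_records = [by_id[i] for i in fracture_ids]
    fracture_records = [fracture_records[i] for i in rng.permutation(len(fracture_records))]

    control_pool = _CandidatePool(r for r in eligible if not r.fracture)
    stage2 = _match_stage(fracture_records, control_pool, cfg, STAGE_FRACTURE_TO_CONTROL)

    ordered_ids: list[str] = []
    for p in stage1:
        ordered_ids.extend((p.anchor_id, p.match_id))
    ordered_ids.extend(p.match_id for p in stage2)
    pairs = stage1 + stage2
    split = TestSetSplit(
        label="balanced", image_ids=ordered_ids, pairs=pairs, seed=cfg.anchor_order_seed
    )
    return split, pairs


def build_random_set(pool: Sequence[ImageRecord], n: int, seed: int) -> TestSetSplit:
    """Uniform sample of ``n`` eligible images without replacement."""
    eligible = exclude_uncertain(pool)
    if n > len(eligible):
        raise ValueError(f"requested {n} images from an eligible pool of {len(eligible)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return TestSetSplit(label="random", image_ids=[eligible[i].image_id for i in idx], seed=seed)


def compute_overlap(a: TestSetSplit, b: TestSetSplit) -> TestSetSplit:
    """Images present in both splits, in sorted-id order."""
    common = sorted(a.id_set() & b.id_set())
    return TestSetSplit(label="overlap", image_ids=common)


def stratify(
    split: TestSetSplit, records: Sequence[ImageRecord] | Mapping[str, ImageRecord]
) -> dict[str, list[str]]:
    """Partition a split into easy_fracture / difficult_fracture / no_fracture id lists."""
    by_id = records if isinstance(records, Mapping) else {r.image_id: r for r in records}
    out: dict[str, list[str]] = {
        "easy_fracture": [],
        "difficult_fracture": [],
        "no_fracture": [],
    }
    for image_id in split.image_ids:
        try:
            rec = by_id[image_id]
        except KeyError:
            raise KeyError(f"split id {image_id!r} not found among records") from None
        out[rec.stratum].append(image_id)
    return out


# ---------------------------------------------------------------------------
# serialization


def write_split(split: TestSetSplit, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "label"])
        for image_id in split.image_ids:
            writer.writerow([image_id, split.label])


def read_split(path: str | Path) -> TestSetSplit:
    ids: list[str] = []
    label = "custom"
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ids.append(row["image_id"])
            label = row["label"]
    return TestSetSplit(label=label, image_ids=ids)


def write_pairs(pairs: Sequence[MatchPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["anchor_id", "match_id", "stage", "age_delta", "projection"])
        for p in pairs:
            writer.writerow(
                [p.anchor_id, p.match_id, p.stage, format(p.age_delta, ".10g"), p.projection]
            )
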
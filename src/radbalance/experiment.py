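"""End-to-end study replica on synthetic data.

``run_experiment`` chains the full pipeline: generate a cohort, build the
balanced (matched) and random test sets and their overlap, simulate every
classifier and detector variant, evaluate each variant per split and
difficulty stratum, and run paired sign tests comparing the balanced and
random conditions across variants.  Every stage draws its seed
deterministically from the master seed, so a run is reproducible end to end
and stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import metrics as M
from . import sampler as S
from .cohort import Detection, ImageRecord, write_detections, write_metadata, write_scores
from .stats import compare_conditions
from .synthetic import (
    CohortConfig,
    VariantProfile,
    classifier_ladder,
    detector_ladder,
    generate_cohort,
    simulate_classifier,
    simulate_detector,
    table2_defaults,
)

__all__ = [
    "ExperimentConfig",
    "MetricsReport",
    "child_seed",
    "build_study_pool",
    "run_experiment",
    "write_report",
    "read_report",
    "load_experiment_config",
    "CLASSIFIER_METRICS",
    "DETECTOR_METRICS",
]

log = logging.getLogger("radbalance")

SPLITS = ("balanced", "random", "overlap")
STRATA_REPORT = ("all", "easy_fracture", "difficult_fracture", "no_fracture")
CLASSIFIER_METRICS = (
    "precision",
    "recall",
    "accuracy",
    "f1",
    "weighted_precision",
    "weighted_recall",
    "weighted_f1",
    "auc",
)
DETECTOR_METRICS = ("ap50", "ap50_95", "det_precision", "det_recall")


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived by hashing the stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def build_study_pool(
    cohort_cfg: CohortConfig,
    match_cfg: S.MatchingConfig | None = None,
    max_anchors: int | None = None,
    max_tries: int = 50,
) -> tuple[list[ImageRecord], S.TestSetSplit, list]:
    """Generate a cohort on which the balanced construction is feasible.

    An iid draw at natural frequencies occasionally leaves an extreme-aged
    oblique fracture with no in-caliper same-projection candidate at all (the
    oblique projection is ~0.6% of images).  The study pool is therefore
    defined as a cohort draw for which the two-stage matching completes —
    rejection sampling over derived cohort seeds, deterministic given
    ``cohort_cfg.seed``.  Returns (cohort, balanced split, provenance pairs).
    """
    match_cfg = match_cfg or S.MatchingConfig()
    base_seed = cohort_cfg.seed
    last_err: Exception | None = None
    for attempt in range(max_tries):
        cohort_cfg.seed = (base_seed + attempt * 1000003) % (2**31)
        cohort = generate_cohort(cohort_cfg)
        try:
            split, pairs = S.build_balanced_set(cohort, match_cfg, max_anchors=max_anchors)
        except S.MatchingError as err:
            last_err = err
            log.info("cohort draw %d infeasible for matching (%s); redrawing", attempt, err)
            continue
        return cohort, split, pairs
    raise S.MatchingError(
        f"no feasible cohort draw in {max_tries} tries; last error: {last_err}"
    )


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=table2_defaults)
    matching: S.MatchingConfig = field(default_factory=S.MatchingConfig)
    random_set_size: int | None = None  # None: same size as the balanced set
    max_anchors: int | None = None
    classifier_variants: list[VariantProfile] = field(default_factory=classifier_ladder)
    detector_variants: list[VariantProfile] = field(default_factory=detector_ladder)
    iou_thresholds: list[float] = field(default_factory=lambda: [0.5])
    classification_threshold: float = 0.5
    output_dir: Path | None = None
    master_seed: int = 0
    #: redraw the cohort (deterministically) if the matched construction is
    #: infeasible on a draw; set False to surface the MatchingError instead
    ensure_feasible: bool = True

    def validate(self) -> None:
        self.cohort.validate()
        self.matching.validate()
        if self.random_set_size is not None and self.random_set_size > self.cohort.n_images:
            raise ValueError("random_set_size exceeds cohort size")
        if not (0.0 < self.classification_threshold <= 1.0):
            raise ValueError("classification_threshold must be in (0, 1]")
        for t in self.iou_thresholds:
            if not (0.0 < t <= 1.0):
                raise ValueError("iou_thresholds must be in (0, 1]")


@dataclass
class MetricsReport:
    """Long-format metric table: one row per (variant, split, stratum, metric)."""

    rows: list[dict] = field(default_factory=list)

    def add(self, variant: str, split: str, stratum: str, metric: str, value: float) -> None:
        self.rows.append(
            {
                "variant": variant,
                "split": split,
                "stratum": stratum,
                "metric": metric,
                "value": value,
            }
        )

    def lookup(self, split: str, stratum: str = "all") -> dict[str, dict[str, float]]:
        """Variant -> {metric -> value} for one split/stratum slice."""
        out: dict[str, dict[str, float]] = {}
        for r in self.rows:
            if r["split"] == split and r["stratum"] == stratum:
                out.setdefault(r["variant"], {})[r["metric"]] = r["value"]
        return out


def _eval_classifier(
    scores, records: Sequence[ImageRecord], threshold: float
) -> dict[str, float]:
    vals: dict[str, float] = {}
    if not records:
        return {m: math.nan for m in CLASSIFIER_METRICS}
    wm = M.weighted_metrics(scores, records, threshold)
    vals.update(
        precision=wm.precision,
        recall=wm.recall,
        accuracy=wm.accuracy,
        f1=wm.f1,
        weighted_precision=wm.weighted_precision,
        weighted_recall=wm.weighted_recall,
        weighted_f1=wm.weighted_f1,
    )
    has_both = any(r.fracture for r in records) and any(not r.fracture for r in records)
    vals["auc"] = M.roc_auc(scores, records).auc if has_both else math.nan
    return vals


def _eval_detector(
    dets: Sequence[Detection], records: Sequence[ImageRecord], iou_thr: float
) -> dict[str, float]:
    ids = {r.image_id for r in records}
    truths = {r.image_id: r.boxes for r in records}
    sub = [d for d in dets if d.image_id in ids]
    n_truth = sum(len(b) for b in truths.values())
    if n_truth == 0:
        return {m: math.nan for m in DETECTOR_METRICS}
    ap = M.ap50_95(sub, truths)
    match = M.match_detections(sub, truths, iou_thr)
    tp = int(match.tp_flags.sum())
    n_det = len(match.detections)
    return {
        "ap50": ap.ap50,
        "ap50_95": ap.ap50_95,
        "det_precision": tp / n_det if n_det else math.nan,
        "det_recall": tp / match.n_truth,
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full pipeline; returns report, comparisons, splits and cohort.

    When ``config.output_dir`` is set, all artifacts (metadata, split and
    provenance CSVs, per-variant predictions, metric reports, sign-test
    tables) are written there.
    """
    config.validate()
    t0 = time.time()
    master = config.master_seed

    cohort_cfg = config.cohort
    cohort_cfg.seed = child_seed(master, "cohort")
    match_cfg = S.MatchingConfig(
        age_caliper=config.matching.age_caliper,
        anchor_order_seed=child_seed(master, "matching"),
        replacement=config.matching.replacement,
    )
    if config.ensure_feasible:
        cohort, balanced, pairs = build_study_pool(
            cohort_cfg, match_cfg, max_anchors=config.max_anchors
        )
    else:
        cohort = generate_cohort(cohort_cfg)
        balanced, pairs = S.build_balanced_set(cohort, match_cfg, max_anchors=config.max_anchors)
    by_id = {r.image_id: r for r in cohort}
    log.info("generated cohort of %d images", len(cohort))
    n_random = config.random_set_size or len(balanced)
    random_split = S.build_random_set(cohort, n_random, child_seed(master, "random"))
    overlap = S.compute_overlap(balanced, random_split)
    splits = {"balanced": balanced, "random": random_split, "overlap": overlap}
    log.info(
        "splits: balanced=%d random=%d overlap=%d",
        len(balanced),
        len(random_split),
        len(overlap),
    )

    split_records = {
        name: {
            stratum: [by_id[i] for i in ids]
            for stratum, ids in S.stratify(sp, by_id).items()
        }
        for name, sp in splits.items()
    }
    for name, sp in splits.items():
        split_records[name]["all"] = [by_id[i] for i in sp.image_ids]

    report = MetricsReport()
    predictions: dict[str, object] = {}
    iou_thr = config.iou_thresholds[0]

    for profile in config.classifier_variants:
        scores = simulate_classifier(cohort, profile, child_seed(master, f"cls:{profile.name}"))
        predictions[f"scores_{profile.name}"] = scores
        for split_name in SPLITS:
            for stratum in STRATA_REPORT:
                recs = split_records[split_name][stratum]
                for metric, value in _eval_classifier(
                    scores, recs, config.classification_threshold
                ).items():
                    report.add(profile.name, split_name, stratum, metric, value)
        log.info("evaluated classifier variant %s", profile.name)

    for profile in config.detector_variants:
        dets = simulate_detector(cohort, profile, child_seed(master, f"det:{profile.name}"))
        predictions[f"detections_{profile.name}"] = dets
        for split_name in SPLITS:
            for stratum in STRATA_REPORT:
                recs = split_records[split_name][stratum]
                for metric, value in _eval_detector(dets, recs, iou_thr).items():
                    report.add(profile.name, split_name, stratum, metric, value)
        log.info("evaluated detector variant %s", profile.name)

    comparisons: dict[str, list[dict]] = {}
    clf_names = {p.name for p in config.classifier_variants}
    det_names = {p.name for p in config.detector_variants}
    bal_all = report.lookup("balanced")
    rnd_all = report.lookup("random")
    if clf_names:
        comparisons["classification"] = compare_conditions(
            {v: m for v, m in bal_all.items() if v in clf_names},
            {v: m for v, m in rnd_all.items() if v in clf_names},
            CLASSIFIER_METRICS,
        )
    if det_names:
        comparisons["detection"] = compare_conditions(
            {v: m for v, m in bal_all.items() if v in det_names},
            {v: m for v, m in rnd_all.items() if v in det_names},
            DETECTOR_METRICS,
        )

    result = {
        "cohort": cohort,
        "splits": splits,
        "pairs": pairs,
        "report": report,
        "comparisons": comparisons,
        "predictions": predictions,
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_metadata(cohort, out / "cohort.csv")
        for name, sp in splits.items():
            S.write_split(sp, out / f"split_{name}.csv")
        S.write_pairs(pairs, out / "pairs_balanced.csv")
        for key, preds in predictions.items():
            if key.startswith("scores_"):
                write_scores(preds, out / f"{key}.csv")
            else:
                write_detections(preds, out / f"{key}.csv")
        write_report(report, out / "metrics")
        with open(out / "sign_tests.json", "w") as fh:
            json.dump(comparisons, fh, indent=2)
        _write_comparison_csv(comparisons, out / "sign_tests.csv")
        log.info("artifacts written to %s", out)

    log.info("experiment finished in %.1f s", time.time() - t0)
    return result


def _write_comparison_csv(comparisons: Mapping[str, list[dict]], path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["task", "metric", "n_pos", "n_neg", "n_ties", "p", "note"])
        for task, rows in comparisons.items():
            for r in rows:
                writer.writerow(
                    [
                        task,
                        r["metric"],
                        r["n_pos"],
                        r["n_neg"],
                        r["n_ties"],
                        "" if r["p"] is None else format(r["p"], ".12g"),
                        r["note"],
                    ]
                )


def write_report(report: MetricsReport, path_stem: str | Path) -> None:
    """Write a metrics report as CSV and JSON twins (``<stem>.csv``, ``<stem>.json``)."""
    import csv

    stem = Path(path_stem)
    with open(stem.with_suffix(".csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["variant", "split", "stratum", "metric", "value"])
        for r in report.rows:
            v = r["value"]
            writer.writerow(
                [
                    r["variant"],
                    r["split"],
                    r["stratum"],
                    r["metric"],
                    "nan" if isinstance(v, float) and math.isnan(v) else format(v, ".12g"),
                ]
            )
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(
            [
                {**r, "value": None if isinstance(r["value"], float) and math.isnan(r["value"]) else r["value"]}
                for r in report.rows
            ],
            fh,
            indent=2,
        )


def read_report(path_stem: str | Path) -> MetricsReport:
    import csv

    report = MetricsReport()
    with open(Path(path_stem).with_suffix(".csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            report.add(
                row["variant"], row["split"], row["stratum"], row["metric"], float(row["value"])
            )
    return report


# ---------------------------------------------------------------------------
# config files


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file.

    ``cohort`` may be the preset name ``"table2_defaults"`` or a mapping of
    :class:`CohortConfig` fields; ``classifier_variants`` /
    ``detector_variants`` may be the preset names ``"classifier_ladder"`` /
    ``"detector_ladder"`` or explicit lists of profile mappings.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    def make_cohort(spec) -> CohortConfig:
        if spec in (None, "table2_defaults"):
            return table2_defaults()
        if isinstance(spec, Mapping):
            base = table2_defaults()
            for k, v in spec.items():
                if not hasattr(base, k):
                    raise ValueError(f"unknown cohort field {k!r}")
                setattr(base, k, tuple(v) if k == "p_projection" else v)
            return base
        raise ValueError(f"bad cohort spec: {spec!r}")

    def make_variants(spec, default):
        if spec is None:
            return default()
        if spec == "classifier_ladder":
            return classifier_ladder()
        if spec == "detector_ladder":
            return detector_ladder()
        if isinstance(spec, list):
            out = []
            for d in spec:
                d = dict(d)
                for key in (
                    "cls_score_params",
                    "det_iou_quality",
                    "det_confidence_params",
                ):
                    if key in d:
                        d[key] = {k: tuple(v) for k, v in d[key].items()}
                if "fp_confidence_params" in d:
                    d["fp_confidence_params"] = tuple(d["fp_confidence_params"])
                out.append(VariantProfile(**d))
            return out
        raise ValueError(f"bad variant spec: {spec!r}")

    matching_raw = raw.get("matching") or {}
    cfg = ExperimentConfig(
        cohort=make_cohort(raw.get("cohort")),
        matching=S.MatchingConfig(**matching_raw),
        random_set_size=raw.get("random_set_size"),
        max_anchors=raw.get("max_anchors"),
        classifier_variants=make_variants(raw.get("classifier_variants"), classifier_ladder),
        detector_variants=make_variants(raw.get("detector_variants"), detector_ladder),
        iou_thresholds=list(raw.get("iou_thresholds", [0.5])),
        classification_threshold=raw.get("classification_threshold", 0.5),
        output_dir=Path(raw["output_dir"]) if raw.get("output_dir") else None,
        master_seed=int(raw.get("master_seed", 0)),
    )
    if "n_images" in raw:
        cfg.cohort.n_images = int(raw["n_images"])
    cfg.validate()
    return cfg
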
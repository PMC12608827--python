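"""Per-animal aggregation, two-group comparison, and report assembly.

The animal, not the image, is the experimental unit: per-image metric
values are first averaged within each animal, and the per-animal means
enter an unpaired two-sample t-test (Student's pooled-variance test by
default, Welch's optional), two-sided, with significance declared at
p < 0.05. Missing per-image values (e.g. an image with no complete
venular segment) are dropped from that animal's mean with the exclusion
counted. No multiple-testing correction is applied; the report records
how many tests were run so users can apply their own.

Densitometry normalization for immunoblots is the ratio of the target
band intensity to the loading-control (β-actin) band intensity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnimalSummary",
    "GroupComparison",
    "DensitometryRecord",
    "average_per_animal",
    "unpaired_t_test",
    "compare_groups",
    "densitometry_ratio",
    "build_report",
]

ALPHA = 0.05


@dataclass
class AnimalSummary:
    """Per-animal means over that animal's images."""

    animal_id: str
    group: str
    means: dict
    n_images: int
    n_missing: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"animal_id": self.animal_id, "group": self.group, "n_images": self.n_images}
        row.update(self.means)
        for metric, n in self.n_missing.items():
            row[f"{metric}_n_missing"] = n
        return row


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    variant: str = "student"
    degenerate: bool = False

    def to_row(self) -> dict:
        return dict(self.__dict__)


@dataclass
class DensitometryRecord:
    sample_id: str
    group: str
    target_band_intensity: float
    loading_band_intensity: float

    @property
    def normalized_expression(self) -> float:
        return densitometry_ratio(self.target_band_intensity, self.loading_band_intensity)

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "group": self.group,
            "target_band_intensity": self.target_band_intensity,
            "loading_band_intensity": self.loading_band_intensity,
            "normalized_expression": self.normalized_expression,
        }


def average_per_animal(
    records: Iterable[Mapping], metrics: Sequence[str] | None = None
) -> list:
    """Collapse per-image records to one :class:`AnimalSummary` per animal.

    Each record needs ``animal_id`` and ``group`` keys; an animal
    appearing under two groups is an error. ``None``/NaN metric values
    are excluded from that animal's mean, with the exclusion counted.
    """
    records = [dict(r) for r in records]
    if not records:
        return []
    if metrics is None:
        skip = {"animal_id", "group", "image_id", "unit"}
        metrics = [
            k
            for k in records[0]
            if k not in skip and isinstance(records[0][k], (int, float, type(None)))
        ]
    by_animal: dict = {}
    groups: dict = {}
    for rec in records:
        animal = str(rec["animal_id"])
        group = str(rec["group"])
        if animal in groups and groups[animal] != group:
            raise ValueError(
                f"animal {animal!r} assigned to groups {groups[animal]!r} and {group!r}"
            )
        groups[animal] = group
        by_animal.setdefault(animal, []).append(rec)
    summaries = []
    for animal in sorted(by_animal):
        recs = by_animal[animal]
        means: dict = {}
        missing: dict = {}
        for metric in metrics:
            values = [
                float(r[metric])
                for r in recs
                if metric in r
                and r[metric] is not None
                and not (isinstance(r[metric], float) and math.isnan(r[metric]))
            ]
            n_miss = len(recs) - len(values)
            if n_miss:
                missing[metric] = n_miss
            means[metric] = float(np.mean(values)) if values else None
        summaries.append(
            AnimalSummary(
                animal_id=animal,
                group=groups[animal],
                means=means,
                n_images=len(recs),
                n_missing=missing,
            )
        )
    return summaries


def unpaired_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str = "student",
    *,
    metric: str = "",
    group_a: str = "A",
    group_b: str = "B",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Two-sided unpaired t-test on two groups of per-animal means.

    ``variant`` is ``"student"`` (pooled variance) or ``"welch"``. Both
    groups need at least 2 finite values. If every value is identical in
    both groups (zero pooled variance, equal means) the comparison is
    reported as t = 0, p = 1 by convention; zero variance with unequal
    means is flagged degenerate (p = 0, infinite t).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "student"
    degenerate = False
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if equal_var:
            df = float(a.size + b.size - 2)
        else:
            df = float("nan")
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.copysign(math.inf, a.mean() - b.mean())
            p = 0.0
            degenerate = True
    else:
        import warnings

        with warnings.catch_warnings():
            # near-identical groups trip scipy's precision-loss warning;
            # exactly-constant groups are already handled above
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(sps.sem(a)),
        sem_b=float(sps.sem(b)),
        n_a=int(a.size),
        n_b=int(b.size),
        t_statistic=t_stat,
        degrees_of_freedom=df,
        p_value=p,
        significant=bool(p < alpha),
        variant=variant,
        degenerate=degenerate,
    )


def compare_groups(
    summaries: Sequence[AnimalSummary],
    metrics: Sequence[str] | None = None,
    variant: str = "student",
    alpha: float = ALPHA,
) -> list:
    """Run the per-metric two-group test over per-animal summaries.

    Expects exactly two groups; animals whose value for a metric is
    missing are dropped from that metric's test. Metrics with fewer than
    2 animals per group are skipped.
    """
    groups = sorted({s.group for s in summaries})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    ga, gb = groups
    if metrics is None:
        metrics = list(summaries[0].means)
    comparisons = []
    for metric in metrics:
        va = [s.means[metric] for s in summaries if s.group == ga and s.means.get(metric) is not None]
        vb = [s.means[metric] for s in summaries if s.group == gb and s.means.get(metric) is not None]
        if len(va) < 2 or len(vb) < 2:
            continue
        comparisons.append(
            unpaired_t_test(
                va, vb, variant, metric=metric, group_a=ga, group_b=gb, alpha=alpha
            )
        )
    return comparisons


def densitometry_ratio(target: float, loading: float) -> float:
    """Target band intensity normalized to the loading-control band."""
    if not (target > 0 and loading > 0):
        raise ValueError("band intensities must be positive")
    return target / loading


def build_report(
    out_dir: str | Path,
    *,
    per_image: Sequence[Mapping] = (),
    summaries: Sequence[AnimalSummary] = (),
    comparisons: Sequence[GroupComparison] = (),
    densitometry: Sequence[DensitometryRecord] = (),
    manifest: Mapping | None = None,
) -> dict:
    """Write CSV tables and a JSON run manifest to ``out_dir``.

    Emits ``per_image.csv``, ``per_animal.csv``, ``comparisons.csv``
    (and ``densitometry.csv`` when records are given) plus
    ``manifest.json`` recording every parameter passed in ``manifest``
    and the number of statistical tests run. Deterministic: regenerating
    from the same inputs is byte-identical (no timestamps are written).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    if per_image:
        df = pd.DataFrame([dict(r) for r in per_image])
        df.to_csv(out_dir / "per_image.csv", index=False)
        paths["per_image"] = out_dir / "per_image.csv"
    if summaries:
        pd.DataFrame([s.to_row() for s in summaries]).to_csv(
            out_dir / "per_animal.csv", index=False
        )
        paths["per_animal"] = out_dir / "per_animal.csv"
    pd.DataFrame([c.to_row() for c in comparisons]).to_csv(
        out_dir / "comparisons.csv", index=False
    )
    paths["comparisons"] = out_dir / "comparisons.csv"
    if densitometry:
        pd.DataFrame([d.to_row() for d in densitometry]).to_csv(
            out_dir / "densitometry.csv", index=False
        )
        paths["densitometry"] = out_dir / "densitometry.csv"
    full_manifest = dict(manifest or {})
    full_manifest["n_tests_run"] = len(comparisons)
    full_manifest["alpha"] = ALPHA
    (out_dir / "manifest.json").write_text(json.dumps(full_manifest, indent=2, sort_keys=True))
    paths["manifest"] = out_dir / "manifest.json"
    return paths
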
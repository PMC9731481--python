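"""Front quality measures: normalization, Range, SumMin, MinSum, tolerance
rates, average Hamming distance and hypervolume.

Normalization pools per-objective bounds over *all* supplied fronts so that
compared algorithms share one frame; maximization objectives (f2, f3) are
negated first so the normalized space is all-minimization with values in
[0, 1].  Range/SumMin/MinSum/hypervolume operate on normalized vectors;
tolerance rates and the average Hamming measure use raw objective values.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from tagsnp.objectives import ObjectiveVector, _MIN_SENSE_SIGN

__all__ = [
    "DEFAULT_REFERENCE",
    "EXACT_HV_THRESHOLD",
    "MetricReport",
    "avg_hamming_metric",
    "compute_report",
    "hypervolume",
    "minsum",
    "monte_carlo_hypervolume",
    "normalize",
    "range_metric",
    "summin",
    "summary_table",
    "tolerance_rates",
]

#: Default hypervolume reference point, per normalized axis.
DEFAULT_REFERENCE = (1.1, 1.1, 1.1, 1.1)

#: Largest front size for which hypervolume is computed exactly by
#: inclusion-exclusion (2^k subset terms).
EXACT_HV_THRESHOLD = 14

FrontLike = Union[np.ndarray, Sequence[ObjectiveVector]]


def _as_raw_array(front: FrontLike) -> np.ndarray:
    """Coerce a front to a raw (k, 4) float array on the original scales."""
    if isinstance(front, np.ndarray):
        arr = np.atleast_2d(np.asarray(front, dtype=float))
    else:
        arr = np.stack([o.as_array() for o in front]) if len(front) else np.empty((0, 4))
    if arr.size == 0:
        raise ValueError("front must be non-empty")
    if arr.shape[1] != 4:
        raise ValueError(f"expected 4 objectives, got shape {arr.shape}")
    return arr


def normalize(
    fronts: Sequence[FrontLike],
) -> tuple[list[np.ndarray], dict[str, np.ndarray]]:
    """Min-max normalize one or more fronts with pooled bounds.

    Maximization objectives are negated to minimization sense first; each
    objective is then scaled to [0, 1] using the min/max pooled over all
    supplied fronts.  A degenerate objective (max == min) maps to 0.

    Returns the normalized fronts and the pooled bounds (min-sense).
    """
    if len(fronts) == 0:
        raise ValueError("normalize requires at least one front")
    raws = [_as_raw_array(f) * _MIN_SENSE_SIGN for f in fronts]
    pooled = np.vstack(raws)
    lo = pooled.min(axis=0)
    hi = pooled.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    normalized = [np.where(span > 0, (r - lo) / safe, 0.0) for r in raws]
    return normalized, {"min": lo, "max": hi}


def range_metric(front: np.ndarray) -> float:
    """Sum over objectives of (max - min) of normalized values; in [0, 4]."""
    arr = _as_raw_array(front)
    return float((arr.max(axis=0) - arr.min(axis=0)).sum())


def summin(front: np.ndarray) -> float:
    """Sum over objectives of the minimum normalized value; in [0, 4]."""
    arr = _as_raw_array(front)
    return float(arr.min(axis=0).sum())


def minsum(front: np.ndarray) -> float:
    """Minimum over solutions of the sum of its normalized values.

    Always >= :func:`summin`, since per-objective minima may come from
    different solutions.
    """
    arr = _as_raw_array(front)
    return float(arr.sum(axis=1).min())


def tolerance_rates(front: FrontLike) -> tuple[float, float]:
    """(max, mean) of f2/f1 over the front; rate is 0 when f1 = 0.

    Uses raw objective values; rates lie in [0, 1] because f2 <= f1.
    """
    arr = _as_raw_array(front)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(arr[:, 0] > 0, arr[:, 1] / arr[:, 0], 0.0)
    return float(rates.max()), float(rates.mean())


def avg_hamming_metric(front: FrontLike) -> float:
    """Mean of raw f3 over the front."""
    arr = _as_raw_array(front)
    return float(arr[:, 2].mean())


def _check_reference(front: np.ndarray, reference: np.ndarray) -> None:
    if np.any(front > reference[None, :]):
        raise ValueError(
            "reference point must be componentwise >= every front member "
            "(minimization sense)"
        )


def _exact_hypervolume(front: np.ndarray, reference: np.ndarray) -> float:
    """Inclusion-exclusion over the union of boxes [member, reference]."""
    # dominated members contribute nothing; dropping them shrinks 2^k
    keep = []
    for i in range(front.shape[0]):
        others = np.delete(front, i, axis=0)
        if others.size and np.any(
            np.all(others <= front[i], axis=1)
            & np.any(others < front[i], axis=1)
        ):
            continue
        keep.append(i)
    pts = np.unique(front[keep], axis=0)
    k = pts.shape[0]
    total = 0.0
    for r in range(1, k + 1):
        sign = 1.0 if r % 2 == 1 else -1.0
        for subset in itertools.combinations(range(k), r):
            corner = pts[list(subset)].max(axis=0)
            total += sign * float(np.prod(np.maximum(reference - corner, 0.0)))
    return total


def monte_carlo_hypervolume(
    front: np.ndarray,
    reference: Sequence[float] = DEFAULT_REFERENCE,
    n_samples: int = 100_000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Monte-Carlo hypervolume estimate and its standard error.

    Samples uniformly in the box [ideal, reference] and counts samples
    dominated by at least one front member.
    """
    arr = _as_raw_array(front)
    ref = np.asarray(reference, dtype=float)
    _check_reference(arr, ref)
    lo = arr.min(axis=0)
    box = float(np.prod(ref - lo))
    if box == 0.0:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, ref, size=(n_samples, arr.shape[1]))
    covered = np.zeros(n_samples, dtype=bool)
    for member in arr:
        covered |= np.all(samples >= member, axis=1)
    p = covered.mean()
    se = box * math.sqrt(max(p * (1 - p), 0.0) / n_samples)
    return box * float(p), se


def hypervolume(
    front: np.ndarray,
    reference: Sequence[float] = DEFAULT_REFERENCE,
    exact_threshold: int = EXACT_HV_THRESHOLD,
    n_samples: int = 200_000,
    seed: Optional[int] = 0,
) -> float:
    """Hypervolume of a normalized front (minimization sense).

    Exact by inclusion-exclusion for fronts of at most ``exact_threshold``
    nondominated members; Monte-Carlo estimate (seeded) above that.
    """
    arr = _as_raw_array(front)
    ref = np.asarray(reference, dtype=float)
    _check_reference(arr, ref)
    # count nondominated, deduplicated members to choose the method
    uniq = np.unique(arr, axis=0)
    if uniq.shape[0] <= exact_threshold:
        return _exact_hypervolume(uniq, ref)
    est, _se = monte_carlo_hypervolume(arr, ref, n_samples=n_samples, seed=seed)
    return est


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

MEASURES = (
    "range",
    "summin",
    "minsum",
    "max_tolerance_rate",
    "avg_tolerance_rate",
    "avg_hamming",
    "hypervolume",
    "front_size",
)


@dataclass
class MetricReport:
    """Quality measures for a group of fronts under pooled normalization."""

    rows: list[dict]
    bounds: dict[str, list[float]]
    reference: list[float] = field(default_factory=lambda: list(DEFAULT_REFERENCE))

    def to_json(self) -> str:
        return json.dumps(
            {"rows": self.rows, "bounds": self.bounds, "reference": self.reference},
            indent=2,
        )

    def to_tsv(self) -> str:
        keys = [k for k in self.rows[0] if k not in MEASURES]
        header = keys + list(MEASURES)
        lines = ["\t".join(header)]
        for row in self.rows:
            lines.append(
                "\t".join(
                    str(row[k]) if k in keys else f"{row[k]:.6g}" for k in header
                )
            )
        return "\n".join(lines) + "\n"


def compute_report(
    fronts: Sequence[FrontLike],
    labels: Optional[Sequence[dict]] = None,
    reference: Sequence[float] = DEFAULT_REFERENCE,
    seed: Optional[int] = 0,
) -> MetricReport:
    """Measures for each front, normalized in one pooled frame.

    ``labels`` supplies identifying fields (e.g. algorithm, init, run) that
    are carried into each report row.
    """
    normalized, bounds = normalize(fronts)
    if labels is None:
        labels = [{"front": i} for i in range(len(fronts))]
    ref = np.asarray(reference, dtype=float)
    rows = []
    for label, raw_front, norm in zip(labels, fronts, normalized):
        raw = _as_raw_array(raw_front)
        max_tr, avg_tr = tolerance_rates(raw)
        # clip to the reference so pooled outliers cannot void the HV contract
        clipped = np.minimum(norm, ref[None, :])
        row = dict(label)
        row.update(
            {
                "range": range_metric(norm),
                "summin": summin(norm),
                "minsum": minsum(norm),
                "max_tolerance_rate": max_tr,
                "avg_tolerance_rate": avg_tr,
                "avg_hamming": avg_hamming_metric(raw),
                "hypervolume": hypervolume(clipped, ref, seed=seed),
                "front_size": int(raw.shape[0]),
            }
        )
        rows.append(row)
    return MetricReport(
        rows=rows,
        bounds={k: [float(x) for x in v] for k, v in bounds.items()},
        reference=[float(x) for x in ref],
    )


def summary_table(
    rows: Iterable[dict], group_keys: Sequence[str] = ("algorithm", "init")
) -> list[dict]:
    """Mean and sd of each measure per group (e.g. algorithm x init)."""
    groups: dict[tuple, list[dict]] = {}
    for row in rows:
        key = tuple(row.get(k) for k in group_keys)
        groups.setdefault(key, []).append(row)
    out = []
    for key in sorted(groups, key=lambda t: tuple(str(x) for x in t)):
        members = groups[key]
        entry = dict(zip(group_keys, key))
        entry["n_runs"] = len(members)
        for measure in MEASURES:
            vals = np.array([r[measure] for r in members], dtype=float)
            entry[f"{measure}_mean"] = float(vals.mean())
            entry[f"{measure}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out.append(entry)
    return out


def summary_to_tsv(summary: list[dict]) -> str:
    header = list(summary[0].keys())
    lines = ["\t".join(header)]
    for row in summary:
        lines.append(
            "\t".join(
                f"{row[k]:.6g}" if isinstance(row[k], float) else str(row[k])
                for k in header
            )
        )
    return "\n".join(lines) + "\n"
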
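"""qHTS concentration-response processing.

Raw multi-concentration response series are range-scaled to a 0-100 scale,
noise-filtered into monotone curve fingerprints, summarised by a single
scalar (the sum of the filtered responses, ``curvep``), classified into one
of four activity categories, and finally aggregated over replicates into a
per-compound call.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_NOISE_THRESHOLD = 10.0

#: category -> numeric activity score
CATEGORY_SCORES = {
    "active": 1.0,
    "potential_active": 0.75,
    "inconclusive": 0.25,
    "inactive": 0.0,
}
SCORE_CATEGORIES = {v: k for k, v in CATEGORY_SCORES.items()}
_SCORES_ASCENDING = sorted(SCORE_CATEGORIES)


class CurveInputError(ValueError):
    """Raised for malformed concentration-response input."""


class DegenerateScaleError(ValueError):
    """Raised when low and high controls coincide."""


@dataclass(frozen=True)
class CurveSeries:
    """One replicate's concentration-response series.

    Concentrations are molar and strictly ascending; responses are on the
    range-scaled 0-100 target scale (values outside that window are allowed,
    the noise filter deals with them).
    """

    compound_id: str
    replicate: int
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if conc.ndim != 1 or resp.ndim != 1 or conc.size != resp.size:
            raise CurveInputError("concentrations and responses must be 1-D and equal length")
        if conc.size < 2:
            raise CurveInputError("a curve needs at least two concentrations")
        if not np.all(np.isfinite(conc)) or not np.all(np.isfinite(resp)):
            raise CurveInputError("non-finite values in curve")
        if not np.all(np.diff(conc) > 0):
            raise CurveInputError("concentrations must be strictly ascending")


@dataclass(frozen=True)
class CurveFingerprint:
    """Noise-filtered summary of one curve.

    ``curvep`` is the sum of the filtered responses (zero means no
    significant signal).  ``max_response`` and ``n_responses_ge20`` are
    consistency measures computed on the filtered vector.
    """

    filtered_responses: np.ndarray
    curvep: float
    max_response: float
    n_responses_ge20: int


@dataclass(frozen=True)
class ActivityCall:
    category: str
    score: float

    def __post_init__(self) -> None:
        if CATEGORY_SCORES.get(self.category) != self.score:
            raise ValueError(f"category/score mismatch: {self.category}/{self.score}")


def range_scale(raw_responses, low_control: float, high_control: float) -> np.ndarray:
    """Linearly map raw signals onto the control-anchored 0-100 scale.

    Values falling outside [0, 100] are preserved (not clipped) so the
    downstream noise filter sees them.
    """
    if high_control == low_control:
        raise DegenerateScaleError("low and high controls are equal")
    raw = np.asarray(raw_responses, dtype=float)
    return 100.0 * (raw - low_control) / (high_control - low_control)


def _min_flatten_repair(values: np.ndarray) -> np.ndarray:
    """Make ``values`` monotone non-decreasing by flattening points.

    A flattened point takes the value of the preceding repaired point (zero
    if there is none).  Among repairs that flatten the minimal number of
    points, the one with the smallest resulting sum is chosen (conservative:
    isolated spikes are removed rather than propagated); remaining ties go
    to the earliest kept positions.  O(n^2) dynamic program over the kept
    (unchanged) subsequence.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return v.copy()
    kept = [0] * n
    tot = [0.0] * n
    nxt: list[int | None] = [None] * n
    for i in range(n - 1, -1, -1):
        best_kept, best_tot, best_nxt = 1, v[i] * (n - i), None
        for j in range(i + 1, n):
            if v[j] >= v[i]:
                cand_kept = 1 + kept[j]
                cand_tot = v[i] * (j - i) + tot[j]
                if cand_kept > best_kept or (cand_kept == best_kept and cand_tot < best_tot):
                    best_kept, best_tot, best_nxt = cand_kept, cand_tot, j
        kept[i], tot[i], nxt[i] = best_kept, best_tot, best_nxt
    # choose the first kept position (positions before it are flattened to 0)
    best_kept, best_tot, first = 0, 0.0, None
    for k in range(n):
        if kept[k] > best_kept or (kept[k] == best_kept and tot[k] < best_tot):
            best_kept, best_tot, first = kept[k], tot[k], k
    out = np.zeros(n)
    i = first
    while i is not None:
        j = nxt[i]
        out[i: (j if j is not None else n)] = v[i]
        i = j
    return out


def curvep_filter(curve, noise_threshold: float = DEFAULT_NOISE_THRESHOLD) -> CurveFingerprint:
    """Noise-filter a curve and compute its fingerprint.

    Responses below ``noise_threshold`` are zeroed (negative responses are
    never significant activation signals and are zeroed as well, keeping the
    filtered vector non-negative), then a monotone non-decreasing envelope is
    enforced by flattening the minimal number of violating points.
    """
    if isinstance(curve, CurveSeries):
        responses = curve.responses
    else:
        responses = np.asarray(curve, dtype=float)
        if responses.ndim != 1:
            raise CurveInputError("responses must be 1-D")
    filtered = np.where(responses >= noise_threshold, responses, 0.0)
    filtered = _min_flatten_repair(filtered)
    return CurveFingerprint(
        filtered_responses=filtered,
        curvep=float(filtered.sum()),
        max_response=float(filtered.max()),
        n_responses_ge20=int(np.count_nonzero(filtered >= 20.0)),
    )


def classify_replicate(fp: CurveFingerprint) -> ActivityCall:
    """Map a fingerprint to the four-level activity category.

    active:            curvep > 0, max >= 20, more than one response >= 20
    potential_active:  curvep > 0, max >= 20, exactly one response >= 20
    inactive:          curvep == 0 and max < 10
    inconclusive:      anything else (inconsistent signal)
    """
    if fp.curvep > 0 and fp.max_response >= 20 and fp.n_responses_ge20 > 1:
        cat = "active"
    elif fp.curvep > 0 and fp.max_response >= 20 and fp.n_responses_ge20 == 1:
        cat = "potential_active"
    elif fp.curvep == 0 and fp.max_response < 10:
        cat = "inactive"
    else:
        cat = "inconclusive"
    return ActivityCall(cat, CATEGORY_SCORES[cat])


def aggregate_compound(calls: Sequence[ActivityCall]) -> ActivityCall:
    """Average replicate scores and snap to the nearest category score.

    Exact midpoints between two category scores resolve toward the lower
    (less active) score.
    """
    if len(calls) == 0:
        raise CurveInputError("cannot aggregate an empty list of calls")
    mean = sum(c.score for c in calls) / len(calls)
    best_score, best_dist = _SCORES_ASCENDING[0], math.inf
    for s in _SCORES_ASCENDING:
        d = abs(mean - s)
        if d < best_dist:  # strict: ties keep the lower score
            best_score, best_dist = s, d
    return ActivityCall(SCORE_CATEGORIES[best_score], best_score)


def process_curves(
    curves: Iterable[CurveSeries],
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD,
) -> pd.DataFrame:
    """Classify every replicate and aggregate per compound.

    Returns a frame indexed by compound_id with columns ``category``,
    ``score``, ``curvep_mean`` and ``n_replicates``.
    """
    per_compound: dict[str, list[ActivityCall]] = {}
    curvep_sums: dict[str, float] = {}
    for curve in curves:
        fp = curvep_filter(curve, noise_threshold)
        call = classify_replicate(fp)
        per_compound.setdefault(curve.compound_id, []).append(call)
        curvep_sums[curve.compound_id] = curvep_sums.get(curve.compound_id, 0.0) + fp.curvep
    rows = []
    for cid, calls in per_compound.items():
        agg = aggregate_compound(calls)
        rows.append(
            {
                "compound_id": cid,
                "category": agg.category,
                "score": agg.score,
                "curvep_mean": curvep_sums[cid] / len(calls),
                "n_replicates": len(calls),
            }
        )
    return pd.DataFrame(rows).set_index("compound_id") if rows else pd.DataFrame(
        columns=["category", "score", "curvep_mean", "n_replicates"]
    )


def read_curves_csv(path) -> list[CurveSeries]:
    """Read long-format curve CSV (compound_id, replicate, conc_index,
    concentration_M, response) into CurveSeries objects."""
    df = pd.read_csv(path)
    required = {"compound_id", "replicate", "conc_index", "concentration_M", "response"}
    missing = required - set(df.columns)
    if missing:
        raise CurveInputError(f"curve CSV missing columns: {sorted(missing)}")
    out = []
    for (cid, rep), grp in df.groupby(["compound_id", "replicate"], sort=True):
        grp = grp.sort_values("conc_index")
        out.append(
            CurveSeries(
                compound_id=str(cid),
                replicate=int(rep),
                concentrations=grp["concentration_M"].to_numpy(),
                responses=grp["response"].to_numpy(),
            )
        )
    return out


def write_calls_csv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, index_label="compound_id")
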
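"""Biological response profile mining.

Scores each assay of a compound x assay categorical response matrix against
a binary endpoint (confusion counts, sensitivity, specificity, CCR, the
likelihood parameter L, Pearson chi-squared), applies the four assay
selection criteria, computes the per-compound rate of actives (RA) over the
selected assays, and assembles a heatmap-ready profile table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

ACTIVE = "active"
INACTIVE = "inactive"
INCONCLUSIVE = "inconclusive"
UNTESTED = "untested"
CATEGORIES = (ACTIVE, INACTIVE, INCONCLUSIVE, UNTESTED)

#: CSV cell encoding for response matrices
_CELL_CODES = {ACTIVE: 1, INACTIVE: 0, INCONCLUSIVE: -1}
_CODE_CELLS = {1: ACTIVE, 0: INACTIVE, -1: INCONCLUSIVE}

DEFAULT_RA_THRESHOLD = 0.25
DEFAULT_MIN_MATCHING_ACTIVES = 10


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero marginal has no defined chi-squared test."""


class EmptyOverlapError(ValueError):
    """No compound is shared between assay calls and endpoint labels."""


def pearson_chi2(table, correction: bool = False) -> tuple[float, float, int]:
    """Pearson chi-squared test of independence on a 2x2 table.

    No continuity correction by default.  Returns (statistic, p, df=1).
    Raises :class:`DegenerateTableError` if any row or column sum is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("cell counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DegenerateTableError("zero marginal in 2x2 table")
    n = t.sum()
    expected = np.outer(rows, cols) / n
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    p = float(_sstats.chi2.sf(stat, df=1))
    return stat, p, 1


def confusion(
    assay_calls: Mapping[str, str] | pd.Series,
    endpoint_labels: Mapping[str, int] | pd.Series,
) -> tuple[int, int, int, int]:
    """Tabulate (TP, TN, FP, FN) of definite assay calls against binary labels.

    Only compounds with a definite call (active/inactive) and a label
    contribute; inconclusive and untested cells are excluded.
    """
    calls = pd.Series(assay_calls)
    labels = pd.Series(endpoint_labels).dropna()
    shared = calls.index.intersection(labels.index)
    if len(shared) == 0:
        raise EmptyOverlapError("no overlapping compounds between calls and labels")
    calls = calls.loc[shared]
    labels = labels.loc[shared].astype(int)
    definite = calls.isin([ACTIVE, INACTIVE])
    calls = calls[definite]
    labels = labels[definite]
    pred = (calls == ACTIVE).to_numpy()
    pos = labels.to_numpy() == 1
    tp = int(np.count_nonzero(pred & pos))
    tn = int(np.count_nonzero(~pred & ~pos))
    fp = int(np.count_nonzero(pred & ~pos))
    fn = int(np.count_nonzero(~pred & pos))
    return tp, tn, fp, fn


@dataclass(frozen=True)
class AssayStats:
    """Quality/reliability statistics of one assay against one endpoint."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    ccr: float
    L: float
    chi2_stat: float
    chi2_p: float
    n_matching_actives: int

    @property
    def defined(self) -> bool:
        """False when either class is absent (statistics undefined)."""
        return not (math_isnan(self.sensitivity) or math_isnan(self.specificity))

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "AssayStats":
        sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
        ccr = (sens + spec) / 2.0
        L = sens * (fp + tp) / (fp + 1.0) if not math_isnan(sens) else float("nan")
        try:
            chi2_stat, chi2_p, _ = pearson_chi2([[tp, fn], [fp, tn]])
        except DegenerateTableError:
            chi2_stat, chi2_p = float("nan"), float("nan")
        return cls(tp, tn, fp, fn, sens, spec, ccr, L, chi2_stat, chi2_p, tp)

    @property
    def ccr_pct(self) -> float:
        return self.ccr * 100.0


def math_isnan(x: float) -> bool:
    return isinstance(x, float) and x != x


def assay_stats(assay_calls, endpoint_labels) -> AssayStats:
    return AssayStats.from_counts(*confusion(assay_calls, endpoint_labels))


@dataclass
class AssayResponseMatrix:
    """Compound x assay categorical response matrix plus assay metadata.

    ``calls`` is indexed by compound_id with assay-id columns and cells in
    {active, inactive, inconclusive, untested}.  ``metadata`` is indexed by
    assay_id with at least a boolean ``in_vitro`` column.
    """

    calls: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy())) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown cell categories: {sorted(bad)}")
        missing = set(self.calls.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"assays without metadata: {sorted(missing)}")

    @property
    def compounds(self) -> list[str]:
        return list(self.calls.index)

    @property
    def assays(self) -> list[str]:
        return list(self.calls.columns)

    def to_csv(self, path) -> None:
        coded = self.calls.apply(lambda col: col.map(_CELL_CODES.get))
        coded.to_csv(path, index_label="compound_id")

    @classmethod
    def read_csv(cls, path, metadata: pd.DataFrame | None = None) -> "AssayResponseMatrix":
        coded = pd.read_csv(path, index_col="compound_id")
        coded.index = coded.index.astype(str)
        coded.index.name = None
        calls = coded.apply(
            lambda col: col.map(lambda x: UNTESTED if pd.isna(x) else _CODE_CELLS[int(x)])
        )
        if metadata is None:
            metadata = pd.DataFrame({"in_vitro": True}, index=calls.columns)
        return cls(calls=calls, metadata=metadata)


def select_assays(
    stats_endpoint_a: Mapping[str, AssayStats],
    stats_endpoint_b: Mapping[str, AssayStats],
    metadata: pd.DataFrame,
    min_matching_actives: int = DEFAULT_MIN_MATCHING_ACTIVES,
    min_ccr: float = 0.5,
    min_L: float = 1.0,
) -> list[str]:
    """Apply the four assay selection criteria.

    An assay is kept iff it (a) appears in both endpoint profiles, (b) has
    strictly more than ``min_matching_actives`` matching active responses in
    each, (c) beats random correlation (CCR > 0.5 and L >= 1) in each, and
    (d) is an in vitro assay.  Result ordered by descending mean CCR, then
    assay id.
    """
    selected = []
    for assay_id in stats_endpoint_a:
        if assay_id not in stats_endpoint_b:
            continue
        sa, sb = stats_endpoint_a[assay_id], stats_endpoint_b[assay_id]
        if not (sa.defined and sb.defined):
            continue
        if not (sa.n_matching_actives > min_matching_actives and sb.n_matching_actives > min_matching_actives):
            continue
        if not (sa.ccr > min_ccr and sa.L >= min_L and sb.ccr > min_ccr and sb.L >= min_L):
            continue
        if assay_id not in metadata.index or not bool(metadata.loc[assay_id, "in_vitro"]):
            continue
        selected.append(assay_id)
    mean_ccr = {a: (stats_endpoint_a[a].ccr + stats_endpoint_b[a].ccr) / 2.0 for a in selected}
    return sorted(selected, key=lambda a: (-mean_ccr[a], a))


@dataclass(frozen=True)
class RAResult:
    compound_id: str
    A: int
    I: int
    ra: float | None
    call: str  # toxic | nontoxic | no_data


def rate_of_actives(
    compound_row: Mapping[str, str] | pd.Series,
    selected_assays: Sequence[str] | None = None,
    threshold: float = DEFAULT_RA_THRESHOLD,
    compound_id: str = "",
) -> RAResult:
    """Rate of actives RA = A/(A+I) over the selected assays.

    Untested and inconclusive responses are excluded from both numerator and
    denominator, so missing data does not bias the rate.  call is toxic iff
    RA strictly exceeds ``threshold``; when no definite response exists the
    call is no_data and RA is undefined (None, never 0).
    """
    row = pd.Series(compound_row)
    if selected_assays is not None:
        if len(selected_assays) == 0:
            raise ValueError("at least one selected assay is required")
        row = row.loc[list(selected_assays)]
    a = int((row == ACTIVE).sum())
    i = int((row == INACTIVE).sum())
    if a + i == 0:
        return RAResult(compound_id, 0, 0, None, "no_data")
    ra = a / (a + i)
    return RAResult(compound_id, a, i, ra, "toxic" if ra > threshold else "nontoxic")


@dataclass
class ProfileResult:
    """Output of :func:`build_profile`."""

    stats_endpoint_a: dict[str, AssayStats]
    stats_endpoint_b: dict[str, AssayStats]
    selected_assays: list[str]
    ra: pd.DataFrame
    profile_table: pd.DataFrame
    combined_chi2: tuple[float, float] | None  # RA call vs endpoint B

    def stats_frame(self) -> pd.DataFrame:
        rows = []
        for endpoint, stats in (("A", self.stats_endpoint_a), ("B", self.stats_endpoint_b)):
            for assay_id, s in stats.items():
                rows.append(
                    {
                        "assay_id": assay_id,
                        "endpoint": endpoint,
                        "TP": s.tp, "TN": s.tn, "FP": s.fp, "FN": s.fn,
                        "sensitivity": s.sensitivity, "specificity": s.specificity,
                        "ccr_pct": s.ccr_pct, "L": s.L, "chi2_p": s.chi2_p,
                        "selected": assay_id in self.selected_assays,
                    }
                )
        return pd.DataFrame(rows)


def build_profile(
    matrix: AssayResponseMatrix,
    endpoint_a: pd.Series,
    endpoint_b: pd.Series,
    ra_threshold: float = DEFAULT_RA_THRESHOLD,
    min_matching_actives: int = DEFAULT_MIN_MATCHING_ACTIVES,
) -> ProfileResult:
    """Run the full profiling stage for two binary endpoints.

    ``endpoint_a``/``endpoint_b`` map compound ids to 0/1 labels (typically
    in vitro pathway activation and in vivo organ damage).  Per-assay
    statistics are computed against both, the selection criteria applied,
    and per-compound RA over the selected assays derived together with a
    heatmap-ready profile table (compounds with at least one definite call).
    """
    endpoint_a = pd.Series(endpoint_a).dropna()
    endpoint_b = pd.Series(endpoint_b).dropna()
    if len(endpoint_a) == 0 or len(endpoint_b) == 0:
        raise ValueError("both probe sets must be nonempty")
    stats_a: dict[str, AssayStats] = {}
    stats_b: dict[str, AssayStats] = {}
    for assay_id in matrix.assays:
        col = matrix.calls[assay_id]
        try:
            stats_a[assay_id] = assay_stats(col, endpoint_a)
            stats_b[assay_id] = assay_stats(col, endpoint_b)
        except EmptyOverlapError:
            continue
    selected = select_assays(stats_a, stats_b, matrix.metadata, min_matching_actives)

    ra_rows = []
    if selected:
        for cid in matrix.compounds:
            res = rate_of_actives(matrix.calls.loc[cid], selected, ra_threshold, compound_id=cid)
            ra_rows.append(
                {"compound_id": cid, "A": res.A, "I": res.I, "ra": res.ra, "call": res.call}
            )
    ra = pd.DataFrame(ra_rows, columns=["compound_id", "A", "I", "ra", "call"]).set_index(
        "compound_id"
    ) if ra_rows else pd.DataFrame(columns=["A", "I", "ra", "call"])

    profile = pd.DataFrame(index=matrix.calls.index)
    for assay_id in selected:
        profile[assay_id] = matrix.calls[assay_id]
    if selected:
        profile["RA"] = ra["ra"]
        profile["ra_call"] = ra["call"]
        profile["endpoint_label"] = endpoint_b.reindex(profile.index)
        has_data = ra["call"] != "no_data"
        profile = profile.loc[has_data]

    combined = None
    if selected:
        merged = ra.join(endpoint_b.rename("label"), how="inner").dropna(subset=["label"])
        merged = merged[merged["call"] != "no_data"]
        tp = int(((merged["call"] == "toxic") & (merged["label"] == 1)).sum())
        fn = int(((merged["call"] == "nontoxic") & (merged["label"] == 1)).sum())
        fp = int(((merged["call"] == "toxic") & (merged["label"] == 0)).sum())
        tn = int(((merged["call"] == "nontoxic") & (merged["label"] == 0)).sum())
        try:
            stat, p, _ = pearson_chi2([[tp, fn], [fp, tn]])
            combined = (stat, p)
        except DegenerateTableError:
            warnings.warn("degenerate RA-vs-endpoint table; combined chi2 undefined")
    return ProfileResult(stats_a, stats_b, selected, ra, profile, combined)


def read_labels_csv(path, label_column: str = "liver_damage") -> pd.Series:
    df = pd.read_csv(path)
    df["compound_id"] = df["compound_id"].astype(str)
    return df.set_index("compound_id")[label_column].astype(int)
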
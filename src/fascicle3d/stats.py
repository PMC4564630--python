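"""Descriptive summaries and nonparametric inference for muscle architecture.

The analysis mirrors classical nonparametric practice for small cadaveric
samples: per-cell medians with minimum-maximum ranges, Mann-Whitney U tests
(tie-corrected normal approximation without continuity correction, or an
exact permutation variant), Kruskal-Wallis tests across >= 3 groups, and
Bonferroni-adjusted pairwise comparisons (alpha / m, e.g. 0.05 / 3 = 0.0167).

The default Mann-Whitney method is the asymptotic tie-corrected z WITHOUT a
continuity correction: with two groups of four, the smallest attainable
exact two-sided p is 2/70 ~ 0.029, so reported p-values near 0.02 at these
sizes can only come from the normal approximation.

``ArchitectureModel`` wraps a per-bundle measurement table and ``fit()``
returns an ``ArchitectureResults`` carrying the per-cell summaries, the
omnibus and pairwise tests, and a ``summary()`` text report.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .specimen import ValidationError

METRICS = ("fbl_cm", "lat_pa_deg", "med_pa_deg")
_PART_ORDER = ("superficial", "middle", "deep")
_CAT_ORDER = ("A", "B", "C")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Display rounding with ties away from zero (2.955 -> 2.96, 3.715 -> 3.72).

    Printed medians in the source tables follow half-up convention; Python's
    built-in round is banker's rounding on binary floats and would print
    3.715 as 3.71.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    mean: float
    sd: Optional[float]  # sample SD (n-1); None for n < 2
    min: float
    max: float
    median: float


def describe(values: Sequence[float]) -> DescriptiveStats:
    """Mean, sample SD, range and median; the even-n median averages the middle two."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("describe() needs at least one value")
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else None
    return DescriptiveStats(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        min=float(np.min(x)),
        max=float(np.max(x)),
        median=float(np.median(x)),
    )


@dataclass(frozen=True)
class TestResult:
    statistic: float              # U (first group) or H
    z_value: Optional[float]      # Mann-Whitney asymptotic only
    p_value: float
    method: str                   # asymptotic_tie_corrected | exact_permutation | kruskal_wallis
    groups_compared: tuple
    n_per_group: tuple
    df: Optional[int] = None      # Kruskal-Wallis only


def _tie_term(pooled_ranks_source: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled data."""
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the first group, from midrank sums."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "asymptotic",
    groups: tuple = ("x", "y"),
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    method="asymptotic": tie-corrected normal approximation without
    continuity correction, z = (U - n1 n2 / 2) / sigma with
    sigma^2 = n1 n2 / 12 * [(N + 1) - sum(t^3 - t) / (N (N - 1))].

    method="exact": full enumeration of all C(n1 + n2, n1) group labelings
    of the pooled midranks (ties handled exactly); two-sided
    p = min(1, 2 * min(P(U <= u), P(U >= u))).  Feasible for n1 + n2 <= 20.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney needs two non-empty groups")
    n1, n2 = x.size, y.size
    N = n1 + n2
    u = _u_statistic(x, y)

    if method == "asymptotic":
        mu = n1 * n2 / 2.0
        tie = _tie_term(np.concatenate([x, y]))
        var = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1))) if N > 1 else 0.0
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (u - mu) / math.sqrt(var)
            p = min(1.0, 2.0 * norm.sf(abs(z)))
        return TestResult(u, z, p, "asymptotic_tie_corrected", tuple(groups), (n1, n2))

    if method == "exact":
        if N > 20:
            raise ValidationError(f"exact enumeration limited to n1 + n2 <= 20, got {N}")
        ranks = rankdata(np.concatenate([x, y]))
        offset = n1 * (n1 + 1) / 2.0
        idx = np.array(list(combinations(range(N), n1)))
        us = ranks[idx].sum(axis=1) - offset
        lo = np.mean(us <= u + 1e-9)
        hi = np.mean(us >= u - 1e-9)
        p = min(1.0, 2.0 * min(lo, hi))
        return TestResult(u, None, float(p), "exact_permutation", tuple(groups), (n1, n2))

    raise ValidationError(f"unknown mann_whitney method {method!r}")


def kruskal_wallis(groups: Sequence[Sequence[float]], labels: Optional[tuple] = None) -> TestResult:
    """Kruskal-Wallis H on midranks with tie correction; p from chi2(k - 1)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValidationError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size].sum()
        h += r * r / a.size
        start += a.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    correction = 1.0 - _tie_term(pooled) / (N**3 - N)
    if correction <= 0.0:  # all pooled values identical
        h, p = 0.0, 1.0
    else:
        h /= correction
        h = max(h, 0.0)
        p = float(chi2.sf(h, df=len(arrays) - 1))
    if labels is None:
        labels = tuple(range(len(arrays)))
    return TestResult(
        h, None, p, "kruskal_wallis", tuple(labels),
        tuple(a.size for a in arrays), df=len(arrays) - 1,
    )


@dataclass(frozen=True)
class PairwiseDecision:
    comparison: str
    p_value: float
    alpha_adjusted: float
    significant: bool
    test: TestResult


def pairwise_compare(
    groups: dict,
    alpha: float = 0.05,
    m: Optional[int] = None,
    method: str = "asymptotic",
) -> list[PairwiseDecision]:
    """All pairwise Mann-Whitney tests with a Bonferroni-adjusted threshold.

    Significance is declared when p < alpha / m; with alpha = 0.05 over the
    three pairwise comparisons of a triplet the threshold is 0.0167.
    ``m`` defaults to the number of pairs.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValidationError("pairwise_compare needs >= 2 groups")
    pairs = list(combinations(labels, 2))
    if m is None:
        m = len(pairs)
    if m < 1:
        raise ValidationError("comparison count m must be >= 1")
    threshold = alpha / m
    out = []
    for a, b in pairs:
        res = mann_whitney(groups[a], groups[b], method=method, groups=(a, b))
        out.append(
            PairwiseDecision(
                comparison=f"{a} vs {b}",
                p_value=res.p_value,
                alpha_adjusted=threshold,
                significant=res.p_value < threshold,
                test=res,
            )
        )
    return out


def summarize_architecture(
    measurements: pd.DataFrame, min_specimens: int = 3
) -> pd.DataFrame:
    """Median (min-max) of FBL and both PAs per (region, part-or-whole, category).

    One row per populated cell; ``part`` = "all" rows pool the whole region.
    Cells whose specimen count falls below ``min_specimens`` are flagged
    ``tests_eligible = False`` and skipped by hypothesis tests (as done for a
    two-specimen cell in the source protocol).
    """
    required = {"specimen_id", "region", "part", "category", *METRICS}
    missing = required - set(measurements.columns)
    if missing:
        raise ValidationError(f"measurement table missing columns: {sorted(missing)}")
    if measurements[["region", "part", "category"]].isna().any().any():
        raise ValidationError("unlabeled measurement rows present")

    rows = []
    df = measurements.copy()
    whole = df.copy()
    whole["part"] = "all"
    for (region, part, category), cell in (
        pd.concat([whole, df]).groupby(["region", "part", "category"], sort=False)
    ):
        row = {
            "region": region,
            "part": part,
            "category": category,
            "n_specimens": cell["specimen_id"].nunique(),
            "n_bundles": len(cell),
        }
        for metric in METRICS:
            d = describe(cell[metric])
            row[f"{metric}_median"] = d.median
            row[f"{metric}_min"] = d.min
            row[f"{metric}_max"] = d.max
        row["tests_eligible"] = row["n_specimens"] >= min_specimens
        rows.append(row)
    out = pd.DataFrame(rows)
    out["part"] = pd.Categorical(out["part"], categories=("all",) + _PART_ORDER, ordered=True)
    out["category"] = pd.Categorical(out["category"], categories=_CAT_ORDER, ordered=True)
    return out.sort_values(["region", "part", "category"]).reset_index(drop=True)


def compare_tear_dimensions(table: pd.DataFrame, method: str = "asymptotic") -> dict[str, TestResult]:
    """Mann-Whitney comparison of tear diameters between categories B and C.

    ``table`` is a specimen summary with columns category, coronal_cm,
    sagittal_cm (missing diameters allowed for partial-thickness tears).
    """
    out = {}
    for plane in ("coronal_cm", "sagittal_cm"):
        b = table.loc[table["category"] == "B", plane].dropna()
        c = table.loc[table["category"] == "C", plane].dropna()
        out[plane] = mann_whitney(b, c, method=method, groups=("B", "C"))
    return out


class ArchitectureModel:
    """Nonparametric architecture comparison model over a measurement table.

    Parameters
    ----------
    measurements : DataFrame with one row per fiber bundle and columns
        specimen_id, region, part, category, fbl_cm, lat_pa_deg, med_pa_deg
        (the output of :func:`fascicle3d.geometry.measure_specimen`).
    alpha : base significance level (default 0.05).
    min_specimens : cells with fewer specimens are summarized but excluded
        from hypothesis tests.

    Bundles are pooled across the specimens of a category, the unit of
    analysis being the individual fascicle.
    """

    def __init__(self, measurements: pd.DataFrame, alpha: float = 0.05, min_specimens: int = 3):
        required = {"specimen_id", "region", "part", "category", *METRICS}
        missing = required - set(measurements.columns)
        if missing:
            raise ValidationError(f"measurement table missing columns: {sorted(missing)}")
        if len(measurements) == 0:
            raise ValidationError("empty measurement table")
        self.measurements = measurements.reset_index(drop=True)
        self.alpha = alpha
        self.min_specimens = min_specimens

    @classmethod
    def from_measurements(cls, measurements: pd.DataFrame, **kwargs) -> "ArchitectureModel":
        return cls(measurements, **kwargs)

    def _eligible(self, region: str, category: str) -> bool:
        cell = self.measurements[
            (self.measurements["region"] == region)
            & (self.measurements["category"] == category)
        ]
        return cell["specimen_id"].nunique() >= self.min_specimens

    def fit(self) -> "ArchitectureResults":
        df = self.measurements
        summaries = summarize_architecture(df, self.min_specimens)
        omnibus: list[TestResult] = []
        pairwise: list[PairwiseDecision] = []
        contexts: list[dict] = []

        def _run_family(sub: pd.DataFrame, by: str, context: dict):
            labels = [l for l in (_CAT_ORDER if by == "category" else _PART_ORDER)
                      if l in set(sub[by])]
            groups = {l: sub.loc[sub[by] == l, context["metric"]].to_numpy() for l in labels}
            if len(groups) < 2:
                return
            if len(groups) == 2:
                a, b = labels
                res = mann_whitney(groups[a], groups[b], groups=(a, b))
                omnibus.append(res)
                contexts.append({**context, "family": f"{by} comparison"})
            else:
                res = kruskal_wallis(list(groups.values()), labels=tuple(labels))
                omnibus.append(res)
                contexts.append({**context, "family": f"{by} comparison"})
                for dec in pairwise_compare(groups, alpha=self.alpha, m=3):
                    pairwise.append(dec)
                    contexts.append({**context, "family": f"{by} pairwise", "comparison": dec.comparison})

        for region in sorted(df["region"].unique()):
            sub_r = df[df["region"] == region]
            eligible_cats = [c for c in _CAT_ORDER
                             if c in set(sub_r["category"]) and self._eligible(region, c)]
            skipped = sorted(set(sub_r["category"]) - set(eligible_cats))
            if skipped:
                warnings.warn(
                    f"region {region}: categories {skipped} excluded from tests "
                    f"(fewer than {self.min_specimens} specimens)",
                    stacklevel=2,
                )
            for metric in METRICS:
                _run_family(
                    sub_r[sub_r["category"].isin(eligible_cats)],
                    "category",
                    {"region": region, "part": "all", "metric": metric},
                )
            for category in eligible_cats:
                sub_c = sub_r[sub_r["category"] == category]
                for metric in METRICS:
                    _run_family(sub_c, "part", {"region": region, "category": category, "metric": metric})

        return ArchitectureResults(self, summaries, omnibus, pairwise, contexts)


@dataclass
class ArchitectureResults:
    """Fitted architecture comparison: summaries, omnibus and pairwise tests."""

    model: ArchitectureModel
    summaries: pd.DataFrame
    omnibus: list[TestResult]
    pairwise: list[PairwiseDecision]
    _contexts: list[dict] = field(default_factory=list)

    @property
    def tests(self) -> pd.DataFrame:
        """All tests as a flat table (one row each, omnibus and pairwise)."""
        rows = []
        it_omni = iter(self.omnibus)
        it_pair = iter(self.pairwise)
        for ctx in self._contexts:
            if "comparison" in ctx:
                dec = next(it_pair)
                rows.append({
                    **ctx, "statistic": dec.test.statistic, "z": dec.test.z_value,
                    "p_value": dec.p_value, "alpha_adjusted": dec.alpha_adjusted,
                    "significant": dec.significant, "method": dec.test.method,
                    "n_per_group": dec.test.n_per_group,
                })
            else:
                res = next(it_omni)
                rows.append({
                    **ctx, "comparison": " vs ".join(str(g) for g in res.groups_compared),
                    "statistic": res.statistic, "z": res.z_value, "p_value": res.p_value,
                    "alpha_adjusted": None,
                    "significant": res.p_value < self.model.alpha, "method": res.method,
                    "n_per_group": res.n_per_group,
                })
        return pd.DataFrame(rows)

    def summary(self, decimals: int = 2) -> str:
        """Plain-text report: per-cell median (min-max) tables and test log."""
        lines = ["Supraspinatus fiber-bundle architecture", "=" * 48, ""]
        disp = self.summaries.copy()
        for metric, label in zip(METRICS, ("FBL (cm)", "PA lat. (deg)", "PA med. (deg)")):
            disp[label] = [
                f"{m:.{decimals}f} ({lo:.{decimals}f}-{hi:.{decimals}f})"
                for m, lo, hi in zip(
                    disp[f"{metric}_median"], disp[f"{metric}_min"], disp[f"{metric}_max"]
                )
            ]
        cols = ["region", "part", "category", "n_specimens", "n_bundles",
                "FBL (cm)", "PA lat. (deg)", "PA med. (deg)", "tests_eligible"]
        lines.append(disp[cols].to_string(index=False))
        lines.append("")
        tests = self.tests
        if len(tests):
            lines.append("Hypothesis tests (two-sided)")
            lines.append("-" * 48)
            t = tests.copy()
            t["p_value"] = t["p_value"].map(lambda p: f"{p:.3f}")
            show = [c for c in ("region", "part", "category", "metric", "family",
                                "comparison", "statistic", "p_value", "significant") if c in t]
            lines.append(t[show].to_string(index=False))
        return "\n".join(lines)
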
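"""Percent-cover agreement: zonal cover per reference polygon with QC discard
rules, rank-based tests, and effect sizes.

There is no generally accepted recipe for comparing a pixel-based binary
classification to multi-class or continuous reference cover data; the
framework here treats satellite percent cover within each reference polygon
(seagrass pixels out of *valid* pixels — those classified seagrass or no
seagrass) as a continuous response and asks whether it orders correctly with
the reference labels:

* two ordinal classes (patchy/continuous polygons) — one-sided Mann-Whitney U
  with the Glass rank-biserial correlation |rrb| = |1 − 2U/(n1·n2)|,
  interpreted on Cohen's correlation scale (0.1 / 0.3 / 0.5);
* four ordinal classes — Kruskal-Wallis with King's epsilon-squared
  ε² = H·(N+1)/(N²−1) = H/(N−1), interpreted on the modified scale
  (0.01 / 0.08 / 0.26), followed by post hoc pairwise two-tailed U tests;
* continuous reference points — one-sided Mann-Whitney U on reference cover
  grouped by the satellite class of the containing pixel.

Effect sizes, not p-values, are the headline: they are computed from U and H
directly. p-values use exact enumeration of rank assignments when n1·n2 ≤ 20
and the normal approximation with tie and continuity corrections otherwise.
Before a four-class test runs, sample sizes are gated (N ≥ 24 total, ≥ 5 per
group); on failure only descriptive medians are reported.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from itertools import combinations

import numpy as np
import shapely
from scipy.stats import chi2, norm, rankdata

from .core import (
    LAND,
    NO_DATA,
    NO_SEAGRASS,
    SEAGRASS,
    ClassMap,
    ConfigurationError,
    DensityScheme,
    ParameterError,
    ReferenceSet,
)

# QC discard rules for reference polygons, applied in this order.
NODATA_FRACTION_LIMIT = 0.90   # > 90% no data -> discard
MIN_VALID_PIXELS = 10          # < 10 valid pixels after exclusions -> discard

# Four-class rank-test sample-size criteria.
MIN_TOTAL_N = 24
MIN_PER_GROUP = 5

EXACT_PRODUCT_LIMIT = 20       # exact U p-value when n1*n2 <= this


@dataclass(frozen=True)
class InterpretationScheme:
    """Effect-size magnitude thresholds; values below `small` are negligible."""

    metric: str  # "rrb" or "eps2"
    small: float
    moderate: float
    large: float


RRB_INTERPRETATION = InterpretationScheme("rrb", 0.1, 0.3, 0.5)
EPS2_INTERPRETATION = InterpretationScheme("eps2", 0.01, 0.08, 0.26)


@dataclass
class PolygonCoverRecord:
    """Per-reference-polygon pixel tallies and the zonal satellite cover."""

    ref_id: str
    reference_label: str
    n_total_pixels: int
    n_nodata: int
    n_land: int
    n_valid: int
    n_seagrass: int
    satellite_cover_pct: float | None
    qc_status: str  # kept | discarded_nodata_fraction | discarded_too_few_valid

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RankTestReport:
    test: str  # mann_whitney_u | kruskal_wallis | descriptive
    group_names: tuple[str, ...]
    group_sizes: tuple[int, ...]
    medians: dict[str, float]
    statistic: float | None = None
    p_value: float | None = None
    tail: str | None = None
    effect_size: float | None = None
    effect_metric: str | None = None
    magnitude: str | None = None
    gate_status: str = "passed"
    posthoc: list["RankTestReport"] | None = None
    notes: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return int(sum(self.group_sizes))

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "group_names": list(self.group_names),
            "group_sizes": list(self.group_sizes),
            "n_total": self.n_total,
            "medians": self.medians,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "tail": self.tail,
            "effect_size": self.effect_size,
            "effect_metric": self.effect_metric,
            "magnitude": self.magnitude,
            "gate_status": self.gate_status,
            "notes": self.notes,
        }
        if self.posthoc is not None:
            d["posthoc"] = [p.to_dict() for p in self.posthoc]
        return d


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def mann_whitney_u(group_a, group_b, tail: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U for group A with average-rank ties.

    Returns (U_A, p). U_A counts pairs (a, b) with a > b plus half the tied
    pairs, so U_A + U_B = n1·n2. ``tail`` is "greater" (A stochastically
    greater), "less", or "two-sided". Exact enumeration of rank assignments
    when n1·n2 ≤ 20; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ParameterError("both groups must be nonempty")
    if tail not in ("greater", "less", "two-sided"):
        raise ParameterError(f"unknown tail: {tail!r}")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_a = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 * n2 <= EXACT_PRODUCT_LIMIT:
        p = _exact_u_pvalue(ranks, n1, u_a, tail)
    else:
        p = _normal_u_pvalue(pooled, ranks, n1, n2, u_a, tail)
    return u_a, float(min(p, 1.0))


def _exact_u_pvalue(ranks: np.ndarray, n1: int, u_obs: float, tail: str) -> float:
    """Enumerate every assignment of n1 of the pooled ranks to group A."""
    n = ranks.size
    offset = n1 * (n1 + 1) / 2.0
    us = np.array([sum(c) - offset for c in combinations(ranks, n1)])
    eps = 1e-9
    p_greater = float(np.mean(us >= u_obs - eps))
    p_less = float(np.mean(us <= u_obs + eps))
    if tail == "greater":
        return p_greater
    if tail == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def _normal_u_pvalue(pooled, ranks, n1, n2, u_obs, tail) -> float:
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every value identical
        return 1.0
    sd = np.sqrt(var)
    if tail == "greater":
        z = (u_obs - mu - 0.5) / sd
        return float(norm.sf(z))
    if tail == "less":
        z = (u_obs - mu + 0.5) / sd
        return float(norm.cdf(z))
    z = (abs(u_obs - mu) - 0.5) / sd
    return float(2.0 * norm.sf(max(z, 0.0)))


def rank_biserial(u: float, n1: int, n2: int) -> float:
    """Glass rank-biserial correlation |rrb| = |1 − 2U/(n1·n2)|.

    Invariant to which group's U is supplied (U_A and U_B give the same value).
    """
    if n1 < 1 or n2 < 1:
        raise ParameterError("group sizes must be at least 1")
    if not (0 <= u <= n1 * n2):
        raise ParameterError(f"U={u} outside [0, {n1 * n2}]")
    return abs(1.0 - 2.0 * u / (n1 * n2))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value (k−1 df).

    H = [12/(N(N+1)) Σ R_j²/n_j − 3(N+1)] / [1 − Σ(t³−t)/(N³−N)] with average
    ranks for ties. If every pooled value is identical, H = 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ParameterError("all groups must be nonempty")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled)
    h_raw = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h_raw += r.sum() ** 2 / g.size
        start += g.size
    h_raw = 12.0 / (n * (n + 1)) * h_raw - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n**3 - n)
    if correction <= 0:  # all values identical
        return 0.0, 1.0
    h = h_raw / correction
    h = max(h, 0.0)
    p = float(chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def epsilon_squared(h: float, n: int) -> float:
    """King's epsilon-squared ε² = H·(N+1)/(N²−1) (= H/(N−1)), clipped to [0, 1]."""
    if n < 2:
        raise ParameterError("N must be at least 2")
    if h < 0:
        raise ParameterError("H must be non-negative")
    return float(np.clip(h * (n + 1) / (n**2 - 1), 0.0, 1.0))


def interpret_effect(value: float, scheme: InterpretationScheme) -> str:
    """Magnitude label on half-open intervals [small, moderate) etc."""
    if not (0 <= value <= 1):
        raise ParameterError("effect size must lie in [0, 1]")
    if value >= scheme.large:
        return "large"
    if value >= scheme.moderate:
        return "moderate"
    if value >= scheme.small:
        return "small"
    return "negligible"


def sample_size_gate(
    group_sizes,
    min_total: int = MIN_TOTAL_N,
    min_per_group: int = MIN_PER_GROUP,
) -> str:
    """Minimum-sample-size gate for the multi-class rank test.

    Checked in order: any group below ``min_per_group`` → failed_min_per_group;
    total below ``min_total`` → failed_min_total; else passed.
    """
    sizes = [int(s) for s in group_sizes]
    if len(sizes) < 2:
        raise ParameterError("need at least two groups")
    if any(s < min_per_group for s in sizes):
        return "failed_min_per_group"
    if sum(sizes) < min_total:
        return "failed_min_total"
    return "passed"


# ---------------------------------------------------------------------------
# Zonal percent cover per reference polygon
# ---------------------------------------------------------------------------

def clip_and_cover(cmap: ClassMap, ref: ReferenceSet) -> list[PolygonCoverRecord]:
    """Clip the collapsed classification to each reference polygon and compute
    satellite percent cover, applying the QC discard rules.

    Cell membership is by center containment. The no-data-fraction rule uses
    all pixels in the polygon footprint as denominator (land included); the
    valid-pixel rule counts only seagrass + no-seagrass pixels. Discarded
    polygons stay in the returned table, flagged.
    """
    if not cmap.is_general:
        raise ConfigurationError("clip_and_cover needs a collapsed class map")
    if ref.dialect not in ("density_polygons", "presence_polygons"):
        raise ConfigurationError("clip_and_cover expects a polygon dialect")
    if not ref.features:
        raise ParameterError("empty reference set")
    label_key = "dens_cls" if ref.dialect == "density_polygons" else "presence"
    x, y = cmap.grid.cell_centers()
    records = []
    for f in ref.features:
        inside = shapely.contains_xy(f.geometry, x, y)
        labels = cmap.labels[inside]
        n_total = int(labels.size)
        n_nodata = int((labels == NO_DATA).sum())
        n_land = int((labels == LAND).sum())
        n_valid = n_total - n_nodata - n_land
        n_sg = int((labels == SEAGRASS).sum())
        if n_total == 0:
            qc = "discarded_too_few_valid"
        elif n_nodata / n_total > NODATA_FRACTION_LIMIT:
            qc = "discarded_nodata_fraction"
        elif n_valid < MIN_VALID_PIXELS:
            qc = "discarded_too_few_valid"
        else:
            qc = "kept"
        records.append(
            PolygonCoverRecord(
                ref_id=f.ref_id,
                reference_label=str(f.attrs.get(label_key, "")),
                n_total_pixels=n_total,
                n_nodata=n_nodata,
                n_land=n_land,
                n_valid=n_valid,
                n_seagrass=n_sg,
                satellite_cover_pct=100.0 * n_sg / n_valid if n_valid > 0 else None,
                qc_status=qc,
            )
        )
    return records


def _kept_by_class(records, class_order) -> dict[str, np.ndarray]:
    out = {}
    for cls in class_order:
        vals = [
            r.satellite_cover_pct
            for r in records
            if r.qc_status == "kept" and r.reference_label == cls
        ]
        out[cls] = np.asarray(vals, dtype=np.float64)
    return out


def _medians(by_class: dict[str, np.ndarray]) -> dict[str, float]:
    return {c: float(np.median(v)) if v.size else float("nan")
            for c, v in by_class.items()}


# ---------------------------------------------------------------------------
# Comparison routines
# ---------------------------------------------------------------------------

def compare_cover_two_class(
    records: list[PolygonCoverRecord], scheme: DensityScheme
) -> RankTestReport:
    """One-sided Mann-Whitney U: is satellite cover in the upper density class
    (continuous) greater than in the lower (patchy)?

    U is reported for the lower class (pairs where the lower class exceeds the
    upper), so strong agreement gives a small U and |rrb| near 1.
    """
    if len(scheme.classes) != 2:
        raise ConfigurationError("two-class comparison needs a 2-class scheme")
    by_class = _kept_by_class(records, scheme.labels)
    low, high = scheme.labels
    if by_class[low].size == 0 or by_class[high].size == 0:
        raise ParameterError(f"both classes must be represented among kept records")
    u, p = mann_whitney_u(by_class[low], by_class[high], tail="less")
    n1, n2 = by_class[low].size, by_class[high].size
    rrb = rank_biserial(u, n1, n2)
    return RankTestReport(
        test="mann_whitney_u",
        group_names=(low, high),
        group_sizes=(n1, n2),
        medians=_medians(by_class),
        statistic=u,
        p_value=p,
        tail="less",
        effect_size=rrb,
        effect_metric="rrb",
        magnitude=interpret_effect(rrb, RRB_INTERPRETATION),
        notes={"alternative": f"{high} > {low}", "u_of_group": low},
    )


def holm_adjusted(p_values) -> list[float]:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def compare_cover_multiclass(
    records: list[PolygonCoverRecord],
    scheme: DensityScheme,
    posthoc_threshold: float = EPS2_INTERPRETATION.small,
    holm_adjust: bool = False,
) -> RankTestReport:
    """Kruskal-Wallis across the ordinal density classes, gated on sample size.

    On gate failure only descriptive per-class medians are reported. When the
    test runs and ε² reaches at least the small threshold, all pairwise
    two-tailed Mann-Whitney U tests are attached (U reported for the
    lower-ordinal class of each pair). ``holm_adjust`` additionally records
    Holm-adjusted post hoc p-values; no adjustment is applied by default.
    """
    by_class = _kept_by_class(records, scheme.labels)
    sizes = tuple(int(v.size) for v in by_class.values())
    gate = sample_size_gate(sizes)
    if gate != "passed":
        return RankTestReport(
            test="descriptive",
            group_names=scheme.labels,
            group_sizes=sizes,
            medians=_medians(by_class),
            gate_status=gate,
            notes={"reason": "sample-size gate failed; medians only"},
        )
    groups = [by_class[c] for c in scheme.labels]
    h, p = kruskal_wallis(groups)
    n = int(sum(sizes))
    eps2 = epsilon_squared(h, n)
    posthoc = None
    if eps2 >= posthoc_threshold:
        posthoc = []
        for (i, lo), (j, hi) in combinations(enumerate(scheme.labels), 2):
            u, pp = mann_whitney_u(by_class[lo], by_class[hi], tail="two-sided")
            rrb = rank_biserial(u, sizes[i], sizes[j])
            posthoc.append(
                RankTestReport(
                    test="mann_whitney_u",
                    group_names=(lo, hi),
                    group_sizes=(sizes[i], sizes[j]),
                    medians={lo: float(np.median(by_class[lo])),
                             hi: float(np.median(by_class[hi]))},
                    statistic=u,
                    p_value=pp,
                    tail="two-sided",
                    effect_size=rrb,
                    effect_metric="rrb",
                    magnitude=interpret_effect(rrb, RRB_INTERPRETATION),
                    notes={"u_of_group": lo},
                )
            )
        if holm_adjust:
            for rep_i, p_adj in zip(posthoc,
                                    holm_adjusted([r.p_value for r in posthoc])):
                rep_i.notes["p_value_holm"] = p_adj
    return RankTestReport(
        test="kruskal_wallis",
        group_names=scheme.labels,
        group_sizes=sizes,
        medians=_medians(by_class),
        statistic=h,
        p_value=p,
        effect_size=eps2,
        effect_metric="eps2",
        magnitude=interpret_effect(eps2, EPS2_INTERPRETATION),
        gate_status=gate,
        posthoc=posthoc,
    )


def compare_reference_cover_by_satellite_class(
    points: ReferenceSet, cmap: ClassMap
) -> RankTestReport:
    """One-sided Mann-Whitney U: is reference percent cover greater at points
    whose containing pixel the satellite classified seagrass than at points it
    classified no seagrass?

    Points on no-data or land pixels (or outside the footprint) are excluded
    and counted. U is reported for the no-seagrass group.
    """
    if points.dialect != "cover_points":
        raise ConfigurationError("expects the cover_points dialect")
    if not cmap.is_general:
        raise ConfigurationError("needs a collapsed class map")
    xs = np.array([f.geometry.x for f in points.features])
    ys = np.array([f.geometry.y for f in points.features])
    cov = np.array([float(f.attrs["cover_pct"]) for f in points.features])
    row, col = cmap.grid.cell_of(xs, ys)
    inside = cmap.grid.in_bounds(row, col)
    n_outside = int((~inside).sum())
    row, col, cov = row[inside], col[inside], cov[inside]
    lab = cmap.labels[row, col]
    n_excluded = int(((lab == NO_DATA) | (lab == LAND)).sum())
    no_sg = cov[lab == NO_SEAGRASS]
    sg = cov[lab == SEAGRASS]
    if no_sg.size == 0 or sg.size == 0:
        raise ParameterError(
            "zero usable groups: need points on both seagrass and no-seagrass pixels"
        )
    u, p = mann_whitney_u(no_sg, sg, tail="less")
    rrb = rank_biserial(u, no_sg.size, sg.size)
    return RankTestReport(
        test="mann_whitney_u",
        group_names=("no_seagrass", "seagrass"),
        group_sizes=(int(no_sg.size), int(sg.size)),
        medians={"no_seagrass": float(np.median(no_sg)),
                 "seagrass": float(np.median(sg))},
        statistic=u,
        p_value=p,
        tail="less",
        effect_size=rrb,
        effect_metric="rrb",
        magnitude=interpret_effect(rrb, RRB_INTERPRETATION),
        notes={
            "alternative": "reference cover greater on seagrass pixels",
            "u_of_group": "no_seagrass",
            "n_excluded_nodata_or_land": n_excluded,
            "n_dropped_outside": n_outside,
        },
    )
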
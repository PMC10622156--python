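"""Presence/absence agreement between a collapsed class map and reference data.

Reference presence polygons are rasterized to the satellite lattice by
cell-center containment; points are matched to the cell containing them.
Pixels the map flags as no data are excluded before comparison (they carry no
evidence either way); land pixels count as *no seagrass*, so a reference bed
that the map calls land registers as disagreement. Agreement is summarized by
sensitivity Se = TP/(TP+FN), specificity Sp = TN/(TN+FP), and balanced
agreement BA = (Se+Sp)/2, the arithmetic mean that is robust to the severe
class imbalance typical of coastal scenes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import shapely

from .core import (
    NO_DATA,
    SEAGRASS,
    ClassMap,
    ConfigurationError,
    GridSpec,
    ParameterError,
    ReferenceSet,
)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    n_excluded_nodata: int
    n_dropped_outside: int = 0

    @property
    def total_compared(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class PresenceAgreementReport:
    tp: int
    tn: int
    fp: int
    fn: int
    n_excluded_nodata: int
    n_reference_seagrass: int
    n_reference_noseagrass: int
    sensitivity: float | None
    specificity: float | None
    balanced_agreement: float | None
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return d


def rasterize_reference(ref: ReferenceSet, grid: GridSpec,
                        extent: shapely.Geometry | None = None) -> np.ndarray:
    """Boolean presence grid: a cell is presence iff its center lies inside any
    presence polygon (union semantics). Absence is inferred everywhere else
    within the analysis extent — pass ``extent`` to restrict it; cells outside
    are left False and should be masked by the caller if needed.
    """
    if ref.dialect != "presence_polygons":
        raise ConfigurationError("rasterize_reference expects presence_polygons")
    if not ref.features:
        raise ParameterError("empty reference set")
    x, y = grid.cell_centers()
    presence = np.zeros(grid.shape, dtype=bool)
    for f in ref.features:
        if f.attrs.get("presence", 1):
            presence |= shapely.contains_xy(f.geometry, x, y)
    if extent is not None:
        presence &= shapely.contains_xy(extent, x, y)
    return presence


def _binary_map(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(map_says_seagrass, usable) with land folded into no seagrass."""
    usable = labels != NO_DATA
    return labels == SEAGRASS, usable


def confusion_counts(
    cmap: ClassMap,
    reference: np.ndarray | ReferenceSet,
    analysis_mask: np.ndarray | None = None,
) -> ConfusionCounts:
    """Cross-tabulate the collapsed map against presence reference data.

    ``reference`` is either a boolean presence grid congruent with the map or
    a point ReferenceSet (``presence_points``). Map no-data units are excluded
    and counted; points outside the footprint are dropped and counted.
    """
    if not cmap.is_general:
        raise ConfigurationError("confusion_counts needs a collapsed class map")
    says_sg, usable = _binary_map(cmap.labels)

    if isinstance(reference, ReferenceSet):
        if reference.dialect != "presence_points":
            raise ConfigurationError("point confusion expects presence_points")
        xs = np.array([f.geometry.x for f in reference.features])
        ys = np.array([f.geometry.y for f in reference.features])
        pres = np.array([bool(f.attrs["presence"]) for f in reference.features])
        row, col = cmap.grid.cell_of(xs, ys)
        inside = cmap.grid.in_bounds(row, col)
        n_dropped = int((~inside).sum())
        row, col, pres = row[inside], col[inside], pres[inside]
        unit_usable = usable[row, col]
        unit_sg = says_sg[row, col]
        n_nodata = int((~unit_usable).sum())
        unit_sg, pres = unit_sg[unit_usable], pres[unit_usable]
        return ConfusionCounts(
            tp=int((unit_sg & pres).sum()),
            tn=int((~unit_sg & ~pres).sum()),
            fp=int((unit_sg & ~pres).sum()),
            fn=int((~unit_sg & pres).sum()),
            n_excluded_nodata=n_nodata,
            n_dropped_outside=n_dropped,
        )

    pres = np.asarray(reference, dtype=bool)
    if pres.shape != cmap.grid.shape:
        raise ParameterError("reference grid not congruent with the class map")
    scope = np.ones(cmap.grid.shape, dtype=bool) if analysis_mask is None else analysis_mask
    n_nodata = int((scope & ~usable).sum())
    use = scope & usable
    return ConfusionCounts(
        tp=int((use & says_sg & pres).sum()),
        tn=int((use & ~says_sg & ~pres).sum()),
        fp=int((use & says_sg & ~pres).sum()),
        fn=int((use & ~says_sg & pres).sum()),
        n_excluded_nodata=n_nodata,
    )


def balanced_agreement(counts: ConfusionCounts) -> PresenceAgreementReport:
    """Se, Sp, and their arithmetic mean; BA is withheld if either rate is
    undefined (a reference class with zero units)."""
    n_ref_sg = counts.tp + counts.fn
    n_ref_no = counts.tn + counts.fp
    undefined = []
    se = counts.tp / n_ref_sg if n_ref_sg > 0 else None
    sp = counts.tn / n_ref_no if n_ref_no > 0 else None
    if se is None:
        undefined.append("sensitivity")
    if sp is None:
        undefined.append("specificity")
    ba = (se + sp) / 2.0 if not undefined else None
    return PresenceAgreementReport(
        tp=counts.tp,
        tn=counts.tn,
        fp=counts.fp,
        fn=counts.fn,
        n_excluded_nodata=counts.n_excluded_nodata,
        n_reference_seagrass=n_ref_sg,
        n_reference_noseagrass=n_ref_no,
        sensitivity=se,
        specificity=sp,
        balanced_agreement=ba,
        undefined=tuple(undefined),
    )


def assess_presence(
    cmap: ClassMap,
    ref: ReferenceSet,
    analysis_mask: np.ndarray | None = None,
) -> PresenceAgreementReport:
    """Full presence-agreement routine for either presence dialect."""
    if ref.dialect == "presence_polygons":
        grid_ref = rasterize_reference(ref, cmap.grid)
        counts = confusion_counts(cmap, grid_ref, analysis_mask=analysis_mask)
    elif ref.dialect == "presence_points":
        counts = confusion_counts(cmap, ref)
    else:
        raise ConfigurationError(
            f"presence agreement needs a presence dialect, got {ref.dialect!r}"
        )
    return balanced_agreement(counts)
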
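"""Follicle soft-tissue cap analysis.

For each unerupted tooth, two cap-shaped follicle volumes are defined:
a *coronal* cap extending 3 mm along the tooth's long axis from the
crown-most follicle tissue towards mid-tooth, and an *apical* cap mirrored
from the root end.  For every cap the analysis computes

* the relative percentage of tissue volume under compression
  (hydrostatic stress < 0) — eruption-consistent caps show > 50 %
  compression coronally and < 50 % apically,
* the same percentage on the BRU basis (share of summated |BRU| carried
  by compressive elements),
* binned relative-percentage distributions over fixed hydrostatic-stress
  and BRU ranges, with underflow/overflow aggregation,
* pooled results across teeth (second molars, which are not actively
  erupting at the developmental stage modelled, are excluded from pools),
* exception classification against the expected coronal-compression /
  apical-tension pattern, including near-misses within a margin of the
  50 % mark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from eruptsim.materials import RegionLabel

logger = logging.getLogger(__name__)

__all__ = [
    "CapSpec",
    "CapSummary",
    "Histogram",
    "ExceptionReport",
    "DEFAULT_STRESS_EDGES",
    "CORONAL_BRU_EDGES",
    "APICAL_BRU_EDGES",
    "tooth_axis",
    "select_cap_elements",
    "compression_volume_percent",
    "compression_bru_percent",
    "histogram_volume",
    "histogram_bru",
    "summarize_cap",
    "pool_caps",
    "classify_exceptions",
]

#: Cap depth along the tooth long axis, mm.
DEFAULT_CAP_DEPTH = 3.0

#: |hydrostatic stress| bin edges, MPa: 0.005 to 0.07 in 0.005 steps.
DEFAULT_STRESS_EDGES = np.round(np.arange(1, 15) * 0.005, 10)

#: |BRU| bin edges for coronal caps, N.mm: 0.00029 to 0.00250 step 0.00017.
CORONAL_BRU_EDGES = np.round(0.00029 + 0.00017 * np.arange(14), 12)

#: |BRU| bin edges for apical caps, N.mm: 0.000050 upward in 0.000045
#: steps; the stated upper limit 0.000630 is not an integer number of
#: increments away, so a final partial bin closes the range at 0.000630.
APICAL_BRU_EDGES = np.append(
    np.round(0.000050 + 0.000045 * np.arange(13), 12), 0.000630
)

_ERUPTIVE_TEETH = ("canine", "first_premolar", "second_premolar")
_SECOND_MOLAR = "second_molar"


@dataclass(frozen=True)
class CapSpec:
    """Identity and geometry of one follicle cap."""

    tooth: str
    side: str  # "left" | "right"
    kind: str  # "coronal" | "apical"
    axis: Tuple[float, float, float]  # unit vector, crown -> apex
    depth: float = DEFAULT_CAP_DEPTH

    def __post_init__(self) -> None:
        if self.kind not in ("coronal", "apical"):
            raise ValueError(f"cap kind must be coronal or apical, got {self.kind}")
        if not self.depth > 0:
            raise ValueError("cap depth must be positive")
        a = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-6:
            raise ValueError("cap axis must be a unit vector")
        object.__setattr__(self, "axis", tuple(a))


@dataclass
class Histogram:
    """Binned relative-percentage distribution.

    ``table`` is indexed by bin label (``underflow``, the half-open
    ``[lo, hi)`` bins, ``overflow``) with one column per curve; every
    curve with any mass normalizes to 100 %.
    """

    basis: str  # "sigma_h" | "bru" — the binned quantity
    edges: np.ndarray
    table: pd.DataFrame

    def curve(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()


@dataclass
class CapSummary:
    """Compression/tension summary for one cap under one load mode."""

    spec: CapSpec
    load_mode: str
    total_volume: float
    compression_volume_pct: float
    compression_bru_pct: float
    stress_histogram: Optional[Histogram] = None
    bru_histogram: Optional[Histogram] = None


@dataclass
class ExceptionReport:
    """Pattern-exception classification over a percentage table.

    ``table`` carries one row per (tooth, side, load, cap) instance with
    the observed compression percentage, the expected pattern, the
    exception flag and the near-miss flag; ``second_molars`` holds the
    same columns for second-molar caps, which are excluded from the
    aggregate counts.
    """

    basis: str
    margin: float
    table: pd.DataFrame
    second_molars: pd.DataFrame
    n_instances: int = field(init=False)
    n_exceptions: int = field(init=False)
    n_near_miss_exceptions: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_instances = len(self.table)
        self.n_exceptions = int(self.table["is_exception"].sum())
        self.n_near_miss_exceptions = int(
            (self.table["is_exception"] & self.table["near_miss"]).sum()
        )


def tooth_axis(mesh, tooth_mask: np.ndarray) -> np.ndarray:
    """Long axis of a tooth, oriented crown -> apex.

    The axis is the dominant principal direction of the tooth element
    centroids; its sign is fixed so that the enamel-region centroid (the
    crown end) projects to the *low* end of the axial coordinate.

    Raises ``ValueError`` when the centroid cloud has no dominant axis
    (top two principal spreads within 1 % of each other) — supply an
    explicit axis in the configuration in that case — or when the tooth
    contains no enamel elements to orient by.
    """
    tooth_mask = np.asarray(tooth_mask, dtype=bool)
    centroids = mesh.centroids()[tooth_mask]
    if len(centroids) < 4:
        raise ValueError("tooth element set too small to define an axis")
    centred = centroids - centroids.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    vals, vecs = np.linalg.eigh(cov)
    spreads = np.sqrt(np.maximum(vals, 0.0))
    if spreads[2] <= 0 or (spreads[2] - spreads[1]) / spreads[2] < 0.01:
        raise ValueError(
            "ambiguous tooth axis: top two principal spreads within 1%; "
            "supply an explicit axis in the configuration"
        )
    axis = vecs[:, 2]
    enamel_mask = tooth_mask & mesh.mask(RegionLabel.ENAMEL)
    if not enamel_mask.any():
        raise ValueError("cannot orient tooth axis: no enamel elements")
    enamel_centroid = mesh.centroids()[enamel_mask].mean(axis=0)
    if (enamel_centroid - centroids.mean(axis=0)) @ axis > 0:
        axis = -axis
    # deterministic sign even without enamel dominance ties
    return axis / np.linalg.norm(axis)


def select_cap_elements(
    centroids: np.ndarray, cap: CapSpec
) -> np.ndarray:
    """Boolean membership mask of follicle elements in one cap.

    ``centroids`` are the centroids of the follicle elements.  The axial
    coordinate is the projection on the crown->apex axis; the coronal cap
    takes elements within ``depth`` of the crown-most follicle centroid,
    the apical cap within ``depth`` of the apex-most.  A finite depth that
    would make the two caps overlap (follicle axial span < 2*depth)
    raises; an infinite depth covers the whole follicle.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.size == 0:
        raise ValueError("empty follicle element set")
    t = centroids @ np.asarray(cap.axis)
    t_min, t_max = float(t.min()), float(t.max())
    if np.isfinite(cap.depth) and (t_max - t_min) < 2.0 * cap.depth:
        raise ValueError(
            f"tooth too short for disjoint caps: follicle axial span "
            f"{t_max - t_min:.2f} mm < 2 x depth {cap.depth:.2f} mm"
        )
    if not np.isfinite(cap.depth):
        return np.ones(len(t), dtype=bool)
    if cap.kind == "coronal":
        return t <= t_min + cap.depth
    return t >= t_max - cap.depth


def compression_volume_percent(records: pd.DataFrame) -> float:
    """Relative % of cap volume under compression (sigma_h < 0).

    Elements with sigma_h exactly 0 count toward neither compression nor
    tension but remain in the denominator.
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    total = records["volume"].sum()
    if not total > 0:
        raise ValueError("total cap volume must be positive")
    comp = records.loc[records["sigma_h"] < 0, "volume"].sum()
    return float(100.0 * comp / total)


def compression_bru_percent(records: pd.DataFrame) -> float:
    """Relative % of summated |BRU| carried by compressive elements."""
    if len(records) == 0:
        raise ValueError("empty record set")
    abs_bru = records["bru"].abs()
    total = abs_bru.sum()
    if not total > 0:
        raise ValueError("total |BRU| is zero; BRU basis undefined")
    comp = abs_bru[records["sigma_h"] < 0].sum()
    return float(100.0 * comp / total)


def _bin_labels(edges: np.ndarray) -> List[str]:
    labels = ["underflow"]
    labels += [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append("overflow")
    return labels


def _binned_percent(x: np.ndarray, w: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Weighted relative-% per bin over [underflow, inner bins, overflow].

    Inner bins are half-open [lo, hi); overflow takes x >= edges[-1].
    A curve with zero total mass returns all zeros.
    """
    out = np.zeros(len(edges) + 1)
    if len(x) == 0:
        return out
    out[0] = w[x < edges[0]].sum()
    inner = (x >= edges[0]) & (x < edges[-1])
    if inner.any():
        idx = np.digitize(x[inner], edges) - 1  # 0-based inner bin
        np.add.at(out, idx + 1, w[inner])
    out[-1] = w[x >= edges[-1]].sum()
    total = out.sum()
    if total > 0:
        out *= 100.0 / total
    return out


def histogram_volume(
    records: pd.DataFrame, edges: np.ndarray = DEFAULT_STRESS_EDGES
) -> Histogram:
    """Relative-%-volume distribution over |hydrostatic stress| ranges,
    with separate compression and tension curves."""
    if len(records) == 0:
        raise ValueError("empty record set")
    edges = np.asarray(edges, dtype=float)
    sigma = records["sigma_h"].to_numpy()
    vol = records["volume"].to_numpy()
    comp, tens = sigma < 0, sigma > 0
    table = pd.DataFrame(
        {
            "compression_volume_pct": _binned_percent(-sigma[comp], vol[comp], edges),
            "tension_volume_pct": _binned_percent(sigma[tens], vol[tens], edges),
        },
        index=_bin_labels(edges),
    )
    return Histogram(basis="sigma_h", edges=edges, table=table)


def histogram_bru(
    records: pd.DataFrame,
    tissue: str,
    edges: Optional[np.ndarray] = None,
) -> Histogram:
    """Distributions over |BRU| ranges, reporting both the relative %
    of volume and the relative % of summated |BRU| per bin.

    ``tissue`` selects the default bin ranges: coronal follicle caps span
    higher BRU magnitudes than apical caps.
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    if edges is None:
        if tissue == "coronal":
            edges = CORONAL_BRU_EDGES
        elif tissue == "apical":
            edges = APICAL_BRU_EDGES
        else:
            raise ValueError(f"tissue must be coronal or apical, got {tissue}")
    edges = np.asarray(edges, dtype=float)
    sigma = records["sigma_h"].to_numpy()
    vol = records["volume"].to_numpy()
    abs_bru = np.abs(records["bru"].to_numpy())
    comp, tens = sigma < 0, sigma > 0
    table = pd.DataFrame(
        {
            "compression_volume_pct": _binned_percent(abs_bru[comp], vol[comp], edges),
            "tension_volume_pct": _binned_percent(abs_bru[tens], vol[tens], edges),
            "compression_bru_pct": _binned_percent(
                abs_bru[comp], abs_bru[comp], edges
            ),
            "tension_bru_pct": _binned_percent(abs_bru[tens], abs_bru[tens], edges),
        },
        index=_bin_labels(edges),
    )
    return Histogram(basis="bru", edges=edges, table=table)


def summarize_cap(
    spec: CapSpec,
    load_mode: str,
    records: pd.DataFrame,
    stress_edges: np.ndarray = DEFAULT_STRESS_EDGES,
    bru_edges: Optional[np.ndarray] = None,
) -> CapSummary:
    """Full per-cap summary: percentages plus both histograms."""
    return CapSummary(
        spec=spec,
        load_mode=load_mode,
        total_volume=float(records["volume"].sum()),
        compression_volume_pct=compression_volume_percent(records),
        compression_bru_pct=compression_bru_percent(records),
        stress_histogram=histogram_volume(records, stress_edges),
        bru_histogram=histogram_bru(records, spec.kind, bru_edges),
    )


def pool_caps(
    caps: Sequence[Tuple[CapSummary, Optional[pd.DataFrame]]],
    exclude_teeth: Iterable[str] = (_SECOND_MOLAR,),
) -> CapSummary:
    """Pool caps of one kind/load across teeth by recomputing over the
    concatenated element records.

    Percentages cannot be pooled from the per-cap percentages alone
    (the caps carry different volumes and BRU masses); each entry must
    therefore supply its element records.  Teeth in ``exclude_teeth``
    (by default the non-erupting second molars) are dropped and logged.
    """
    exclude = set(exclude_teeth)
    kept: List[Tuple[CapSummary, pd.DataFrame]] = []
    for summary, records in caps:
        if summary.spec.tooth in exclude:
            logger.info(
                "pool_caps: excluding %s %s %s cap from pooled analysis",
                summary.spec.side, summary.spec.tooth, summary.spec.kind,
            )
            continue
        if records is None:
            raise ValueError(
                "cannot pool bare percentages: pooling requires the per-cap "
                "element records because percentages must be re-weighted by "
                "volume and |BRU| mass, not averaged"
            )
        kept.append((summary, records))
    if not kept:
        raise ValueError("no caps left to pool after exclusions")
    kinds = {s.spec.kind for s, _ in kept}
    modes = {s.load_mode for s, _ in kept}
    if len(kinds) > 1 or len(modes) > 1:
        raise ValueError(
            f"pooled caps must share kind and load mode, got kinds={kinds}, "
            f"modes={modes}"
        )
    pooled_records = pd.concat([r for _, r in kept], ignore_index=True)
    spec0 = kept[0][0].spec
    pooled_spec = replace(spec0, tooth="pooled", side="both")
    return summarize_cap(pooled_spec, kept[0][0].load_mode, pooled_records)


def _expected_pattern(cap: str) -> str:
    return "compression_dominant" if cap == "coronal" else "tension_dominant"


def _is_exception(cap: str, pct: float) -> bool:
    if cap == "coronal":
        return pct < 50.0
    return pct > 50.0


def classify_exceptions(
    table: pd.DataFrame,
    basis: str,
    margin: float = 4.0,
    require_full_grid: bool = True,
) -> ExceptionReport:
    """Classify pattern exceptions in a compression-percentage table.

    ``table`` needs columns ``side, load, tooth, cap, basis,
    compression_pct``.  For the chosen basis, every canine/premolar
    (tooth, side, load, cap) instance is checked against the expected
    pattern: coronal caps should be compression-dominant (> 50 %),
    apical caps tension-dominant (< 50 % compression); values of exactly
    50 are exceptions for neither.  ``near_miss`` flags entries within
    ``margin`` percentage points of 50 (inclusive).  Second molars are
    reported separately and never counted in the aggregates.

    With ``require_full_grid`` the full canine/premolar grid
    (3 teeth x 2 sides x 2 caps x all loads present) must be covered;
    missing cells raise with an explicit list.
    """
    if basis not in set(table["basis"]):
        raise ValueError(f"basis '{basis}' not present in table")
    sub = table[table["basis"] == basis].copy()
    loads = sorted(sub["load"].unique())
    if require_full_grid:
        missing = []
        for tooth in _ERUPTIVE_TEETH:
            for side in ("left", "right"):
                for load in loads:
                    for cap in ("coronal", "apical"):
                        hit = (
                            (sub["tooth"] == tooth)
                            & (sub["side"] == side)
                            & (sub["load"] == load)
                            & (sub["cap"] == cap)
                        )
                        if not hit.any():
                            missing.append((tooth, side, load, cap))
        if missing:
            raise ValueError(f"missing table cells: {missing}")

    sub["expected_pattern"] = [_expected_pattern(c) for c in sub["cap"]]
    sub["is_exception"] = [
        _is_exception(c, p) for c, p in zip(sub["cap"], sub["compression_pct"])
    ]
    sub["near_miss"] = (sub["compression_pct"] - 50.0).abs() <= margin

    molars = sub[sub["tooth"] == _SECOND_MOLAR].reset_index(drop=True)
    eruptive = sub[sub["tooth"].isin(_ERUPTIVE_TEETH)].reset_index(drop=True)
    return ExceptionReport(
        basis=basis, margin=margin, table=eruptive, second_molars=molars
    )
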
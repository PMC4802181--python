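"""High-content FISH/IF image and spot-distance analysis.

The measurement chain: z-stacks are maximum-projected per channel; nuclei
are segmented from the nuclear-stain projection (border-touching nuclei
discarded); spots are detected as intensity local maxima whose brightest
pixel is the spot centre; per-cell minimum Euclidean pixel distances
between channels are tabulated; each RNU1 spot is classified as
CB-dependent, CB-independent or neither from the gene-gene and gene-CB
distance thresholds (3 px / 5 px at 320 nm pixels, i.e. 0.96 and 1.6 um),
with CB "bridging" as an orthogonal flag; interaction frequency is the
percentage of eligible cells carrying at least one qualifying event.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.segmentation import clear_border

CHANNELS = ("RNU1", "VGOI", "CB")
DEFAULT_PIXEL_SIZE_NM = 320.0
DEFAULT_GENE_THRESH_PX = 3.0  # 0.96 um at 320 nm / px
DEFAULT_CB_THRESH_PX = 5.0  # 1.6 um at 320 nm / px


def px_to_um(px: float, pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM) -> float:
    return px * pixel_size_nm / 1000.0


def um_to_px(um: float, pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM) -> float:
    return um * 1000.0 / pixel_size_nm


@dataclass(frozen=True)
class Spot:
    channel: str
    x: float
    y: float
    intensity: float = 0.0

    def distance_to(self, other: "Spot") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass
class CellSpotTable:
    """Per-cell spot sets, one list per channel."""

    cell_id: str
    spots: dict[str, list[Spot]] = field(default_factory=dict)

    def channel(self, name: str) -> list[Spot]:
        return self.spots.get(name, [])

    @property
    def eligible(self) -> bool:
        """A cell enters the analysis only with >=1 spot in every channel."""
        return all(len(self.channel(c)) >= 1 for c in CHANNELS)


@dataclass
class NucleusMask:
    label_id: int
    mask: np.ndarray  # boolean, full-image shape
    touches_border: bool

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PairEvent:
    """Per-RNU1-spot distance bookkeeping and classification."""

    cell_id: str
    rnu1_index: int
    d_gene: float
    d_cb: float
    d_cb_vgoi: float
    label: str  # CB_dependent | CB_independent | none
    bridging: bool


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the leading (z) axis."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be (z, y, x) with >= 1 plane")
    return stack.max(axis=0)


def segment_nuclei(
    projection: np.ndarray,
    min_area: int = 50,
    threshold: float | None = None,
) -> list[NucleusMask]:
    """Segment nuclei from the projected nuclear-stain channel.

    Global automatic (Otsu) threshold unless an explicit one is given, hole
    filling, connected-component labelling, minimum-area filter. Masks
    touching the image border are returned flagged; downstream statistics
    exclude them.
    """
    img = np.asarray(projection, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if threshold is None:
        if img.max() == img.min():
            return []
        threshold = float(threshold_otsu(img))
    binary = ndimage.binary_fill_holes(img > threshold)
    labelled = sk_label(binary)
    interior = clear_border(labelled)
    nuclei = []
    for lab in range(1, labelled.max() + 1):
        mask = labelled == lab
        if mask.sum() < min_area:
            continue
        touches = not (interior == lab).any()
        nuclei.append(NucleusMask(label_id=lab, mask=mask, touches_border=touches))
    return nuclei


def detect_spots(
    projection: np.ndarray,
    nucleus: NucleusMask | np.ndarray,
    channel: str,
    min_intensity: float,
    min_separation: float = 2.0,
) -> list[Spot]:
    """Intensity local maxima inside the nucleus; the brightest pixel of each
    signal is its centre.

    Candidates are 8-neighbourhood local maxima above ``min_intensity``;
    candidates closer than ``min_separation`` px are suppressed greedily in
    order of decreasing intensity, ties broken toward the smallest (y, x).
    """
    img = np.asarray(projection, dtype=float)
    mask = nucleus.mask if isinstance(nucleus, NucleusMask) else np.asarray(nucleus)
    if not mask.any():
        raise ValueError("nucleus mask is empty")
    local_max = img == ndimage.maximum_filter(img, size=3, mode="constant", cval=-np.inf)
    cand = np.argwhere(local_max & mask & (img >= min_intensity))
    order = sorted(range(len(cand)), key=lambda i: (-img[tuple(cand[i])], cand[i][0], cand[i][1]))
    kept: list[tuple[int, int]] = []
    for i in order:
        y, x = map(int, cand[i])
        if all(math.hypot(x - kx, y - ky) >= min_separation for ky, kx in kept):
            kept.append((y, x))
    return [
        Spot(channel=channel, x=float(x), y=float(y), intensity=float(img[y, x]))
        for y, x in sorted(kept, key=lambda p: (p[0], p[1]))
    ]


def min_pairwise_distances(
    cell: CellSpotTable, bridging_any_cb: bool = False
) -> list[dict]:
    """Per-RNU1-spot minimum distances.

    Each RNU1 spot carries its minimum distance to any VGOI spot (d_gene)
    and to any CB (d_cb). The CB that realizes d_cb supplies its own
    minimum CB-VGOI distance (d_cb_vgoi) for bridging; with
    ``bridging_any_cb`` the minimum over all CBs is used instead.
    """
    if not cell.eligible:
        raise ValueError(
            f"cell {cell.cell_id} ineligible: needs >=1 spot per channel"
        )
    rnu1, vgoi, cbs = (cell.channel(c) for c in CHANNELS)
    records = []
    cb_vgoi_min = [min(cb.distance_to(v) for v in vgoi) for cb in cbs]
    for i, r in enumerate(rnu1):
        d_gene = min(r.distance_to(v) for v in vgoi)
        d_to_cbs = [r.distance_to(cb) for cb in cbs]
        j = int(np.argmin(d_to_cbs))
        d_cb = d_to_cbs[j]
        d_cb_vgoi = min(cb_vgoi_min) if bridging_any_cb else cb_vgoi_min[j]
        records.append(
            {
                "cell_id": cell.cell_id,
                "rnu1_index": i,
                "d_gene": d_gene,
                "d_cb": d_cb,
                "d_cb_vgoi": d_cb_vgoi,
            }
        )
    return records


def classify_rnu1_spot(
    d_gene: float,
    d_cb: float,
    d_cb_vgoi: float,
    gene_thresh: float = DEFAULT_GENE_THRESH_PX,
    cb_thresh: float = DEFAULT_CB_THRESH_PX,
) -> tuple[str, bool]:
    """Threshold classification of one RNU1 spot.

    CB_dependent iff d_gene <= gene_thresh and d_cb <= cb_thresh;
    CB_independent iff d_gene <= gene_thresh and d_cb > cb_thresh (strict);
    otherwise none. Bridging (d_cb <= cb_thresh and d_cb_vgoi <= cb_thresh)
    is an orthogonal flag that can co-occur with any label.
    """
    if min(d_gene, d_cb, d_cb_vgoi) < 0:
        raise ValueError("distances must be >= 0")
    if d_gene <= gene_thresh:
        label = "CB_dependent" if d_cb <= cb_thresh else "CB_independent"
    else:
        label = "none"
    bridging = d_cb <= cb_thresh and d_cb_vgoi <= cb_thresh
    return label, bridging


def classify_cells(
    cells: list[CellSpotTable],
    gene_thresh: float = DEFAULT_GENE_THRESH_PX,
    cb_thresh: float = DEFAULT_CB_THRESH_PX,
    bridging_any_cb: bool = False,
) -> pd.DataFrame:
    """Per-RNU1-spot event table over all eligible cells.

    Ineligible cells are excluded (column ``eligible`` marks exclusion in
    the companion cell summary; here they simply contribute no rows).
    """
    rows = []
    for cell in cells:
        if not cell.eligible:
            continue
        for rec in min_pairwise_distances(cell, bridging_any_cb):
            label, bridging = classify_rnu1_spot(
                rec["d_gene"], rec["d_cb"], rec["d_cb_vgoi"], gene_thresh, cb_thresh
            )
            rows.append({**rec, "label": label, "bridging": bridging})
    return pd.DataFrame(
        rows,
        columns=["cell_id", "rnu1_index", "d_gene", "d_cb", "d_cb_vgoi", "label", "bridging"],
    )


def interaction_frequency(
    cells: list[CellSpotTable],
    event_predicate,
    gene_thresh: float = DEFAULT_GENE_THRESH_PX,
    cb_thresh: float = DEFAULT_CB_THRESH_PX,
    bridging_any_cb: bool = False,
) -> tuple[float, float, int]:
    """Percentage of eligible cells with >=1 qualifying event, with binomial
    s.e. (also in percent) and the number of eligible cells.

    ``event_predicate`` receives (label, bridging) per RNU1 spot and returns
    whether that spot constitutes an event. Ineligible cells enter neither
    numerator nor denominator.
    """
    eligible = [c for c in cells if c.eligible]
    n = len(eligible)
    if n == 0:
        raise ValueError("no eligible cells")
    hits = 0
    for cell in eligible:
        has_event = False
        for rec in min_pairwise_distances(cell, bridging_any_cb):
            label, bridging = classify_rnu1_spot(
                rec["d_gene"], rec["d_cb"], rec["d_cb_vgoi"], gene_thresh, cb_thresh
            )
            if event_predicate(label, bridging):
                has_event = True
                break
        hits += has_event
    p = hits / n
    se = math.sqrt(p * (1 - p) / n)
    return 100.0 * p, 100.0 * se, n


def locus_position_class(
    spot: Spot, territory_mask: np.ndarray, edge_width: float
) -> str:
    """Position of a locus relative to a (projected) territory mask.

    interior: inside the mask, farther than ``edge_width`` px from its
    boundary; periphery: within ±``edge_width`` of the boundary (either
    side); exterior: outside beyond ``edge_width``.
    """
    mask = np.asarray(territory_mask, dtype=bool)
    if not mask.any():
        raise ValueError("territory mask is empty")
    inside_dist = ndimage.distance_transform_edt(mask)
    outside_dist = ndimage.distance_transform_edt(~mask)
    y, x = int(round(spot.y)), int(round(spot.x))
    if not (0 <= y < mask.shape[0] and 0 <= x < mask.shape[1]):
        return "exterior"
    signed = inside_dist[y, x] if mask[y, x] else -outside_dist[y, x]
    if signed > edge_width:
        return "interior"
    if signed >= -edge_width:
        return "periphery"
    return "exterior"


def cells_from_dataframe(df: pd.DataFrame) -> list[CellSpotTable]:
    """Build per-cell spot tables from a tidy spot table
    (cell_id, channel, x_px, y_px, intensity)."""
    cells = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        spots: dict[str, list[Spot]] = {}
        for row in group.itertuples(index=False):
            spots.setdefault(row.channel, []).append(
                Spot(
                    channel=row.channel,
                    x=float(row.x_px),
                    y=float(row.y_px),
                    intensity=float(getattr(row, "intensity", 0.0)),
                )
            )
        cells.append(CellSpotTable(cell_id=str(cell_id), spots=spots))
    return cells


def cells_to_dataframe(cells: list[CellSpotTable]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": cell.cell_id,
            "channel": s.channel,
            "x_px": s.x,
            "y_px": s.y,
            "intensity": s.intensity,
        }
        for cell in cells
        for ch in sorted(cell.spots)
        for s in cell.spots[ch]
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "channel", "x_px", "y_px", "intensity"]
    )
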
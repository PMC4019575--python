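"""Region-growing segmentation of the backscatter mosaic.

Every valid pixel starts as its own region; adjacent (4-connected) region
pairs are merged smallest-mean-difference-first under a similarity threshold
that ramps up geometrically over a fixed number of passes, becoming
increasingly less stringent. A final pass forces regions smaller than the
area threshold into their most similar neighbour. All tie-breaks are by
lower region id, so outputs are fully deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .core_io import RasterGrid, SegmentSet


@dataclass(frozen=True)
class SegmentationConfig:
    similarity_threshold: float = 1.0   # grey-level units
    area_threshold: int = 2500          # pixels
    n_passes: int = 4                   # length of the threshold ramp

    def __post_init__(self):
        if self.similarity_threshold <= 0:
            raise ValueError("similarity_threshold must be > 0")
        if self.area_threshold <= 0:
            raise ValueError("area_threshold must be > 0")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")


def _threshold_schedule(cfg: SegmentationConfig) -> list[float]:
    # geometric ramp ending exactly at the configured threshold
    return [cfg.similarity_threshold / 2 ** (cfg.n_passes - 1 - k) for k in range(cfg.n_passes)]


class _Regions:
    """Union-find over pixel regions with mean tracking and adjacency sets.

    The surviving root of any merge is always the lower id, which (together
    with the heap key) fixes the merge order under ties.
    """

    def __init__(self, ids: np.ndarray, values: np.ndarray):
        self.parent = {int(i): int(i) for i in ids}
        self.total = {int(i): float(v) for i, v in zip(ids, values)}
        self.count = {int(i): 1 for i in ids}
        self.neighbours: dict[int, set[int]] = {int(i): set() for i in ids}

    def find(self, a: int) -> int:
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def mean(self, a: int) -> float:
        return self.total[a] / self.count[a]

    def add_edge(self, a: int, b: int) -> None:
        self.neighbours[a].add(b)
        self.neighbours[b].add(a)

    def merge(self, a: int, b: int) -> int:
        """Merge roots a and b; the lower id survives. Returns the survivor."""
        keep, gone = (a, b) if a < b else (b, a)
        self.parent[gone] = keep
        self.total[keep] += self.total[gone]
        self.count[keep] += self.count[gone]
        nk, ng = self.neighbours[keep], self.neighbours[gone]
        nk.discard(gone)
        ng.discard(keep)
        for n in ng:
            self.neighbours[n].discard(gone)
            self.neighbours[n].add(keep)
            nk.add(n)
        del self.total[gone], self.count[gone], self.neighbours[gone]
        return keep


def region_grow(mosaic: RasterGrid, cfg: SegmentationConfig = SegmentationConfig()) -> SegmentSet:
    """Segment the mosaic into contiguous homogeneous regions.

    Returns a SegmentSet whose label raster holds 1-based segment ids
    (nodata = 0 where the mosaic had no data).
    """
    mask = mosaic.mask()
    n_rows, n_cols = mosaic.shape
    label_grid = mosaic.copy_with(np.zeros(mosaic.shape))
    label_grid.nodata = 0.0
    if not mask.any():
        return SegmentSet(label_raster=label_grid, areas={})

    rows, cols = np.nonzero(mask)
    pix_ids = rows * n_cols + cols
    regions = _Regions(pix_ids, mosaic.values[rows, cols])

    # 4-connected adjacency between valid pixels
    heap: list[tuple[float, int, int]] = []
    right = mask[:, :-1] & mask[:, 1:]
    down = mask[:-1, :] & mask[1:, :]
    for (rr, cc), (dr, dc) in ((np.nonzero(right), (0, 1)), (np.nonzero(down), (1, 0))):
        a = rr * n_cols + cc
        b = (rr + dr) * n_cols + (cc + dc)
        diffs = np.abs(mosaic.values[rr, cc] - mosaic.values[rr + dr, cc + dc])
        for ai, bi, d in zip(a.tolist(), b.tolist(), diffs.tolist()):
            regions.add_edge(ai, bi)
            heap.append((d, ai, bi))
    heapq.heapify(heap)

    for threshold in _threshold_schedule(cfg):
        _merge_under(regions, heap, threshold)

    _enforce_min_area(regions, cfg.area_threshold)

    # relabel surviving roots 1..k in scan order of their lowest pixel id
    roots = sorted({regions.find(int(i)) for i in pix_ids})
    relabel = {root: k + 1 for k, root in enumerate(roots)}
    flat_labels = np.array([relabel[regions.find(int(i))] for i in pix_ids])
    values = np.zeros(mosaic.shape)
    values[rows, cols] = flat_labels
    label_grid = label_grid.copy_with(values)
    label_grid.nodata = 0.0
    areas = {relabel[r]: regions.count[r] for r in roots}
    return SegmentSet(label_raster=label_grid, areas=areas)


def _merge_under(regions: _Regions, heap: list, threshold: float) -> None:
    """Merge adjacent region pairs smallest-difference-first while diff < threshold."""
    while heap:
        diff, a, b = heap[0]
        if diff >= threshold:
            break
        heapq.heappop(heap)
        ra, rb = regions.find(a), regions.find(b)
        if ra == rb:
            continue
        lo, hi = (ra, rb) if ra < rb else (rb, ra)
        if hi not in regions.neighbours[lo]:
            continue
        actual = abs(regions.mean(lo) - regions.mean(hi))
        if actual != diff or (a, b) != (lo, hi):
            heapq.heappush(heap, (actual, lo, hi))  # stale entry: reinsert with current key
            continue
        keep = regions.merge(lo, hi)
        m = regions.mean(keep)
        for n in sorted(regions.neighbours[keep]):
            d = abs(m - regions.mean(n))
            pair = (keep, n) if keep < n else (n, keep)
            heapq.heappush(heap, (d, pair[0], pair[1]))


def _enforce_min_area(regions: _Regions, area_threshold: int) -> None:
    """Merge every region below the area threshold into its most similar neighbour.

    Smallest region first, ties by id; a lazy heap keeps this near-linear.
    Isolated small regions (no neighbours) are left alone.
    """
    heap = [
        (regions.count[r], r)
        for r in regions.count
        if regions.parent[r] == r and regions.count[r] < area_threshold
    ]
    heapq.heapify(heap)
    while heap:
        cnt, r = heapq.heappop(heap)
        if regions.parent.get(r, -1) != r:
            continue  # absorbed since queued
        cur = regions.count[r]
        if cur >= area_threshold:
            continue
        if cur != cnt:
            heapq.heappush(heap, (cur, r))  # stale size: requeue at current size
            continue
        if not regions.neighbours[r]:
            continue
        m = regions.mean(r)
        best = min(
            sorted(regions.neighbours[r]),
            key=lambda n: (abs(m - regions.mean(n)), n),
        )
        keep = regions.merge(r, best)
        if regions.count[keep] < area_threshold:
            heapq.heappush(heap, (regions.count[keep], keep))


def vectorize(segment_set: SegmentSet) -> dict[int, object]:
    """Vectorise each segment to a polygon (possibly with holes) in world coordinates.

    Polygon areas equal pixel_count * cell_size^2; the result is also stored
    on ``segment_set.polygons``.
    """
    import shapely

    grid = segment_set.label_raster
    cs = grid.cell_size
    polygons: dict[int, object] = {}
    labels = grid.values.astype(int)
    for seg_id in segment_set.segment_ids:
        rows, cols = np.nonzero(labels == seg_id)
        x0 = grid.origin_x + cols * cs
        y1 = grid.origin_y - rows * cs
        boxes = shapely.box(x0, y1 - cs, x0 + cs, y1)
        geom = shapely.union_all(boxes)
        # snap away floating-point slivers on shared edges
        geom = shapely.set_precision(geom, 1e-9)
        polygons[seg_id] = geom
    segment_set.polygons = polygons
    return polygons


def polygons_to_geojson(segment_set: SegmentSet, path: str) -> None:
    """Write segment polygons as a GeoJSON FeatureCollection with id and area."""
    import json

    import shapely

    if not segment_set.polygons:
        vectorize(segment_set)
    features = []
    for seg_id, geom in segment_set.polygons.items():
        features.append(
            {
                "type": "Feature",
                "geometry": json.loads(shapely.to_geojson(geom)),
                "properties": {"segment_id": seg_id, "area_px": segment_set.areas[seg_id]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
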
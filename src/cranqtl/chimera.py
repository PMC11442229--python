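"""Berry-shape chimeras and quantitative shape descriptors.

Categorical berry-shape scores are replaced by canonical binary template
silhouettes, normalized to a common area and centroid, and fused per
genotype-year into a single "chimera" silhouette: the differential distance
transform (Euclidean distance transform of the image minus that of its
inverse, positive exactly on foreground) is summed across uprights and
thresholded at zero. Six descriptors quantify the chimera:

- UKEC  — eccentricity of the moment-fitted ellipse (0 = circle),
- UKLvW — major/minor axis ratio of the same ellipse,
- UKTO  — tortuosity as the sum of absolute slope-chain-code turns,
- UKSO  — solidity (area / convex hull area),
- UKUX, UKUY — log10 counts of horizontal / vertical unit moves of the
  unsigned Manhattan chain code of the outer contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure


def _as_binary(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D image")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("expected a binary {0,1} image")
    return arr.astype(bool)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def _removal_keeps_connectivity(mask: np.ndarray, y: int, x: int) -> bool:
    """Simple-point test: removing (y, x) must not split its 3x3 neighborhood.

    The foreground neighbors must form exactly one 4-connected component
    (diagonal neighbors count only when bridged through an adjacent edge
    neighbor), which is the local criterion for preserving global
    4-connectivity of the foreground under single-pixel removal.
    """
    h, w = mask.shape
    nb = [bool(mask[y + dy, x + dx]) if 0 <= y + dy < h and 0 <= x + dx < w
          else False for dy, dx in _N8]
    if not any(nb):
        return False   # isolated pixel: removal deletes a whole component
    # crossing-number style count of 4-connected foreground runs around the
    # 8-neighborhood ring; corners belong to a run only via an adjacent edge
    edges = [nb[1], nb[3], nb[5], nb[7]]            # N, E, S, W
    if not any(edges):
        return False
    if all(edges):
        return False   # interior pixel: removal would punch a hole
    present = [i for i in range(4) if edges[i]]
    # two edge neighbors are 4-connected within the ring iff the corner
    # between them is foreground; union-find over the 4-cycle
    parent = {i: i for i in present}

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    bridge = {(0, 1): nb[2], (1, 2): nb[4], (2, 3): nb[6], (3, 0): nb[0]}
    for (i, j), corner_fg in bridge.items():
        if corner_fg and i in parent and j in parent:
            parent[find(i)] = find(j)
    return len({find(i) for i in present}) == 1


def _adjust_area(mask: np.ndarray, target: int) -> np.ndarray:
    """Nudge a single-component mask to exactly ``target`` pixels.

    Surplus pixels are peeled from the boundary inward (smallest interior
    EDT first); deficits are grown outward (nearest background first). Both
    directions follow the signed distance field, so holes cannot appear.
    """
    out = mask.copy()
    area = int(out.sum())
    if area == target:
        return out
    cy, cx = ndimage.center_of_mass(out)
    golden = 0.6180339887498949

    def ordered(sel_mask, dist):
        """Candidates band by band; within a band, golden-angle spread so the
        partially used band is taken evenly around the boundary."""
        coords = np.argwhere(sel_mask)
        d = dist[sel_mask].astype(float)
        ang = np.arctan2(coords[:, 0] - cy, coords[:, 1] - cx)
        chunks = []
        for dv in np.unique(d):
            idx = np.flatnonzero(d == dv)
            rank = np.argsort(np.argsort(ang[idx], kind="stable"), kind="stable")
            chunks.append(idx[np.argsort((rank * golden) % 1.0, kind="stable")])
        return coords[np.concatenate(chunks)]

    if area < target:
        # taxicab bands: every band-k pixel is 4-adjacent to a band-(k-1)
        # pixel, so growing band by band preserves 4-connectivity
        d = ndimage.distance_transform_cdt(~out, metric="taxicab")
        coords = ordered(~out, d)[: target - area]
        out[coords[:, 0], coords[:, 1]] = True
        return out

    # peel: only remove simple pixels (removal keeps the foreground
    # 4-connected), skipping neck pixels; re-band until the target is met
    need = area - target
    while need > 0:
        d = ndimage.distance_transform_cdt(out, metric="taxicab")
        removed_this_pass = 0
        for yx in ordered(out, d):
            if need == 0:
                break
            y, x = int(yx[0]), int(yx[1])
            if _removal_keeps_connectivity(out, y, x):
                out[y, x] = False
                need -= 1
                removed_this_pass += 1
        if removed_this_pass == 0:
            break   # nothing left that is safely removable
    return out


def normalize_shape(img: np.ndarray, target_area: int = 12_000) -> np.ndarray:
    """Center a silhouette on the grid and scale it to ``target_area`` pixels.

    The binary mask is resampled with linear interpolation by the areal
    scale factor, then re-thresholded at the intensity that yields exactly
    ``target_area`` foreground pixels (so the area error is at most the
    tie-count at the threshold, ≤1 px in practice), hole-filled to a single
    4-connected component, and shifted by an integer offset that puts the
    centroid within half a pixel of the grid center.
    """
    mask = _as_binary(img)
    if mask.sum() == 0:
        raise ValueError("empty foreground")
    mask = ndimage.binary_fill_holes(_largest_component(mask))
    h, w = mask.shape

    zoom = np.sqrt(target_area / mask.sum())
    smooth = ndimage.zoom(mask.astype(float), zoom, order=1)
    sh, sw = smooth.shape
    canvas = np.zeros((max(h, sh), max(w, sw)))
    oy, ox = (canvas.shape[0] - sh) // 2, (canvas.shape[1] - sw) // 2
    canvas[oy:oy + sh, ox:ox + sw] = smooth

    if (canvas > 0).sum() < target_area:
        raise ValueError("image grid too small for target_area")
    out = ndimage.binary_fill_holes(_largest_component(canvas >= 0.5))
    out = _adjust_area(out, target_area)

    cy, cx = ndimage.center_of_mass(out)
    dy = int(round((out.shape[0] - 1) / 2.0 - cy))
    dx = int(round((out.shape[1] - 1) / 2.0 - cx))
    out = np.roll(out, (dy, dx), axis=(0, 1))

    if out.shape != (h, w):
        # crop back to the input grid around its center
        cy0 = (out.shape[0] - h) // 2
        cx0 = (out.shape[1] - w) // 2
        cropped = out[cy0:cy0 + h, cx0:cx0 + w]
        if cropped.sum() != out.sum():
            raise ValueError("normalized shape does not fit the input grid")
        out = cropped
    return out.astype(np.uint8)


def differential_distance_transform(img: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance field: positive on foreground, negative on background.

    ``DDT = EDT(img) - EDT(~img)`` where EDT(x) is the Euclidean distance of
    each nonzero pixel of x to its nearest zero pixel.
    """
    mask = _as_binary(img)
    return (ndimage.distance_transform_edt(mask)
            - ndimage.distance_transform_edt(~mask))


def synthesize_chimera(uprights: list[np.ndarray]) -> np.ndarray:
    """Fuse normalized silhouettes into one chimera: pixels where the summed DDT > 0.

    Summation makes a single repeated shape exactly idempotent and a mixed
    set a majority-like blend; ties (summed DDT == 0) go to background.
    """
    if len(uprights) == 0:
        raise ValueError("need at least one upright image")
    shapes = {np.asarray(u).shape for u in uprights}
    if len(shapes) != 1:
        raise ValueError(f"mismatched image grids: {sorted(shapes)}")
    total = np.zeros(next(iter(shapes)))
    for u in uprights:
        total += differential_distance_transform(u)
    return (total > 0).astype(np.uint8)


@dataclass(frozen=True)
class ChimeraDescriptors:
    UKEC: float
    UKLvW: float
    UKTO: float
    UKSO: float
    UKUX: float
    UKUY: float
    degenerate: bool = False


def _region(img: np.ndarray):
    mask = _as_binary(img)
    if mask.sum() == 0:
        raise ValueError("empty foreground")
    props = measure.regionprops(mask.astype(np.uint8))
    return props[0]


def eccentricity(img: np.ndarray) -> float:
    """Moment-ellipse eccentricity sqrt(1 - b²/a²); 1.0 sentinel if degenerate."""
    p = _region(img)
    if p.axis_minor_length == 0:
        return 1.0
    return float(p.eccentricity)


def length_width(img: np.ndarray) -> float:
    """Major/minor axis length ratio of the moment-fitted ellipse (>= 1)."""
    p = _region(img)
    if p.axis_minor_length == 0:
        return float("inf")
    return float(p.axis_major_length / p.axis_minor_length)


def solidity(img: np.ndarray) -> float:
    """Foreground area over convex-hull area, in (0, 1]."""
    return float(_region(img).solidity)


def _outer_contour(img: np.ndarray) -> np.ndarray:
    mask = ndimage.binary_fill_holes(_as_binary(img))
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no contour found")
    contour = max(contours, key=len)
    if not np.allclose(contour[0], contour[-1]):
        raise ValueError("outer contour is not closed")
    return contour - 1.0  # undo padding offset


def _resample_closed(contour: np.ndarray, m: int) -> np.ndarray:
    """Resample a closed polyline into m points at equal arc length."""
    seg = np.linalg.norm(np.diff(contour, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate contour")
    t = np.linspace(0.0, total, m, endpoint=False)
    y = np.interp(t, s, contour[:, 0])
    x = np.interp(t, s, contour[:, 1])
    return np.column_stack([y, x])


def tortuosity(img: np.ndarray, m: int = 64) -> float:
    """Slope-chain-code tortuosity: sum of |turn angle| / pi over m equal segments.

    The outer contour is resampled into ``m`` equal-arc-length segments; the
    change of slope between consecutive segments, wrapped to (-pi, pi] and
    normalized by pi, is accumulated in absolute value. Any convex contour
    scores 2.0 (one full turn); waviness adds to the sum.
    """
    if m < 3:
        raise ValueError("need m >= 3 segments")
    pts = _resample_closed(_outer_contour(img), m)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    ang = np.arctan2(d[:, 0], d[:, 1])
    turn = np.diff(np.concatenate([ang, ang[:1]]))
    turn = (turn + np.pi) % (2 * np.pi) - np.pi
    return float(np.abs(turn).sum() / np.pi)


def total_turning(img: np.ndarray, m: int = 64) -> float:
    """Signed total turning of the outer contour in turns (±1 for simple curves)."""
    pts = _resample_closed(_outer_contour(img), m)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    ang = np.arctan2(d[:, 0], d[:, 1])
    turn = np.diff(np.concatenate([ang, ang[:1]]))
    turn = (turn + np.pi) % (2 * np.pi) - np.pi
    return float(turn.sum() / (2 * np.pi))


def chain_code_moves(img: np.ndarray) -> tuple[int, int]:
    """Unit moves of the unsigned Manhattan chain code of the outer boundary.

    The 4-connected crack boundary of the hole-filled silhouette is a closed
    path of unit horizontal and vertical moves along pixel edges; a crack
    between vertically adjacent differing pixels is traversed horizontally
    (an X move) and vice versa. Returns ``(n_x, n_y)``.
    """
    mask = ndimage.binary_fill_holes(_as_binary(img)).astype(np.int8)
    padded = np.pad(mask, 1)
    n_x = int(np.abs(np.diff(padded, axis=0)).sum())  # horizontal edges
    n_y = int(np.abs(np.diff(padded, axis=1)).sum())  # vertical edges
    if n_x + n_y < 4:
        raise ValueError("contour shorter than 4 moves")
    return n_x, n_y


def umcc(img: np.ndarray) -> tuple[float, float]:
    """(UKUX, UKUY): log10 of horizontal and vertical chain-code move counts."""
    n_x, n_y = chain_code_moves(img)
    return float(np.log10(n_x)), float(np.log10(n_y))


def shape_descriptors(img: np.ndarray, scc_segments: int = 64) -> ChimeraDescriptors:
    """All six chimera descriptors of a single-component binary silhouette."""
    p = _region(img)
    degenerate = p.axis_minor_length == 0
    ukux, ukuy = umcc(img)
    return ChimeraDescriptors(
        UKEC=1.0 if degenerate else float(p.eccentricity),
        UKLvW=float("inf") if degenerate else float(p.axis_major_length / p.axis_minor_length),
        UKTO=tortuosity(img, m=scc_segments),
        UKSO=float(p.solidity),
        UKUX=ukux,
        UKUY=ukuy,
        degenerate=bool(degenerate),
    )


def chimera_table(shape_scores, templates: dict, scc_segments: int = 64):
    """Per-(genotype, year) chimera descriptors from categorical shape scores.

    ``shape_scores`` is the long table from the simulator (genotype, year,
    upright, shape_class); ``templates`` maps class id to a normalized binary
    template. Returns a tidy DataFrame with the six descriptor columns.
    """
    import pandas as pd

    recs = []
    for (gid, year), grp in shape_scores.groupby(["genotype", "year"]):
        imgs = [templates[c] for c in grp["shape_class"]]
        chim = synthesize_chimera(imgs)
        d = shape_descriptors(chim, scc_segments=scc_segments)
        recs.append((gid, year, d.UKEC, d.UKLvW, d.UKTO, d.UKSO, d.UKUX, d.UKUY))
    return pd.DataFrame(recs, columns=["genotype", "year", "UKEC", "UKLvW",
                                       "UKTO", "UKSO", "UKUX", "UKUY"])
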
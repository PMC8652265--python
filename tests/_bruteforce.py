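"""Independent brute-force oracles used by the tests.

Pure-Python flood fill, edge counting and all-pairs park-effect
computation — deliberately naive and independent of the package's
vectorized implementations.
"""

import math


def flood_fill_patches(mask, connectivity=8):
    """List of patches (lists of (i, j) cells) by breadth-first search."""
    h = len(mask)
    w = len(mask[0])
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = [[False] * w for _ in range(h)]
    patches = []
    for i in range(h):
        for j in range(w):
            if mask[i][j] and not seen[i][j]:
                queue = [(i, j)]
                seen[i][j] = True
                cells = []
                while queue:
                    ci, cj = queue.pop()
                    cells.append((ci, cj))
                    for di, dj in nbrs:
                        ni, nj = ci + di, cj + dj
                        if 0 <= ni < h and 0 <= nj < w and mask[ni][nj] \
                                and not seen[ni][nj]:
                            seen[ni][nj] = True
                            queue.append((ni, nj))
                patches.append(cells)
    return patches


def patch_perimeter_cells(cells, shape, count_boundary=True):
    """Exposed cell-edge count of one patch."""
    cellset = set(cells)
    h, w = shape
    per = 0
    for (i, j) in cells:
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ni, nj = i + di, j + dj
            if not (0 <= ni < h and 0 <= nj < w):
                per += 1 if count_boundary else 0
            elif (ni, nj) not in cellset:
                per += 1
    return per


def brute_metrics(mask, cell_size, count_boundary=True):
    """(pland, area_mn, shape_mn, ed) by explicit counting."""
    h = len(mask)
    w = len(mask[0])
    landscape_ha = h * w * cell_size ** 2 / 1e4
    patches = flood_fill_patches(mask, connectivity=8)
    if not patches:
        return 0.0, float("nan"), float("nan"), 0.0
    areas_ha = [len(c) * cell_size ** 2 / 1e4 for c in patches]
    perims_m = [patch_perimeter_cells(c, (h, w), count_boundary) * cell_size
                for c in patches]
    pland = 100.0 * sum(areas_ha) / landscape_ha
    area_mn = sum(areas_ha) / len(patches)
    shape_mn = sum(0.25 * p / math.sqrt(a * 1e4)
                   for p, a in zip(perims_m, areas_ha)) / len(patches)
    ed = sum(perims_m) / landscape_ha
    return pland, area_mn, shape_mn, ed


def brute_heat_mitigation(cc, green_mask, cell_size, d_cool, min_area_ha):
    """All-pairs park-effect computation.

    Green patches (8-connected) of at least ``min_area_ha`` influence
    every pixel within ``d_cool``; there the heat-mitigation index is the
    exp(-d/d_cool)-weighted mean of the qualifying green pixels' cooling
    capacity, if larger than the pixel's own.
    """
    h = len(cc)
    w = len(cc[0])
    big = set()
    for patch in flood_fill_patches(green_mask, connectivity=8):
        if len(patch) * cell_size ** 2 / 1e4 >= min_area_ha:
            big.update(patch)
    hm = [[cc[i][j] for j in range(w)] for i in range(h)]
    for i in range(h):
        for j in range(w):
            num = den = 0.0
            for (gi, gj) in big:
                d = math.hypot(i - gi, j - gj) * cell_size
                if d <= d_cool:
                    wgt = math.exp(-d / d_cool)
                    num += wgt * cc[gi][gj]
                    den += wgt
            if den > 0:
                hm[i][j] = max(cc[i][j], num / den)
    return hm
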
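"""Exact ray/voxel-grid traversal (Siddon-type) for radiological depths."""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def trace_rays(red, origin, spacing, p0, p_det, t_split):  # pragma: no cover - jit
    """Integrate ``red`` along segments ``p0 -> p_det[r]``, split at ``t_split``.

    ``red`` is indexed ``[ix, iy, iz]`` with voxel (0,0,0) centred at
    ``origin`` (mm) and voxel size ``spacing`` (mm).  Returns two arrays of
    path-weighted integrals (mm of water-equivalent path): the part of each
    segment with parameter < ``t_split`` and the part beyond it.
    """
    n = p_det.shape[0]
    t_up = np.zeros(n)
    t_down = np.zeros(n)
    nx, ny, nz = red.shape
    nvox = np.empty(3, np.int64)
    nvox[0], nvox[1], nvox[2] = nx, ny, nz
    b0 = np.empty(3)
    for ax in range(3):
        b0[ax] = origin[ax] - 0.5 * spacing[ax]

    for r in range(n):
        d = np.empty(3)
        for ax in range(3):
            d[ax] = p_det[r, ax] - p0[ax]
        length = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        if length == 0.0:
            continue
        # Parametric entry/exit of the grid bounding box.
        a_min = 0.0
        a_max = 1.0
        inside = True
        for ax in range(3):
            if d[ax] != 0.0:
                a1 = (b0[ax] - p0[ax]) / d[ax]
                a2 = (b0[ax] + nvox[ax] * spacing[ax] - p0[ax]) / d[ax]
                lo = min(a1, a2)
                hi = max(a1, a2)
                if lo > a_min:
                    a_min = lo
                if hi < a_max:
                    a_max = hi
            else:
                if p0[ax] <= b0[ax] or p0[ax] >= b0[ax] + nvox[ax] * spacing[ax]:
                    inside = False
        if not inside or a_min >= a_max:
            continue

        a = a_min
        up = 0.0
        down = 0.0
        eps = 1e-12
        while a < a_max - eps:
            # Voxel under the segment starting at `a`: probe just beyond `a`.
            a_next = a_max
            probe = a + eps
            iv = np.empty(3, np.int64)
            for ax in range(3):
                pos = p0[ax] + probe * d[ax]
                k = int(np.floor((pos - b0[ax]) / spacing[ax]))
                if k < 0:
                    k = 0
                if k >= nvox[ax]:
                    k = nvox[ax] - 1
                iv[ax] = k
            # Next plane crossing along each axis.
            for ax in range(3):
                if d[ax] > 0.0:
                    ac = (b0[ax] + (iv[ax] + 1) * spacing[ax] - p0[ax]) / d[ax]
                elif d[ax] < 0.0:
                    ac = (b0[ax] + iv[ax] * spacing[ax] - p0[ax]) / d[ax]
                else:
                    continue
                if ac < a_next and ac > a + eps:
                    a_next = ac
            if a_next > a_max:
                a_next = a_max
            seg = (a_next - a) * length
            val = seg * red[iv[0], iv[1], iv[2]]
            if a_next <= t_split:
                up += val
            elif a >= t_split:
                down += val
            else:
                frac = (t_split - a) / (a_next - a)
                up += val * frac
                down += val * (1.0 - frac)
            a = a_next
        t_up[r] = up
        t_down[r] = down
    return t_up, t_down
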
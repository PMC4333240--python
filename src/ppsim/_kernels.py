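"""Compiled inner loop of the simulation.

`run_chunk` advances a block of consecutive time steps: cell injection,
chemokine-biased or unbiased moves, boundary wrapping, LTo contact
collection, arrest tests, and the synchronous LTo update.  All random
numbers are drawn by the caller from the run's `numpy` Generator and passed
in — one direction draw and one arrest draw per live cell per step (draws
for already-arrested cells are simply unused), and one position draw per
injected cell — so the kernel is a pure function and the run's random
stream is defined entirely by the engine's (deterministic) draw layout.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LTIN = 0
LTI = 1


@njit(cache=True)
def _wrapped_dist(ax, ay, bx, by, width):
    dx = abs(ax - bx)
    if dx > width - dx:
        dx = width - dx
    dy = ay - by
    return math.sqrt(dx * dx + dy * dy)


@njit(cache=True)
def _level_at(x, y, src_x, src_y, src_expr, n_src, r_chem, width):
    total = 0.0
    for s in range(n_src):
        d = _wrapped_dist(x, y, src_x[s], src_y[s], width)
        if d < r_chem:
            total += src_expr[s] * (1.0 - d / r_chem)
    return total


@njit(cache=True)
def run_chunk(
    pos,  # (capacity, 2) float64, in place
    kind,  # (capacity,) int8
    arrested,  # (capacity,) bool, in place
    entry_time,  # (capacity,) float64 hours, in place
    n0,  # live cells before the chunk
    ltin_counts,  # (S,) int64 injections per step
    lti_counts,  # (S,) int64
    inj_pos,  # (total_injections, 2) uniform [0,1) draws, consumed in order
    step_t_hours,  # (S,) time at the end of each step
    theta_u,  # (S, n_max) uniform [0,1) direction draws, per live cell
    arrest_u,  # (S, n_max) uniform [0,1) arrest draws
    lto_xy,
    lto_diff,  # in place
    lto_expr,  # in place
    lto_contacts,  # in place
    width,
    height,
    step_len,
    contact_r,
    r_adh,
    r_chem,
    chem_threshold,
    fd_step,
    l0,
    dl,
):
    """Advance ``S`` steps; returns the live-cell count after the chunk."""
    n_lto = lto_xy.shape[0]
    n = n0
    inj = 0
    diff0 = np.empty(n_lto, dtype=np.bool_)
    expr0 = np.empty(n_lto)
    src_x = np.empty(n_lto)
    src_y = np.empty(n_lto)
    src_expr = np.empty(n_lto)
    new_diff = np.empty(n_lto, dtype=np.bool_)
    lti_hits = np.empty(n_lto, dtype=np.int64)

    for s in range(ltin_counts.shape[0]):
        # inject this step's arrivals (LTin first, then LTi)
        for k in range(2):
            count = ltin_counts[s] if k == 0 else lti_counts[s]
            for _ in range(count):
                pos[n, 0] = inj_pos[inj, 0] * width
                pos[n, 1] = inj_pos[inj, 1] * height
                kind[n] = LTIN if k == 0 else LTI
                arrested[n] = False
                entry_time[n] = step_t_hours[s]
                inj += 1
                n += 1

        # start-of-step LTo snapshot; all interactions this step see it
        n_src = 0
        for j in range(n_lto):
            diff0[j] = lto_diff[j]
            expr0[j] = lto_expr[j]
            new_diff[j] = False
            lti_hits[j] = 0
            if diff0[j] and expr0[j] >= chem_threshold:
                src_x[n_src] = lto_xy[j, 0]
                src_y[n_src] = lto_xy[j, 1]
                src_expr[n_src] = expr0[j]
                n_src += 1

        for i in range(n):
            if arrested[i]:
                continue
            x = pos[i, 0]
            y = pos[i, 1]
            t = theta_u[s, i] * 2.0 * math.pi
            ux = math.cos(t)
            uy = math.sin(t)
            dirx = ux
            diry = uy

            if kind[i] == LTI and n_src > 0:
                level = _level_at(x, y, src_x, src_y, src_expr, n_src, r_chem, width)
                b = level if level < 1.0 else 1.0
                if b > 0.0:
                    gx = (
                        _level_at(x + fd_step, y, src_x, src_y, src_expr, n_src, r_chem, width)
                        - _level_at(x - fd_step, y, src_x, src_y, src_expr, n_src, r_chem, width)
                    ) / (2.0 * fd_step)
                    # reflect the y probes at the mirror boundary
                    yp = y + fd_step
                    if yp > height:
                        yp = 2.0 * height - yp
                    ym = y - fd_step
                    if ym < 0.0:
                        ym = -ym
                    gy = (
                        _level_at(x, yp, src_x, src_y, src_expr, n_src, r_chem, width)
                        - _level_at(x, ym, src_x, src_y, src_expr, n_src, r_chem, width)
                    ) / (2.0 * fd_step)
                    gnorm = math.sqrt(gx * gx + gy * gy)
                    if gnorm > 1e-12:
                        bx = (1.0 - b) * ux + b * gx / gnorm
                        by = (1.0 - b) * uy + b * gy / gnorm
                    else:
                        bx = (1.0 - b) * ux
                        by = (1.0 - b) * uy
                    bnorm = math.sqrt(bx * bx + by * by)
                    if bnorm > 1e-9:
                        dirx = bx / bnorm
                        diry = by / bnorm

            # move and wrap (periodic x, reflective y)
            x = (x + step_len * dirx) % width
            y = (y + step_len * diry) % (2.0 * height)
            if y > height:
                y = 2.0 * height - y
            pos[i, 0] = x
            pos[i, 1] = y

            if n_lto > 0:
                d_near = 1e30
                j_near = -1
                for j in range(n_lto):
                    d = _wrapped_dist(x, y, lto_xy[j, 0], lto_xy[j, 1], width)
                    if d <= contact_r:
                        if kind[i] == LTIN:
                            if not diff0[j]:
                                new_diff[j] = True
                        elif diff0[j]:
                            lti_hits[j] += 1
                    if diff0[j] and d < d_near:
                        d_near = d
                        j_near = j
                if j_near >= 0 and d_near < r_adh:
                    p = expr0[j_near] * (1.0 - d_near / r_adh)
                    if arrest_u[s, i] < p:
                        arrested[i] = True

        # synchronous LTo update from this step's events
        for j in range(n_lto):
            if new_diff[j]:
                lto_diff[j] = True
                lto_expr[j] = l0
            elif lti_hits[j] > 0:
                lto_contacts[j] += lti_hits[j]
                e = expr0[j] + dl * lti_hits[j]
                lto_expr[j] = e if e < 1.0 else 1.0

    return n
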
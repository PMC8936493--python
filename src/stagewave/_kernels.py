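"""Numba integration kernels for the delayed mean-field network.

State convention: buffers have ``H + n_steps`` columns; columns ``0..H-1``
hold the initial history, with column ``H-1`` being the state at t = 0.
Column ``H-1+t`` holds the state after ``t`` Euler steps. Delayed reads at
step ``t`` address column ``H-2+t-d`` where ``d`` is the delay in steps, so a
history of ``max(d)+1`` samples is always sufficient.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _wrap(phi: float) -> float:
    return (phi + np.pi) % TWO_PI - np.pi


@njit(cache=True)
def integrate_reduced_full(
    weights,  # (R, R) float64
    dsteps,  # (R, R) int64 delay in integration steps
    r_hist,  # (R, H) float64 initial modulus history, col H-1 = t0
    psi_hist,  # (R, H) float64 initial phase history
    omega,  # (R,) rad/s
    delta,  # (R,)
    l_base,  # (R,)
    g: float,
    dt: float,
    r_floor: float,
    n_steps: int,
    pulse_start,  # (S,) int64 step index of pulse onset
    pulse_stop,  # (S,) int64 first step past the pulse
    delta_l,  # (S, R) signed local-coupling increments
):
    """Forward-Euler integration of the delayed Ott-Antonsen network.

    Returns ``(r_buf, psi_buf, cos_buf, sin_buf, bad_step)`` where the
    buffers have ``H + n_steps`` columns and ``bad_step`` is -1 on success
    or the first step at which a non-finite value appeared. The cos/sin
    buffers cache the phase phasors so delayed coupling reads and
    phase-lag statistics need no per-edge trigonometry.
    """
    n_regions = weights.shape[0]
    horizon = r_hist.shape[1]
    n_pulses = pulse_start.shape[0]
    gr = g / (2.0 * n_regions)

    width = horizon + n_steps
    r_buf = np.empty((n_regions, width))
    psi_buf = np.empty((n_regions, width))
    c_buf = np.empty((n_regions, width))
    s_buf = np.empty((n_regions, width))
    r_buf[:, :horizon] = r_hist
    psi_buf[:, :horizon] = psi_hist
    for i in range(n_regions):
        for k in range(horizon):
            c_buf[i, k] = np.cos(psi_hist[i, k])
            s_buf[i, k] = np.sin(psi_hist[i, k])

    l_eff = np.empty(n_regions)
    for t in range(1, n_steps + 1):
        c = horizon - 1 + t
        for i in range(n_regions):
            l_eff[i] = l_base[i]
        for s in range(n_pulses):
            if pulse_start[s] <= t - 1 < pulse_stop[s]:
                for i in range(n_regions):
                    l_eff[i] += delta_l[s, i]
        for i in range(n_regions):
            r_i = r_buf[i, c - 1]
            psi_i = psi_buf[i, c - 1]
            ci = c_buf[i, c - 1]
            si = s_buf[i, c - 1]
            coup_c = 0.0
            coup_s = 0.0
            for j in range(n_regions):
                if j == i or weights[i, j] == 0.0:
                    continue
                cd = c - 1 - dsteps[i, j]
                a_r = weights[i, j] * r_buf[j, cd]
                cj = c_buf[j, cd]
                sj = s_buf[j, cd]
                # cos/sin(psi_j' - psi_i) from cached phasors
                coup_c += a_r * (cj * ci + sj * si)
                coup_s += a_r * (sj * ci - cj * si)
            one_m = 1.0 - r_i * r_i
            dr = (
                -delta[i] * r_i
                + 0.5 * l_eff[i] * r_i * one_m
                + gr * one_m * coup_c
            )
            r_f = r_i if r_i > r_floor else r_floor
            dpsi = omega[i] + gr * (r_f + 1.0 / r_f) * coup_s
            r_new = r_i + dt * dr
            if r_new < 0.0:
                r_new = 0.0
            elif r_new > 1.0:
                r_new = 1.0
            psi_new = _wrap(psi_i + dt * dpsi)
            if not (np.isfinite(r_new) and np.isfinite(psi_new)):
                return r_buf, psi_buf, c_buf, s_buf, t
            r_buf[i, c] = r_new
            psi_buf[i, c] = psi_new
            c_buf[i, c] = np.cos(psi_new)
            s_buf[i, c] = np.sin(psi_new)
    return r_buf, psi_buf, c_buf, s_buf, -1


@njit(cache=True)
def integrate_reduced(
    weights, dsteps, r_hist, psi_hist, omega, delta, l_base,
    g: float, dt: float, r_floor: float, n_steps: int,
    pulse_start, pulse_stop, delta_l,
):
    """Compatibility wrapper returning ``(r_buf, psi_buf, bad_step)``."""
    r_buf, psi_buf, _, _, bad = integrate_reduced_full(
        weights, dsteps, r_hist, psi_hist, omega, delta, l_base,
        g, dt, r_floor, n_steps, pulse_start, pulse_stop, delta_l,
    )
    return r_buf, psi_buf, bad


@njit(cache=True)
def stage_response_batch(
    weights,
    dsteps,
    r_hists,  # (B, R, H) replicate modulus histories
    psi_hists,  # (B, R, H)
    omega,
    delta,
    l_base,
    g: float,
    dt: float,
    r_floor: float,
    n_steps: int,
    pulse_start: int,
    pulse_stop: int,
    pulse_dl,  # (R,) increments; zeros = unpulsed
    flat_start: int,  # first step of the dpFC window (after the pulse)
    onset_step: int,
    pre_idx,  # (P,) envelope pre-window offsets relative to onset
    post_idx,  # (Q,)
    tail_h: int,
):
    """Integrate a replicate batch and accumulate the stage statistics.

    Returns ``(dpfc_vals, env_change, r_tails, psi_tails, bad)`` where
    ``dpfc_vals[i, j]`` is the replicate- and time-averaged sign of
    sin(psi_i - psi_j) over steps ``flat_start..n_steps`` and ``env_change``
    the replicate-averaged modulus difference between the post- and
    pre-onset windows. ``bad`` is -1 on success.
    """
    n_rep = r_hists.shape[0]
    n_regions = weights.shape[0]
    p_start = np.empty(1, dtype=np.int64)
    p_stop = np.empty(1, dtype=np.int64)
    p_start[0] = pulse_start
    p_stop[0] = pulse_stop
    p_dl = pulse_dl.reshape(1, n_regions)
    dpfc = np.zeros((n_regions, n_regions))
    env = np.zeros(n_regions)
    r_tails = np.empty((n_rep, n_regions, tail_h))
    psi_tails = np.empty((n_rep, n_regions, tail_h))
    n_flat = n_steps - flat_start + 1
    for b in range(n_rep):
        r_buf, psi_buf, c_buf, s_buf, bad = integrate_reduced_full(
            weights, dsteps, r_hists[b], psi_hists[b], omega, delta, l_base,
            g, dt, r_floor, n_steps, p_start, p_stop, p_dl,
        )
        if bad >= 0:
            return dpfc, env, r_tails, psi_tails, bad
        horizon = r_hists.shape[2]
        base = horizon - 1  # column of the t=0 state
        for i in range(n_regions):
            for j in range(i + 1, n_regions):
                acc = 0.0
                for t in range(flat_start, n_steps + 1):
                    # sin(psi_i - psi_j) from cached phasors
                    s = s_buf[i, base + t] * c_buf[j, base + t] - c_buf[
                        i, base + t
                    ] * s_buf[j, base + t]
                    if s > 0.0:
                        acc += 1.0
                    elif s < 0.0:
                        acc -= 1.0
                dpfc[i, j] += acc / n_flat
        for i in range(n_regions):
            pre = 0.0
            post = 0.0
            for k in range(pre_idx.shape[0]):
                pre += r_buf[i, base + onset_step + pre_idx[k]]
            for k in range(post_idx.shape[0]):
                post += r_buf[i, base + onset_step + post_idx[k]]
            env[i] += post / post_idx.shape[0] - pre / pre_idx.shape[0]
        r_tails[b] = r_buf[:, r_buf.shape[1] - tail_h :]
        psi_tails[b] = psi_buf[:, psi_buf.shape[1] - tail_h :]
    for i in range(n_regions):
        for j in range(i + 1, n_regions):
            v = dpfc[i, j] / n_rep
            dpfc[i, j] = v
            dpfc[j, i] = -v
    return dpfc, env / n_rep, r_tails, psi_tails, -1


@njit(cache=True)
def integrate_micro(
    weights,  # (R, R)
    dsteps,  # (R, R) int64
    theta0,  # (R, N) initial oscillator phases
    nat_freq,  # (R, N) rad/s, Lorentzian-distributed
    r_hist,  # (R, H) mean-field history for delayed reads
    psi_hist,  # (R, H)
    l_base,  # (R,)
    g: float,
    dt: float,
    n_steps: int,
):
    """Finite-N Kuramoto network-of-networks; returns regional order parameters.

    Within a region the N oscillators are all-to-all coupled at strength
    L_i/N (i.e. through their own mean field); between regions the coupling
    is via delayed regional mean fields at per-oscillator strength
    G*A_ij/R, matching the mean-field reduction integrated by
    :func:`integrate_reduced`.
    """
    n_regions, n_osc = theta0.shape
    horizon = r_hist.shape[1]
    gr = g / n_regions

    theta = theta0.copy()
    r_buf = np.empty((n_regions, horizon + n_steps))
    psi_buf = np.empty((n_regions, horizon + n_steps))
    r_buf[:, :horizon] = r_hist
    psi_buf[:, :horizon] = psi_hist
    # overwrite the t=0 column with the actual oscillator mean field
    for i in range(n_regions):
        sx = 0.0
        sy = 0.0
        for m in range(n_osc):
            sx += np.cos(theta[i, m])
            sy += np.sin(theta[i, m])
        r_buf[i, horizon - 1] = np.sqrt(sx * sx + sy * sy) / n_osc
        psi_buf[i, horizon - 1] = np.arctan2(sy, sx)

    for t in range(1, n_steps + 1):
        c = horizon - 1 + t
        for i in range(n_regions):
            # complex mean-field drive: local + delayed between-region
            f_re = (
                l_base[i]
                * r_buf[i, c - 1]
                * np.cos(psi_buf[i, c - 1])
            )
            f_im = (
                l_base[i]
                * r_buf[i, c - 1]
                * np.sin(psi_buf[i, c - 1])
            )
            for j in range(n_regions):
                if j == i or weights[i, j] == 0.0:
                    continue
                cd = c - 1 - dsteps[i, j]
                amp = gr * weights[i, j] * r_buf[j, cd]
                f_re += amp * np.cos(psi_buf[j, cd])
                f_im += amp * np.sin(psi_buf[j, cd])
            sx = 0.0
            sy = 0.0
            for m in range(n_osc):
                th = theta[i, m]
                dth = nat_freq[i, m] + f_im * np.cos(th) - f_re * np.sin(th)
                th_new = _wrap(th + dt * dth)
                theta[i, m] = th_new
                sx += np.cos(th_new)
                sy += np.sin(th_new)
            r_buf[i, c] = np.sqrt(sx * sx + sy * sy) / n_osc
            psi_buf[i, c] = np.arctan2(sy, sx)
    return r_buf, psi_buf
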
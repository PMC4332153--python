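"""Compiled Euler-Maruyama integration kernels.

Pure numerical loops, jit-compiled with numba.  Randomness is supplied by
the caller as pre-drawn standard-normal arrays so that seeding and draw
order are controlled entirely by numpy Generators in the calling code; the
population kernel advances in chunks so the noise (which can reach ~1e8
draws, ordered step-major then cell-major) is materialized a bounded slab
at a time.

Noise modes: 0 = activator equation, 1 = external cAMP, 2 = none.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NOISE_ACTIVATOR = 0
NOISE_EXTERNAL = 1
NOISE_NONE = 2


@njit(cache=True)
def integrate_cell(A0, R0, camp_input, dt, n_steps, record_stride,
                   eps, gamma, c0, a, kd, sigma, noise_mode, noise):
    """Single-cell Euler-Maruyama integration.

    camp_input : (n_steps,) applied extracellular cAMP at each step start.
    noise      : (n_steps,) standard normals (unused entries ignored).

    Returns (A_rec, R_rec, input_rec, fail_step); fail_step is -1 on
    success, else the index of the first non-finite state.
    """
    n_rec = n_steps // record_stride + 1
    A_rec = np.empty(n_rec)
    R_rec = np.empty(n_rec)
    in_rec = np.empty(n_rec)
    sqdt = np.sqrt(dt)

    A = A0
    R = R0
    j = 0
    for k in range(n_steps):
        camp = camp_input[k]
        if noise_mode == NOISE_EXTERNAL:
            camp = camp + sigma * sqdt * noise[k]
            if camp < 0.0:
                camp = 0.0
        if k % record_stride == 0:
            A_rec[j] = A
            R_rec[j] = R
            in_rec[j] = camp
            j += 1
            if not (np.isfinite(A) and np.isfinite(R)):
                return A_rec, R_rec, in_rec, k
        drive = a * np.log1p(camp / kd)
        dA = (A - A * A * A / 3.0 - R + drive) * dt
        dR = eps * (A - gamma * R + c0) * dt
        if noise_mode == NOISE_ACTIVATOR:
            dA += sigma * sqdt * noise[k]
        A += dA
        R += dR
    A_rec[j] = A
    R_rec[j] = R
    in_rec[j] = camp_input[n_steps - 1]
    if not (np.isfinite(A) and np.isfinite(R)):
        return A_rec, R_rec, in_rec, n_steps
    return A_rec, R_rec, in_rec, -1


@njit(cache=True)
def integrate_population_chunk(A, R, camp0, alpha_f_chunk, noise_chunk,
                               dt, k0, n_chunk, record_stride,
                               eps, gamma, c0, a, kd, kd_uniform,
                               noise_mode, rho, alpha0, S, D,
                               A_rec, R_rec, camp_rec):
    """Advance the N-cell + field system by n_chunk Euler-Maruyama steps.

    A, R          : (N,) current per-cell states (updated in place).
    camp0         : current external-cAMP value.
    alpha_f_chunk : (n_chunk,) inflow source rate for these steps.
    noise_chunk   : pre-scaled noise increments sigma*sqrt(dt)*xi; shape
                    (n_chunk, N) for activator noise, (n_chunk, 1) for
                    external noise, (1, 1) when noise is off.
    k0            : global index of the chunk's first step (recording at
                    global steps divisible by record_stride writes into
                    A_rec/R_rec/camp_rec at slot k//record_stride).
    kd            : (N,) response thresholds; kd_uniform marks the
                    homogeneous case (the per-step drive is then shared).

    Returns (fail_step, camp); fail_step is the global index of the first
    non-finite state, or -1.  The external field is clipped at 0 every
    step.
    """
    N = A.shape[0]
    camp = camp0
    for k in range(n_chunk):
        g = k0 + k
        if g % record_stride == 0:
            j = g // record_stride
            ok = np.isfinite(camp)
            for i in range(N):
                A_rec[j, i] = A[i]
                R_rec[j, i] = R[i]
                if not (np.isfinite(A[i]) and np.isfinite(R[i])):
                    ok = False
            camp_rec[j] = camp
            if not ok:
                return g, camp
        shared_drive = a * np.log1p(camp / kd[0])
        n_firing = 0
        if noise_mode == NOISE_ACTIVATOR:
            for i in range(N):
                if A[i] > 0.0:
                    n_firing += 1
                drive = shared_drive if kd_uniform \
                    else a * np.log1p(camp / kd[i])
                dA = (A[i] - A[i] * A[i] * A[i] / 3.0 - R[i] + drive) * dt \
                    + noise_chunk[k, i]
                dR = eps * (A[i] - gamma * R[i] + c0) * dt
                A[i] += dA
                R[i] += dR
        else:
            for i in range(N):
                if A[i] > 0.0:
                    n_firing += 1
                drive = shared_drive if kd_uniform \
                    else a * np.log1p(camp / kd[i])
                dA = (A[i] - A[i] * A[i] * A[i] / 3.0 - R[i] + drive) * dt
                dR = eps * (A[i] - gamma * R[i] + c0) * dt
                A[i] += dA
                R[i] += dR
        dcamp = (alpha_f_chunk[k] + rho * alpha0
                 + rho * S * n_firing / N - D * camp) * dt
        if noise_mode == NOISE_EXTERNAL:
            dcamp += noise_chunk[k, 0]
        camp += dcamp
        if camp < 0.0:
            camp = 0.0
    return -1, camp
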
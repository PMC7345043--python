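"""Numba-compiled numerical kernels.

These are the hot loops of the simulator: Gauss--Seidel relaxation sweeps of
the 7-point discrete Laplacian, and the per-particle time-stepping loop.
Everything here is plain scalar arithmetic on contiguous float64 arrays; the
physically meaningful interfaces live in :mod:`depsep.field` and
:mod:`depsep.dynamics`.
"""

import numpy as np
from numba import njit

# particle terminal status codes shared with dynamics.py
IN_TRANSIT = 0
CAPTURED = 1
SETTLED = 2
EXITED = 3


@njit(cache=True)
def gs_sweep(V, fixed, omega, periodic_x):
    """One in-place Gauss--Seidel (optionally over-relaxed) sweep.

    Non-Dirichlet boundary nodes use the mirror-node convention for the
    zero-normal-derivative (insulated) condition; with ``periodic_x`` the
    axial neighbours wrap instead (nodes 0 and nx-1 are the same physical
    plane).  Returns the largest absolute node update of the sweep.
    """
    nx, ny, nz = V.shape
    maxd = 0.0
    for i in range(nx):
        if periodic_x:
            im = i - 1 if i > 0 else nx - 2
            ip = i + 1 if i < nx - 1 else 1
        else:
            im = i - 1 if i > 0 else 1
            ip = i + 1 if i < nx - 1 else nx - 2
        for j in range(ny):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < ny - 1 else ny - 2
            for k in range(nz):
                if fixed[i, j, k]:
                    continue
                km = k - 1 if k > 0 else 1
                kp = k + 1 if k < nz - 1 else nz - 2
                vnew = (
                    V[im, j, k] + V[ip, j, k]
                    + V[i, jm, k] + V[i, jp, k]
                    + V[i, j, km] + V[i, j, kp]
                ) / 6.0
                d = omega * (vnew - V[i, j, k])
                V[i, j, k] += d
                ad = abs(d)
                if ad > maxd:
                    maxd = ad
    return maxd


@njit(cache=True)
def laplacian_residual(V, fixed):
    """Max absolute 7-point Laplacian defect over non-Dirichlet nodes
    (mirror convention at faces), in volts."""
    nx, ny, nz = V.shape
    maxr = 0.0
    for i in range(nx):
        im = i - 1 if i > 0 else 1
        ip = i + 1 if i < nx - 1 else nx - 2
        for j in range(ny):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < ny - 1 else ny - 2
            for k in range(nz):
                if fixed[i, j, k]:
                    continue
                km = k - 1 if k > 0 else 1
                kp = k + 1 if k < nz - 1 else nz - 2
                r = (
                    V[im, j, k] + V[ip, j, k]
                    + V[i, jm, k] + V[i, jp, k]
                    + V[i, j, km] + V[i, j, kp]
                ) / 6.0 - V[i, j, k]
                ar = abs(r)
                if ar > maxr:
                    maxr = ar
    return maxr


@njit(cache=True)
def trilinear(A, fx, fy, fz):
    """Trilinear interpolation of A at fractional indices (fx, fy, fz),
    clamped to the grid."""
    nx, ny, nz = A.shape
    if fx < 0.0:
        fx = 0.0
    if fx > nx - 1:
        fx = nx - 1.0
    if fy < 0.0:
        fy = 0.0
    if fy > ny - 1:
        fy = ny - 1.0
    if fz < 0.0:
        fz = 0.0
    if fz > nz - 1:
        fz = nz - 1.0
    i0 = int(fx)
    j0 = int(fy)
    k0 = int(fz)
    if i0 > nx - 2:
        i0 = nx - 2
    if j0 > ny - 2:
        j0 = ny - 2
    if k0 > nz - 2:
        k0 = nz - 2
    tx = fx - i0
    ty = fy - j0
    tz = fz - k0
    c00 = A[i0, j0, k0] * (1 - tx) + A[i0 + 1, j0, k0] * tx
    c10 = A[i0, j0 + 1, k0] * (1 - tx) + A[i0 + 1, j0 + 1, k0] * tx
    c01 = A[i0, j0, k0 + 1] * (1 - tx) + A[i0 + 1, j0, k0 + 1] * tx
    c11 = A[i0, j0 + 1, k0 + 1] * (1 - tx) + A[i0 + 1, j0 + 1, k0 + 1] * tx
    c0 = c00 * (1 - ty) + c10 * ty
    c1 = c01 * (1 - ty) + c11 * ty
    return c0 * (1 - tz) + c1 * tz


@njit(cache=True)
def bilinear(T, fy, fz):
    """Bilinear interpolation of the flow table at fractional indices."""
    ny, nz = T.shape
    if fy < 0.0:
        fy = 0.0
    if fy > ny - 1:
        fy = ny - 1.0
    if fz < 0.0:
        fz = 0.0
    if fz > nz - 1:
        fz = nz - 1.0
    j0 = int(fy)
    k0 = int(fz)
    if j0 > ny - 2:
        j0 = ny - 2
    if k0 > nz - 2:
        k0 = nz - 2
    ty = fy - j0
    tz = fz - k0
    return (
        T[j0, k0] * (1 - ty) * (1 - tz)
        + T[j0 + 1, k0] * ty * (1 - tz)
        + T[j0, k0 + 1] * (1 - ty) * tz
        + T[j0 + 1, k0 + 1] * ty * tz
    )


@njit(cache=True)
def integrate(
    y0, z0,
    W, H, Lu, Larr, r,
    a, b, cdrag, fdep_coef, fz_net,
    gx, gy, gz, hf,
    utab, duy, duz,
    dt, max_steps,
    mode, tau,
    traj, stride,
):
    """Time-step one particle from the inlet until a terminal event.

    mode 0: the central-difference scheme of the equation of motion with the
    drag velocity taken as the centered difference, solved semi-implicitly
    per component.  mode 1: exact exponential integration of the linear drag
    over each step with the DEP/weight forcing frozen at the step start.

    Returns (status, t, x, y, z, vx, vy, vz, n_recorded).  traj rows are
    (t, x, y, z); pass stride <= 0 to disable recording.
    """
    # current position
    x1 = 0.0
    y1 = y0
    z1 = z0
    u0 = bilinear(utab, y1 / duy, z1 / duz)
    # previous position bootstrapped from the initial (fluid) velocity
    x0 = x1 - u0 * dt
    y0p = y1
    z0p = z1
    vx = u0
    vy = 0.0
    vz = 0.0
    t = 0.0
    status = IN_TRANSIT
    nrec = 0
    if stride > 0:
        traj[0, 0] = t
        traj[0, 1] = x1
        traj[0, 2] = y1
        traj[0, 3] = z1
        nrec = 1
    apb = a + b
    amb = a - b
    for n in range(max_steps):
        u = bilinear(utab, y1 / duy, z1 / duz)
        fx = 0.0
        fy = 0.0
        fz = fz_net
        if fdep_coef != 0.0 and x1 < Larr:
            xr = x1 - Lu * np.floor(x1 / Lu)
            fxg = xr / hf
            fyg = y1 / hf
            fzg = z1 / hf
            fx = fdep_coef * trilinear(gx, fxg, fyg, fzg)
            fy += fdep_coef * trilinear(gy, fxg, fyg, fzg)
            fz += fdep_coef * trilinear(gz, fxg, fyg, fzg)
        if mode == 0:
            x2 = (2.0 * a * x1 - amb * x0 + cdrag * u + fx) / apb
            y2 = (2.0 * a * y1 - amb * y0p + fy) / apb
            z2 = (2.0 * a * z1 - amb * z0p + fz) / apb
            vx = (x2 - x0) / (2.0 * dt)
            vy = (y2 - y0p) / (2.0 * dt)
            vz = (z2 - z0p) / (2.0 * dt)
        else:
            e = np.exp(-dt / tau)
            uex = u + fx / cdrag
            uey = fy / cdrag
            uez = fz / cdrag
            x2 = x1 + uex * dt + (vx - uex) * tau * (1.0 - e)
            y2 = y1 + uey * dt + (vy - uey) * tau * (1.0 - e)
            z2 = z1 + uez * dt + (vz - uez) * tau * (1.0 - e)
            vx = uex + (vx - uex) * e
            vy = uey + (vy - uey) * e
            vz = uez + (vz - uez) * e
        t += dt
        if not (np.isfinite(x2) and np.isfinite(y2) and np.isfinite(z2)):
            status = -1
            break
        # top wall: contact clamps without terminating
        if z2 > H - r:
            z2 = H - r
        x0 = x1
        y0p = y1
        z0p = z1
        x1 = x2
        y1 = y2
        z1 = z2
        if stride > 0 and (n + 1) % stride == 0 and nrec < traj.shape[0]:
            traj[nrec, 0] = t
            traj[nrec, 1] = x1
            traj[nrec, 2] = y1
            traj[nrec, 3] = z1
            nrec += 1
        if (y1 <= r or y1 >= W - r) and x1 < Larr:
            status = CAPTURED
            break
        if z1 <= r:
            status = SETTLED
            break
        if x1 >= Larr:
            status = EXITED
            break
    if stride > 0 and nrec < traj.shape[0]:
        traj[nrec, 0] = t
        traj[nrec, 1] = x1
        traj[nrec, 2] = y1
        traj[nrec, 3] = z1
        nrec += 1
    return status, t, x1, y1, z1, vx, vy, vz, nrec


@njit(cache=True)
def integrate_batch(
    seeds,
    W, H, Lu, Larr, r,
    a, b, cdrag, fdep_coef, fz_net,
    gx, gy, gz, hf,
    utab, duy, duz,
    dt, max_steps,
    mode, tau,
    out,
):
    """Run :func:`integrate` for every (W0, H0) seed; fill ``out`` rows with
    (status, t, x, y, z, vx, vy, vz)."""
    dummy = np.empty((1, 4))
    for p in range(seeds.shape[0]):
        res = integrate(
            seeds[p, 0], seeds[p, 1],
            W, H, Lu, Larr, r,
            a, b, cdrag, fdep_coef, fz_net,
            gx, gy, gz, hf,
            utab, duy, duz,
            dt, max_steps,
            mode, tau,
            dummy, 0,
        )
        out[p, 0] = res[0]
        out[p, 1] = res[1]
        out[p, 2] = res[2]
        out[p, 3] = res[3]
        out[p, 4] = res[4]
        out[p, 5] = res[5]
        out[p, 6] = res[6]
        out[p, 7] = res[7]
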
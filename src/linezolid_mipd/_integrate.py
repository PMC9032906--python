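"""Low-level ODE kernel: adaptive Dormand-Prince RK45, numba-compiled.

State vector (10 entries, amounts in mg, concentrations in mg/L):

    y[0:5]  A1..A5   transit-compartment amounts
    y[5]    Aa       absorption-compartment amount
    y[6]    Ac       central-compartment amount
    y[7]    Ci       inhibition-compartment concentration
    y[8]    Ae       cumulative eliminated amount (mass-balance bookkeeping)
    y[9]    AUCc     cumulative integral of the central concentration Ac/V

The integration is restarted at every breakpoint (dose event, occasion
parameter switch, or requested output time); doses are instantaneous
boluses into the first transit compartment.  Parameters are constant
within each inter-breakpoint interval, which is what makes the cumulative
AUC state well defined (V is fixed inside an interval).

The embedded 4th-order error estimate drives standard PI-free step
control; the pair is explicit, which is adequate here because the wide
rate range of the model (k_IC ~ 5e-4/h vs k_tr ~ 11/h) puts the slow mode
in the inhibition compartment, not a fast decaying one.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate_breakpoints", "NSTATE"]

NSTATE = 10


@njit(cache=True, inline='always')
def _rhs(y, CL, V, ka, ktr, kIC, IC50, RCLF, inhib, out):
    out[0] = -ktr * y[0]
    out[1] = ktr * (y[0] - y[1])
    out[2] = ktr * (y[1] - y[2])
    out[3] = ktr * (y[2] - y[3])
    out[4] = ktr * (y[3] - y[4])
    out[5] = ktr * y[4] - ka * y[5]
    conc = y[6] / V
    if inhib:
        mult = RCLF + (1.0 - RCLF) * (1.0 - y[7] / (IC50 + y[7]))
    else:
        mult = 1.0
    elim = (CL / V) * y[6] * mult
    out[6] = ka * y[5] - elim
    out[7] = kIC * (conc - y[7])
    out[8] = elim
    out[9] = conc


@njit(cache=True, inline='always')
def _step_dopri(t, y, h, CL, V, ka, ktr, kIC, IC50, RCLF, inhib,
                k1, ynew, err, k2, k3, k4, k5, k6, ytmp):
    """One Dormand-Prince 5(4) step from t with size h.

    k1 must hold f(t, y) on entry (FSAL); on exit it holds f(t+h, ynew).
    Returns nothing; ynew, err and the scratch arrays are filled in place.
    """
    n = y.shape[0]

    for i in range(n):
        ytmp[i] = y[i] + h * 0.2 * k1[i]
    _rhs(ytmp, CL, V, ka, ktr, kIC, IC50, RCLF, inhib, k2)

    for i in range(n):
        ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
    _rhs(ytmp, CL, V, ka, ktr, kIC, IC50, RCLF, inhib, k3)

    for i in range(n):
        ytmp[i] = y[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                              + 32.0 / 9.0 * k3[i])
    _rhs(ytmp, CL, V, ka, ktr, kIC, IC50, RCLF, inhib, k4)

    for i in range(n):
        ytmp[i] = y[i] + h * (19372.0 / 6561.0 * k1[i]
                              - 25360.0 / 2187.0 * k2[i]
                              + 64448.0 / 6561.0 * k3[i]
                              - 212.0 / 729.0 * k4[i])
    _rhs(ytmp, CL, V, ka, ktr, kIC, IC50, RCLF, inhib, k5)

    for i in range(n):
        ytmp[i] = y[i] + h * (9017.0 / 3168.0 * k1[i]
                              - 355.0 / 33.0 * k2[i]
                              + 46732.0 / 5247.0 * k3[i]
                              + 49.0 / 176.0 * k4[i]
                              - 5103.0 / 18656.0 * k5[i])
    _rhs(ytmp, CL, V, ka, ktr, kIC, IC50, RCLF, inhib, k6)

    for i in range(n):
        ynew[i] = y[i] + h * (35.0 / 384.0 * k1[i]
                              + 500.0 / 1113.0 * k3[i]
                              + 125.0 / 192.0 * k4[i]
                              - 2187.0 / 6784.0 * k5[i]
                              + 11.0 / 84.0 * k6[i])
    _rhs(ynew, CL, V, ka, ktr, kIC, IC50, RCLF, inhib, k2)  # k7 (FSAL)

    for i in range(n):
        err[i] = h * (71.0 / 57600.0 * k1[i]
                      - 71.0 / 16695.0 * k3[i]
                      + 71.0 / 1920.0 * k4[i]
                      - 17253.0 / 339200.0 * k5[i]
                      + 22.0 / 525.0 * k6[i]
                      - 1.0 / 40.0 * k2[i])
        k1[i] = k2[i]


@njit(cache=True)
def integrate_breakpoints(break_ts, dose_amts, theta, y0,
                          kIC, IC50, RCLF, inhib, rtol, atol):
    """Integrate across breakpoints, recording the state at each one.

    break_ts : (nb,) strictly increasing times, break_ts[0] is the start.
    dose_amts: (nb,) bolus added to the first transit compartment at each
               breakpoint *after* the state is recorded (troughs are
               therefore pre-dose values; the central concentration itself
               is continuous across a transit-compartment bolus).
    theta    : (nb-1, 4) rows (CL, V, ka, ktr) valid on each interval.
    y0       : (10,) state at break_ts[0], recorded before dose_amts[0].

    Returns (Y, status): Y is (nb, 10); status 0 on success, 1 if the step
    size underflowed (non-convergence).
    """
    nb = break_ts.shape[0]
    n = y0.shape[0]
    Y = np.empty((nb, n))
    y = y0.copy()
    Y[0] = y
    y[0] += dose_amts[0]

    k1 = np.empty(n)
    ynew = np.empty(n)
    errv = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    ytmp = np.empty(n)
    h = 1e-3

    for seg in range(nb - 1):
        t = break_ts[seg]
        t_end = break_ts[seg + 1]
        CL = theta[seg, 0]
        V = theta[seg, 1]
        ka = theta[seg, 2]
        ktr = theta[seg, 3]
        span = t_end - t
        if span <= 1e-10:
            # degenerate interval (coincident breakpoints up to round-off):
            # carry the state across
            Y[seg + 1] = y
            y[0] += dose_amts[seg + 1]
            continue
        if h > span:
            h = span
        _rhs(y, CL, V, ka, ktr, kIC, IC50, RCLF, inhib, k1)
        while t < t_end:
            if h < 1e-12 * max(1.0, t_end):
                return Y, 1
            clipped = False
            if t + h >= t_end:
                h_use = t_end - t
                clipped = True
            else:
                h_use = h
            _step_dopri(t, y, h_use, CL, V, ka, ktr, kIC, IC50, RCLF, inhib,
                        k1, ynew, errv, k2, k3, k4, k5, k6, ytmp)
            # weighted RMS error norm
            acc = 0.0
            for i in range(n):
                sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
                e = errv[i] / sc
                acc += e * e
            enorm = np.sqrt(acc / n)
            if enorm <= 1.0:
                t = t + h_use
                for i in range(n):
                    y[i] = ynew[i]
                # Snap emptied absorption-chain states (fast eigenvalues
                # k_tr, ka) to exact zero: amounts below 1e-14 mg are
                # physically negligible but, left nonzero, keep the explicit
                # pair stability-limited long after absorption is complete.
                for i in range(6):
                    if -1e-14 < y[i] < 1e-14:
                        y[i] = 0.0
                if enorm == 0.0:
                    fac = 10.0
                else:
                    fac = min(10.0, max(0.2, 0.9 * enorm ** -0.2))
                if not clipped or fac < 1.0:
                    h = h_use * fac
                # k1 already holds f(t, y) via FSAL
            else:
                h = h_use * max(0.2, 0.9 * enorm ** -0.2)
                _rhs(y, CL, V, ka, ktr, kIC, IC50, RCLF, inhib, k1)
        Y[seg + 1] = y
        y[0] += dose_amts[seg + 1]
    return Y, 0
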
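"""Independent brute-force oracles used by the test suite.

These re-derive results through deliberately simple routes (fixed-step
integration, directly coded formulas) and never call the code paths they
check.
"""

import numpy as np

from dinobloom.model import STATE_VARS


def rk4_trajectory(initial, params, mask, horizon, dt=1e-3, out_step=0.1,
                   options=None):
    """Classic fixed-step 4th-order Runge-Kutta integration.

    The right-hand side is re-coded here from the model equations, term by
    term, independent of the package's flux machinery.
    """
    from dinobloom.model import ModelOptions

    opt = options or ModelOptions()
    p = params
    active = mask.active_states()
    frozen = tuple(v in mask.frozen for v in STATE_VARS)
    ft = 0.94 / (1.0 + 219000.0 * p.T ** -4.35) * 24.0

    def f(y):
        H, I, P, D, A, C, R, N = [max(v, 0.0) for v in y]
        if not active[0]:
            H = I = 0.0
        if not active[2]:
            P = I = 0.0
        if not active[3]:
            D = 0.0
        if not active[4]:
            A = 0.0
        if not active[5]:
            C = 0.0
        if not active[6]:
            R = 0.0
        fh = N / (p.K_h + N)
        fd = N / (p.K_d + N)
        fa = N / (p.K_a + N)
        phi = p.a * H / (1.0 + p.a * p.h * H)
        pc = H + I + D
        pr = A + P
        Gc = p.G_cmax * pc / (p.K_Gc + pc)
        Gr = p.G_rmax * pr / (p.K_Gr + pr) * ft
        rc = p.r_cmax * (pc - p.x_c) / (p.K_rc + (pc - p.x_c))
        rr = p.r_rmax * (pr - p.x_r) / (p.K_rr + (pr - p.x_r))
        qH = H / pc if pc > 0 else 0.0
        qI = I / pc if pc > 0 else 0.0
        qD = D / pc if pc > 0 else 0.0
        qP = P / pr if pr > 0 else 0.0
        qA = A / pr if pr > 0 else 0.0
        dH = p.r_h * H * fh - phi * P - C * Gc * qH
        dI = phi * P - I / p.h - C * Gc * qI
        dP = p.epsilon * I / p.h - phi * P - p.m * P - R * Gr * qP
        dD = p.r_d * D * fd - C * Gc * qD
        dA = p.r_a * A * fa - R * Gr * qA
        dC = rc * C
        dR = rr * (C if opt.strict_rotifer_growth else R)
        if opt.strict_nitrate_uptake:
            dN = -H * (p.r_h * fh * p.Q_h + p.r_d * fd * p.Q_d
                       + p.r_a * fa * p.Q_a)
        else:
            dN = -(H * p.r_h * fh * p.Q_h + D * p.r_d * fd * p.Q_d
                   + A * p.r_a * fa * p.Q_a)
        dy = [dH, dI, dP, dD, dA, dC, dR, dN]
        return np.array([
            0.0 if frozen[i] or not active[i] else dy[i] for i in range(8)
        ])

    y = initial.to_array()
    n = int(round(horizon / dt))
    per = int(round(out_step / dt))
    out = [np.maximum(y, 0.0)]
    for i in range(1, n + 1):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if i % per == 0:
            out.append(np.maximum(y, 0.0))
    return np.array(out)
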
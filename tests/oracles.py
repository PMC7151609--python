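"""Independent numerical oracles used by the mechanics and acceptance tests."""

import numpy as np


def monolithic_step(model, state, dt, load_value):
    """Dense simultaneous solve of one poroelastic time step.

    Assembles the coupled (displacement, pressure) block system from the
    model's discrete operators and solves it in one shot — no sequential
    splitting — as an oracle for the fixed-stress iteration.
    """
    C = model.n_cells
    nc = model.n_comp
    alpha = model.params.biot_alpha
    K = model.K.toarray()
    D = model.D.toarray()
    T = model.T.toarray()
    free, fixed = model.free, model.fixed
    W = np.hstack([model.weights[c] * np.eye(C) for c in range(nc)])
    u_d = np.zeros(3 * model.n_nodes)
    f_ext = np.zeros(3 * model.n_nodes)
    if model.mode == "column" and model.load_control:
        f_ext[model._top_zdofs] = -load_value * model._top_trib_area
    else:
        u_d[model._top_zdofs] = -load_value
    invM = np.diag(model.invM_vol)
    nf = int(free.sum())
    A = np.block(
        [
            [K[np.ix_(free, free)], -alpha * (D[:, free].T @ W)],
            [alpha * (W.T @ D[:, free]), invM + dt * T],
        ]
    )
    b1 = f_ext[free] - K[np.ix_(free, fixed)] @ u_d[fixed]
    b2 = (
        invM @ state.pressure
        + alpha * W.T @ (D @ state.displacement)
        - alpha * W.T @ (D[:, fixed] @ u_d[fixed])
    )
    x = np.linalg.solve(A, np.concatenate([b1, b2]))
    u = u_d.copy()
    u[free] = x[:nf]
    return u, x[nf:]


def terzaghi_series(xi, t, c_v, H, p0, ramp=0.0, n_terms=300):
    """Uniaxial consolidation series: drained at xi=0, sealed at xi=1.

    ``xi`` is depth from the drained face normalized by the drainage path
    ``H``; a linear load ramp of duration ``ramp`` is folded in exactly by
    Duhamel superposition of the step response.
    """
    p = np.zeros_like(np.asarray(xi, dtype=float))
    for k in range(n_terms):
        m = 2 * k + 1
        lam = (m * np.pi / 2.0) ** 2 * c_v / H**2
        if ramp > 0.0 and lam * ramp < 50.0:
            corr = (np.exp(lam * ramp) - 1.0) / (lam * ramp)
        elif ramp > 0.0:
            corr = 1.0 / (lam * ramp)
        else:
            corr = 1.0
        p += 4.0 / (m * np.pi) * np.sin(m * np.pi * xi / 2.0) * np.exp(-lam * t) * corr
    return p0 * p
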
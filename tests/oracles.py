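"""Independent oracles used by the test suite.

These are deliberately coded from closed forms or direct scipy integration,
sharing nothing with the package's compiled kernels, so that agreement is a
genuine cross-check of the likelihood machinery.
"""

import numpy as np
from scipy.integrate import solve_ivp


def bd_constant_closed_form(tree, lam, mu, f=1.0, conditioning="crown"):
    """Constant-rate birth-death log-likelihood from the closed form.

    Uses the analytic solutions of the E and D equations with sampling
    fraction f: with r = lam - mu and c = lam(1-f) - mu,
    E(t) = 1 - f r / (f lam + c e^(-r t)) and the per-branch log survival
    factor g(t) = r t - 2 log(f lam e^(r t) + c). Requires lam != mu.
    """
    bt = tree.branching_times()
    n = tree.n_tips
    r = lam - mu
    c = lam * (1.0 - f) - mu

    def g(t):
        return r * t - 2.0 * np.log(f * lam * np.exp(r * t) + c)

    def E(t):
        return 1.0 - f * r / (f * lam + c * np.exp(-r * t))

    def psi(t):
        return g(t) - g(0.0)

    lnl = (n * np.log(f) + sum(psi(b) for b in bt) + psi(bt[0])
           + len(bt) * np.log(lam))
    if conditioning == "crown":
        lnl -= np.log(lam) + 2.0 * np.log1p(-E(bt[0]))
    return lnl


def geosse2_direct(tree, tip_states, s_A, s_B, s_x, x_A, x_B, d_AB, d_BA,
                   f=1.0):
    """Two-region GeoSSE log-likelihood by direct integration of the full
    six-equation system (states {A}, {B}, {A,B}) with scipy.solve_ivp,
    recursing over the tree without any of the package's kernel code."""

    def rhs(_t, y):
        EA, EB, EAB, DA, DB, DAB = y
        dEA = (x_A - (s_A + x_A + d_AB) * EA + d_AB * EAB + s_A * EA * EA)
        dEB = (x_B - (s_B + x_B + d_BA) * EB + d_BA * EAB + s_B * EB * EB)
        dEAB = (-(s_A + s_B + s_x + x_A + x_B) * EAB + x_A * EB + x_B * EA
                + s_A * EA * EAB + s_B * EB * EAB + s_x * EA * EB)
        dDA = (-(s_A + x_A + d_AB) * DA + d_AB * DAB + 2.0 * s_A * DA * EA)
        dDB = (-(s_B + x_B + d_BA) * DB + d_BA * DAB + 2.0 * s_B * DB * EB)
        dDAB = (-(s_A + s_B + s_x + x_A + x_B) * DAB + x_A * DB + x_B * DA
                + s_A * (DA * EAB + DAB * EA) + s_B * (DB * EAB + DAB * EB)
                + s_x * (DA * EB + DB * EA))
        return [dEA, dEB, dEAB, dDA, dDB, dDAB]

    smap = {(0,): 0, (1,): 1, (0, 1): 2}
    post = tree.postorder_arrays()
    vals = {}
    for i in range(len(post.age)):
        if post.left[i] < 0:
            st = smap[tip_states[post.tip_labels[post.tip_index[i]]]]
            y = [1.0 - f] * 3 + [0.0] * 3
            y[3 + st] = f
        else:
            l, r = post.left[i], post.right[i]
            El, Dl = vals[l][:3], vals[l][3:]
            Dr = vals[r][3:]
            DA = s_A * Dl[0] * Dr[0]
            DB = s_B * Dl[1] * Dr[1]
            DAB = 0.5 * (s_A * (Dl[0] * Dr[2] + Dl[2] * Dr[0])
                         + s_B * (Dl[1] * Dr[2] + Dl[2] * Dr[1])
                         + s_x * (Dl[0] * Dr[1] + Dl[1] * Dr[0]))
            y = list(El) + [DA, DB, DAB]
        if i < len(post.age) - 1 and post.parent_age[i] - post.age[i] > 1e-12:
            sol = solve_ivp(rhs, (post.age[i], post.parent_age[i]), y,
                            rtol=1e-10, atol=1e-12)
            y = sol.y[:, -1].tolist()
        vals[i] = y
    D = np.array(vals[len(post.age) - 1][3:])
    w = D / D.sum()
    return float(np.log(np.dot(w, D)))


def geosse2_root_marginal(tree, tip_states, s_A, s_B, s_x, x_A, x_B,
                          d_AB, d_BA, f=1.0):
    """Root-state marginal probabilities from the direct six-equation
    integration (likelihood-proportional weighting): P(S) = w_S D_S / sum."""

    # re-run the direct integration, capturing the root D vector
    def run():
        def rhs(_t, y):
            EA, EB, EAB, DA, DB, DAB = y
            return [
                x_A - (s_A + x_A + d_AB) * EA + d_AB * EAB + s_A * EA * EA,
                x_B - (s_B + x_B + d_BA) * EB + d_BA * EAB + s_B * EB * EB,
                -(s_A + s_B + s_x + x_A + x_B) * EAB + x_A * EB + x_B * EA
                + s_A * EA * EAB + s_B * EB * EAB + s_x * EA * EB,
                -(s_A + x_A + d_AB) * DA + d_AB * DAB + 2.0 * s_A * DA * EA,
                -(s_B + x_B + d_BA) * DB + d_BA * DAB + 2.0 * s_B * DB * EB,
                -(s_A + s_B + s_x + x_A + x_B) * DAB + x_A * DB + x_B * DA
                + s_A * (DA * EAB + DAB * EA) + s_B * (DB * EAB + DAB * EB)
                + s_x * (DA * EB + DB * EA),
            ]

        smap = {(0,): 0, (1,): 1, (0, 1): 2}
        post = tree.postorder_arrays()
        vals = {}
        for i in range(len(post.age)):
            if post.left[i] < 0:
                st = smap[tip_states[post.tip_labels[post.tip_index[i]]]]
                y = [1.0 - f] * 3 + [0.0] * 3
                y[3 + st] = f
            else:
                l, r = post.left[i], post.right[i]
                Dl, Dr = vals[l][3:], vals[r][3:]
                El = vals[l][:3]
                DA = s_A * Dl[0] * Dr[0]
                DB = s_B * Dl[1] * Dr[1]
                DAB = 0.5 * (s_A * (Dl[0] * Dr[2] + Dl[2] * Dr[0])
                             + s_B * (Dl[1] * Dr[2] + Dl[2] * Dr[1])
                             + s_x * (Dl[0] * Dr[1] + Dl[1] * Dr[0]))
                y = list(El) + [DA, DB, DAB]
            if i < len(post.age) - 1 and post.parent_age[i] - post.age[i] > 1e-12:
                sol = solve_ivp(rhs, (post.age[i], post.parent_age[i]), y,
                                rtol=1e-10, atol=1e-12)
                y = sol.y[:, -1].tolist()
            vals[i] = y
        return np.array(vals[len(post.age) - 1][3:])

    D = run()
    w = D / D.sum()
    p = w * D
    return p / p.sum()
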
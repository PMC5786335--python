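"""Independent oracles for the solver tests: outcome enumeration and dense
finite-horizon dynamic programs written without the solver's operator
machinery."""

import math

import numpy as np

from riskforage.params import ModelParams, PATCH, REFUGE, legal_actions

LOCS = (REFUGE, PATCH)


def enumerate_outcomes(p: ModelParams, loc: str, action: str, bp: float, bg: float):
    """All one-step joint outcomes from a belief, written from the model
    definition without using the solver's operator machinery."""
    dt = p.dt
    bp1 = bp * math.exp(-p.gamma_PA * dt) + (1 - bp) * (1 - math.exp(-p.gamma_AP * dt))
    bg1 = bg * math.exp(-p.gamma_GB * dt) + (1 - bg) * (1 - math.exp(-p.gamma_BG * dt))
    exposed = loc == PATCH or action == "transit"
    out = []
    pcap = bp1 * (1 - math.exp(-p.delta_by_action[action] * dt)) if exposed else 0.0
    if exposed:
        out.append((pcap, 1.0, bg1, p.reward_rate(action) * dt + p.r_pred, True))
    channels = []
    if action != "rest":
        channels.append((p.lambda_oi_plus * dt, p.lambda_oi_minus * dt))
    if action == "assess":
        channels.append((p.lambda_od_plus * dt, p.lambda_od_minus * dt))
    combos = [(1.0, 1.0)]
    for lp, lm in channels:
        combos = [
            (Lp * x, La * y) for Lp, La in combos for x, y in ((lp, lm), (1 - lp, 1 - lm))
        ]
    if action == "feed":
        encs = [
            (p.rho_rG * dt, p.rho_rB * dt, p.r_feed_rich * dt),
            (p.rho_pG * dt, p.rho_pB * dt, p.r_feed_poor * dt),
            (1 - (p.rho_rG + p.rho_pG) * dt, 1 - (p.rho_rB + p.rho_pB) * dt, 0.0),
        ]
        encs = [e for e in encs if e[0] > 0 or e[1] > 0]
    else:
        encs = [(1.0, 1.0, p.reward_rate(action) * dt)]
    for Lp, La in combos:
        m = bp1 * Lp + (1 - bp1) * La
        post_p = bp1 * Lp / m if m > 0 else bp1
        for Eg, Eb, r in encs:
            me = bg1 * Eg + (1 - bg1) * Eb
            post_g = bg1 * Eg / me if me > 0 else bg1
            out.append(((1 - pcap) * m * me, post_p, post_g, r, False))
    return out


def _end_loc(p: ModelParams, loc: str, action: str) -> str:
    if loc == REFUGE:
        return PATCH if action == "transit" else REFUGE
    return REFUGE if (action == "escape" and p.escape_effective) else PATCH


def brute_force_values(p: ModelParams, horizon: int):
    """Finite-horizon backward induction with its own bilinear interpolation."""
    n = int(round(1 / p.d_beta)) + 1
    betas = np.linspace(0, 1, n)
    pts = [(bp, bg) for bp in betas for bg in betas]
    disc = math.exp(-p.alpha * p.dt)

    def interp(vals, bp, bg):
        fP, fG = bp / p.d_beta, bg / p.d_beta
        i0 = min(int(fP), n - 2)
        j0 = min(int(fG), n - 2)
        tP, tG = fP - i0, fG - j0
        v = vals.reshape(n, n)
        return (
            v[i0, j0] * (1 - tP) * (1 - tG)
            + v[i0, j0 + 1] * (1 - tP) * tG
            + v[i0 + 1, j0] * tP * (1 - tG)
            + v[i0 + 1, j0 + 1] * tP * tG
        )

    branches = {
        (loc, a): [enumerate_outcomes(p, loc, a, bp, bg) for bp, bg in pts]
        for loc in LOCS
        for a in legal_actions(loc)
    }
    V = {loc: np.zeros(len(pts)) for loc in LOCS}
    for _ in range(horizon):
        newV = {}
        for loc in LOCS:
            best = np.full(len(pts), -np.inf)
            for a in legal_actions(loc):
                W = V[_end_loc(p, loc, a)].copy()
                for k in range(1, max(p.tau_set) + 1):
                    Wk = np.empty(len(pts))
                    for i in range(len(pts)):
                        total = 0.0
                        for prob, post_p, post_g, r, cap in branches[(loc, a)][i]:
                            if prob == 0.0:
                                continue
                            cont = (
                                interp(V[REFUGE], post_p, post_g)
                                if cap
                                else interp(W, post_p, post_g)
                            )
                            total += prob * (r + disc * cont)
                        Wk[i] = total
                    W = Wk
                    if k in p.tau_set:
                        best = np.maximum(best, W)
            newV[loc] = best - p.c_d
        V = newV
    return V


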
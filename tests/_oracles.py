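"""Independent oracles used by the tests.

Everything here is deliberately written without reference to the package
implementation paths it checks: a second literal transcription of the
closed-form reflectance, a Monte-Carlo photon random walk, exhaustive
sign-enumeration for the Wilcoxon signed-rank null, and brute-force pair
counting for Kendall's tau-b.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata


def reflectance_transcription(mu_a: float, mu_s_prime: float, rho: float, A: float) -> float:
    """Independent transcription of the extrapolated-boundary CW solution."""
    mu_tr = mu_a + mu_s_prime
    z0 = 1.0 / mu_tr
    D = 1.0 / (3.0 * mu_tr)
    mu_eff = math.sqrt(mu_a / D)
    z_b = 2.0 * A * D
    r1 = math.hypot(rho, z0)
    r2 = math.hypot(rho, z0 + 2.0 * z_b)
    t1 = z0 * (mu_eff + 1.0 / r1) * math.exp(-mu_eff * r1) / r1**2
    t2 = (z0 + 2.0 * z_b) * (mu_eff + 1.0 / r2) * math.exp(-mu_eff * r2) / r2**2
    return (t1 + t2) / (4.0 * math.pi)


def mc_diffuse_reflectance(
    mu_a: float,
    mu_s_prime: float,
    rhos: list[float],
    n_photons: int,
    rng: np.random.Generator,
    annulus_half_mm: float = 2.0,
):
    """Monte-Carlo photon random walk in a semi-infinite medium (matched
    boundary, A=1): isotropic scattering at rate mu_s', absorption by path
    weighting exp(-mu_a * L), exit position scored on the z=0 plane.

    Returns (R_estimates, standard_errors) per requested radius, as
    reflectance per unit area per launched photon.
    """
    mfp = 1.0 / mu_s_prime
    # kill photons whose surviving weight is negligible
    l_max = 18.0 / mu_a
    pos = np.zeros((n_photons, 3))
    # launch downward; first interaction after one exponential step
    dirs = np.tile(np.array([0.0, 0.0, 1.0]), (n_photons, 1))
    path = np.zeros(n_photons)
    active = np.ones(n_photons, dtype=bool)
    exit_r = np.full(n_photons, np.nan)
    exit_w = np.zeros(n_photons)

    while active.any():
        idx = np.flatnonzero(active)
        step = rng.exponential(mfp, len(idx))
        p = pos[idx]
        d = dirs[idx]
        new_z = p[:, 2] + d[:, 2] * step

        escaping = new_z < 0.0
        esc = idx[escaping]
        if len(esc):
            s_exit = -p[escaping, 2] / d[escaping, 2]
            ex = p[escaping, 0] + d[escaping, 0] * s_exit
            ey = p[escaping, 1] + d[escaping, 1] * s_exit
            ltot = path[esc] + s_exit
            exit_r[esc] = np.hypot(ex, ey)
            exit_w[esc] = np.exp(-mu_a * ltot)
            active[esc] = False

        stay = idx[~escaping]
        if len(stay):
            pos[stay] += dirs[stay] * step[~escaping, None]
            path[stay] += step[~escaping]
            # isotropic rescattering
            u = 2.0 * rng.random(len(stay)) - 1.0
            phi = 2.0 * np.pi * rng.random(len(stay))
            s = np.sqrt(1.0 - u * u)
            dirs[stay, 0] = s * np.cos(phi)
            dirs[stay, 1] = s * np.sin(phi)
            dirs[stay, 2] = u
            dead = stay[path[stay] > l_max]
            active[dead] = False

    R, SE = [], []
    for rho in rhos:
        in_ann = (exit_r >= rho - annulus_half_mm) & (exit_r < rho + annulus_half_mm)
        area = np.pi * ((rho + annulus_half_mm) ** 2 - (rho - annulus_half_mm) ** 2)
        w = np.where(in_ann, exit_w, 0.0)
        R.append(w.sum() / (n_photons * area))
        SE.append(np.sqrt(max(w.var(ddof=1), 0.0) / n_photons) / area)
    return np.array(R), np.array(SE)


def enum_signed_rank_p(values: np.ndarray, alternative: str) -> float:
    """Exact one-sided signed-rank p by exhaustive enumeration of all 2^n
    sign assignments (midranks for ties).  Feasible for n <= ~16."""
    v = np.asarray(values, dtype=float)
    v = v[v != 0.0]
    n = len(v)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    W = signs @ ranks
    if alternative == "greater":
        return float(np.mean(W >= w_obs - 1e-9))
    return float(np.mean(W <= w_obs + 1e-9))


def enum_tost_p(x: np.ndarray, y: np.ndarray, delta: float) -> float:
    d = np.asarray(x, float) - np.asarray(y, float)
    return max(
        enum_signed_rank_p(d + delta, "greater"),
        enum_signed_rank_p(d - delta, "less"),
    )


def kendall_tau_b_pairs(x: np.ndarray, y: np.ndarray) -> float:
    """tau-b by explicit concordant/discordant pair counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = np.sign(x[i] - x[j])
            b = np.sign(y[i] - y[j])
            if a == 0 and b == 0:
                continue
            if a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a == b:
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom if denom else float("nan")


def mc_tost_power(
    n: int,
    sd_diff: float,
    delta: float,
    alpha: float,
    true_diff: float,
    n_reps: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo power of the parametric paired TOST (t-test based)."""
    from scipy.stats import t as tdist

    d = rng.normal(true_diff, sd_diff, (n_reps, n))
    mean = d.mean(axis=1)
    se = d.std(axis=1, ddof=1) / math.sqrt(n)
    tcrit = tdist.ppf(1 - alpha, n - 1)
    t_lo = (mean + delta) / se
    t_hi = (mean - delta) / se
    return float(np.mean((t_lo >= tcrit) & (t_hi <= -tcrit)))
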
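"""Numba kernels for the Metropolis-within-Gibbs sampler.

Data layout: predictions ``B`` and outcomes ``r`` are (n_participants,
T_max) arrays padded past each participant's ``lengths[i]``; the latent
indicators ``z`` share that layout.  The forward recursion initialises
the belief at the first observed location with zero drift and evaluates
each prediction against the pre-update belief.

The chain updates, per sweep: random-walk Metropolis steps for
(alpha_low, alpha_high) on the logit scale (ordering enforced by
rejection), beta on the logit scale, eta on the log scale with an
inverse-gamma-type prior on the variance (Gamma(0.01, 0.01) on the
precision); a conjugate Beta draw for phi given z; and a single-site
Gibbs sweep over every z_t with the forward pass recomputed from the
flipped trial onward (O(T) per site, T <= 90).

Proposal scales adapt toward ~40% acceptance during burn-in only.
"""

import math

import numpy as np
from numba import njit

_LOG_2PI = math.log(2.0 * math.pi)
_GAMMA_A = 0.01  # prior shape on the precision 1/eta
_GAMMA_B = 0.01  # prior rate on the precision 1/eta


@njit(cache=True)
def _seq_loglik_tail(B, r, z, T, t0, z_t0, V, Vd, a_lo, a_hi, beta, eta):
    """Log-likelihood of trials t0..T-1 starting from belief (V, Vd),
    with the indicator at t0 overridden by z_t0."""
    c = -0.5 * (_LOG_2PI + math.log(eta))
    ll = 0.0
    for s in range(t0, T):
        d = B[s] - V
        ll += c - 0.5 * d * d / eta
        pe = r[s] - V
        zs = z_t0 if s == t0 else z[s]
        a = a_hi if zs == 1 else a_lo
        Vd_new = Vd + beta * pe
        V = V + Vd + a * pe
        Vd = Vd_new
    return ll


@njit(cache=True)
def total_loglik(B, r, lengths, z, a_lo, a_hi, beta, eta):
    """Summed response log-likelihood over all participants."""
    ll = 0.0
    for i in range(B.shape[0]):
        T = lengths[i]
        ll += _seq_loglik_tail(B[i], r[i], z[i], T, 0, z[i, 0], r[i, 0], 0.0, a_lo, a_hi, beta, eta)
    return ll


@njit(cache=True)
def _gibbs_z_sweep(B, r, lengths, z, a_lo, a_hi, beta, eta, phi, inv_temp):
    """Single-site Gibbs update of every z_t, in trial order.

    ``inv_temp`` scales the likelihood contribution (< 1 only during
    burn-in annealing; 1 in the sampling phase)."""
    log_odds_prior = math.log(phi) - math.log(1.0 - phi)
    for i in range(B.shape[0]):
        T = lengths[i]
        V = r[i, 0]
        Vd = 0.0
        for t in range(T):
            ll0 = _seq_loglik_tail(B[i], r[i], z[i], T, t, 0, V, Vd, a_lo, a_hi, beta, eta)
            ll1 = _seq_loglik_tail(B[i], r[i], z[i], T, t, 1, V, Vd, a_lo, a_hi, beta, eta)
            x = log_odds_prior + inv_temp * (ll1 - ll0)
            if x >= 0:
                p1 = 1.0 / (1.0 + math.exp(-x))
            else:
                e = math.exp(x)
                p1 = e / (1.0 + e)
            z[i, t] = 1 if np.random.random() < p1 else 0
            pe = r[i, t] - V
            a = a_hi if z[i, t] == 1 else a_lo
            Vd_new = Vd + beta * pe
            V = V + Vd + a * pe
            Vd = Vd_new


@njit(cache=True)
def accumulate_trace(B, r, lengths, z, a_lo, a_hi, beta, V_sum, z_sum, alpha_sum):
    """Add the current draw's per-trial V, z and alpha* to running sums."""
    for i in range(B.shape[0]):
        T = lengths[i]
        V = r[i, 0]
        Vd = 0.0
        for t in range(T):
            a = a_hi if z[i, t] == 1 else a_lo
            V_sum[i, t] += V
            z_sum[i, t] += z[i, t]
            alpha_sum[i, t] += a
            pe = r[i, t] - V
            Vd_new = Vd + beta * pe
            V = V + Vd + a * pe
            Vd = Vd_new


@njit(cache=True)
def _logit(u):
    return math.log(u) - math.log(1.0 - u)


@njit(cache=True)
def _expit(x):
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _log_prior_eta(eta):
    # Gamma(a, b) prior on the precision 1/eta, as a density in eta.
    return -(_GAMMA_A + 1.0) * math.log(eta) - _GAMMA_B / eta


@njit(cache=True)
def run_chain(B, r, lengths, n_samples, n_burn, seed, init, scales, thin=3):
    """Run one MCMC chain.

    Parameters
    ----------
    init : array (5,) — starting values (a_lo, a_hi, phi, beta, eta)
    scales : array (4,) — initial RW scales for (a_lo, a_hi, beta, log eta)
    thin : int — full update sweeps per stored draw (improves mixing of
        the tightly coupled (alpha_high, z) pair at fixed storage)

    Returns
    -------
    draws : (n_samples, 5) parameter values per stored draw
    V_sum, z_sum, alpha_sum : per-trial posterior sums over kept draws
    n_kept : number of post-burn-in draws
    accept : (4,) post-burn-in acceptance rates
    """
    np.random.seed(seed)
    N, Tmax = B.shape
    a_lo, a_hi, phi, beta, eta = init[0], init[1], init[2], init[3], init[4]
    sc = scales.copy()
    z = np.zeros((N, Tmax), dtype=np.int8)
    n_valid = 0
    for i in range(N):
        n_valid += lengths[i]
        for t in range(lengths[i]):
            if np.random.random() < phi:
                z[i, t] = 1
    draws = np.empty((n_samples, 5))
    V_sum = np.zeros((N, Tmax))
    z_sum = np.zeros((N, Tmax))
    alpha_sum = np.zeros((N, Tmax))
    acc = np.zeros(4)
    prop = np.zeros(4)
    acc_win = np.zeros(4)
    prop_win = np.zeros(4)
    ll = total_loglik(B, r, lengths, z, a_lo, a_hi, beta, eta)
    n_kept = 0
    anneal_end = max(1, int(0.8 * n_burn))
    for it in range(n_samples):
        # Annealed burn-in: likelihood raised to inv_temp ramping 0.3 -> 1
        # over the first 80% of burn-in, so chains escape secondary modes
        # of the (z, alpha_high) configuration before sampling.
        if it < anneal_end:
            inv_temp = 0.3 + 0.7 * it / anneal_end
        else:
            inv_temp = 1.0
        for _sub in range(thin):
            # --- alpha_low, alpha_high, beta: logit-scale random walks ---
            for j in range(3):
                if j == 0:
                    cur = a_lo
                elif j == 1:
                    cur = a_hi
                else:
                    cur = beta
                x = _logit(cur)
                x_new = x + sc[j] * np.random.normal()
                new = _expit(x_new)
                if j == 0:
                    ok = new < a_hi
                elif j == 1:
                    ok = new > a_lo
                else:
                    ok = True
                prop[j] += 1.0
                prop_win[j] += 1.0
                if ok:
                    if j == 0:
                        ll_new = total_loglik(B, r, lengths, z, new, a_hi, beta, eta)
                    elif j == 1:
                        ll_new = total_loglik(B, r, lengths, z, a_lo, new, beta, eta)
                    else:
                        ll_new = total_loglik(B, r, lengths, z, a_lo, a_hi, new, eta)
                    # Uniform(0,1) prior; logit-scale Jacobian u(1-u)
                    log_acc = inv_temp * (ll_new - ll) + (
                        math.log(new * (1.0 - new)) - math.log(cur * (1.0 - cur))
                    )
                    if math.log(np.random.random()) < log_acc:
                        if j == 0:
                            a_lo = new
                        elif j == 1:
                            a_hi = new
                        else:
                            beta = new
                        ll = ll_new
                        acc[j] += 1.0
                        acc_win[j] += 1.0
            # --- eta: log-scale random walk ---
            x = math.log(eta)
            x_new = x + sc[3] * np.random.normal()
            eta_new = math.exp(x_new)
            ll_new = total_loglik(B, r, lengths, z, a_lo, a_hi, beta, eta_new)
            log_acc = (
                inv_temp * (ll_new - ll)
                + (_log_prior_eta(eta_new) - _log_prior_eta(eta))
                + (x_new - x)  # Jacobian of the log transform
            )
            prop[3] += 1.0
            prop_win[3] += 1.0
            if math.log(np.random.random()) < log_acc:
                eta = eta_new
                ll = ll_new
                acc[3] += 1.0
                acc_win[3] += 1.0
            # --- phi: conjugate Beta(1 + n1, 1 + n0) given z ---
            n1 = 0
            for i in range(N):
                for t in range(lengths[i]):
                    n1 += z[i, t]
            phi = np.random.beta(1.0 + n1, 1.0 + (n_valid - n1))
            if phi < 1e-6:
                phi = 1e-6
            elif phi > 1.0 - 1e-6:
                phi = 1.0 - 1e-6
            # --- z: single-site Gibbs sweep ---
            _gibbs_z_sweep(B, r, lengths, z, a_lo, a_hi, beta, eta, phi, inv_temp)
            ll = total_loglik(B, r, lengths, z, a_lo, a_hi, beta, eta)
        # --- burn-in adaptation toward ~40% acceptance ---
        if it < n_burn and (it + 1) % 50 == 0:
            for j in range(4):
                rate = acc_win[j] / max(prop_win[j], 1.0)
                if rate < 0.25:
                    sc[j] *= 0.8
                elif rate > 0.55:
                    sc[j] *= 1.25
                acc_win[j] = 0.0
                prop_win[j] = 0.0
            if it + 50 >= n_burn:
                # freeze counters entering the sampling phase
                acc[:] = 0.0
                prop[:] = 0.0
        draws[it, 0] = a_lo
        draws[it, 1] = a_hi
        draws[it, 2] = phi
        draws[it, 3] = beta
        draws[it, 4] = eta
        if it >= n_burn:
            accumulate_trace(B, r, lengths, z, a_lo, a_hi, beta, V_sum, z_sum, alpha_sum)
            n_kept += 1
    for j in range(4):
        acc[j] = acc[j] / max(prop[j], 1.0)
    return draws, V_sum, z_sum, alpha_sum, n_kept, acc
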
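"""Numba kernels for the adaptive Metropolis-within-Gibbs sampler.

The model state is ``(delta, mu0, z, mu[1..k], d[1..k])`` where ``z`` is an
unconstrained coordinate for the heterogeneity prior's native scale g(tau)
(log for positive supports, logit for bounded ones); the prior term below
includes the Jacobian of that reparameterisation.  Every scalar is updated
by a Gaussian random walk whose log proposal SD is adapted toward a 0.44
acceptance rate during burn-in only, so the post-burn-in chain is a fixed
Markov kernel.
"""

import numpy as np
from numba import njit

# Prior family codes (kept in sync with sparsemeta.priors).
GAMMA_PRECISION = 0
UNIFORM_LOG_TAU2 = 1
UNIFORM_TAU2 = 2
UNIFORM_TAU = 3
HALFNORMAL_TAU = 4
DUMOUCHEL = 5
HALFNORMAL_TAU2 = 6
FIXED = 7

_TAU_FLOOR = 1e-12


@njit(cache=True, inline="always")
def _log_sigmoid(x):
    if x >= 0.0:
        return -np.log1p(np.exp(-x))
    return x - np.log1p(np.exp(x))


@njit(cache=True, inline="always")
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _tau_and_logprior(code, p0, p1, z):
    """tau(z) and log prior density in z (native density + Jacobian)."""
    if code == GAMMA_PRECISION:
        v = np.exp(z)
        tau = 1.0 / np.sqrt(v)
        return tau, p0 * z - p1 * v
    if code == UNIFORM_LOG_TAU2:
        x = p0 + (p1 - p0) * _sigmoid(z)
        return np.exp(0.5 * x), _log_sigmoid(z) + _log_sigmoid(-z)
    if code == UNIFORM_TAU2:
        t2 = p0 + (p1 - p0) * _sigmoid(z)
        return np.sqrt(t2), _log_sigmoid(z) + _log_sigmoid(-z)
    if code == UNIFORM_TAU:
        tau = p0 + (p1 - p0) * _sigmoid(z)
        return tau, _log_sigmoid(z) + _log_sigmoid(-z)
    if code == HALFNORMAL_TAU:
        tau = np.exp(z)
        return tau, -tau * tau / (2.0 * p0) + z
    if code == DUMOUCHEL:
        u = _sigmoid(z)
        tau = p0 * (1.0 - u) / u
        return tau, _log_sigmoid(z) + _log_sigmoid(-z)
    if code == HALFNORMAL_TAU2:
        t2 = np.exp(z)
        return np.sqrt(t2), -t2 * t2 / (2.0 * p0) + z
    # FIXED
    return p0, 0.0


@njit(cache=True, inline="always")
def _binom_loglik(r_t, m_t, r_c, m_c, mu, d):
    """Binomial log likelihood of one trial; m_* are non-event counts."""
    eta_t = mu + 0.5 * d
    eta_c = mu - 0.5 * d
    return (
        r_t * _log_sigmoid(eta_t)
        + m_t * _log_sigmoid(-eta_t)
        + r_c * _log_sigmoid(eta_c)
        + m_c * _log_sigmoid(-eta_c)
    )


@njit(cache=True, inline="always")
def _normal_lp(x, mean, var):
    return -0.5 * np.log(var) - (x - mean) * (x - mean) / (2.0 * var)


@njit(cache=True)
def run_chain(
    r_t,
    m_t,
    r_c,
    m_c,
    prior_code,
    prior_p0,
    prior_p1,
    delta_var,
    mu_var,
    mu0_var,
    use_likelihood,
    n_iter,
    burn_in,
    thin,
    seed,
    delta0,
    mu00,
    z0,
    mu_init,
    d_init,
):
    """One MCMC chain; returns draws of shape (n_keep, 3 + 2k).

    Column order: delta, tau, mu0, mu_1..mu_k, d_1..d_k.
    """
    np.random.seed(seed)
    k = r_t.shape[0]
    n_par = 3 + 2 * k  # update blocks: delta, mu0, z, mu_i, d_i

    delta = delta0
    mu0 = mu00
    z = z0
    mu = mu_init.copy()
    d = d_init.copy()

    tau, prior_lp = _tau_and_logprior(prior_code, prior_p0, prior_p1, z)
    if tau < _TAU_FLOOR:
        tau = _TAU_FLOOR
    tau2 = tau * tau

    ls = np.zeros(n_par)  # log proposal SDs
    for j in range(n_par):
        ls[j] = np.log(0.5)

    n_keep = (n_iter - burn_in + thin - 1) // thin
    out = np.empty((n_keep, 3 + 2 * k))
    kept = 0
    target = 0.44

    binlik = np.empty(k)
    for i in range(k):
        binlik[i] = _binom_loglik(r_t[i], m_t[i], r_c[i], m_c[i], mu[i], d[i])

    for it in range(n_iter):
        adapt = it < burn_in
        step = (it + 1.0) ** -0.6

        # -- delta -----------------------------------------------------
        lp_cur = -delta * delta / (2.0 * delta_var)
        for i in range(k):
            lp_cur += _normal_lp(d[i], delta, tau2)
        prop = delta + np.exp(ls[0]) * np.random.normal()
        lp_prop = -prop * prop / (2.0 * delta_var)
        for i in range(k):
            lp_prop += _normal_lp(d[i], prop, tau2)
        acc = 0.0
        if np.log(np.random.random()) < lp_prop - lp_cur:
            delta = prop
            acc = 1.0
        if adapt:
            ls[0] = min(max(ls[0] + step * (acc - target), -10.0), 5.0)

        # -- mu0 -------------------------------------------------------
        lp_cur = -mu0 * mu0 / (2.0 * mu0_var)
        for i in range(k):
            lp_cur += _normal_lp(mu[i], mu0, mu_var)
        prop = mu0 + np.exp(ls[1]) * np.random.normal()
        lp_prop = -prop * prop / (2.0 * mu0_var)
        for i in range(k):
            lp_prop += _normal_lp(mu[i], prop, mu_var)
        acc = 0.0
        if np.log(np.random.random()) < lp_prop - lp_cur:
            mu0 = prop
            acc = 1.0
        if adapt:
            ls[1] = min(max(ls[1] + step * (acc - target), -10.0), 5.0)

        # -- z (heterogeneity) ----------------------------------------
        if prior_code != FIXED:
            lp_cur = prior_lp
            for i in range(k):
                lp_cur += _normal_lp(d[i], delta, tau2)
            zp = z + np.exp(ls[2]) * np.random.normal()
            tau_p, plp_p = _tau_and_logprior(prior_code, prior_p0, prior_p1, zp)
            if tau_p < _TAU_FLOOR:
                tau_p = _TAU_FLOOR
            tau2_p = tau_p * tau_p
            lp_prop = plp_p
            for i in range(k):
                lp_prop += _normal_lp(d[i], delta, tau2_p)
            acc = 0.0
            if np.log(np.random.random()) < lp_prop - lp_cur:
                z = zp
                tau = tau_p
                tau2 = tau2_p
                prior_lp = plp_p
                acc = 1.0
            if adapt:
                ls[2] = min(max(ls[2] + step * (acc - target), -10.0), 5.0)

        # -- mu_i ------------------------------------------------------
        for i in range(k):
            j = 3 + i
            lp_cur = _normal_lp(mu[i], mu0, mu_var) + use_likelihood * binlik[i]
            prop = mu[i] + np.exp(ls[j]) * np.random.normal()
            bl_prop = _binom_loglik(r_t[i], m_t[i], r_c[i], m_c[i], prop, d[i])
            lp_prop = _normal_lp(prop, mu0, mu_var) + use_likelihood * bl_prop
            acc = 0.0
            if np.log(np.random.random()) < lp_prop - lp_cur:
                mu[i] = prop
                binlik[i] = bl_prop
                acc = 1.0
            if adapt:
                ls[j] = min(max(ls[j] + step * (acc - target), -10.0), 5.0)

        # -- d_i -------------------------------------------------------
        for i in range(k):
            j = 3 + k + i
            lp_cur = _normal_lp(d[i], delta, tau2) + use_likelihood * binlik[i]
            prop = d[i] + np.exp(ls[j]) * np.random.normal()
            bl_prop = _binom_loglik(r_t[i], m_t[i], r_c[i], m_c[i], mu[i], prop)
            lp_prop = _normal_lp(prop, delta, tau2) + use_likelihood * bl_prop
            acc = 0.0
            if np.log(np.random.random()) < lp_prop - lp_cur:
                d[i] = prop
                binlik[i] = bl_prop
                acc = 1.0
            if adapt:
                ls[j] = min(max(ls[j] + step * (acc - target), -10.0), 5.0)

        # -- store -----------------------------------------------------
        if it >= burn_in and (it - burn_in) % thin == 0:
            out[kept, 0] = delta
            out[kept, 1] = tau
            out[kept, 2] = mu0
            for i in range(k):
                out[kept, 3 + i] = mu[i]
                out[kept, 3 + k + i] = d[i]
            kept += 1

    return out[:kept]
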
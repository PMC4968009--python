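"""Independent reference computations used only by the test suite.

Everything here is deliberately naive — dense covariance matrices,
O(N^2) sums, brute-force minimization — so it shares no code path with
the package implementations it certifies.
"""

import numpy as np

HOUR = 3600.0
DAY = 86400.0


def dense_gaussian_loglik(x, cov, profile_mean=False):
    """Multivariate-normal loglik per dimension with shared covariance.

    With ``profile_mean`` the GLS mean estimate is substituted per
    dimension (matching profiled-mean state-space likelihoods).
    """
    x = np.atleast_2d(x)
    if x.shape[0] != cov.shape[0]:
        x = x.T
    n = cov.shape[0]
    inv = np.linalg.inv(cov)
    _, logdet = np.linalg.slogdet(cov)
    one = np.ones(n)
    ll = 0.0
    for k in range(x.shape[1]):
        v = x[:, k]
        if profile_mean:
            v = v - one @ inv @ v / (one @ inv @ one)
        ll += -0.5 * (n * np.log(2 * np.pi) + logdet + v @ inv @ v)
    return ll


def ou_cov(times, sigma, tau):
    d = np.abs(times[:, None] - times[None, :])
    return sigma * np.exp(-d / tau)


def bm_cond_cov(times, sigma):
    """Covariance of x(t_2..n) - x(t_1) for Brownian motion."""
    tt = times - times[0]
    return sigma * np.minimum(tt[1:, None], tt[None, 1:])


def iou_cond_cov(times, sigma, tau_v):
    """Covariance of x - x(t_1) for integrated OU with stationary velocity."""
    eta2 = sigma / (2.0 * tau_v)
    tt = times - times[0]
    m = np.minimum(tt[1:, None], tt[None, 1:])
    d = np.abs(tt[1:, None] - tt[None, 1:])
    return eta2 * tau_v * (
        2.0 * m - tau_v * (1.0 - np.exp(-m / tau_v)) * (1.0 + np.exp(-d / tau_v))
    )


def ouf_cov(times, sigma, tau_p, tau_v):
    d = np.abs(times[:, None] - times[None, :])
    rho = (tau_p * np.exp(-d / tau_p) - tau_v * np.exp(-d / tau_v)) / (
        tau_p - tau_v
    )
    return sigma * rho


def naive_dft_power(times, values, freqs):
    """O(N F) direct summation of the DFT periodogram (mean removed)."""
    values = np.atleast_2d(values)
    if values.shape[0] != times.size:
        values = values.T
    x = values - values.mean(axis=0)
    n = times.size
    out = np.empty((freqs.size, x.shape[1]))
    for i, f in enumerate(freqs):
        phase = np.exp(-2j * np.pi * f * times)
        out[i] = np.abs(phase @ x) ** 2 / n
    return out


def lsq_power_bruteforce(times, values, weights, freq, n_grid=41, n_refine=6):
    """LSP at one frequency by direct cost minimization over (Re A, Im A).

    Grid search plus iterative refinement around the best cell; completely
    independent of the closed-form normal-equation solve.
    """
    w = np.asarray(weights, float)
    x = np.asarray(values, float)
    x = x - (w * x).sum() / w.sum()
    theta = 2 * np.pi * freq * np.asarray(times)
    c, s = np.cos(theta), np.sin(theta)

    def cost(a, b):
        model = a * c + b * s  # A = (a - i b)/2
        return (w * (x - model) ** 2).sum()

    scale = 4 * np.sqrt((w * x**2).sum() / w.sum()) + 1e-9
    a0 = b0 = 0.0
    half = scale
    best = cost(a0, b0)
    for _ in range(n_refine):
        aa = np.linspace(a0 - half, a0 + half, n_grid)
        bb = np.linspace(b0 - half, b0 + half, n_grid)
        grid_a, grid_b = np.meshgrid(aa, bb)
        costs = np.array(
            [cost(a, b) for a, b in zip(grid_a.ravel(), grid_b.ravel())]
        )
        i = np.argmin(costs)
        a0, b0 = grid_a.ravel()[i], grid_b.ravel()[i]
        best = costs[i]
        half = 2 * half / (n_grid - 1) * 2
    total = (w * x**2).sum()
    return 0.5 * (total - best)


def haversine_m(lon1, lat1, lon2, lat2):
    r = 6_371_008.8
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    dp = p2 - p1
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(a))
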
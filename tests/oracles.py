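"""Independent reference estimators used only to cross-check statescan.

The MBAR-style estimator here works on the raw (unbinned) samples and is
deliberately implemented without reference to the production WHAM solver:
window free energies f_i solve the self-consistent equations

    exp(-f_i/RT) = sum_n exp(-w_i(x_n)/RT) / sum_j N_j exp((f_j - w_j(x_n))/RT)

over all pooled samples x_n, with harmonic biases w_i.  Binning is the only
difference from WHAM, so converged window free energies must agree closely.
"""

import numpy as np
from scipy.special import logsumexp

KJ_PER_KCAL = 4.184
R_KCAL = 0.0019872


def mbar_window_free_energies(dataset, tol=1e-12, max_iter=20000):
    """Window free energies (kcal/mol, f[0]=0) from raw umbrella samples."""
    temps = {w.temperature for w in dataset.windows}
    assert len(temps) == 1
    rt = R_KCAL * temps.pop()
    x = np.concatenate([w.samples for w in dataset.windows])
    n_j = np.array([len(w.samples) for w in dataset.windows], dtype=float)
    centers = np.array([w.center for w in dataset.windows])
    k_kcal = np.array([w.force_const for w in dataset.windows]) / KJ_PER_KCAL
    # (windows, samples) reduced bias energies in units of RT
    u = 0.5 * k_kcal[:, None] * (x[None, :] - centers[:, None]) ** 2 / rt

    f = np.zeros(len(n_j))  # in units of RT
    for _ in range(max_iter):
        log_denom = logsumexp(np.log(n_j)[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return f * rt
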
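"""Vectorized binomial-family IRLS for many single-covariate fits.

Fits ``logit(E[y]) = a + b*x`` independently for each row of ``y`` by
iteratively reweighted least squares, following the numerical conventions
of R's ``glm(..., family=binomial)``: proportion responses with prior
weights, starting values ``mu0 = (w*y + 0.5)/(w + 1)``, the relative
deviance-change stopping rule with tolerance 1e-8, and an iteration cap of
25.  This matters for absorbed allele-frequency trajectories (y hitting 0
or 1), where the quasi-binomial deviance still has a finite, well-defined
optimum that per-locus fits must locate quickly: a selection scan fits
10^4-10^6 loci, far too many for one model object per locus.
"""

from __future__ import annotations

import numpy as np

_MU_EPS = 1e-10


def _deviance(y, mu, w):
    # binomial deviance valid for fractional y in [0,1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return 2.0 * np.sum(w * (t1 + t2), axis=-1)


def logistic_slope_many(y: np.ndarray, x: np.ndarray,
                        weights: np.ndarray | None = None,
                        *, maxit: int = 25, tol: float = 1e-8):
    """Per-row logistic-regression slopes.

    Parameters
    ----------
    y
        (loci, timepoints) proportions in [0, 1].
    x
        (timepoints,) covariate (generation numbers).
    weights
        Binomial prior weights (sample sizes); scalar 1 per observation
        when ``None`` (unweighted proportions, the R ``glm`` default call).

    Returns
    -------
    slopes : (loci,) ndarray
        Fitted per-generation log-odds slopes.
    converged : (loci,) bool ndarray
        False where the iteration cap was reached (separated data).
    """
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    x = np.asarray(x, dtype=np.float64)
    L, T = y.shape
    if weights is None:
        w = np.ones((1, T))
    else:
        w = np.atleast_2d(np.asarray(weights, dtype=np.float64))
        w = np.broadcast_to(w, (L, T)) if w.shape[0] != L else w

    mu = (w * y + 0.5) / (w + 1.0)
    eta = np.log(mu / (1 - mu))
    a = np.zeros(L)
    b = np.zeros(L)
    dev = _deviance(y, mu, w)
    active = np.ones(L, dtype=bool)
    converged = np.zeros(L, dtype=bool)

    for _ in range(maxit):
        if not active.any():
            break
        ya, wa, etaa, mua = y[active], np.broadcast_to(w, y.shape)[active], \
            eta[active], mu[active]
        var = mua * (1 - mua)
        z = etaa + (ya - mua) / var
        ww = wa * var
        # closed-form 2x2 weighted least squares of z on (1, x)
        Sw = ww.sum(axis=1)
        Swx = (ww * x).sum(axis=1)
        Swxx = (ww * x * x).sum(axis=1)
        Swz = (ww * z).sum(axis=1)
        Swxz = (ww * x * z).sum(axis=1)
        det = Sw * Swxx - Swx * Swx
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        b_new = (Sw * Swxz - Swx * Swz) / det
        a_new = (Swz - b_new * Swx) / Sw
        eta_new = a_new[:, None] + b_new[:, None] * x
        mu_new = 1.0 / (1.0 + np.exp(-eta_new))
        mu_new = np.clip(mu_new, _MU_EPS, 1 - _MU_EPS)
        dev_new = _deviance(ya, mu_new, wa)

        done = (np.abs(dev_new - dev[active]) / (np.abs(dev_new) + 0.1) < tol)
        done |= ~np.isfinite(dev_new) | ~np.isfinite(b_new)
        idx = np.flatnonzero(active)
        keep = np.isfinite(b_new)
        a[idx[keep]] = a_new[keep]
        b[idx[keep]] = b_new[keep]
        eta[idx], mu[idx], dev[idx] = eta_new, mu_new, dev_new
        converged[idx[done & keep]] = True
        active[idx[done | ~keep]] = False

    return b, converged
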
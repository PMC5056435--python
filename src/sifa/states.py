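"""Discrete transmembrane states from pooled intensity distributions.

The peptide visits a handful of preferred heights in the bilayer; through
the quenching law each height maps to an intensity level, so the pooled
intensity distribution of many traces is a finite Gaussian mixture whose
component count is itself the scientific question (the study system
resolves five levels on a lifted bilayer, two plus a blind background on an
unlifted one).

Pipeline: pool live frames into an intensity sample and histogram, fit
Gaussian mixtures with a free component number by seeded multi-restart
maximum likelihood and pick N by BIC, convert fitted peak intensities to
heights through the inverse quench law with first-order error propagation,
then label every frame with its maximum-posterior component. Frames
indistinguishable from the camera background are flagged "blind": below
roughly 2 nm the quenching is total and no height can be reported, only the
bound.

Two fitting modes coexist. The plain mode ("gaussian") is a seeded
multi-restart Gaussian-mixture MLE on the pooled intensity sample. The
physically specified mode ("physical", the pipeline default) recognises
that intensities are NOT Gaussian per state — each state's intensity
density is the push-forward of a Gaussian height profile through the curved
quenching law, convolved with the camera noise — and fits exactly that
family by binned-likelihood EM, parameterised directly in heights. The
distinction matters: near saturation the push-forward is strongly skewed,
so Gaussian components make BIC overcount states, while the physical family
is correctly specified and BIC behaves. A histogram least-squares mode is
kept behind a flag for fidelity to the classic visual procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

from .quench import QuenchModel, invert_intensity, relative_intensity
from .synthetic import IntensityTrace, NoiseModel

__all__ = [
    "IntensityPDF",
    "MixtureFit",
    "build_intensity_pdf",
    "fit_mixture",
    "peaks_to_positions",
    "assign_states",
    "trace_to_positions",
    "BLIND_BOUND_NM",
]

# Below this height the dye is quenched into the camera background and no
# number can be reported, only the bound.
BLIND_BOUND_NM = 2.0


@dataclass
class IntensityPDF:
    """Pooled intensity sample with its normalised histogram."""

    sample: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray
    trace_ids: tuple = ()

    @property
    def n_points(self) -> int:
        return len(self.sample)


@dataclass
class MixtureFit:
    """A selected Gaussian mixture over pooled intensities.

    ``scores`` maps every tried component count to its BIC so the
    N-selection evidence (including near-ties) stays inspectable.
    Components are always sorted by ascending mean.
    """

    n: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    scores: dict = field(default_factory=dict)
    log_likelihood: float = np.nan
    background_weight: float = 0.0  # mass excluded as blind/background
    positions_nm: Optional[np.ndarray] = None
    position_sds_nm: Optional[np.ndarray] = None  # state spreads, nm
    position_ses_nm: Optional[np.ndarray] = None  # standard errors of the estimates
    saturated: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        out = {
            "n": int(self.n),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "scores": {str(k): float(v) for k, v in self.scores.items()},
            "log_likelihood": float(self.log_likelihood),
            "background_weight": float(self.background_weight),
        }
        if self.positions_nm is not None:
            out["positions_nm"] = self.positions_nm.tolist()
            out["position_sds_nm"] = self.position_sds_nm.tolist()
            out["saturated"] = [bool(s) for s in self.saturated]
        if self.position_ses_nm is not None:
            out["position_ses_nm"] = self.position_ses_nm.tolist()
        return out


def build_intensity_pdf(
    traces: Sequence[IntensityTrace], bins="auto", min_points: int = 100
) -> IntensityPDF:
    """Pool live (pre-bleach) frames of many traces into one sample.

    The histogram uses uniform bins (numpy's "auto" rule by default) and is
    normalised to integrate to one; the raw pooled sample is kept alongside
    because the mixture fit works on it directly.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    parts = [tr.live_intensity() for tr in traces]
    sample = np.concatenate(parts)
    if len(sample) < min_points:
        raise ValueError(f"only {len(sample)} pooled points, need >= {min_points}")
    density, edges = np.histogram(sample, bins=bins, density=True)
    return IntensityPDF(
        sample=sample,
        bin_edges=edges,
        density=density,
        trace_ids=tuple(tr.trace_id for tr in traces),
    )


def _sorted_gmm(gmm: GaussianMixture) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = gmm.means_.ravel()
    order = np.argsort(means)
    weights = gmm.weights_[order]
    sds = np.sqrt(gmm.covariances_.ravel())[order]
    return weights, means[order], sds


def fit_mixture(
    pdf: IntensityPDF,
    n_range: Sequence[int] = range(1, 8),
    seed: int = 0,
    n_init: int = 5,
    background: Optional[tuple[float, float]] = None,
    histogram_least_squares: bool = False,
    method: str = "gaussian",
    quench: Optional[QuenchModel] = None,
    noise: Optional[NoiseModel] = None,
) -> MixtureFit:
    """Free-N mixture fit with BIC model selection.

    method "gaussian" (default): for each candidate N a Gaussian-mixture EM
    fit with ``n_init`` seeded restarts is run on the pooled sample; the N
    with the lowest BIC wins. method "physical": components are Gaussian in
    HEIGHT, not intensity — each component's intensity density is the
    push-forward of Normal(position, position_sd) through the quenching law
    of ``quench`` convolved with the camera noise of ``noise``; the fit (a
    binned-likelihood EM, see :func:`_fit_mixture_physical`) directly yields
    heights, and intensity-domain means/sds are attached by linearisation.

    If ``background`` (mean, sd) is given, points below mean + 2*sd are
    treated as the blind background, excluded from the mixture and reported
    as ``background_weight`` — the mixture then describes only the
    resolvable states. ``histogram_least_squares`` switches to a
    least-squares fit of the binned density at each N (selection then uses
    the residual-based BIC analogue).
    """
    n_range = list(n_range)
    if not n_range:
        raise ValueError("n_range must be non-empty")
    sample = pdf.sample
    bg_weight = 0.0
    if background is not None:
        bg_mean, bg_sd = background
        keep = sample >= bg_mean + 2.0 * bg_sd
        bg_weight = 1.0 - keep.mean()
        sample = sample[keep]
        if len(sample) < 50:
            raise ValueError("almost all points fall in the blind background")

    if histogram_least_squares:
        return _fit_mixture_histogram(pdf, n_range, bg_weight)
    if method == "physical":
        if quench is None or noise is None:
            raise ValueError("physical mode needs the quench and noise models")
        # the physical mode absorbs blind mass with a fixed background
        # component on the unfiltered sample instead of truncating
        return _fit_mixture_physical(
            pdf.sample, n_range, quench, noise, seed=seed, n_init=n_init,
            background_component=background,
        )
    if method != "gaussian":
        raise ValueError(f"unknown method {method!r}")

    x = sample.reshape(-1, 1)
    scores: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for n in n_range:
        gmm = GaussianMixture(
            n_components=n,
            covariance_type="diag",
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-6 * float(np.var(sample)),
            max_iter=1000,
            tol=1e-5,
        )
        gmm.fit(x)
        if not gmm.converged_:
            continue
        scores[n] = float(gmm.bic(x))
        fits[n] = gmm
    if not fits:
        raise RuntimeError("no mixture fit converged over the requested range")
    best_n = min(scores, key=scores.get)
    weights, means, sds = _sorted_gmm(fits[best_n])
    return MixtureFit(
        n=best_n,
        weights=weights,
        means=means,
        sds=sds,
        scores=scores,
        log_likelihood=float(fits[best_n].score(x) * len(sample)),
        background_weight=float(bg_weight),
    )


def _mixture_density(x, *params):
    n = len(params) // 3
    w = np.abs(params[:n])
    mu = np.asarray(params[n : 2 * n])
    sd = np.abs(params[2 * n :])
    w = w / w.sum()
    out = np.zeros_like(np.asarray(x, float))
    for k in range(n):
        out += w[k] / (np.sqrt(2 * np.pi) * sd[k]) * np.exp(-0.5 * ((x - mu[k]) / sd[k]) ** 2)
    return out


def _fit_mixture_histogram(pdf: IntensityPDF, n_range, bg_weight) -> MixtureFit:
    centers = 0.5 * (pdf.bin_edges[:-1] + pdf.bin_edges[1:])
    lo, hi = pdf.sample.min(), pdf.sample.max()
    scores: dict[int, float] = {}
    best = None
    m = len(centers)
    for n in n_range:
        mu0 = np.linspace(lo, hi, n + 2)[1:-1]
        p0 = np.concatenate([np.full(n, 1.0 / n), mu0, np.full(n, (hi - lo) / (4 * n))])
        try:
            popt, _ = curve_fit(_mixture_density, centers, pdf.density, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        resid = pdf.density - _mixture_density(centers, *popt)
        rss = float(np.sum(resid**2))
        scores[n] = m * np.log(rss / m) + (3 * n - 1) * np.log(m)
        if best is None or scores[n] < scores[best[0]]:
            best = (n, popt)
    if best is None:
        raise RuntimeError("histogram least-squares fit failed for every N")
    n, popt = best
    w = np.abs(popt[:n])
    w = w / w.sum()
    mu = np.asarray(popt[n : 2 * n])
    sd = np.abs(popt[2 * n :])
    order = np.argsort(mu)
    return MixtureFit(
        n=n, weights=w[order], means=mu[order], sds=sd[order], scores=scores,
        background_weight=float(bg_weight),
    )


# --------------------------------------------------------------------------
# physically specified mixture (components Gaussian in height)

class _PushForwardFamily:
    """Intensity density of a Gaussian height profile seen through the
    quenching law plus camera noise, evaluated on a bin grid.

    p(x | mu, s) = Int phi(h; mu, s) * phi(x; g(h), sigma(h)) dh with
    g(h) = i0 * I/I0(h) + background_mean and
    sigma(h)^2 = background_sd^2 + (gain * i0 * I/I0(h))^2.

    The integral runs over a fine fixed height grid (trapezoid). Quadrature
    over the HEIGHT Gaussian instead would fail here: where the curve is
    steep the noise kernel is only ~0.1 nm wide in height units, far below
    any practical node spacing, so the grid must resolve the kernel, not
    the component.
    """

    def __init__(self, centers: np.ndarray, quench: QuenchModel, noise: NoiseModel,
                 grid_step: float = 0.01):
        h_hi = max(12.0, 1.3 * invert_intensity(0.99, quench))
        self.h_grid = np.arange(0.3, h_hi, grid_step)
        self.dh = grid_step
        r = relative_intensity(self.h_grid, quench)
        g = quench.i0 * r + noise.background_mean
        sig = np.sqrt(noise.background_sd**2 + (noise.gain_sd_fraction * quench.i0 * r) ** 2)
        sig = np.maximum(sig, 1e-6)
        self.kernel = np.exp(-0.5 * ((centers[:, None] - g[None, :]) / sig[None, :]) ** 2) / (
            np.sqrt(2 * np.pi) * sig[None, :]
        )

    def component_pdf(self, mu: float, s: float) -> np.ndarray:
        w = np.exp(-0.5 * ((self.h_grid - mu) / s) ** 2) / (np.sqrt(2 * np.pi) * s)
        return self.kernel @ w * self.dh


def _fit_mixture_physical(
    sample: np.ndarray,
    n_range: Sequence[int],
    quench: QuenchModel,
    noise: NoiseModel,
    seed: int = 0,
    n_init: int = 2,
    background_component: Optional[tuple[float, float]] = None,
    bins: int = 256,
    max_em_iter: int = 120,
    em_tol: float = 0.01,
) -> MixtureFit:
    """Binned-likelihood EM over the push-forward family, BIC over N.

    E-step: standard responsibilities on bin centres weighted by counts.
    M-step: weights in closed form; each component's (height, height sd) by
    a short Nelder-Mead on its weighted log-likelihood, warm-started at the
    current value. Initial heights are seeded perturbations of the
    quantiles of the naively inverted sample.

    ``background_component`` (mean, sd of the camera background) adds one
    blind component: a push-forward component whose height is constrained
    below the detectability limit (where the emitted signal falls under two
    background sds). The blind-region mass is then modelled instead of
    truncated, which keeps the free components unbiased when traces dip
    below ~2 nm. Heights inside the blind zone are unidentifiable (the
    density there is flat), so only the blind component's weight is
    reported, as ``background_weight``.
    """
    from scipy.optimize import minimize

    counts, edges = np.histogram(sample, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = counts > 0
    centers, counts = centers[mask], counts[mask].astype(float)
    n_tot = counts.sum()
    family = _PushForwardFamily(centers, quench, noise)
    h_lo, h_hi = family.h_grid[0], family.h_grid[-1]

    has_blind = background_component is not None
    if has_blind:
        bg_mean, bg_sd = background_component
        r_blind = float(np.clip(2.0 * bg_sd / quench.i0, 1e-4, 0.5))
        blind_cap = float(invert_intensity(r_blind, quench))  # detectability limit
        bright = sample[sample >= bg_mean + 2.0 * bg_sd]
        if len(bright) < 50:
            raise ValueError("almost no points above the blind background")
    else:
        bright = sample
    # naive per-point inversion only to place starting heights
    r = np.clip((bright - noise.background_mean) / quench.i0, 1e-4, 1 - 1e-4)
    h_conv = np.clip(invert_intensity(r, quench), h_lo, h_hi)

    rng = np.random.default_rng(seed)

    def em(k: int, mu0: np.ndarray):
        n_comp = k + (1 if has_blind else 0)
        wts = np.full(n_comp, 1.0 / n_comp)
        mus = mu0.astype(float).copy()
        sds = np.full(k, 0.4)
        if has_blind:  # blind component is the last one, height-capped
            mus = np.append(mus, 0.7 * blind_cap)
            sds = np.append(sds, 0.15)
        prev = np.inf
        nll = np.inf
        for _ in range(max_em_iter):
            pk = np.stack([family.component_pdf(m, s) for m, s in zip(mus, sds)], axis=1)
            dens = np.maximum(pk @ wts, 1e-300)
            resp = pk * wts[None, :] / dens[:, None]
            wts = (counts[:, None] * resp).sum(axis=0) / n_tot
            for j in range(n_comp):
                ck = counts * resp[:, j]
                blind_j = has_blind and j == n_comp - 1
                lo = h_lo + 0.05 if blind_j else h_lo + 0.1
                hi = blind_cap if blind_j else h_hi - 0.1
                s_hi = 0.5 if blind_j else 4.0

                def neg(theta):
                    m, ls = theta
                    s = np.exp(ls)
                    if not (lo < m < hi) or not (0.02 < s < s_hi):
                        return 1e12
                    p = family.component_pdf(m, s)
                    return -float(np.sum(ck * np.log(np.maximum(p, 1e-300))))

                res = minimize(
                    neg, [mus[j], np.log(sds[j])], method="Nelder-Mead",
                    options={"maxiter": 60, "xatol": 1e-4, "fatol": 1e-6},
                )
                mus[j], sds[j] = res.x[0], float(np.exp(res.x[1]))
            pk = np.stack([family.component_pdf(m, s) for m, s in zip(mus, sds)], axis=1)
            dens = np.maximum(pk @ wts, 1e-300)
            nll = -float(np.sum(counts * np.log(dens)))
            if prev - nll < em_tol:
                break
            prev = nll
        return wts, mus, sds, nll

    def polish(wts, mus, sds, nll_em):
        """Simplex refinement over all free parameters at once: EM crawls on
        strongly overlapping components, so finish the climb jointly and
        keep the result only if the likelihood actually improves."""
        n_comp = len(mus)
        mu_lo = np.full(n_comp, h_lo + 0.1)
        mu_hi = np.full(n_comp, h_hi - 0.1)
        s_hi = np.full(n_comp, 4.0)
        if has_blind:
            mu_lo[-1], mu_hi[-1], s_hi[-1] = h_lo + 0.05, blind_cap, 0.5
        lg = np.log(np.maximum(wts, 1e-12))
        theta0 = np.concatenate([lg[:-1] - lg[-1], mus, np.log(sds)])

        def neg(theta):
            lgf = np.concatenate([theta[: n_comp - 1], [0.0]])
            w = np.exp(lgf - lgf.max())
            w = w / w.sum()
            m = theta[n_comp - 1 : 2 * n_comp - 1]
            s = np.exp(theta[2 * n_comp - 1 :])
            if np.any(m < mu_lo) or np.any(m > mu_hi) or np.any(s < 0.02) or np.any(s > s_hi):
                return 1e12
            pk = np.stack([family.component_pdf(mi, si) for mi, si in zip(m, s)], axis=1)
            return -float(np.sum(counts * np.log(np.maximum(pk @ w, 1e-300))))

        res = minimize(
            neg, theta0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-7},
        )
        if not np.isfinite(res.fun) or res.fun >= nll_em:
            return wts, mus, sds, nll_em
        lgf = np.concatenate([res.x[: n_comp - 1], [0.0]])
        w = np.exp(lgf - lgf.max())
        w = w / w.sum()
        m = res.x[n_comp - 1 : 2 * n_comp - 1].copy()
        s = np.exp(res.x[2 * n_comp - 1 :])
        return w, m, s, float(res.fun)

    scores: dict[int, float] = {}
    fits: dict[int, tuple] = {}
    for k in n_range:
        qs = np.quantile(h_conv, (np.arange(k) + 0.5) / k)
        best = None
        for trial in range(max(n_init, 1)):
            mu0 = qs if trial == 0 else np.sort(qs * (1 + 0.05 * rng.standard_normal(k)))
            out = em(k, np.asarray(mu0))
            if best is None or out[3] < best[3]:
                best = out
        if best is None:
            continue
        best = polish(*best)
        n_params = 3 * k - 1 + (3 if has_blind else 0)
        scores[k] = 2.0 * best[3] + n_params * np.log(n_tot)
        fits[k] = best
    if not fits:
        raise RuntimeError("physical mixture fit failed for every N")

    best_n = min(scores, key=scores.get)
    wts_all, mus_all, sds_all, nll = fits[best_n]
    pos_ses = _physical_position_ses(family, counts, wts_all, mus_all, sds_all)
    bg_weight = 0.0
    if has_blind:
        bg_weight = float(wts_all[-1])
        wts, mus, sds = wts_all[:-1], mus_all[:-1], sds_all[:-1]
        pos_ses = pos_ses[: len(mus)]
        wts = wts / wts.sum()
    else:
        wts, mus, sds = wts_all, mus_all, sds_all
    order = np.argsort(mus)
    wts, mus, sds, pos_ses = wts[order], mus[order], sds[order], pos_ses[order]

    # intensity-domain component parameters by linearisation around mu
    r_mu = relative_intensity(mus, quench)
    means_int = quench.i0 * r_mu + noise.background_mean
    dgdh = quench.i0 * 4.0 * mus**3 * quench.d0**4 / (mus**4 + quench.d0**4) ** 2
    sig_noise = np.sqrt(
        noise.background_sd**2 + (noise.gain_sd_fraction * quench.i0 * r_mu) ** 2
    )
    sds_int = np.sqrt((dgdh * sds) ** 2 + sig_noise**2)

    return MixtureFit(
        n=best_n,
        weights=wts,
        means=means_int,
        sds=sds_int,
        scores=scores,
        log_likelihood=-nll,
        background_weight=float(bg_weight),
        positions_nm=mus,
        position_sds_nm=sds,
        position_ses_nm=pos_ses,
        saturated=mus > 1.7 * quench.d0,
    )


def _physical_position_ses(family, counts, wts, mus, sds) -> np.ndarray:
    """Observed-information standard errors of the fitted heights.

    Numerical Hessian of the binned negative log-likelihood over all free
    parameters (weight logits, heights, log height-sds) at the optimum,
    inverted; returns the height block's square-rooted diagonal. Falls back
    to NaN when the information matrix is singular (flat directions, e.g. a
    barely occupied component)."""
    n_comp = len(mus)
    logits = np.log(np.maximum(wts, 1e-12))
    logits = logits[:-1] - logits[-1]
    theta0 = np.concatenate([logits, mus, np.log(sds)])
    npar = len(theta0)

    def nll(theta):
        lg = np.concatenate([theta[: n_comp - 1], [0.0]])
        w = np.exp(lg - lg.max())
        w = w / w.sum()
        m = theta[n_comp - 1 : 2 * n_comp - 1]
        s = np.exp(theta[2 * n_comp - 1 :])
        pk = np.stack([family.component_pdf(mi, si) for mi, si in zip(m, s)], axis=1)
        dens = np.maximum(pk @ w, 1e-300)
        return -float(np.sum(counts * np.log(dens)))

    h = 1e-3
    hess = np.zeros((npar, npar))
    for i in range(npar):
        for j in range(i, npar):
            ei = np.zeros(npar); ei[i] = h
            ej = np.zeros(npar); ej[j] = h
            val = (
                nll(theta0 + ei + ej) - nll(theta0 + ei - ej)
                - nll(theta0 - ei + ej) + nll(theta0 - ei - ej)
            ) / (4 * h * h)
            hess[i, j] = hess[j, i] = val
    ses = np.full(n_comp, np.nan)
    try:
        cov = np.linalg.inv(hess)
        var = np.diag(cov)[n_comp - 1 : 2 * n_comp - 1]
        good = (var > 0) & np.isfinite(var)
        ses[good] = np.sqrt(var[good])
    except np.linalg.LinAlgError:
        pass
    return ses


def peaks_to_positions(
    fit: MixtureFit,
    quench: QuenchModel,
    i0: Optional[float] = None,
    background_mean: float = 0.0,
) -> MixtureFit:
    """Convert fitted intensity peaks to heights above the quencher.

    Each component mean m becomes a height d = invert(r) with
    r = (m - background) / i0; the component's intensity sd propagates to a
    height sd through the first-order derivative of the inverse map,
    |dd/dr| = d / (4 r (1 - r)). Peaks beyond the upper sensitivity bound
    (r > I/I0 at 1.7 d0) sit on the flat shoulder of the curve where the
    same intensity noise spans a much larger height range; they are flagged
    saturated and keep their (inflated) propagated sds as the honest
    uncertainty. Returns the fit with position fields attached.
    """
    if fit.positions_nm is not None:
        return fit  # physical-mode fits are parameterised in heights already
    if i0 is None:
        i0 = quench.i0
    r = (fit.means - background_mean) / i0
    if np.any(r >= 1.0):
        raise ValueError("fitted mean at or above i0: saturation, no finite height")
    if np.any(r <= 0.0):
        raise ValueError(
            "fitted mean at or below background: blind region, fit with a "
            "background component instead"
        )
    d = invert_intensity(r, quench)
    deriv = d / (4.0 * r * (1.0 - r))  # dd/dr of the inverse map
    pos_sds = (fit.sds / i0) * deriv
    r_sat = relative_intensity(1.7 * quench.d0, quench)
    saturated = r > r_sat
    fit.positions_nm = np.atleast_1d(d)
    fit.position_sds_nm = np.atleast_1d(pos_sds)
    fit.saturated = np.atleast_1d(saturated)
    return fit


def assign_states(
    trace: IntensityTrace,
    fit: MixtureFit,
    background_mean: float = 0.0,
    background_sd: float = 0.0,
    median_window: int = 3,
) -> np.ndarray:
    """Per-frame state labels by maximum posterior, -1 for blind frames.

    A frame is blind when its intensity cannot be told from the camera
    background (below background_mean + 2*background_sd). A short median
    filter (window 3 by default, 0 disables) runs on the combined
    blind/state sequence, so single-frame flickers in either direction —
    a noise spike inside a blind stretch as much as a one-frame dropout
    inside a bright dwell — are suppressed.
    """
    x = trace.intensity
    log_post = (
        np.log(np.maximum(fit.weights, 1e-300))[None, :]
        - np.log(fit.sds)[None, :]
        - 0.5 * ((x[:, None] - fit.means[None, :]) / fit.sds[None, :]) ** 2
    )
    labels = np.argmax(log_post, axis=1).astype(int)
    blind = x < background_mean + 2.0 * background_sd
    labels = labels.copy()
    labels[blind] = -1
    if median_window and median_window > 1:
        labels = median_filter(labels, size=median_window, mode="nearest")
    return labels


def trace_to_positions(
    trace: IntensityTrace,
    quench: QuenchModel,
    i0: Optional[float] = None,
    background_mean: float = 0.0,
    background_sd: float = 0.0,
) -> pd.DataFrame:
    """Frame-by-frame intensity-to-height conversion (the 3-D trace).

    Heights are reported only inside the informative zone: blind frames
    (intensity at background level, dye below ~2 nm) get NaN with flag
    "blind" — the height is the bound "< 2 nm", not a number; frames at or
    above i0 get NaN with flag "saturated". The xy columns pass through so
    lateral and axial motion stay joined.
    """
    if i0 is None:
        i0 = quench.i0
    x = np.asarray(trace.intensity, float)
    net = x - background_mean
    r = net / i0
    flags = np.full(len(x), "ok", dtype=object)
    blind = x < background_mean + 2.0 * background_sd
    blind |= r <= 0.0
    saturated = r >= 1.0
    flags[blind] = "blind"
    flags[saturated & ~blind] = "saturated"
    heights = np.full(len(x), np.nan)
    ok = ~(blind | saturated)
    if ok.any():
        heights[ok] = invert_intensity(r[ok], quench)
    if trace.bleach_index is not None:
        flags[trace.bleach_index :] = "bleached"
        heights[trace.bleach_index :] = np.nan
    return pd.DataFrame(
        {
            "frame": np.arange(len(x)),
            "time_s": trace.time,
            "intensity_au": x,
            "height_nm": heights,
            "flag": flags,
            "blind_bound_nm": np.where(flags == "blind", BLIND_BOUND_NM, np.nan),
            "x_um": trace.x_um if trace.x_um is not None else np.nan,
            "y_um": trace.y_um if trace.y_um is not None else np.nan,
        }
    )
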
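"""Flow-cytometry DNA-content analysis: G1/G2 peak fitting and ploidy calls.

Gated fluorescence event intensities are modelled as a two-component normal
mixture whose components correspond to cells before (G1) and after (G2)
genome replication; the G2 mean is physically twice the G1 mean, enforced
here as a ratio band of [1.7, 2.3] (the 2x constraint relaxed by +/-15%).
Relative ploidy is called by scaling a reference strain of known ploidy:
ploidy = reference_ploidy * G1(sample) / G1(reference), which is invariant
to the instrument's arbitrary intensity scale.

Input is a plain one-column event table (CSV/TSV); binary FCS parsing is out
of scope — convert upstream with any FCS reader and feed the gated
intensities here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import gaussian_kde, norm

__all__ = ["FlowSample", "G1G2Fit", "detect_g1_g2", "call_ploidy", "fit_flow_sample"]

RATIO_BAND = (1.7, 2.3)


@dataclass
class G1G2Fit:
    g1_mean: float
    g2_mean: Optional[float]
    g1_fraction: float
    fit_quality: float          # mean log-likelihood per event
    g2_absent: bool = False
    ambiguous: bool = False

    @property
    def ratio(self) -> Optional[float]:
        return None if self.g2_mean is None else self.g2_mean / self.g1_mean


@dataclass
class FlowSample:
    """One strain's event data and fitted G1/G2 summary."""

    strain: str
    intensities: np.ndarray
    fit: Optional[G1G2Fit] = None

    @property
    def g1_mean(self) -> Optional[float]:
        return None if self.fit is None else self.fit.g1_mean


def _kde_modes(x: np.ndarray, n_grid: int = 512):
    """Local maxima of a kernel density estimate, strongest first."""
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), n_grid)
    dens = kde(grid)
    idx = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])) + 1
    modes = sorted(((grid[i], dens[i]) for i in idx), key=lambda m: -m[1])
    return modes


def _em_two_normals(x: np.ndarray, m1: float, m2: float, w2: float,
                    ratio_band=RATIO_BAND, n_iter: int = 200, tol: float = 1e-8):
    """EM for a two-component normal mixture with a mean-ratio constraint.

    After each M-step the second mean is projected into
    ``[ratio_band[0]*m1, ratio_band[1]*m1]``.  Returns
    (m1, m2, sd1, sd2, w2, mean log-likelihood).
    """
    sd1 = sd2 = max(x.std() / 4.0, 1e-6)
    w2 = min(max(w2, 1e-3), 1 - 1e-3)
    ll_old = -np.inf
    for _ in range(n_iter):
        p1 = (1 - w2) * norm.pdf(x, m1, sd1)
        p2 = w2 * norm.pdf(x, m2, sd2)
        tot = p1 + p2 + 1e-300
        r2 = p2 / tot
        r1 = 1.0 - r2
        n1, n2 = r1.sum(), r2.sum()
        if n1 < 1e-6 or n2 < 1e-6:
            break
        m1 = float((r1 * x).sum() / n1)
        m2 = float((r2 * x).sum() / n2)
        m2 = float(np.clip(m2, ratio_band[0] * m1, ratio_band[1] * m1))
        sd1 = float(np.sqrt((r1 * (x - m1) ** 2).sum() / n1) + 1e-9)
        sd2 = float(np.sqrt((r2 * (x - m2) ** 2).sum() / n2) + 1e-9)
        w2 = float(n2 / (n1 + n2))
        ll = float(np.log(tot).mean())
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return m1, m2, sd1, sd2, w2, ll_old


def detect_g1_g2(intensities, n_restarts: int = 5, seed: int = 0,
                 ratio_band=RATIO_BAND) -> G1G2Fit:
    """Fit G1/G2 component means from gated event intensities.

    Initialization comes from the two strongest kernel-density modes whose
    ratio falls in the accepted band; EM refines the fit with ``n_restarts``
    jittered restarts (fixed seed).  When no secondary mode exists within
    [1.7, 2.3] times the primary one, G2 is reported absent.  Populations
    with additional substantial density modes outside the G1/G2 pair (mixed
    cell populations with different genome content) raise the ambiguity
    flag.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 1000:
        raise ValueError("need at least 1000 events")
    rng = np.random.default_rng(seed)
    modes = _kde_modes(x)
    main = modes[0][0]
    # candidate G1 is the smaller of the pairing; search mode pairs in band
    pair = None
    for m_i, d_i in modes:
        for m_j, d_j in modes:
            if m_j <= m_i:
                continue
            if ratio_band[0] <= m_j / m_i <= ratio_band[1]:
                if pair is None or d_i + d_j > pair[2]:
                    pair = (m_i, m_j, d_i + d_j)
    if pair is None:
        g1 = main
        mask = np.abs(x - g1) < 0.5 * g1
        g1 = float(x[mask].mean()) if mask.any() else float(g1)
        return G1G2Fit(g1_mean=g1, g2_mean=None, g1_fraction=1.0,
                       fit_quality=float(np.log(gaussian_kde(x)(x) + 1e-300).mean()),
                       g2_absent=True, ambiguous=_extra_modes(modes, (main,)))

    m1_0, m2_0, _ = pair
    best = None
    for _ in range(n_restarts):
        jit1 = m1_0 * (1 + 0.05 * rng.standard_normal())
        jit2 = m2_0 * (1 + 0.05 * rng.standard_normal())
        w0 = rng.uniform(0.1, 0.5)
        fit = _em_two_normals(x, jit1, jit2, w0, ratio_band)
        if best is None or fit[5] > best[5]:
            best = fit
    m1, m2, sd1, sd2, w2, ll = best
    ambiguous = _extra_modes(modes, (m1, m2))
    return G1G2Fit(g1_mean=m1, g2_mean=m2, g1_fraction=1.0 - w2,
                   fit_quality=ll, ambiguous=ambiguous)


def _extra_modes(modes, expected, rel_height: float = 0.1,
                 rel_dist: float = 0.15) -> bool:
    """True when a substantial KDE mode sits far from every expected peak."""
    if not modes:
        return False
    top = modes[0][1]
    for m, d in modes:
        if d < rel_height * top:
            continue
        if all(abs(m - e) > rel_dist * e for e in expected):
            return True
    return False


def fit_flow_sample(strain: str, intensities, **kwargs) -> FlowSample:
    x = np.asarray(intensities, dtype=float)
    if np.any(x <= 0):
        raise ValueError("intensities must be positive (gated events)")
    return FlowSample(strain=strain, intensities=x,
                      fit=detect_g1_g2(x, **kwargs))


def call_ploidy(sample: FlowSample, reference: FlowSample, reference_ploidy: int):
    """Relative ploidy of a sample against a reference of known ploidy.

    Returns (estimate, nearest integer, distance to nearest integer).  The
    distance acts as a confidence proxy: large values mean the DNA content
    does not sit near an integer multiple of the reference's 1n content.
    """
    if sample.fit is None or reference.fit is None:
        raise ValueError("both samples must be fitted first")
    if reference.fit.g1_mean is None or reference.fit.g2_absent and reference.fit.g1_mean <= 0:
        raise ValueError("reference G1 peak absent")
    est = reference_ploidy * sample.fit.g1_mean / reference.fit.g1_mean
    nearest = int(round(est))
    return est, nearest, abs(est - nearest)
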
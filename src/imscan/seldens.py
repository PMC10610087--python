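"""Aggregate polygenic-barrier model: selection density from m_e scans.

Barrier loci are assumed uniformly distributed along the genome with
density ``nu`` per bp, each under divergent selection ``s`` against
migrant alleles. The local reduction in effective migration at a neutral
window depends only on its closest flanking barrier locus on either side;
with exponentially distributed nearest-locus distances the expected
reduction depends on recombination rate and the two densities solely
through the *selection density* ``sigma = nu * s``:

    E[m_e,i] / m = E[g]^2,   E[g] = \\int_0^inf e^-u g(u, a) du,  a = sigma_i / r_bp,i

where ``g(u, a) = u / (u + a)`` is the gene-flow factor of a single
linked barrier locus at scaled map distance ``u`` (pluggable, see
``gene_flow_factor``), the two flanks are independent, and ``sigma_i``
optionally rescales with local coding density (more coding sequence =>
denser barrier targets).

Fitting minimises the sum of squared differences between predicted and
scan-inferred window-wise ``m_e``. Derived quantities: the per-locus
selection coefficient implied by a given number of barrier regions, and
the maximum number of barrier loci allowed by a drift bound on ``s``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.integrate
import scipy.optimize


def default_gene_flow_factor(u: np.ndarray, a: float) -> np.ndarray:
    """Standard linked-barrier reduction d/(d+s) in scaled units."""
    return u / (u + a)


def _flank_expectation(a: float,
                       g: Callable[[np.ndarray, float], np.ndarray]) -> float:
    """E over an Exp(1)-distributed scaled nearest-locus distance of g(u, a)."""
    if a == 0:
        return 1.0
    # split at the crossover scale of the integrand to keep the adaptive
    # rule well-conditioned for very small and very large a
    split = min(max(a, 1e-6), 30.0)
    with warnings.catch_warnings():
        # for a below ~1e-10 the requested tolerance sits at roundoff level;
        # the achieved accuracy is still far beyond what the fit needs
        warnings.simplefilter("ignore", scipy.integrate.IntegrationWarning)
        head, _ = scipy.integrate.quad(lambda u: np.exp(-u) * g(u, a), 0.0, split,
                                       epsabs=1e-13, epsrel=1e-12, limit=200)
        tail, _ = scipy.integrate.quad(lambda u: np.exp(-u) * g(u, a), split, np.inf,
                                       epsabs=1e-13, epsrel=1e-12, limit=200)
    return float(head + tail)


def _sigma_scale(cds: Optional[np.ndarray], scaling: str) -> np.ndarray:
    if cds is None:
        return np.array(1.0)
    cds = np.asarray(cds, dtype=float)
    rel = cds / cds.mean()
    if scaling == "proportional":
        return rel
    if scaling == "inverse":
        return 1.0 / rel
    raise ValueError("scaling must be 'proportional' or 'inverse'")


def predict_me(
    sigma: float,
    m: float,
    r_bp: Sequence[float] | float,
    cds: Optional[Sequence[float]] = None,
    scaling: str = "proportional",
    gene_flow_factor: Callable = default_gene_flow_factor,
) -> np.ndarray:
    """Expected window-wise effective migration rate under the model.

    ``m_e,i / m`` depends only on ``sigma_i / r_bp,i``; it is strictly
    decreasing in ``sigma`` and strictly increasing in ``r_bp``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    r = np.atleast_1d(np.asarray(r_bp, dtype=float))
    if np.any(r <= 0):
        raise ValueError("recombination rate must be > 0")
    scale = np.broadcast_to(_sigma_scale(cds, scaling), r.shape)
    out = np.empty_like(r)
    for k in range(r.size):
        e = _flank_expectation(sigma * scale.flat[k] / r.flat[k], gene_flow_factor)
        out.flat[k] = m * e * e   # two independent flanks
    return out if np.ndim(r_bp) else float(out[0])


@dataclass
class SelectionDensityFit:
    sigma: float
    m: float
    sse: float
    predicted: np.ndarray
    n_windows: int


def fit_selection_density(
    me_estimates: Sequence[float],
    r_bp: Sequence[float],
    cds: Optional[Sequence[float]] = None,
    scaling: str = "proportional",
    gene_flow_factor: Callable = default_gene_flow_factor,
    start: Optional[tuple[float, float]] = None,
) -> SelectionDensityFit:
    """Least-squares fit of (sigma, m) to window-wise m_e estimates.

    Deterministic given the start; the default start sets ``m`` just above
    the largest observed m_e and ``sigma`` at half the median r_bp.
    """
    me = np.asarray(me_estimates, dtype=float)
    r = np.asarray(r_bp, dtype=float)
    if me.shape != r.shape or me.size < 2:
        raise ValueError("need >= 2 windows with matching m_e and r_bp")
    if np.unique(r).size < 2 and (cds is None or np.unique(np.asarray(cds)).size < 2):
        raise ValueError("degenerate input: r_bp (and CDS) constant across windows; "
                         "sigma and m are not separately identifiable")
    if start is None:
        start = (0.5 * float(np.median(r)), 1.05 * float(me.max()))
    x0 = np.log10(np.array(start))

    def residuals(x):
        sigma, m = 10.0 ** x
        return predict_me(sigma, m, r, cds, scaling, gene_flow_factor) - me

    res = scipy.optimize.least_squares(residuals, x0, xtol=1e-15, ftol=1e-15,
                                       gtol=1e-15, method="lm")
    sigma, m = 10.0 ** res.x
    pred = predict_me(sigma, m, r, cds, scaling, gene_flow_factor)
    return SelectionDensityFit(sigma=float(sigma), m=float(m),
                               sse=float(np.sum((pred - me) ** 2)),
                               predicted=pred, n_windows=me.size)


def implied_s(sigma: float, n_regions: int, L_autosome: float) -> float:
    """Per-locus selection coefficient if exactly `n_regions` loci carry sigma.

    With one barrier locus per region, the locus density is
    ``n_regions / L`` and ``s = sigma / (n_regions / L)``.
    """
    if n_regions < 1 or L_autosome <= 0:
        raise ValueError("n_regions must be >= 1 and L_autosome > 0")
    return sigma * L_autosome / n_regions


def max_barrier_loci(
    sigma: float,
    N_e: float,
    L_autosome: float,
    drift_bound_convention: str = "Ne_s",
    m: Optional[float] = None,
) -> float:
    """Upper bound on the number of barrier loci from a drift bound on s.

    For a barrier locus to resist drift its selection coefficient must
    exceed a threshold ``s_min``: the ``"Ne_s"`` convention takes
    ``N_e * s > 1`` (``s_min = 1/N_e``), the ``"2Ne_s"`` convention
    ``2 N_e * s > 1`` (``s_min = 1/(2 N_e)``; exactly twice as many
    loci). If the background migration rate ``m`` is supplied, the
    maintenance condition ``s > m`` is also enforced and the binding
    constraint wins. The bound is ``(sigma / s_min) * L``.
    """
    if N_e <= 0:
        raise ValueError("N_e must be > 0")
    if drift_bound_convention == "Ne_s":
        s_min = 1.0 / N_e
    elif drift_bound_convention == "2Ne_s":
        s_min = 1.0 / (2.0 * N_e)
    else:
        raise ValueError("drift_bound_convention must be 'Ne_s' or '2Ne_s'")
    if m is not None:
        s_min = max(s_min, m)
    return sigma / s_min * L_autosome


def window_scale_average(
    intervals: Sequence[tuple[int, int, float]] | np.ndarray,
    midpoints: Sequence[int] | int,
    scale: int,
    chrom_length: int,
) -> np.ndarray:
    """Length-weighted mean of an interval-valued map around window midpoints.

    Averages the map value over a physical region of width ``scale``
    centred on each midpoint, truncated at the chromosome ends. Intervals
    are half-open (start, end, value) and must be sorted; gaps contribute
    no weight.
    """
    arr = np.asarray(intervals, dtype=float).reshape(-1, 3)
    if np.any(np.diff(arr[:, 0]) < 0):
        raise ValueError("intervals must be sorted by start")
    mids = np.atleast_1d(np.asarray(midpoints, dtype=float))
    out = np.empty(mids.shape)
    for k, mid in enumerate(mids):
        if not (0 <= mid <= chrom_length):
            raise ValueError(f"midpoint {mid} outside chromosome of length {chrom_length}")
        lo = max(0.0, mid - scale / 2.0)
        hi = min(float(chrom_length), mid + scale / 2.0)
        w = np.clip(np.minimum(arr[:, 1], hi) - np.maximum(arr[:, 0], lo), 0, None)
        if w.sum() == 0:
            out[k] = np.nan
        else:
            out[k] = float((w * arr[:, 2]).sum() / w.sum())
    return out if np.ndim(midpoints) else float(out[0])


def crossover_to_r_bp(cm_per_mb: float | np.ndarray) -> np.ndarray:
    """cM/Mb -> per-bp per-generation crossover probability (1 cM/Mb = 1e-8)."""
    return np.asarray(cm_per_mb, dtype=float) * 1e-8
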
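"""Composite-likelihood inference of IM-type demographies from bSFS tallies.

The log composite likelihood of a tally is
``ln CL(theta) = sum_i n_i ln p(k_i | theta)``, the sum over folded bSFS
configurations of the observed count times the model log-probability;
blocks from all heterospecific sample pairs are pooled, so ln CL is
invariant to block order and to which pair contributed a block.

Global estimates come from bounded numeric optimization on
log-transformed parameters (positivity plus scale-free steps); window
scans use a pre-computed likelihood grid searched exhaustively.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.optimize

from imscan.demography import DemographyParams, KmaxSpec, Model
from imscan.engine import compute_bsfs_pmf
from imscan.engine.pmf import EngineError
from imscan.tally import BsfsTally

logger = logging.getLogger(__name__)

#: canonical free-parameter order per model
FREE_PARAMS = {
    Model.DIV: ("N_A", "N_B", "N_anc", "T"),
    Model.MIG_AtoB: ("N_A", "N_B", "m_e"),
    Model.MIG_BtoA: ("N_A", "N_B", "m_e"),
    Model.IM_AtoB: ("N_A", "N_B", "N_anc", "T", "m_e"),
    Model.IM_BtoA: ("N_A", "N_B", "N_anc", "T", "m_e"),
}


def ln_composite_likelihood(tally: BsfsTally, log_pmf: np.ndarray) -> float:
    """Sum of count * log-probability over folded configurations.

    Cells with a positive count but zero model probability yield ``-inf``
    and are reported via a warning (they indicate four-gamete leakage or a
    kmax mismatch), never silently clipped.
    """
    log_pmf = np.asarray(log_pmf)
    if log_pmf.shape != tally.counts.shape:
        raise ValueError(f"shape mismatch: tally {tally.counts.shape} vs pmf {log_pmf.shape}")
    sel = tally.counts > 0
    if not sel.any():
        return 0.0
    terms = tally.counts[sel] * log_pmf[sel]
    if np.isneginf(log_pmf[sel]).any():
        bad = np.argwhere(sel & np.isneginf(log_pmf))
        logger.warning("observed configurations with zero model probability: %s",
                       bad.tolist())
        return float("-inf")
    return float(terms.sum())


@dataclass
class OptimizeResult:
    params: DemographyParams
    ln_cl: float
    n_evaluations: int
    converged: bool
    start: dict
    trace: list = field(default_factory=list)  # (param dict, ln CL) per evaluation


def optimize(
    tally: BsfsTally,
    model: Model | str,
    bounds: dict[str, tuple[float, float]],
    fixed: Optional[dict[str, float]] = None,
    mu: float = 2.9e-9,
    block_length: int = 64,
    start: str = "midpoint",
    seed: Optional[int] = None,
    rel_tol: float = 1e-6,
    max_evaluations: int = 10_000,
    keep_trace: bool = False,
) -> OptimizeResult:
    """Bounded maximum-composite-likelihood fit (Nelder-Mead on log10 scale).

    ``start`` is either ``"midpoint"`` (the midpoint of the log-bounded
    space, the default) or ``"random"`` (log-uniform in the bounds, seeded
    with ``seed``); repeated random starts allow convergence assessment.
    """
    model = Model(model)
    fixed = dict(fixed or {})
    free = [p for p in FREE_PARAMS[model] if p not in fixed]
    for p in free:
        if p not in bounds:
            raise ValueError(f"missing bounds for free parameter {p}")
        lo, hi = bounds[p]
        if not (0 < lo <= hi and np.isfinite(hi)):
            raise ValueError(f"bounds for {p} must be finite and positive")
    lo = np.log10([bounds[p][0] for p in free])
    hi = np.log10([bounds[p][1] for p in free])

    def make_params(x: np.ndarray) -> DemographyParams:
        vals = dict(zip(free, 10.0 ** np.asarray(x)))
        for p in free:  # collapsed bounds are honoured exactly
            if bounds[p][0] == bounds[p][1]:
                vals[p] = bounds[p][0]
        vals.update(fixed)
        kw = dict(model=model, mu=mu, block_length=block_length,
                  N_A=vals["N_A"], N_B=vals["N_B"])
        if model.has_split:
            kw.update(N_anc=vals["N_anc"], T=vals["T"])
        if model.has_migration:
            kw.update(m_e=vals["m_e"])
        return DemographyParams(**kw)

    trace: list = []
    n_eval = [0]

    def neg_ln_cl(x: np.ndarray) -> float:
        n_eval[0] += 1
        try:
            pmf = compute_bsfs_pmf(make_params(x), tally.kmax)
            val = ln_composite_likelihood(tally, pmf.log())
        except EngineError as exc:
            logger.warning("engine failure at %s: %s", x, exc)
            val = float("-inf")
        if keep_trace:
            trace.append((dict(zip(free, 10.0 ** np.asarray(x))), val))
        return -val if np.isfinite(val) else 1e300

    if np.all(lo == hi):
        x0 = lo.copy()
    elif start == "midpoint":
        x0 = 0.5 * (lo + hi)
    elif start == "random":
        rng = np.random.default_rng(seed)
        x0 = lo + (hi - lo) * rng.random(len(free))
    else:
        raise ValueError("start must be 'midpoint' or 'random'")

    if np.all(lo == hi):
        # collapsed bounds: nothing to optimize, evaluate the single point
        value = -neg_ln_cl(x0)
        return OptimizeResult(params=make_params(x0), ln_cl=value,
                              n_evaluations=n_eval[0], converged=True,
                              start=dict(zip(free, 10.0 ** x0)), trace=trace)

    f0 = neg_ln_cl(x0)
    fatol = rel_tol * max(1.0, abs(f0))
    res = scipy.optimize.minimize(
        neg_ln_cl, x0, method="Nelder-Mead",
        bounds=list(zip(lo, hi)),
        options=dict(maxfev=max_evaluations, fatol=fatol, xatol=1e-5,
                     adaptive=len(free) > 3),
    )
    if not res.success:
        logger.warning("optimizer did not report convergence: %s", res.message)
    return OptimizeResult(
        params=make_params(res.x), ln_cl=float(-res.fun),
        n_evaluations=n_eval[0], converged=bool(res.success),
        start=dict(zip(free, 10.0 ** x0)), trace=trace,
    )


# ---------------------------------------------------------------------------
# likelihood grids
# ---------------------------------------------------------------------------


@dataclass
class GridSpec:
    """Ordered per-parameter value lists plus fixed parameters.

    ``axes`` maps free parameter names to their grid values; the cartesian
    product is enumerated in C order (last axis fastest). Size grids are
    conventionally log-spaced; the ``m_e`` axis should include 0 exactly
    so that complete-barrier support is defined.
    """

    model: Model
    axes: dict[str, np.ndarray]
    fixed: dict[str, float]
    mu: float = 2.9e-9
    block_length: int = 64
    kmax: KmaxSpec = field(default_factory=KmaxSpec)

    def __post_init__(self) -> None:
        self.model = Model(self.model)
        self.axes = {k: np.asarray(v, dtype=float) for k, v in self.axes.items()}
        missing = [p for p in FREE_PARAMS[self.model]
                   if p not in self.axes and p not in self.fixed]
        if missing:
            raise ValueError(f"parameters neither on the grid nor fixed: {missing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.axes.values())

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def points(self) -> list[dict[str, float]]:
        names = list(self.axes)
        out = []
        for combo in itertools.product(*(self.axes[n] for n in names)):
            d = dict(zip(names, (float(c) for c in combo)))
            d.update(self.fixed)
            out.append(d)
        return out

    def axis_values(self, name: str) -> np.ndarray:
        """Per-point values of one grid axis, in point enumeration order."""
        names = list(self.axes)
        mesh = np.meshgrid(*(self.axes[n] for n in names), indexing="ij")
        return mesh[names.index(name)].ravel()

    def params_at(self, point: dict[str, float]) -> DemographyParams:
        kw = dict(model=self.model, mu=self.mu, block_length=self.block_length,
                  N_A=point["N_A"], N_B=point["N_B"])
        if self.model.has_split:
            kw.update(N_anc=point["N_anc"], T=point["T"])
        if self.model.has_migration:
            kw.update(m_e=point["m_e"])
        return DemographyParams(**kw)


def default_grid(model: Model, center: dict[str, float], fixed: dict[str, float],
                 n_sizes: int = 12, n_m: int = 16, spread: float = 10.0,
                 mu: float = 2.9e-9, block_length: int = 64,
                 kmax: Optional[KmaxSpec] = None) -> GridSpec:
    """Log-spaced grid spanning ``spread``-fold around a central estimate.

    Sizes get ``n_sizes`` log-uniform values in ``[c/spread, c*spread]``;
    the migration axis gets 0 exactly plus ``n_m - 1`` log-spaced values
    whose ladder contains the central ``m_e`` itself (required for
    barrier support to be well defined).
    """
    axes: dict[str, np.ndarray] = {}
    for p in FREE_PARAMS[Model(model)]:
        if p in fixed:
            continue
        c = center[p]
        if p == "m_e":
            ladder = c * np.logspace(-1, 1, n_m - 1, base=spread)
            # make sure the centre is one of the grid values exactly
            ladder[np.argmin(np.abs(np.log(ladder / c)))] = c
            axes[p] = np.concatenate([[0.0], ladder])
        else:
            axes[p] = np.logspace(np.log10(c / spread), np.log10(c * spread), n_sizes)
    return GridSpec(model=Model(model), axes=axes, fixed=dict(fixed), mu=mu,
                    block_length=block_length, kmax=kmax or KmaxSpec())


@dataclass
class LikelihoodGrid:
    """Log-probabilities of every folded configuration at every grid point."""

    spec: GridSpec
    log_pmfs: np.ndarray          # (n_points, *kmax.shape)
    errors: dict[int, str] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.log_pmfs.shape[0]

    def flat(self) -> np.ndarray:
        return self.log_pmfs.reshape(self.n_points, -1)


def makegrid(spec: GridSpec, progress: bool = False) -> LikelihoodGrid:
    """One engine call per grid point; failures are recorded and skipped."""
    shape = spec.kmax.shape
    pts = spec.points()
    log_pmfs = np.full((len(pts), *shape), -np.inf)
    errors: dict[int, str] = {}
    for h, point in enumerate(pts):
        try:
            pmf = compute_bsfs_pmf(spec.params_at(point), spec.kmax)
            log_pmfs[h] = pmf.log()
        except (EngineError, ValueError) as exc:
            errors[h] = str(exc)
            logger.warning("grid point %d failed: %s", h, exc)
    return LikelihoodGrid(spec=spec, log_pmfs=log_pmfs, errors=errors)


@dataclass
class GridsearchResult:
    best_index: np.ndarray        # (n_tallies,)
    best_point: list[dict]
    ln_cl: np.ndarray             # (n_tallies, n_points) full surfaces
    ties: list[list[int]]


def gridsearch(tallies: Sequence[BsfsTally] | BsfsTally,
               grid: LikelihoodGrid) -> GridsearchResult:
    """Exhaustive maximization of ln CL over the grid, per tally.

    The full per-tally surface is retained (needed for barrier support);
    ties are broken toward the lowest grid index and reported.
    """
    single = isinstance(tallies, BsfsTally)
    tallies = [tallies] if single else list(tallies)
    shape = grid.spec.kmax.shape
    flat_logp = grid.flat()
    pts = grid.spec.points()
    surfaces = np.empty((len(tallies), grid.n_points))
    for t, tally in enumerate(tallies):
        if tally.counts.shape != shape:
            raise ValueError("tally kmax shape does not match grid kmax shape")
        c = tally.counts.ravel()
        sel = c > 0
        if sel.any():
            with np.errstate(invalid="ignore"):
                surfaces[t] = flat_logp[:, sel] @ c[sel]
        else:
            surfaces[t] = 0.0
    best = np.argmax(surfaces, axis=1)
    ties = []
    for t in range(len(tallies)):
        tie_idx = np.flatnonzero(surfaces[t] == surfaces[t, best[t]])
        ties.append(tie_idx.tolist() if len(tie_idx) > 1 else [])
        if len(tie_idx) > 1:
            logger.info("tally %d: %d tied grid points, lowest index reported",
                        t, len(tie_idx))
    return GridsearchResult(
        best_index=best,
        best_point=[pts[b] for b in best],
        ln_cl=surfaces,
        ties=ties,
    )
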
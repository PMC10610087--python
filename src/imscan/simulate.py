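"""Coalescent simulation of block and window tallies.

Backed by msprime (demographies are specified through the demes graph
exported by :meth:`DemographyParams.to_demes`). Windows are contiguous
runs of blocks sharing one recombining ancestry; distinct windows are
independent. Within-block recombination is deliberately allowed — the
likelihood model assumes none, and simulating with it is how the bias of
that assumption (and the false-positive rate of the scan) is quantified.
Four-gamete-violating blocks arising under recombination are excluded at
tally time exactly as for real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from imscan.demography import DemographyParams, KmaxSpec
from imscan.tally import BsfsTally

logger = logging.getLogger(__name__)


@dataclass
class SimulationSpec:
    """What to simulate: demography, layout, sampling, recombination."""

    params: DemographyParams
    n_windows: int = 1
    blocks_per_window: int = 100
    samples_per_taxon: tuple[int, int] = (1, 1)
    #: per-bp per-generation crossover rate; scalar or one value per window
    r_bp: Union[float, np.ndarray] = 0.0
    kmax: KmaxSpec = field(default_factory=KmaxSpec)
    replicates: int = 1

    def window_rates(self) -> np.ndarray:
        r = np.asarray(self.r_bp, dtype=float)
        if r.ndim == 0:
            return np.full(self.n_windows, float(r))
        if r.shape != (self.n_windows,):
            raise ValueError("r_bp must be scalar or one value per window")
        return r


def _classify_sites(G: np.ndarray, ia: int, ib: int, n_a: int) -> np.ndarray:
    """Mutation type per site for pair (A individual ia, B individual ib).

    ``G`` is the haplotype genotype matrix (n_sites, 2*(n_a+n_b)) of 0/1
    alleles; returns -1 for sites invariant in the pair.
    """
    a1 = G[:, 2 * ia]
    a2 = G[:, 2 * ia + 1]
    b1 = G[:, 2 * (n_a + ib)]
    b2 = G[:, 2 * (n_a + ib) + 1]
    het_a = a1 != a2
    het_b = b1 != b2
    types = np.full(G.shape[0], -1, dtype=np.int64)
    types[het_a & het_b] = 2
    types[het_a & ~het_b] = 1
    types[~het_a & het_b] = 0
    types[~het_a & ~het_b & (a1 != b1)] = 3
    return types


def _tally_window(positions: np.ndarray, G: np.ndarray, spec: SimulationSpec) -> BsfsTally:
    """Fold per-block mutation-type counts of one window into a tally."""
    n_a, n_b = spec.samples_per_taxon
    L = spec.params.block_length
    n_blocks = spec.blocks_per_window
    block_idx = np.minimum((positions // L).astype(np.int64), n_blocks - 1)
    kmax = spec.kmax
    caps = np.array(kmax.caps)
    shape = kmax.shape
    counts = np.zeros(shape, dtype=np.int64)
    n_fgv = 0
    n_kept = 0
    for ia in range(n_a):
        for ib in range(n_b):
            types = _classify_sites(G, ia, ib, n_a)
            unfolded = np.zeros((n_blocks, 4), dtype=np.int64)
            seg = types >= 0
            if seg.any():
                flat = block_idx[seg] * 4 + types[seg]
                np.add.at(unfolded.reshape(-1), flat, 1)
            fgv = (unfolded[:, 2] > 0) & (unfolded[:, 3] > 0)
            n_fgv += int(fgv.sum())
            kept = unfolded[~fgv]
            n_kept += kept.shape[0]
            folded = np.minimum(kept, caps + 1)
            flat_idx = np.ravel_multi_index(folded.T, shape)
            np.add.at(counts.reshape(-1), flat_idx, 1)
    return BsfsTally(counts=counts, kmax=kmax, scope="windows",
                     n_blocks_retained=n_kept, n_fgv_excluded=n_fgv)


def _sim_window_raw(spec: SimulationSpec, r: float, seeds: tuple[int, int],
                    demography=None):
    """One window's site positions and haplotype genotype matrix."""
    import msprime

    n_a, n_b = spec.samples_per_taxon
    L = spec.params.block_length * spec.blocks_per_window
    ts = msprime.sim_ancestry(
        samples={"A": n_a, "B": n_b},
        demography=demography if demography is not None else spec.params.to_msprime(),
        sequence_length=L,
        recombination_rate=r,
        random_seed=seeds[0],
    )
    mts = msprime.sim_mutations(
        ts, rate=spec.params.mu, random_seed=seeds[1],
        model=msprime.BinaryMutationModel(), discrete_genome=False,
    )
    if mts.num_sites:
        positions = mts.tables.sites.position
        G = mts.genotype_matrix().astype(np.int8)  # (n_sites, n_haplotypes)
    else:
        positions = np.empty(0)
        G = np.empty((0, 2 * (n_a + n_b)), dtype=np.int8)
    return positions, G


def simulate_windows(spec: SimulationSpec, seed: int = 1,
                     return_genotypes: bool = False):
    """Per-window folded bSFS tallies (optionally with the raw genotypes).

    Windows are simulated independently; results are reproducible by
    seed (the same seed always yields identical tallies).
    """
    rates = spec.window_rates()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(1, 2 ** 31 - 1, size=(spec.n_windows, 2))
    demography = spec.params.to_msprime()
    tallies: list[BsfsTally] = []
    raw = []
    for w in range(spec.n_windows):
        try:
            positions, G = _sim_window_raw(spec, rates[w], tuple(seeds[w]), demography)
        except Exception as exc:
            raise RuntimeError(
                f"simulation backend failure for window {w} "
                f"(spec={spec!r}, seed={seed})") from exc
        tallies.append(_tally_window(positions, G, spec))
        if return_genotypes:
            raw.append((positions, G))
    return (tallies, raw) if return_genotypes else tallies


# ---------------------------------------------------------------------------
# independent non-recombining blocks (replicate mode)
# ---------------------------------------------------------------------------


def simulate_block_replicates(params: DemographyParams, kmax: KmaxSpec,
                              n_blocks: int, seed: int = 1) -> np.ndarray:
    """Folded tally of independent single-genealogy blocks via msprime.

    Each block is one ancestry replicate for a 2+2 sample; mutations are
    dropped as Poisson counts on the typed branch lengths. This is the
    simulator-side twin of the engine's Monte-Carlo oracle and is used to
    cross-validate the two against `compute_bsfs_pmf`.
    """
    import msprime

    from imscan.demography import BRANCH_TYPE

    reps = msprime.sim_ancestry(
        samples={"A": 1, "B": 1},
        demography=params.to_msprime(),
        sequence_length=params.block_length,
        recombination_rate=0.0,
        num_replicates=n_blocks,
        random_seed=max(1, int(seed) % (2 ** 31)),
    )
    L = np.zeros((n_blocks, 4))
    for rix, ts in enumerate(reps):
        time = ts.nodes_time.tolist()
        e_p = ts.edges_parent.tolist()
        e_c = ts.edges_child.tolist()
        # samples 0,1 are the A individual's haplotypes, 2,3 the B's
        i = [0] * len(time)
        j = [0] * len(time)
        i[0] = i[1] = 1
        j[2] = j[3] = 1
        # tskit edges are sorted by nondecreasing parent time, so child
        # subtrees are complete before the child acts as a parent
        for p, c in zip(e_p, e_c):
            i[p] += i[c]
            j[p] += j[c]
        row = L[rix]
        for p, c in zip(e_p, e_c):
            t = BRANCH_TYPE[(i[c], j[c])]
            if t >= 0:
                row[t] += time[p] - time[c]
    rng = np.random.default_rng(seed)
    counts4 = rng.poisson(params.theta_per_lineage * L)
    caps = np.array(kmax.caps)
    folded = np.minimum(counts4, caps + 1)
    out = np.zeros(kmax.shape, dtype=np.int64)
    np.add.at(out.reshape(-1), np.ravel_multi_index(folded.T, kmax.shape), 1)
    return out


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapCI:
    point: dict[str, float]
    ci: dict[str, tuple[float, float]]       # point +/- 2 SD across replicates
    replicate_estimates: "np.ndarray"        # (n_reps, n_free)
    free_names: list[str]
    n_failed: int


def parametric_bootstrap_ci(
    mcle: DemographyParams,
    bounds: dict[str, tuple[float, float]],
    n_reps: int = 100,
    n_windows: int = 50,
    blocks_per_window: int = 500,
    r_bp: float = 0.0,
    kmax: Optional[KmaxSpec] = None,
    fixed: Optional[dict[str, float]] = None,
    seed: int = 1,
    max_evaluations: int = 4000,
) -> BootstrapCI:
    """Simulate at the MCLE, refit each replicate, CI = point +/- 2 SD.

    Replicate datasets should be thinned relative to the real data (the
    windows of a real scan overlap and are linked, simulated ones are
    independent), which is what `n_windows` controls.
    """
    from imscan.inference import FREE_PARAMS, optimize
    from imscan.tally import BsfsTally

    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    kmax = kmax or KmaxSpec()
    fixed = dict(fixed or {})
    free = [p for p in FREE_PARAMS[mcle.model] if p not in fixed]
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(1, 2 ** 31 - 1, size=n_reps)
    estimates = np.full((n_reps, len(free)), np.nan)
    n_failed = 0
    for rep in range(n_reps):
        spec = SimulationSpec(params=mcle, n_windows=n_windows,
                              blocks_per_window=blocks_per_window,
                              r_bp=r_bp, kmax=kmax)
        tallies = simulate_windows(spec, seed=int(rep_seeds[rep]))
        counts = np.sum([t.counts for t in tallies], axis=0)
        tally = BsfsTally(counts=counts.astype(np.int64), kmax=kmax, scope="blocks",
                          n_blocks_retained=int(counts.sum()),
                          n_fgv_excluded=sum(t.n_fgv_excluded for t in tallies))
        res = optimize(tally, mcle.model, bounds, fixed=fixed, mu=mcle.mu,
                       block_length=mcle.block_length, seed=int(rep_seeds[rep]),
                       max_evaluations=max_evaluations)
        if not res.converged:
            n_failed += 1
            logger.warning("bootstrap replicate %d did not converge", rep)
        estimates[rep] = [getattr(res.params, p) for p in free]
    sd = np.nanstd(estimates, axis=0, ddof=1)
    point = {p: float(getattr(mcle, p)) for p in free}
    ci = {p: (point[p] - 2 * sd[k], point[p] + 2 * sd[k]) for k, p in enumerate(free)}
    return BootstrapCI(point=point, ci=ci, replicate_estimates=estimates,
                       free_names=free, n_failed=n_failed)


# ---------------------------------------------------------------------------
# power / ROC analysis
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    scores_positive: np.ndarray
    scores_negative: np.ndarray


def power_roc(
    background: DemographyParams,
    grid,
    m_hat: float,
    barrier_fractions: Sequence[float] = (0.0, 0.5),
    window_sizes: Sequence[int] = (100,),
    r_bp: float = 1.89e-8,
    n_reps: int = 200,
    seed: int = 1,
) -> dict[tuple[int, float], RocResult]:
    """ROC of the barrier statistic against simulated true barriers.

    True negatives are windows simulated under the background model
    (m_e = m_hat); true positives under a locally reduced migration rate
    (m_e = fraction * m_hat). Each window is scored by Delta_B at the
    matching threshold. Returns one ROC per (window size, fraction).
    """
    from sklearn.metrics import roc_curve

    from imscan.inference import gridsearch
    from imscan.scan import delta_b, resolve_threshold

    rng = np.random.default_rng(seed)
    out: dict[tuple[int, float], RocResult] = {}
    for ws in window_sizes:
        neg_spec = SimulationSpec(params=background.with_(m_e=m_hat),
                                  n_windows=n_reps, blocks_per_window=ws,
                                  r_bp=r_bp, kmax=grid.spec.kmax)
        neg_tallies = simulate_windows(neg_spec, seed=int(rng.integers(1, 2 ** 31)))
        neg_surfaces = gridsearch(neg_tallies, grid).ln_cl
        for frac in barrier_fractions:
            pos_spec = SimulationSpec(params=background.with_(m_e=frac * m_hat),
                                      n_windows=n_reps, blocks_per_window=ws,
                                      r_bp=r_bp, kmax=grid.spec.kmax)
            pos_tallies = simulate_windows(pos_spec, seed=int(rng.integers(1, 2 ** 31)))
            pos_surfaces = gridsearch(pos_tallies, grid).ln_cl
            m_star = resolve_threshold(frac, m_hat, grid.spec.model)
            s_neg = np.array([delta_b(s, grid, m_hat, m_star) for s in neg_surfaces])
            s_pos = np.array([delta_b(s, grid, m_hat, m_star) for s in pos_surfaces])
            y = np.r_[np.zeros(len(s_neg)), np.ones(len(s_pos))]
            scores = np.r_[s_neg, s_pos]
            fpr, tpr, _ = roc_curve(y, scores)
            auc = float(np.trapezoid(tpr, fpr))
            out[(ws, frac)] = RocResult(auc=auc, fpr=fpr, tpr=tpr,
                                        scores_positive=s_pos, scores_negative=s_neg)
    return out
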
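"""Window-wise barrier support, barrier regions, and false-positive rates.

For each window the barrier statistic is the log-composite-likelihood
support for a locally reduced migration rate:

    Delta_B = max_{m_i <= m*, N_i} ln CL(m_i, T_hat, N_i)
            - max_{N_i} ln CL(m_hat, T_hat, N_i)

where ``m_hat`` and ``T_hat`` are the global background estimates and the
maxima run over the inference grid. Windows with Delta_B > 0 support
reduced gene flow; overlapping positive windows merge into barrier
regions. Because the feasible set of the first term grows with the
threshold, Delta_B is non-decreasing in ``m*``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from imscan.demography import Model
from imscan.inference import GridsearchResult, LikelihoodGrid, gridsearch
from imscan.tally import BsfsTally

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.0, 0.2, 0.5)


class BarrierDefinitionError(ValueError):
    pass


def _m_values(grid: LikelihoodGrid) -> np.ndarray:
    if "m_e" not in grid.spec.axes:
        raise BarrierDefinitionError("grid has no m_e axis; barrier support undefined")
    return grid.spec.axis_values("m_e")


def delta_b(surface: np.ndarray, grid: LikelihoodGrid, m_hat: float,
            m_star: float) -> float:
    """Barrier support for one window from its ln CL grid surface.

    ``m_star`` is an absolute migration-rate threshold (0 for complete
    barriers); the constraint ``m_i <= m_star`` is inclusive. ``m_hat``
    must be one of the grid's m_e values.
    """
    surface = np.asarray(surface).ravel()
    m_vals = _m_values(grid)
    if surface.shape != m_vals.shape:
        raise ValueError("surface length does not match grid size")
    at_hat = np.isclose(m_vals, m_hat, rtol=1e-12, atol=0.0) if m_hat > 0 else m_vals == 0.0
    if not at_hat.any():
        raise BarrierDefinitionError(
            f"global estimate m_hat={m_hat!r} is not a grid value; "
            "re-make the grid with the global estimate on the m_e axis")
    feasible = m_vals <= m_star * (1 + 1e-12)
    if not feasible.any():
        raise BarrierDefinitionError(f"no grid point satisfies m_e <= {m_star!r}")
    return float(surface[feasible].max() - surface[at_hat].max())


def resolve_threshold(fraction: float, m_hat: float, model: Model) -> float:
    """Absolute m_e* from a threshold expressed as a fraction of m_hat.

    Complete-barrier support (fraction 0) is undefined under MIG models:
    with an infinitely old split and m_e = 0 the two populations never
    share ancestry, so that likelihood does not exist.
    """
    if fraction < 0:
        raise BarrierDefinitionError("threshold fraction must be >= 0")
    if fraction == 0 and Model(model) in (Model.MIG_AtoB, Model.MIG_BtoA):
        raise BarrierDefinitionError(
            "complete-barrier (m_e* = 0) support is undefined under the MIG model: "
            "m_e = 0 with no split leaves the demes disconnected; use a positive "
            "threshold fraction or an IM grid")
    return float(fraction) * float(m_hat)


@dataclass(frozen=True)
class BarrierRegion:
    sequence: str
    start: int
    end: int
    windows: tuple[int, ...]
    max_delta_b: float


@dataclass
class BarrierScanResult:
    """Per-window barrier support at each threshold plus local MCLEs."""

    table: pd.DataFrame           # index, sequence, start, end, m_i, N columns,
                                  # delta_b_<frac>, is_barrier_<frac>, fpr (optional)
    thresholds: tuple[float, ...]
    m_hat: float
    grid: LikelihoodGrid
    surfaces: np.ndarray          # (n_windows, n_points)


def scan_windows(
    window_tallies: Sequence[BsfsTally],
    window_meta: pd.DataFrame,
    grid: LikelihoodGrid,
    m_hat: float,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> BarrierScanResult:
    """Gridsearch every window and attach Delta_B at each threshold fraction.

    ``window_meta`` needs columns sequence/start/end (one row per tally).
    """
    if len(window_tallies) != len(window_meta):
        raise ValueError("one metadata row per window tally required")
    gs: GridsearchResult = gridsearch(list(window_tallies), grid)
    model = grid.spec.model
    rows = window_meta.reset_index(drop=True).copy()
    for name in grid.spec.axes:
        rows[f"best_{name}"] = [p[name] for p in gs.best_point]
    for frac in thresholds:
        m_star = resolve_threshold(frac, m_hat, model)
        vals = [delta_b(gs.ln_cl[w], grid, m_hat, m_star)
                for w in range(len(window_tallies))]
        rows[f"delta_b_{frac:g}"] = vals
        rows[f"is_barrier_{frac:g}"] = np.array(vals) > 0
    return BarrierScanResult(table=rows, thresholds=tuple(thresholds),
                             m_hat=m_hat, grid=grid, surfaces=gs.ln_cl)


def call_barrier_regions(result: BarrierScanResult | pd.DataFrame,
                         threshold: float = 0.0) -> list[BarrierRegion]:
    """Merge overlapping Delta_B > 0 windows into maximal barrier regions.

    Merging requires actual span overlap in bp (half-open coordinates);
    step-adjacent but non-overlapping windows stay separate regions.
    """
    table = result.table if isinstance(result, BarrierScanResult) else result
    col = f"delta_b_{threshold:g}"
    if col not in table.columns:
        raise KeyError(f"no column {col!r}; scanned thresholds: "
                       f"{[c for c in table.columns if c.startswith('delta_b')]}")
    pos = table[table[col] > 0].sort_values(["sequence", "start"])
    regions: list[BarrierRegion] = []
    cur: Optional[dict] = None
    for idx, row in pos.iterrows():
        if (cur is not None and row["sequence"] == cur["sequence"]
                and row["start"] < cur["end"]):
            cur["end"] = max(cur["end"], int(row["end"]))
            cur["windows"].append(idx)
            cur["max"] = max(cur["max"], float(row[col]))
        else:
            if cur is not None:
                regions.append(BarrierRegion(cur["sequence"], cur["start"], cur["end"],
                                             tuple(cur["windows"]), cur["max"]))
            cur = dict(sequence=row["sequence"], start=int(row["start"]),
                       end=int(row["end"]), windows=[idx], max=float(row[col]))
    if cur is not None:
        regions.append(BarrierRegion(cur["sequence"], cur["start"], cur["end"],
                                     tuple(cur["windows"]), cur["max"]))
    return regions


def estimate_fpr(
    local_best: dict[str, float],
    grid: LikelihoodGrid,
    m_hat: float,
    t_hat: Optional[float],
    n_blocks: int,
    block_length: int,
    mu: float,
    r_bp: float,
    threshold_fraction: float = 0.0,
    n_reps: int = 100,
    seed: int = 1,
) -> float:
    """Per-window false positive rate by parametric simulation.

    Simulates ``n_reps`` replicate windows under the locally best-fitting
    population sizes with migration fixed at the global ``m_hat`` (and
    split time at ``t_hat``), using the window's recombination rate, and
    returns the fraction of replicates with Delta_B > 0 at the requested
    threshold.
    """
    from imscan.demography import DemographyParams
    from imscan.simulate import SimulationSpec, simulate_windows

    model = grid.spec.model
    kw = dict(model=model, N_A=local_best["N_A"], N_B=local_best["N_B"],
              mu=mu, block_length=block_length, m_e=m_hat)
    if model.has_split:
        kw.update(N_anc=local_best.get("N_anc", local_best["N_B"]), T=t_hat)
    params = DemographyParams(**kw)
    spec = SimulationSpec(params=params, n_windows=n_reps,
                          blocks_per_window=n_blocks, r_bp=r_bp,
                          kmax=grid.spec.kmax)
    tallies = simulate_windows(spec, seed=seed)
    gs = gridsearch(tallies, grid)
    m_star = resolve_threshold(threshold_fraction, m_hat, model)
    hits = sum(delta_b(gs.ln_cl[w], grid, m_hat, m_star) > 0
               for w in range(len(tallies)))
    return hits / float(n_reps)
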
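"""Exact folded bSFS probabilities via an augmented continuous-time Markov chain.

The lineage state graph (:mod:`imscan.engine.state_space`) is augmented
with one capped, sticky mutation counter per mutation type. A mutation on
a lineage of type ``t`` moves counter ``t`` up by one; counters saturate
at ``k_t + 1`` (the ">k" cell), where further mutations of that type no
longer change the state. Because the saturated cell is an absorbing
counter value, the folded probabilities obtained at the end are exact
marginals of the unfolded distribution, not residuals.

Internally all rates are expressed in coalescent units of ``2 N_ref``
generations (``N_ref`` defaults to ``N_A``); results are invariant to the
choice of ``N_ref``. The two-deme phase is advanced over ``[0, T]`` with
the action of the matrix exponential (scaling-and-squaring Taylor method
of :func:`scipy.sparse.linalg.expm_multiply`); the merged ancestral phase
— or the whole process for MIG models, which have no split — is an
absorbing phase-type solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from imscan.demography import DemographyParams, KmaxSpec, Model
from imscan.engine.state_space import StateGraph, enumerate_state_graph

_NORM_TOL = 1e-8


class EngineError(RuntimeError):
    """Raised when the linear-algebra phase fails or probabilities are invalid."""


@dataclass(frozen=True)
class BsfsPmf:
    """Folded probability array over all bSFS configurations, with provenance.

    ``probs[c_b, c_a, c_ab, c_fd]`` is the probability that a single
    non-recombining block carries exactly those folded mutation-type
    counts; the last index of each axis is the ">k" cell.
    """

    probs: np.ndarray
    params: DemographyParams
    kmax: KmaxSpec

    @property
    def total(self) -> float:
        return float(self.probs.sum())

    def log(self) -> np.ndarray:
        """Elementwise log-probabilities; cells with zero mass map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log(self.probs)


# ---------------------------------------------------------------------------
# structure templates, cached per (model, kmax)
# ---------------------------------------------------------------------------


class _PhaseTemplate:
    """Sparse-generator template for one phase of one model at one kmax."""

    def __init__(self, graph: StateGraph, cfg_indices: list[int], kmax: KmaxSpec,
                 kinds: tuple[str, ...]):
        self.kmax = kmax
        self.shape = kmax.shape
        self.C = int(np.prod(self.shape))
        self.local = {g: i for i, g in enumerate(cfg_indices)}
        self.cfg_indices = list(cfg_indices)
        self.n_cfg = len(cfg_indices)
        self.n_states = self.n_cfg * self.C

        # counter moves per axis (flat indices), computed once
        coords = np.indices(self.shape).reshape(4, -1)
        strides = np.array([int(np.prod(self.shape[a + 1:])) for a in range(4)])
        self._mut_src, self._mut_dst = [], []
        for a in range(4):
            movable = np.flatnonzero(coords[a] <= self.kmax.caps[a])
            self._mut_src.append(movable)
            self._mut_dst.append(movable + strides[a])

        cfg_set = set(cfg_indices)
        rows, cols, kind_id, mult = [], [], [], []
        arangeC = np.arange(self.C)
        self._kind_names = kinds
        kind_code = {k: i for i, k in enumerate(kinds)}
        for tr in graph.transitions:
            if tr.src not in cfg_set or tr.dst not in cfg_set:
                continue
            if tr.kind == "split":
                continue
            name = tr.kind if tr.kind == "migration" else f"coal_{tr.deme}"
            if name not in kind_code:
                continue
            s, d = self.local[tr.src], self.local[tr.dst]
            rows.append(s * self.C + arangeC)
            cols.append(d * self.C + arangeC)
            kind_id.append(np.full(self.C, kind_code[name], dtype=np.int8))
            mult.append(np.full(self.C, float(tr.multiplicity)))
        mut_code = kind_code["mutation"]
        for g in cfg_indices:
            s = self.local[g]
            counts = graph.configs[g].type_counts()
            for a in range(4):
                if counts[a] == 0:
                    continue
                rows.append(s * self.C + self._mut_src[a])
                cols.append(s * self.C + self._mut_dst[a])
                kind_id.append(np.full(len(self._mut_src[a]), mut_code, dtype=np.int8))
                mult.append(np.full(len(self._mut_src[a]), float(counts[a])))
        self.rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
        self.cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
        self.kind_id = np.concatenate(kind_id) if kind_id else np.empty(0, dtype=np.int8)
        self.mult = np.concatenate(mult) if mult else np.empty(0)

    def generator(self, rate_by_kind: dict[str, float]) -> sp.csr_matrix:
        rates = np.array([rate_by_kind[k] for k in self._kind_names])
        data = self.mult * rates[self.kind_id]
        Q = sp.coo_matrix((data, (self.rows, self.cols)),
                          shape=(self.n_states, self.n_states)).tocsr()
        Q.setdiag(Q.diagonal() - np.asarray(Q.sum(axis=1)).ravel())
        return Q


class _ModelTemplate:
    def __init__(self, model: Model, kmax: KmaxSpec):
        self.model = model
        self.kmax = kmax
        self.graph = enumerate_state_graph(model)
        if model.has_split:
            kinds1 = ("coal_0", "coal_1", "migration", "mutation")
            self.phase1 = _PhaseTemplate(self.graph, self.graph.structured, kmax, kinds1)
            self.phase2 = _PhaseTemplate(self.graph, self.graph.ancestral, kmax,
                                         ("coal_2", "mutation"))
            # split remap: structured local cfg -> ancestral local cfg
            remap = np.empty(self.phase1.n_cfg, dtype=np.int64)
            for g in self.graph.structured:
                a = self.graph.config_index(self.graph.configs[g].strip_demes())
                remap[self.phase1.local[g]] = self.phase2.local[a]
            self.split_map = remap
        else:
            kinds1 = ("coal_0", "coal_1", "migration", "mutation")
            self.phase1 = _PhaseTemplate(self.graph, self.graph.structured, kmax, kinds1)
            self.phase2 = None
            self.split_map = None


_TEMPLATES: dict[tuple[Model, tuple[int, ...]], _ModelTemplate] = {}


def _template(model: Model, kmax: KmaxSpec) -> _ModelTemplate:
    key = (model, kmax.caps)
    if key not in _TEMPLATES:
        _TEMPLATES[key] = _ModelTemplate(model, kmax)
    return _TEMPLATES[key]


# ---------------------------------------------------------------------------
# solves
# ---------------------------------------------------------------------------


def _absorption_pmf(tpl: _PhaseTemplate, graph: StateGraph, Q: sp.csr_matrix,
                    p0: np.ndarray) -> np.ndarray:
    """Distribution of counter states at absorption into the MRCA config(s)."""
    C = tpl.C
    mrca_local = [tpl.local[g] for g in tpl.cfg_indices if graph.configs[g].is_mrca]
    absorbing = np.zeros(tpl.n_states, dtype=bool)
    for s in mrca_local:
        absorbing[s * C:(s + 1) * C] = True
    trans = ~absorbing
    p_abs = p0[absorbing].reshape(len(mrca_local), C).sum(axis=0)
    p_t = p0[trans]
    if p_t.sum() > 1e-300:
        Qtt = Q[trans][:, trans]
        R = Q[trans][:, absorbing]
        try:
            x = spla.spsolve((-Qtt).T.tocsc(), p_t)
        except Exception as exc:  # pragma: no cover - surfaced, not truncated
            raise EngineError(f"phase-type absorption solve failed: {exc}") from exc
        if not np.all(np.isfinite(x)):
            raise EngineError("phase-type absorption solve produced non-finite values")
        h = R.T @ x
        p_abs = p_abs + np.asarray(h).ravel().reshape(len(mrca_local), C).sum(axis=0)
    return p_abs


def compute_bsfs_pmf(params: DemographyParams, kmax: KmaxSpec | None = None,
                     n_ref: float | None = None) -> BsfsPmf:
    """Exact folded bSFS probabilities for one heterospecific pair-block.

    Deterministic, non-Monte-Carlo; invariant to the internal reference
    size ``n_ref`` used for coalescent scaling.
    """
    kmax = kmax or KmaxSpec()
    model = params.model
    if model in (Model.MIG_AtoB, Model.MIG_BtoA) and params.effective_m <= 0:
        raise EngineError(
            "MIG model with m_e = 0 never reaches the common ancestor: "
            "migration must connect the demes toward the coalescing configuration")
    n_ref = float(n_ref if n_ref is not None else params.N_A)
    if not np.isfinite(n_ref) or n_ref <= 0:
        raise ValueError("n_ref must be finite and > 0")

    tpl = _template(model, kmax)
    # rates in units of 2*N_ref generations
    rates1 = {
        "coal_0": n_ref / params.N_A,
        "coal_1": n_ref / params.N_B,
        "migration": 2.0 * n_ref * params.effective_m,
        "mutation": 2.0 * n_ref * params.theta_per_lineage,
    }
    C = tpl.phase1.C
    p0 = np.zeros(tpl.phase1.n_states)
    p0[tpl.phase1.local[tpl.graph.initial] * C] = 1.0

    if model.has_split:
        tau = params.T / (2.0 * n_ref)
        if tau > 0:
            Q1 = tpl.phase1.generator(rates1)
            try:
                pT = spla.expm_multiply(Q1.T * tau, p0)
            except Exception as exc:  # pragma: no cover
                raise EngineError(f"matrix exponential failed: {exc}") from exc
            if not np.all(np.isfinite(pT)):
                raise EngineError("matrix exponential produced non-finite probabilities")
        else:
            pT = p0
        # instantaneous split remap into the merged ancestral deme
        p2 = np.zeros(tpl.phase2.n_states)
        blocks = pT.reshape(tpl.phase1.n_cfg, C)
        np.add.at(p2.reshape(tpl.phase2.n_cfg, C), tpl.split_map, blocks)
        rates2 = {"coal_2": n_ref / params.N_anc,
                  "mutation": rates1["mutation"]}
        Q2 = tpl.phase2.generator(rates2)
        pmf_flat = _absorption_pmf(tpl.phase2, tpl.graph, Q2, p2)
    else:
        Q1 = tpl.phase1.generator(rates1)
        pmf_flat = _absorption_pmf(tpl.phase1, tpl.graph, Q1, p0)

    probs = pmf_flat.reshape(kmax.shape)
    total = probs.sum()
    if not np.isfinite(total) or abs(total - 1.0) > _NORM_TOL:
        raise EngineError(f"bSFS pmf does not normalise: total = {total!r}")
    if probs.min() < -1e-10:
        raise EngineError(f"negative probability encountered: {probs.min()!r}")
    probs = np.clip(probs, 0.0, None)
    return BsfsPmf(probs=probs, params=params, kmax=kmax)
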
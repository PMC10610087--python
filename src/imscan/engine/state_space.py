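"""Enumeration of ancestral lineage configurations and their transitions.

A sample of two diploids (one from population A, one from B) consists of
four haplotypes: two "A-haplotypes" and two "B-haplotypes". An ancestral
lineage is summarised by the number of A- and B-haplotypes descending
from it, ``(i, j)``, together with the deme it currently occupies.
Haplotypes within an individual are exchangeable (the data are unphased),
so a configuration is a multiset of ``(i, j, deme)`` lineages.

Transitions are typed:

* ``coalescence`` — two lineages in the same deme merge (rate ``1/(2N)``
  per pair per generation, with the combinatorial pair count as the
  transition multiplicity);
* ``migration`` — one lineage moves from the backward source deme to the
  other deme (rate ``m_e`` per lineage per generation);
* ``split`` — the instantaneous remap of every lineage into the ancestral
  deme at time ``T`` (models with a split only).

The graph is finite; the absorbing state is the single most recent common
ancestor lineage ``(2, 2)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

from imscan.demography import BRANCH_TYPE, Model

#: deme codes: 0 = A, 1 = B, 2 = merged ancestral deme
DEME_A, DEME_B, DEME_ANC = 0, 1, 2


@dataclass(frozen=True)
class LineageConfig:
    """A multiset of ``(i, j, deme)`` ancestral lineages."""

    lineages: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lineages", tuple(sorted(self.lineages)))
        si = sum(l[0] for l in self.lineages)
        sj = sum(l[1] for l in self.lineages)
        if (si, sj) != (2, 2):
            raise ValueError("lineage descendant counts must sum to (2, 2)")
        if not 1 <= len(self.lineages) <= 4:
            raise ValueError("1-4 lineages required")

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)

    @property
    def is_mrca(self) -> bool:
        return len(self.lineages) == 1

    def type_counts(self) -> tuple[int, int, int, int]:
        """Number of lineages subtending each mutation type
        (het_b, het_a, het_ab, fixed_diff); the root branch is invisible."""
        counts = [0, 0, 0, 0]
        for i, j, _ in self.lineages:
            t = BRANCH_TYPE[(i, j)]
            if t >= 0:
                counts[t] += 1
        return tuple(counts)

    def strip_demes(self) -> "LineageConfig":
        return LineageConfig(tuple((i, j, DEME_ANC) for i, j, _ in self.lineages))


@dataclass(frozen=True)
class Transition:
    src: int
    dst: int
    kind: str            # "coalescence" | "migration" | "split"
    deme: Optional[int]  # deme of the coalescence / source deme of migration
    multiplicity: int    # combinatorial factor multiplying the per-event rate

    @property
    def rate_expression(self) -> str:
        if self.kind == "coalescence":
            deme = {DEME_A: "N_A", DEME_B: "N_B", DEME_ANC: "N_anc"}[self.deme]
            return f"{self.multiplicity} / (2 {deme})"
        if self.kind == "migration":
            return f"{self.multiplicity} m_e"
        return "instantaneous at T"


@dataclass
class StateGraph:
    """Typed transition graph over lineage configurations for one model."""

    model: Model
    configs: list[LineageConfig]
    transitions: list[Transition]
    initial: int
    absorbing: list[int]
    #: indices of configs belonging to the two-deme (structured) phase
    structured: list[int] = field(default_factory=list)
    #: indices of configs belonging to the merged ancestral phase
    ancestral: list[int] = field(default_factory=list)

    def config_index(self, cfg: LineageConfig) -> int:
        return self._index[cfg]

    def __post_init__(self) -> None:
        self._index = {cfg: i for i, cfg in enumerate(self.configs)}


def _coalescence_targets(cfg: LineageConfig) -> list[tuple[LineageConfig, int, int]]:
    """All distinct coalescence outcomes: (new config, deme, pair multiplicity)."""
    out: dict[tuple[LineageConfig, int], int] = {}
    lineages = cfg.lineages
    for a, b in itertools.combinations(range(len(lineages)), 2):
        ia, ja, da = lineages[a]
        ib, jb, db = lineages[b]
        if da != db:
            continue
        merged = list(lineages)
        merged[a] = (ia + ib, ja + jb, da)
        del merged[b]
        key = (LineageConfig(tuple(merged)), da)
        out[key] = out.get(key, 0) + 1
    return [(new, deme, mult) for (new, deme), mult in out.items()]


def _migration_targets(cfg: LineageConfig, source: int) -> list[tuple[LineageConfig, int]]:
    """Distinct single-lineage moves out of `source`: (new config, multiplicity)."""
    out: dict[LineageConfig, int] = {}
    dest = DEME_B if source == DEME_A else DEME_A
    for idx, (i, j, d) in enumerate(cfg.lineages):
        if d != source:
            continue
        moved = list(cfg.lineages)
        moved[idx] = (i, j, dest)
        new = LineageConfig(tuple(moved))
        out[new] = out.get(new, 0) + 1
    return list(out.items())


def initial_config() -> LineageConfig:
    """Sampling configuration: two (1,0) lineages in A, two (0,1) in B."""
    return LineageConfig(((1, 0, DEME_A), (1, 0, DEME_A), (0, 1, DEME_B), (0, 1, DEME_B)))


def enumerate_state_graph(model: Model | str) -> StateGraph:
    """Breadth-first construction of the full typed state graph for `model`."""
    model = Model(model)
    src_deme = {"A": DEME_A, "B": DEME_B, None: None}[model.backward_source_deme]

    configs: list[LineageConfig] = []
    index: dict[LineageConfig, int] = {}
    transitions: list[Transition] = []

    def add(cfg: LineageConfig) -> int:
        if cfg not in index:
            index[cfg] = len(configs)
            configs.append(cfg)
        return index[cfg]

    # --- structured (two-deme) phase -------------------------------------
    start = add(initial_config())
    frontier = [start]
    seen = {start}
    while frontier:
        nxt: list[int] = []
        for s in frontier:
            cfg = configs[s]
            if cfg.is_mrca:
                continue  # treated as absorbing: no further typed transitions
            moves: list[Transition] = []
            for new, deme, mult in _coalescence_targets(cfg):
                moves.append(Transition(s, add(new), "coalescence", deme, mult))
            if model.has_migration and src_deme is not None:
                for new, mult in _migration_targets(cfg, src_deme):
                    moves.append(Transition(s, add(new), "migration", src_deme, mult))
            for tr in moves:
                transitions.append(tr)
                if tr.dst not in seen:
                    seen.add(tr.dst)
                    nxt.append(tr.dst)
        frontier = nxt
    structured = list(range(len(configs)))

    ancestral: list[int] = []
    if model.has_split:
        # --- split remap + ancestral single-deme phase --------------------
        for s in list(structured):
            a = add(configs[s].strip_demes())
            transitions.append(Transition(s, a, "split", None, 1))
            if a not in ancestral and a >= len(structured):
                ancestral.append(a)
        frontier = list(ancestral)
        seen_a = set(ancestral)
        while frontier:
            nxt = []
            for s in frontier:
                cfg = configs[s]
                if cfg.is_mrca:
                    continue
                for new, deme, mult in _coalescence_targets(cfg):
                    tr = Transition(s, add(new), "coalescence", deme, mult)
                    transitions.append(tr)
                    if tr.dst not in seen_a and tr.dst >= len(structured):
                        seen_a.add(tr.dst)
                        nxt.append(tr.dst)
            frontier = nxt
        ancestral = sorted(seen_a)

    absorbing = [i for i, c in enumerate(configs) if c.is_mrca]
    if model.has_split:
        absorbing = [i for i in absorbing if i in set(ancestral)]
        # structured-phase MRCA states remap to the ancestral MRCA via split;
        # they carry no further events either way.
    graph = StateGraph(
        model=model,
        configs=configs,
        transitions=transitions,
        initial=start,
        absorbing=absorbing,
        structured=structured,
        ancestral=ancestral,
    )
    return graph


def absorption_reachable(graph: StateGraph) -> bool:
    """True iff every config reachable from the start can reach an MRCA.

    Under MIG models absorption is only guaranteed when migration connects
    the demes toward the coalescing configuration (e.g. ``m_e > 0``); the
    caller uses this check to fail loudly instead of hanging.
    """
    fwd: dict[int, set[int]] = {}
    for tr in graph.transitions:
        fwd.setdefault(tr.src, set()).add(tr.dst)
    # backwards reachability from MRCA states (any deme)
    rev: dict[int, set[int]] = {}
    for tr in graph.transitions:
        rev.setdefault(tr.dst, set()).add(tr.src)
    targets = [i for i, c in enumerate(graph.configs) if c.is_mrca]
    can_reach = set(targets)
    stack = list(targets)
    while stack:
        s = stack.pop()
        for p in rev.get(s, ()):
            if p not in can_reach:
                can_reach.add(p)
                stack.append(p)
    # forward closure from the initial state
    seen = {graph.initial}
    stack = [graph.initial]
    while stack:
        s = stack.pop()
        for d in fwd.get(s, ()):
            if d not in seen:
                seen.add(d)
                stack.append(d)
    return seen <= can_reach
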
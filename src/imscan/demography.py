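"""Demographic models and parameter containers.

The framework considers a pair of populations/species A and B under three
nested demographic histories:

* ``DIV`` — strict divergence: A and B split from a common ancestor ``T``
  generations ago and exchange no migrants.
* ``MIG`` — migration only: the two populations are infinitely old
  (no split event) and exchange migrants at a constant per-generation
  probability ``m_e``.
* ``IM`` — isolation with migration: a split ``T`` generations ago plus
  constant unidirectional migration at rate ``m_e`` since the split.

Direction convention: ``AtoB`` means gene flow from A into B *forwards in
time*; backwards in time, lineages sampled in B may trace back into A via
migration at rate ``m_e`` per generation.

All population sizes are numbers of diploid individuals, so a pair of
lineages in a population of size ``N`` coalesces at rate ``1/(2N)`` per
generation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional


class Model(str, enum.Enum):
    """Supported demographic histories."""

    DIV = "DIV"
    MIG_AtoB = "MIG_AtoB"
    MIG_BtoA = "MIG_BtoA"
    IM_AtoB = "IM_AtoB"
    IM_BtoA = "IM_BtoA"

    @property
    def has_split(self) -> bool:
        return self in (Model.DIV, Model.IM_AtoB, Model.IM_BtoA)

    @property
    def has_migration(self) -> bool:
        return self is not Model.DIV

    @property
    def backward_source_deme(self) -> Optional[str]:
        """Deme whose lineages migrate, backwards in time.

        Forwards-in-time gene flow A->B means lineages currently in B may
        trace back to A, i.e. the backward migration source is B.
        """
        if self in (Model.MIG_AtoB, Model.IM_AtoB):
            return "B"
        if self in (Model.MIG_BtoA, Model.IM_BtoA):
            return "A"
        return None


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class DemographyParams:
    """The five IM parameters plus mutation rate and block length.

    Parameters
    ----------
    model:
        One of the five supported demographic histories.
    N_A, N_B, N_anc:
        Effective sizes in diploid individuals. ``N_anc`` is ignored for
        MIG models (no ancestral population) but must still be positive
        when given.
    T:
        Split time in generations; required for DIV/IM, must be ``None``
        for MIG models.
    m_e:
        Per-generation migration probability; required for MIG/IM models,
        must be ``None`` (or 0) for DIV.
    mu:
        Mutation rate per base pair per generation.
    block_length:
        Number of callable sites per block (bp); mutations accumulate on a
        lineage at rate ``mu * block_length``.
    """

    model: Model
    N_A: float
    N_B: float
    N_anc: Optional[float] = None
    T: Optional[float] = None
    m_e: Optional[float] = None
    mu: float = 0.0
    block_length: int = 64

    def __post_init__(self) -> None:
        model = Model(self.model)
        object.__setattr__(self, "model", model)
        for name in ("N_A", "N_B"):
            v = getattr(self, name)
            _require(v is not None and math.isfinite(v) and v > 0, f"{name} must be finite and > 0")
        if model.has_split:
            _require(self.N_anc is not None and math.isfinite(self.N_anc) and self.N_anc > 0,
                     "N_anc must be finite and > 0 for models with a split")
            _require(self.T is not None and math.isfinite(self.T) and self.T >= 0,
                     "T must be finite and >= 0 for models with a split")
        else:
            _require(self.T is None, "MIG models have no split time T")
        if model.has_migration:
            _require(self.m_e is not None and math.isfinite(self.m_e) and self.m_e >= 0,
                     "m_e must be finite and >= 0 for models with migration")
        else:
            _require(self.m_e in (None, 0, 0.0), "DIV has no migration rate")
        _require(math.isfinite(self.mu) and self.mu >= 0, "mu must be finite and >= 0")
        _require(self.block_length >= 1, "block_length must be >= 1")

    @property
    def effective_m(self) -> float:
        return 0.0 if self.m_e is None else float(self.m_e)

    @property
    def theta_per_lineage(self) -> float:
        """Per-lineage, per-generation mutation rate over the block."""
        return self.mu * self.block_length

    def with_(self, **kwargs) -> "DemographyParams":
        return replace(self, **kwargs)

    # ------------------------------------------------------------------
    # Interop with the simulation ecosystem
    # ------------------------------------------------------------------
    def to_demes(self):
        """Export as a :class:`demes.Graph` (MIG models use a deep-rooted split)."""
        import demes

        b = demes.Builder(time_units="generations")
        if self.model.has_split:
            t_split = max(float(self.T), 1e-9)
            n_anc = float(self.N_anc)
        else:
            # no split event: approximate infinite divergence with a root
            # far deeper than any coalescence time scale in the model
            t_split = 1e4 * 4.0 * max(self.N_A, self.N_B)
            n_anc = float(max(self.N_A, self.N_B))
        b.add_deme("anc", epochs=[dict(start_size=n_anc, end_time=t_split)])
        b.add_deme("A", ancestors=["anc"], epochs=[dict(start_size=float(self.N_A))])
        b.add_deme("B", ancestors=["anc"], epochs=[dict(start_size=float(self.N_B))])
        if self.model.has_migration and self.effective_m > 0:
            if self.model.backward_source_deme == "B":
                src, dst = "A", "B"  # forwards-in-time direction for demes
            else:
                src, dst = "B", "A"
            b.add_migration(source=src, dest=dst, rate=self.effective_m)
        return b.resolve()

    def to_msprime(self):
        """Export as an :class:`msprime.Demography`."""
        import msprime

        return msprime.Demography.from_demes(self.to_demes())


@dataclass(frozen=True)
class KmaxSpec:
    """Per-mutation-type caps for folding the bSFS.

    Each folded axis has cells ``{0, 1, ..., k, ">k"}``, i.e. ``k + 2``
    cells; mutation counts above ``k`` all land in the ``">k"`` cell.
    Axis order is ``(het_b, het_a, het_ab, fixed_diff)`` throughout.
    """

    k_b: int = 2
    k_a: int = 2
    k_ab: int = 2
    k_fd: int = 2

    def __post_init__(self) -> None:
        for name in ("k_b", "k_a", "k_ab", "k_fd"):
            _require(int(getattr(self, name)) >= 0, f"{name} must be >= 0")
            object.__setattr__(self, name, int(getattr(self, name)))

    @property
    def caps(self) -> tuple[int, int, int, int]:
        return (self.k_b, self.k_a, self.k_ab, self.k_fd)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(k + 2 for k in self.caps)

    @classmethod
    def parse(cls, text: str) -> "KmaxSpec":
        parts = [int(p) for p in str(text).replace(" ", "").split(",")]
        if len(parts) != 4:
            raise ValueError("kmax must have four comma-separated values")
        return cls(*parts)


#: Axis order of every folded bSFS array in the package.
MUTATION_AXES = ("het_b", "het_a", "het_ab", "fixed_diff")

#: Index into MUTATION_AXES for a branch with (i, j) descendants, or -1 if
#: mutations on that branch are invisible (the root branch (2, 2)).
BRANCH_TYPE = {
    (0, 1): 0, (2, 1): 0,   # het_b
    (1, 0): 1, (1, 2): 1,   # het_a
    (1, 1): 2,              # het_ab
    (2, 0): 3, (0, 2): 3,   # fixed_diff
    (2, 2): -1,
}
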
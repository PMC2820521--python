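"""Mass-action reaction networks built from two reaction forms.

Every reaction in the model is either a bimolecular binding reaction

    A + B  <->  AB          (forward kf, backward kb)

or an enzymatic reaction expressed as its two elementary steps

    E + S  <->  ES  ->  E + P   (kf, kb, kcat)

The Michaelis–Menten rate law is deliberately not used: enzymatic
reactions are always integrated as the two elementary mass-action steps,
so no quasi-steady-state assumption enters the dynamics.

Units are micromolar (µM) and seconds throughout; the spine is treated
as a homogeneous volume so concentrations are the state variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import sympy

__all__ = [
    "Species",
    "BindingReaction",
    "EnzymaticReaction",
    "ReactionNetwork",
    "NetworkError",
    "rate_constants_from_kd_tau",
    "rate_constants_from_km_kcat",
    "assemble_rhs",
    "conserved_moieties",
]


class NetworkError(ValueError):
    """Structural problem in a reaction network definition."""


ClampValue = float | Callable[[float], float]


@dataclass
class Species:
    """A molecular state of the spine model.

    Parameters
    ----------
    name : str
        Unique identifier within a network.
    initial_conc : float
        Initial concentration in µM; must be non-negative.
    clamped : bool
        If True the species' derivative is zero and its value is imposed
        externally (a constant or a waveform of time). Clamped species
        still participate as reactants, which is how input baths
        (calcium, dopamine, ATP) and knockout/fixation experiments are
        represented.
    clamp_value : float or callable, optional
        Imposed concentration, or a function ``t -> µM``. Defaults to
        ``initial_conc`` when the species is clamped.
    moieties : dict
        Elemental composition in protein moieties, e.g. the
        CaMKII–calmodulin complex is ``{"CaMKII": 1, "CaM": 1}``. Used
        for total-protein conservation bookkeeping and knockouts.
    """

    name: str
    initial_conc: float
    clamped: bool = False
    clamp_value: ClampValue | None = None
    moieties: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.initial_conc < 0:
            raise NetworkError(
                f"species {self.name!r}: initial_conc must be >= 0, "
                f"got {self.initial_conc}"
            )
        if self.clamped and self.clamp_value is None:
            self.clamp_value = self.initial_conc
        if not self.moieties:
            self.moieties = {self.name: 1}


@dataclass
class BindingReaction:
    """A + B <-> AB with mass-action kinetics.

    ``kf`` is in µM⁻¹ s⁻¹, ``kb`` in s⁻¹; the dissociation constant is
    Kd = kb/kf.
    """

    a: str
    b: str
    ab: str
    kf: float
    kb: float
    label: str = ""
    param_id: str = ""

    def __post_init__(self) -> None:
        if len({self.a, self.b, self.ab}) != 3:
            raise NetworkError(
                f"binding reaction {self.label or self.ab}: species "
                f"{self.a}, {self.b}, {self.ab} must be distinct"
            )
        if self.kf <= 0 or self.kb < 0:
            raise NetworkError(
                f"binding reaction {self.label or self.ab}: need kf > 0 "
                f"and kb >= 0 (got kf={self.kf}, kb={self.kb})"
            )

    @property
    def kd(self) -> float:
        return self.kb / self.kf

    def species_names(self) -> tuple[str, ...]:
        return (self.a, self.b, self.ab)


@dataclass
class EnzymaticReaction:
    """E + S <-> ES -> E + P as two elementary mass-action steps."""

    enzyme: str
    substrate: str
    complex_es: str
    product: str
    kf: float
    kb: float
    kcat: float
    label: str = ""
    param_id: str = ""

    def __post_init__(self) -> None:
        if self.kf <= 0 or self.kcat <= 0 or self.kb < 0:
            raise NetworkError(
                f"enzymatic reaction {self.label or self.complex_es}: need "
                f"kf, kcat > 0 and kb >= 0 (got kf={self.kf}, kb={self.kb}, "
                f"kcat={self.kcat})"
            )

    @property
    def km(self) -> float:
        return (self.kb + self.kcat) / self.kf

    def species_names(self) -> tuple[str, ...]:
        return (self.enzyme, self.substrate, self.complex_es, self.product)


Reaction = BindingReaction | EnzymaticReaction


def rate_constants_from_kd_tau(kd: float, tau: float) -> tuple[float, float]:
    """Convert a (dissociation constant, time constant) pair to (kf, kb).

    The convention is kb = 1/τ and kf = kb/Kd, so that Kd = kb/kf holds
    exactly and τ sets the relaxation time of the unbinding step.
    """
    if kd <= 0 or tau <= 0:
        raise ValueError(f"kd and tau must be positive (got kd={kd}, tau={tau})")
    kb = 1.0 / tau
    return kb / kd, kb


def rate_constants_from_km_kcat(km: float, kcat: float) -> tuple[float, float, float]:
    """Convert (Km, kcat) to elementary constants (kf, kb, kcat).

    Databases frequently report only the Michaelis constant and the
    catalytic constant. The elementary constants are fixed by taking the
    unbinding rate four times the catalytic rate, kb = 4·kcat, following
    the default convention of the GENESIS/Kinetikit simulator, and
    kf = (kb + kcat)/Km so that Km = (kb + kcat)/kf holds exactly.
    """
    if km <= 0 or kcat <= 0:
        raise ValueError(f"km and kcat must be positive (got km={km}, kcat={kcat})")
    kb = 4.0 * kcat
    kf = (kb + kcat) / km
    return kf, kb, kcat


class ReactionNetwork:
    """Species + reactions, with derived stoichiometric structure.

    The network is immutable once built; experiment helpers produce
    modified copies (see :meth:`copy_with`).
    """

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction],
                 name: str = "network"):
        names = [s.name for s in species]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise NetworkError(f"duplicate species names: {sorted(dupes)}")
        self.name = name
        self.species = list(species)
        self.reactions = list(reactions)
        self.index = {s.name: i for i, s in enumerate(self.species)}
        for r in self.reactions:
            for n in r.species_names():
                if n not in self.index:
                    raise NetworkError(
                        f"reaction {r.label or r!r} references unknown species {n!r}"
                    )
        self._build_steps()

    # -- structural assembly -------------------------------------------------

    def _build_steps(self) -> None:
        """Decompose reactions into irreversible elementary steps.

        Each step has a rate k·[i] or k·[i]·[j]; the stoichiometric
        matrix S maps step fluxes to species derivatives.
        """
        n = len(self.species)
        cols: list[np.ndarray] = []
        k_list: list[float] = []
        ri: list[int] = []
        rj: list[int] = []

        def add_step(k: float, i: int, j: int,
                     delta: list[tuple[int, int]]) -> None:
            col = np.zeros(n)
            for s_ix, w in delta:  # pairs accumulate (autocatalysis: i == j)
                col[s_ix] += w
            cols.append(col)
            k_list.append(k)
            ri.append(i)
            rj.append(j)

        ix = self.index
        for r in self.reactions:
            if isinstance(r, BindingReaction):
                a, b, ab = ix[r.a], ix[r.b], ix[r.ab]
                add_step(r.kf, a, b, [(a, -1), (b, -1), (ab, +1)])
                add_step(r.kb, ab, -1, [(a, +1), (b, +1), (ab, -1)])
            else:
                e, s, es, p = (ix[r.enzyme], ix[r.substrate],
                               ix[r.complex_es], ix[r.product])
                add_step(r.kf, e, s, [(e, -1), (s, -1), (es, +1)])
                add_step(r.kb, es, -1, [(e, +1), (s, +1), (es, -1)])
                add_step(r.kcat, es, -1, [(e, +1), (p, +1), (es, -1)])

        self._S = np.array(cols).T if cols else np.zeros((n, 0))
        self._k = np.array(k_list)
        self._ri = np.array(ri, dtype=int)
        self._rj = np.array(rj, dtype=int)
        self._clamped_idx = np.array(
            [i for i, s in enumerate(self.species) if s.clamped], dtype=int
        )

    # -- public structure ----------------------------------------------------

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        """Species × elementary-step stoichiometric matrix."""
        return self._S.copy()

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def clamped_names(self) -> list[str]:
        return [s.name for s in self.species if s.clamped]

    def initial_state(self) -> np.ndarray:
        y0 = np.array([s.initial_conc for s in self.species], float)
        for i in self._clamped_idx:
            cv = self.species[i].clamp_value
            y0[i] = cv(0.0) if callable(cv) else cv
        return y0

    def species_by_moiety(self, protein: str) -> list[str]:
        """All species whose composition contains the given protein."""
        return [s.name for s in self.species if s.moieties.get(protein, 0) > 0]

    def moiety_weights(self, protein: str) -> np.ndarray:
        return np.array([s.moieties.get(protein, 0) for s in self.species], float)

    def copy_with(self, species: Sequence[Species] | None = None,
                  reactions: Sequence[Reaction] | None = None,
                  name: str | None = None) -> "ReactionNetwork":
        return ReactionNetwork(
            species if species is not None else [
                Species(s.name, s.initial_conc, s.clamped, s.clamp_value,
                        dict(s.moieties)) for s in self.species
            ],
            reactions if reactions is not None else list(self.reactions),
            name if name is not None else self.name,
        )

    # -- dynamics ------------------------------------------------------------

    def _apply_clamps(self, t: float, y: np.ndarray) -> np.ndarray:
        if self._clamped_idx.size == 0:
            return y
        ye = y.copy()
        for i in self._clamped_idx:
            cv = self.species[i].clamp_value
            ye[i] = cv(t) if callable(cv) else cv
        return ye

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        ye = self._apply_clamps(t, y)
        flux = self._k * ye[self._ri]
        has_j = self._rj >= 0
        flux[has_j] *= ye[self._rj[has_j]]
        dy = self._S @ flux
        dy[self._clamped_idx] = 0.0
        return dy

    def jacobian(self, t: float, y: np.ndarray) -> np.ndarray:
        ye = self._apply_clamps(t, y)
        n, m = self._S.shape
        dv = np.zeros((m, n))
        rows = np.arange(m)
        has_j = self._rj >= 0
        # d flux / d y[i]
        fi = self._k.copy()
        fi[has_j] *= ye[self._rj[has_j]]
        np.add.at(dv, (rows, self._ri), fi)
        # d flux / d y[j]
        fj = self._k[has_j] * ye[self._ri[has_j]]
        np.add.at(dv, (rows[has_j], self._rj[has_j]), fj)
        J = self._S @ dv
        J[self._clamped_idx, :] = 0.0
        J[:, self._clamped_idx] = 0.0
        return J


def assemble_rhs(network: ReactionNetwork):
    """Return ``(rhs, jac)`` callables ``f(t, y)`` for the network ODEs.

    Clamped species have zero derivative; their externally imposed value
    (constant or waveform) is substituted before fluxes are evaluated,
    so they still drive the reactions they take part in.
    """
    return network.rhs, network.jacobian


def _integerize(vec: list[Fraction]) -> np.ndarray:
    dens = [f.denominator for f in vec]
    lcm = 1
    for d in dens:
        lcm = lcm * d // np.gcd(lcm, d)
    ints = np.array([int(f * lcm) for f in vec], dtype=object)
    g = 0
    for v in ints:
        g = np.gcd(g, abs(int(v)))
    if g > 1:
        ints = ints // g
    out = ints.astype(float)
    if (out <= 0).all() and (out < 0).any():
        out = -out
    return out


def conserved_moieties(network: ReactionNetwork,
                       include_clamped: bool = False) -> list[dict[str, float]]:
    """Basis of conservation laws (left null space of the stoichiometry).

    Clamped species act as external baths, so by default laws are
    restricted to have zero weight on them (a weighted sum touching a
    bath is not conserved along trajectories). Weights are scaled to
    integers.
    """
    S = network.stoichiometric_matrix
    free = [i for i, s in enumerate(network.species)
            if include_clamped or not s.clamped]
    Sf = S[free, :]

    chosen: list[np.ndarray] = []
    laws: list[dict[str, float]] = []

    def rank_of(vectors) -> int:
        return np.linalg.matrix_rank(np.array(vectors)) if vectors else 0

    def try_add(w: np.ndarray) -> bool:
        if not np.any(w):
            return False
        if np.abs(w @ Sf).max() != 0.0:
            return False
        if rank_of(chosen + [w]) == rank_of(chosen):
            return False
        chosen.append(w)
        laws.append({network.species[free[i]].name: float(w[i])
                     for i in range(len(free)) if w[i] != 0})
        return True

    # prefer moiety-aligned laws (total protein sums) where they are
    # genuinely conserved
    moieties = sorted({m for s in network.species for m in s.moieties})
    for m in moieties:
        w = np.array([network.species[i].moieties.get(m, 0) for i in free],
                     float)
        try_add(w)

    # complete the basis from the exact left null space
    M = sympy.Matrix(Sf.T.astype(object))
    for vec in M.nullspace():
        fracs = [Fraction(sympy.Rational(x)) for x in vec]
        try_add(_integerize(fracs))
    return laws


def law_value(network: ReactionNetwork, law: dict[str, float],
              y: np.ndarray) -> float:
    return float(sum(w * y[network.index[n]] for n, w in law.items()))
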
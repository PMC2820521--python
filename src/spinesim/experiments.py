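"""In-silico experiments on the spine network.

The battery mirrors the standard protocol: equilibrate the network
under basal calcium and dopamine, apply pulsed inputs, and read out
synaptic efficacy as the number of AMPA receptors in the post-synaptic
membrane (anchored pool), summarized as the ratio of membrane receptors
10 minutes after stimulation onset to the pre-stimulus level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .reaction_core import NetworkError, ReactionNetwork, Species
from .striatal_model import ACTIVITY_REMOVE, ACTIVITY_SPECIES, MEMBRANE_SPECIES
from .stimulus import (
    CalciumProtocol,
    DopamineProtocol,
    calcium_waveform,
    dopamine_waveform,
)

__all__ = [
    "TimeCourse",
    "PlasticityResult",
    "PlasticityMap",
    "pre_equilibrate",
    "run",
    "plasticity_ratio",
    "clamp_experiment",
    "plasticity_map",
    "timing_experiment",
    "membrane_ampar",
]

#: Default stiff-solver tolerances (µM scale).
RTOL = 1e-8
ATOL = 1e-12


@dataclass
class TimeCourse:
    """A simulated trajectory: time grid (s) × species concentrations (µM)."""

    t: np.ndarray
    y: np.ndarray  # shape (n_times, n_species)
    names: list[str]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.y[:, self.names.index(name)]

    def total(self, names: Iterable[str]) -> np.ndarray:
        return sum(self[n] for n in names)


@dataclass
class PlasticityResult:
    """Post/pre membrane AMPA receptor ratio (LTP > 1 > LTD)."""

    ratio: float
    eval_time: float
    pre_value: float
    post_value: float


@dataclass
class PlasticityMap:
    """Plasticity ratio over a grid of calcium × dopamine amplitudes."""

    ca_amplitudes: np.ndarray
    da_amplitudes: np.ndarray
    ratio: np.ndarray  # shape (n_ca, n_da)
    meta: dict = field(default_factory=dict)


def membrane_ampar(tc: TimeCourse) -> np.ndarray:
    """Membrane-inserted AMPA receptor concentration along a trajectory."""
    return tc.total(MEMBRANE_SPECIES)


def _with_constant_inputs(network: ReactionNetwork, basal_ca: float,
                          basal_da: float) -> ReactionNetwork:
    species = []
    for s in network.species:
        if s.name == "Ca" and s.clamped:
            species.append(Species("Ca", basal_ca, True, basal_ca, dict(s.moieties)))
        elif s.name == "DA" and s.clamped:
            species.append(Species("DA", basal_da, True, basal_da, dict(s.moieties)))
        else:
            species.append(Species(s.name, s.initial_conc, s.clamped,
                                   s.clamp_value, dict(s.moieties)))
    return network.copy_with(species=species)


def pre_equilibrate(network: ReactionNetwork, basal_ca: float = 0.06,
                    basal_da: float = 0.01, tol: float = 1e-9,
                    chunk: float = 500.0, t_max: float = 40000.0,
                    rtol: float = RTOL, atol: float = ATOL) -> np.ndarray:
    """Relax the network to its resting state under constant basal inputs.

    Integrates in chunks until the largest derivative of any free
    species falls below ``tol`` (µM/s). Raises if the cap ``t_max`` is
    reached without settling.
    """
    if basal_ca < 0 or basal_da < 0:
        raise ValueError("basal levels must be non-negative")
    net = _with_constant_inputs(network, basal_ca, basal_da)
    y = net.initial_state()
    t = 0.0
    while t < t_max:
        sol = solve_ivp(net.rhs, (0.0, chunk), y, method="LSODA",
                        jac=net.jacobian, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"equilibration solver failed: {sol.message}")
        y = sol.y[:, -1]
        t += chunk
        resid = np.max(np.abs(net.rhs(0.0, y)))
        if resid < tol:
            return y
    raise RuntimeError(
        f"failed to settle within {t_max} s; residual {resid:.3e} µM/s"
    )


def _segment_times(windows: Sequence[tuple[float, float]], t_end: float
                   ) -> list[tuple[float, float, float | None]]:
    """Split [0, t_end] into (start, stop, max_step) integration segments.

    Stimulus-active windows get a bounded step so the solver cannot leap
    over a 10-ms spike; quiescent gaps are left to the step controller.
    """
    events = sorted(set(
        [0.0, t_end] + [max(0.0, min(t_end, e)) for w in windows for e in w]
    ))
    merged: list[tuple[float, float]] = []
    for a, b in windows:
        a, b = max(0.0, a), min(t_end, b)
        if b <= a:
            continue
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    segs: list[tuple[float, float, float | None]] = []
    cursor = 0.0
    for a, b in merged:
        if a > cursor:
            segs.append((cursor, a, None))
        segs.append((a, b, 0.005))
        cursor = b
    if cursor < t_end:
        segs.append((cursor, t_end, None))
    return segs


def run(network: ReactionNetwork,
        calcium_protocol: CalciumProtocol | None = None,
        dopamine_protocol: DopamineProtocol | None = None,
        t_end: float = 600.0, y0: np.ndarray | None = None,
        n_out: int = 601, rtol: float = RTOL, atol: float = ATOL,
        equilibrate: bool = True) -> TimeCourse:
    """Integrate the network under pulsed calcium/dopamine input.

    The starting state is the resting state under the protocols' basal
    levels (computed here unless ``y0`` is given). Input species are
    forced as time-dependent clamps.
    """
    ca = calcium_protocol or CalciumProtocol(ca_amp=0.0)
    da = dopamine_protocol or DopamineProtocol(da_amp=0.0)
    if y0 is None and equilibrate:
        y0 = pre_equilibrate(network, ca.ca_basal, da.da_basal,
                             rtol=rtol, atol=atol)
    species = []
    for s in network.species:
        if s.name == "Ca" and s.clamped:
            species.append(Species("Ca", ca.ca_basal, True,
                                   (lambda t, p=ca: calcium_waveform(t, p)),
                                   dict(s.moieties)))
        elif s.name == "DA" and s.clamped:
            species.append(Species("DA", da.da_basal, True,
                                   (lambda t, p=da: dopamine_waveform(t, p)),
                                   dict(s.moieties)))
        else:
            species.append(Species(s.name, s.initial_conc, s.clamped,
                                   s.clamp_value, dict(s.moieties)))
    net = network.copy_with(species=species)
    if y0 is None:
        y0 = net.initial_state()

    windows = []
    if ca.ca_amp > 0:
        windows += ca.active_windows()
    if da.da_amp > 0:
        windows += da.active_windows()
    segs = _segment_times(windows, t_end)

    t_eval = np.linspace(0.0, t_end, n_out)
    ts: list[np.ndarray] = [np.array([0.0])]
    ys: list[np.ndarray] = [np.asarray(y0, float)[:, None]]
    y = np.asarray(y0, float)
    for a, b, max_step in segs:
        grid = t_eval[(t_eval > a) & (t_eval <= b)]
        pts = np.unique(np.concatenate([grid, [b]]))
        kwargs = {} if max_step is None else {"max_step": max_step}
        sol = solve_ivp(net.rhs, (a, b), y, method="LSODA", jac=net.jacobian,
                        rtol=rtol, atol=atol, t_eval=pts, **kwargs)
        if not sol.success:
            raise RuntimeError(
                f"solver failed at t={sol.t[-1] if sol.t.size else a:.2f}s: "
                f"{sol.message}"
            )
        y = sol.y[:, -1]
        keep = np.isin(sol.t, grid)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1).T
    # report forced inputs at their imposed values
    y_all[:, net.index["Ca"]] = calcium_waveform(t_all, ca)
    y_all[:, net.index["DA"]] = dopamine_waveform(t_all, da)
    return TimeCourse(t=t_all, y=y_all, names=[s.name for s in net.species],
                      meta={"calcium": ca, "dopamine": da, "t_end": t_end,
                            "rtol": rtol, "atol": atol,
                            "network": network.name})


def plasticity_ratio(tc: TimeCourse, eval_time: float = 600.0) -> PlasticityResult:
    """Synaptic efficacy change: membrane AMPAR at eval_time over t=0."""
    if tc.t[-1] < eval_time:
        raise ValueError(f"trajectory ends at {tc.t[-1]} s < eval_time {eval_time} s")
    mem = membrane_ampar(tc)
    pre = float(mem[0])
    post = float(np.interp(eval_time, tc.t, mem))
    if pre <= 0:
        raise ValueError("pre-stimulus membrane pool is zero; ratio undefined")
    return PlasticityResult(ratio=post / pre, eval_time=eval_time,
                            pre_value=pre, post_value=post)


def clamp_experiment(network: ReactionNetwork,
                     species_to_fix: Sequence[str] | str,
                     basal_ca: float = 0.06, basal_da: float = 0.01,
                     state: np.ndarray | None = None) -> ReactionNetwork:
    """Fix the named active species at their resting (steady-state) levels.

    ``species_to_fix`` may be an activity name ("CaMKII", "PKA", "PP1")
    or an explicit list of species names. The clamped species keep
    acting as reactants/enzymes at the frozen concentration.
    """
    remove: tuple[str, ...] = ()
    if isinstance(species_to_fix, str):
        try:
            names = list(ACTIVITY_SPECIES[species_to_fix])
            remove = ACTIVITY_REMOVE.get(species_to_fix, ())
        except KeyError:
            names = [species_to_fix]
    else:
        names = list(species_to_fix)
    for n in names:
        if n not in network.index:
            raise NetworkError(f"unknown species {n!r}")
    if state is None:
        state = pre_equilibrate(network, basal_ca, basal_da)
    species = []
    for i, s in enumerate(network.species):
        if s.name in names:
            v = float(state[i])
            species.append(Species(s.name, v, True, v, dict(s.moieties)))
        else:
            species.append(Species(s.name, s.initial_conc, s.clamped,
                                   s.clamp_value, dict(s.moieties)))
    reactions = [r for r in network.reactions if r.label not in set(remove)]
    return network.copy_with(species=species, reactions=reactions,
                             name=f"{network.name}_fix_{'_'.join(names)}")


def plasticity_map(network: ReactionNetwork, ca_grid: Sequence[float],
                   da_grid: Sequence[float], t_end: float = 600.0,
                   basal_ca: float = 0.06, basal_da: float = 0.01,
                   rtol: float = RTOL, atol: float = ATOL) -> PlasticityMap:
    """Plasticity ratio for every (calcium, dopamine) amplitude pair.

    Solver failures in individual cells are recorded as NaN rather than
    aborting the scan.
    """
    ca_grid = np.asarray(list(ca_grid), float)
    da_grid = np.asarray(list(da_grid), float)
    if ca_grid.size == 0 or da_grid.size == 0:
        raise ValueError("amplitude grids must be non-empty")
    y0 = pre_equilibrate(network, basal_ca, basal_da, rtol=rtol, atol=atol)
    out = np.full((ca_grid.size, da_grid.size), np.nan)
    errors: dict[tuple[int, int], str] = {}
    for i, ca_amp in enumerate(ca_grid):
        for j, da_amp in enumerate(da_grid):
            ca = CalciumProtocol(ca_basal=basal_ca, ca_amp=float(ca_amp))
            da = DopamineProtocol(da_basal=basal_da, da_amp=float(da_amp))
            try:
                tc = run(network, ca, da, t_end=t_end, y0=y0,
                         rtol=rtol, atol=atol)
                out[i, j] = plasticity_ratio(tc, eval_time=t_end).ratio
            except (RuntimeError, ValueError) as exc:
                errors[(i, j)] = str(exc)
    return PlasticityMap(ca_amplitudes=ca_grid, da_amplitudes=da_grid,
                         ratio=out,
                         meta={"t_end": t_end, "basal_ca": basal_ca,
                               "basal_da": basal_da, "errors": errors,
                               "network": network.name})


def timing_experiment(network: ReactionNetwork, offsets: Sequence[float],
                      ca_amp: float = 1.0, da_amp: float = 1.0,
                      t_end: float = 600.0, basal_ca: float = 0.06,
                      basal_da: float = 0.01) -> dict:
    """Plasticity vs dopamine/calcium timing offset.

    Positive offsets delay every dopamine pulse relative to the matching
    calcium train onset (dopamine-following). Also returns AC5, cAMP and
    PKA traces for each offset.
    """
    y0 = pre_equilibrate(network, basal_ca, basal_da)
    ratios, traces = {}, {}
    for off in offsets:
        ca = CalciumProtocol(ca_basal=basal_ca, ca_amp=ca_amp,
                             t_start=max(0.0, -off) + 1.0)
        da = DopamineProtocol(da_basal=basal_da, da_amp=da_amp,
                              offset_vs_calcium=off, t_start=ca.t_start)
        tc = run(network, ca, da, t_end=t_end, y0=y0)
        ratios[off] = plasticity_ratio(tc, eval_time=t_end).ratio
        traces[off] = {
            "t": tc.t,
            "AC5_active": tc["AC5_Golf"],
            "cAMP": tc["cAMP"],
            "PKA_active": tc["PKAc"],
        }
    return {"ratios": ratios, "traces": traces}
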
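"""Configuration, result serialization, fixtures and SBML export.

All tabular output is comma-separated UTF-8 text with a ``#``-prefixed
header carrying provenance metadata (package version, solver settings,
a hash of the configuration). Experiment configuration files are YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiments import PlasticityMap, TimeCourse
from .reaction_core import (
    BindingReaction,
    EnzymaticReaction,
    ReactionNetwork,
    Species,
    rate_constants_from_km_kcat,
)

__all__ = [
    "ExperimentConfig",
    "load_config",
    "generate_fixture",
    "write_results",
    "read_results",
    "export_sbml",
]

_CONFIG_KEYS = {
    "tables": dict,          # optional paths: species/enzymatic/binding
    "stimulus": dict,        # amplitudes, basal levels, timing offset...
    "clamps": list,          # activity names or species to fix
    "knockouts": list,
    "ablations": list,
    "ca_grid": list,
    "da_grid": list,
    "t_end": (int, float),
    "eval_time": (int, float),
    "rtol": (int, float),
    "atol": (int, float),
    "outdir": str,
    "seed": int,
}

_DEFAULTS = {
    "tables": {},
    "stimulus": {},
    "clamps": [],
    "knockouts": [],
    "ablations": [],
    "ca_grid": [],
    "da_grid": [],
    "t_end": 600.0,
    "eval_time": 600.0,
    "rtol": 1e-8,
    "atol": 1e-12,
    "outdir": "results",
    "seed": 0,
}


@dataclass
class ExperimentConfig:
    """Validated experiment configuration with defaults applied."""

    values: dict = field(default_factory=dict)

    def __getattr__(self, key):
        try:
            return self.values[key]
        except KeyError as exc:
            raise AttributeError(key) from exc

    @property
    def hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML experiment config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, typ in _CONFIG_KEYS.items():
        if key in raw and not isinstance(raw[key], typ):
            raise ValueError(f"config key {key!r}: expected {typ}, "
                             f"got {type(raw[key]).__name__}")
    values = {**_DEFAULTS, **raw}
    for key in ("rtol", "atol", "t_end", "eval_time"):
        if values[key] <= 0:
            raise ValueError(f"config key {key!r} must be positive")
    for p in values["tables"].values():
        if not Path(p).exists():
            raise FileNotFoundError(p)
    return ExperimentConfig(values)


# ---------------------------------------------------------------- fixtures

def generate_fixture(kind: str, seed: int = 0):
    """Deterministic toy networks with independent reference values.

    Kinds: ``binding_equilibrium`` (A+B⇌AB with the closed-form
    quadratic equilibrium), ``enzymatic_mm_limit`` (single enzymatic
    reaction with the quasi-steady-state initial-velocity reference),
    ``bistable_toy`` (an autocatalytic phosphorylation cycle with two
    stable states), and ``random_small_network`` (≤5 random reactions
    for brute-force derivative checks).
    """
    rng = np.random.default_rng(seed)
    if kind == "binding_equilibrium":
        a0, b0 = rng.uniform(0.5, 5.0, 2)
        kf, kb = rng.uniform(0.5, 5.0), rng.uniform(0.1, 2.0)
        net = ReactionNetwork(
            [Species("A", a0), Species("B", b0), Species("AB", 0.0,
             moieties={"A": 1, "B": 1})],
            [BindingReaction("A", "B", "AB", kf=kf, kb=kb)],
            name="binding_equilibrium",
        )
        kd = kb / kf
        # AB* solves AB^2 - (a0+b0+Kd) AB + a0 b0 = 0 (smaller root)
        s = a0 + b0 + kd
        ab = (s - np.sqrt(s * s - 4 * a0 * b0)) / 2
        ref = {"AB": ab, "A": a0 - ab, "B": b0 - ab, "kd": kd}
        return net, ref
    if kind == "enzymatic_mm_limit":
        e0 = rng.uniform(0.01, 0.05)
        s0 = rng.uniform(5.0, 20.0)
        km, kcat = rng.uniform(1.0, 5.0), rng.uniform(0.5, 2.0)
        kf, kb, kcat = rate_constants_from_km_kcat(km, kcat)
        net = ReactionNetwork(
            [Species("E", e0), Species("S", s0),
             Species("ES", 0.0, moieties={"E": 1, "S": 1}),
             Species("P", 0.0, moieties={"S": 1})],
            [EnzymaticReaction("E", "S", "ES", "P", kf=kf, kb=kb, kcat=kcat)],
            name="enzymatic_mm_limit",
        )
        ref = {"v0": kcat * e0 * s0 / (km + s0), "km": km, "kcat": kcat,
               "e0": e0, "s0": s0}
        return net, ref
    if kind == "bistable_toy":
        # Ep autocatalytically phosphorylates E; a constant phosphatase
        # (zero-order regime) removes Ep: classic one-variable switch.
        net = ReactionNetwork(
            [Species("E", 4.0), Species("Ep", 0.0, moieties={"E": 1}),
             Species("K", 0.02, clamped=True),   # basal kinase leak
             Species("P", 0.5),
             Species("Ep__E", 0.0, moieties={"E": 2}),
             Species("K__E", 0.0, moieties={"E": 1, "K": 1}),
             Species("P__Ep", 0.0, moieties={"E": 1, "P": 1})],
            [EnzymaticReaction("Ep", "E", "Ep__E", "Ep", kf=5.0, kb=4.0,
                               kcat=1.0, label="autocatalysis"),
             EnzymaticReaction("K", "E", "K__E", "Ep", kf=5.0, kb=4.0,
                               kcat=1.0, label="leak"),
             EnzymaticReaction("P", "Ep", "P__Ep", "E", kf=40.0, kb=4.0,
                               kcat=2.0, label="phosphatase")],
            name="bistable_toy",
        )
        ref = {"low_start": {"Ep": 0.0}, "high_start": {"Ep": 3.9, "E": 0.1}}
        return net, ref
    if kind == "random_small_network":
        n_sp = int(rng.integers(3, 7))
        species = [Species(f"X{i}", float(rng.uniform(0.1, 2.0)))
                   for i in range(n_sp)]
        reactions = []
        n_rxn = int(rng.integers(1, 6))
        for k in range(n_rxn):
            i, j = rng.choice(n_sp, 2, replace=False)
            ab = Species(f"C{k}", 0.0, moieties={f"X{i}": 1, f"X{j}": 1})
            species.append(ab)
            reactions.append(BindingReaction(
                f"X{i}", f"X{j}", f"C{k}",
                kf=float(rng.uniform(0.1, 3.0)),
                kb=float(rng.uniform(0.0, 2.0)), label=f"r{k}"))
        return ReactionNetwork(species, reactions,
                               name=f"random_{seed}"), {"seed": seed}
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------- results

def _header(meta: dict) -> str:
    lines = [f"# spinesim {__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_results(result, path: str | Path, meta: dict | None = None) -> Path:
    """Write a TimeCourse or PlasticityMap as annotated CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(meta or {})
    if isinstance(result, TimeCourse):
        df = pd.DataFrame(result.y, columns=result.names)
        df.insert(0, "time", result.t)
        meta.setdefault("kind", "timecourse")
    elif isinstance(result, PlasticityMap):
        rows = [(ca, da, result.ratio[i, j])
                for i, ca in enumerate(result.ca_amplitudes)
                for j, da in enumerate(result.da_amplitudes)]
        df = pd.DataFrame(rows, columns=["ca_amp", "da_amp", "ratio"])
        meta.setdefault("kind", "map")
    elif isinstance(result, pd.DataFrame):
        df = result
        meta.setdefault("kind", "table")
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    with open(path, "w") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_results(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read an annotated CSV back: (dataframe, header metadata)."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            text = ln[1:].strip()
            if ":" in text:
                k, _, v = text.partition(":")
                meta[k.strip()] = v.strip()
        else:
            body.append(ln)
    from io import StringIO
    return pd.read_csv(StringIO("".join(body)), float_precision="round_trip"), meta


# ---------------------------------------------------------------- SBML

def export_sbml(network: ReactionNetwork, path: str | Path,
                volume: float = 1e-16) -> Path:
    """Export the network as SBML Level 3 Version 2 (species, reactions,
    mass-action kinetic laws). Export only — no import path exists.
    """
    import xml.etree.ElementTree as ET

    NS = "http://www.sbml.org/sbml/level3/version2/core"
    ET.register_namespace("", NS)
    sbml = ET.Element(f"{{{NS}}}sbml", level="3", version="2")
    model = ET.SubElement(sbml, f"{{{NS}}}model", id=network.name)
    lc = ET.SubElement(model, f"{{{NS}}}listOfCompartments")
    ET.SubElement(lc, f"{{{NS}}}compartment", id="spine",
                  size=repr(volume), constant="true", spatialDimensions="3")
    ls = ET.SubElement(model, f"{{{NS}}}listOfSpecies")
    for s in network.species:
        ET.SubElement(ls, f"{{{NS}}}species", id=s.name, compartment="spine",
                      initialConcentration=repr(float(s.initial_conc)),
                      hasOnlySubstanceUnits="false",
                      boundaryCondition="true" if s.clamped else "false",
                      constant="false")
    lp = ET.SubElement(model, f"{{{NS}}}listOfParameters")
    lr = ET.SubElement(model, f"{{{NS}}}listOfReactions")

    def math_mass_action(terms: list[str]) -> "ET.Element":
        MNS = "http://www.w3.org/1998/Math/MathML"
        math = ET.Element(f"{{{MNS}}}math")
        apply_ = ET.SubElement(math, f"{{{MNS}}}apply")
        ET.SubElement(apply_, f"{{{MNS}}}times")
        for t in terms:
            ci = ET.SubElement(apply_, f"{{{MNS}}}ci")
            ci.text = f" {t} "
        return math

    def add_reaction(rid, reactants, products, k_id, k_val, rate_species):
        ET.SubElement(lp, f"{{{NS}}}parameter", id=k_id, value=repr(k_val),
                      constant="true")
        rxn = ET.SubElement(lr, f"{{{NS}}}reaction", id=rid,
                            reversible="false")
        lre = ET.SubElement(rxn, f"{{{NS}}}listOfReactants")
        for sp in reactants:
            ET.SubElement(lre, f"{{{NS}}}speciesReference", species=sp,
                          stoichiometry="1", constant="true")
        lpr = ET.SubElement(rxn, f"{{{NS}}}listOfProducts")
        for sp in products:
            ET.SubElement(lpr, f"{{{NS}}}speciesReference", species=sp,
                          stoichiometry="1", constant="true")
        kl = ET.SubElement(rxn, f"{{{NS}}}kineticLaw")
        kl.append(math_mass_action([k_id] + list(rate_species)))

    for i, r in enumerate(network.reactions):
        base = r.label or f"r{i}"
        base = base.replace(" ", "_")
        if isinstance(r, BindingReaction):
            add_reaction(f"{base}_f", [r.a, r.b], [r.ab], f"kf_{i}", r.kf,
                         [r.a, r.b])
            add_reaction(f"{base}_b", [r.ab], [r.a, r.b], f"kb_{i}", r.kb,
                         [r.ab])
        else:
            add_reaction(f"{base}_bind", [r.enzyme, r.substrate],
                         [r.complex_es], f"kf_{i}", r.kf,
                         [r.enzyme, r.substrate])
            add_reaction(f"{base}_unbind", [r.complex_es],
                         [r.enzyme, r.substrate], f"kb_{i}", r.kb,
                         [r.complex_es])
            add_reaction(f"{base}_cat", [r.complex_es],
                         [r.enzyme, r.product], f"kcat_{i}", r.kcat,
                         [r.complex_es])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ET.ElementTree(sbml).write(path, xml_declaration=True, encoding="UTF-8")
    return path
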
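"""Reaction networks, truncated state spaces, and model-config files.

A model is a set of chemical species, a parameter table, and reactions.
Each reaction carries a propensity expression (probability per unit time,
evaluated in molecule-number units) and either a fixed integer change
vector or a jump kernel that spreads probability over many destination
states (used e.g. for binomial partitioning at cell division).

State spaces are rectangular boxes ``[0, upper_i]`` per species, optionally
coarsened by an integer scale factor ``S``: the enumerated lattice then
consists of multiples of ``S``.  Transitions that would leave the box get
zero rate (reflecting, mass-conserving truncation).
"""

from __future__ import annotations

import ast
import io
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ModelError",
    "ConfigError",
    "Reaction",
    "ReactionNetwork",
    "StateSpace",
    "DistributionGrid",
    "parse_model_config",
    "serialize_model_config",
    "register_kernel",
]


class ModelError(ValueError):
    """A structurally invalid network, state space, or propensity value."""


class ConfigError(ValueError):
    """A malformed or inconsistent model-config document."""


# ---------------------------------------------------------------------------
# propensity expressions

_ALLOWED_FUNCS = {
    "exp": np.exp,
    "log": np.log,
    "sqrt": np.sqrt,
    "abs": np.abs,
    "min": np.minimum,
    "max": np.maximum,
}

_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.Pow,
    ast.USub,
    ast.UAdd,
    ast.Name,
    ast.Load,
    ast.Constant,
    ast.Call,
)


def _compile_expression(text: str, allowed_names: Iterable[str]):
    """Compile an arithmetic expression to a code object, rejecting any
    syntax or symbol outside the arithmetic/Hill subset."""
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ConfigError(f"cannot parse expression {text!r}: {exc.msg}") from exc
    allowed = set(allowed_names)
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ConfigError(
                f"expression {text!r}: construct {type(node).__name__} not allowed"
            )
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_FUNCS:
                raise ConfigError(f"expression {text!r}: only {sorted(_ALLOWED_FUNCS)} callable")
        elif isinstance(node, ast.Name):
            if node.id not in allowed and node.id not in _ALLOWED_FUNCS:
                raise ConfigError(f"expression {text!r}: unknown symbol '{node.id}'")
        elif isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
            raise ConfigError(f"expression {text!r}: non-numeric constant {node.value!r}")
    return compile(tree, "<propensity>", "eval")


# ---------------------------------------------------------------------------
# jump kernels

#: registry of named jump-kernel factories usable from model-config files.
#: A factory receives (network, options-dict) and returns a callable
#: ``kernel(state) -> (dest_states (K, d) int array, probs (K,) float array)``.
_KERNEL_REGISTRY: dict[str, Callable] = {}


def register_kernel(name: str, factory: Callable) -> None:
    _KERNEL_REGISTRY[name] = factory


@dataclass
class Reaction:
    """A single reaction channel.

    ``change`` is a per-species integer vector; a jump-kernel reaction keeps
    ``change`` as None and instead names a kernel.  A fixed-change reaction
    is the degenerate kernel that puts mass 1 on ``state + change``.
    """

    name: str
    propensity: str
    change: np.ndarray | None = None
    kernel_name: str | None = None
    kernel_options: dict = field(default_factory=dict)
    _code: object = field(default=None, repr=False, compare=False)
    _kernel: Callable | None = field(default=None, repr=False, compare=False)

    @property
    def is_jump(self) -> bool:
        return self.kernel_name is not None

    def destinations(self, state: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Destination states and probabilities for one source state."""
        if self.is_jump:
            dests, probs = self._kernel(np.asarray(state, dtype=int))
            total = float(np.sum(probs))
            if abs(total - 1.0) > 1e-12:
                raise ModelError(
                    f"reaction '{self.name}': jump-kernel mass {total} != 1"
                )
            return np.asarray(dests, dtype=int), np.asarray(probs, dtype=float)
        dest = np.asarray(state, dtype=int) + self.change
        return dest[None, :], np.array([1.0])


class ReactionNetwork:
    """Species, reactions and parameters of a stochastic chemical network."""

    def __init__(
        self,
        species: Sequence[str],
        reactions: Sequence[Reaction],
        parameters: Mapping[str, float],
    ):
        self.species = list(species)
        if len(set(self.species)) != len(self.species):
            raise ModelError("duplicate species names")
        self.parameters = {k: float(v) for k, v in parameters.items()}
        clash = set(self.species) & set(self.parameters)
        if clash:
            raise ModelError(f"names used as both species and parameter: {sorted(clash)}")
        self.reactions = list(reactions)
        names = [r.name for r in self.reactions]
        if len(set(names)) != len(names):
            raise ModelError("duplicate reaction names")
        allowed = self.species + list(self.parameters)
        for r in self.reactions:
            if r._code is None:
                r._code = _compile_expression(r.propensity, allowed)
            if r.change is not None:
                r.change = np.asarray(r.change, dtype=int)
                if r.change.shape != (len(self.species),):
                    raise ModelError(
                        f"reaction '{r.name}': change vector length "
                        f"{r.change.shape} != number of species {len(self.species)}"
                    )
            elif r.kernel_name is not None:
                if r.kernel_name not in _KERNEL_REGISTRY:
                    raise ModelError(f"reaction '{r.name}': unknown kernel '{r.kernel_name}'")
                r._kernel = _KERNEL_REGISTRY[r.kernel_name](self, dict(r.kernel_options))
            else:
                raise ModelError(f"reaction '{r.name}': neither change vector nor kernel")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    # -- propensity evaluation ------------------------------------------------
    def _env(self, states: np.ndarray) -> dict:
        states = np.asarray(states)
        env = dict(self.parameters)
        for i, s in enumerate(self.species):
            env[s] = states[..., i]
        env.update(_ALLOWED_FUNCS)
        env["__builtins__"] = {}
        return env

    def propensity_matrix(self, states: np.ndarray) -> np.ndarray:
        """Vectorized propensities: ``states`` is (N, d), result (N, R)."""
        states = np.atleast_2d(np.asarray(states, dtype=float))
        env = self._env(states)
        out = np.empty((states.shape[0], len(self.reactions)))
        with np.errstate(divide="ignore", invalid="ignore"):
            for j, r in enumerate(self.reactions):
                out[:, j] = np.broadcast_to(eval(r._code, env), states.shape[:1])
        for j, r in enumerate(self.reactions):
            col = out[:, j]
            if not np.all(np.isfinite(col)):
                raise ModelError(f"reaction '{r.name}': non-finite propensity")
            if np.any(col < 0):
                raise ModelError(f"reaction '{r.name}': negative propensity")
        return out

    def propensity_vector(self, state: Sequence[int]) -> np.ndarray:
        """Per-reaction propensities at one state (events per unit time)."""
        return self.propensity_matrix(np.asarray(state)[None, :])[0]

    # -- per-species synthesis / degradation split ----------------------------
    def unit_step_reactions(self, i: int) -> tuple[list[int], list[int]]:
        """Indices of fixed-change reactions that change species ``i`` by
        exactly +1 / -1 and nothing else (the channels entering the
        per-species detailed-balance ratio)."""
        up, down = [], []
        e = np.zeros(self.n_species, dtype=int)
        e[i] = 1
        for j, r in enumerate(self.reactions):
            if r.change is None:
                continue
            if np.array_equal(r.change, e):
                up.append(j)
            elif np.array_equal(r.change, -e):
                down.append(j)
        return up, down

    def _step_codes(self, i: int):
        """Cached compiled sums of the +1/-1 channel propensities for
        species ``i`` (hot path of the line sampler)."""
        cache = getattr(self, "_step_code_cache", None)
        if cache is None:
            cache = self._step_code_cache = {}
        if i not in cache:
            up, down = self.unit_step_reactions(i)
            allowed = self.species + list(self.parameters)
            mk = lambda idx: (
                _compile_expression(
                    " + ".join(f"({self.reactions[j].propensity})" for j in idx),
                    allowed,
                )
                if idx
                else None
            )
            cache[i] = (mk(up), mk(down))
        return cache[i]

    def step_propensities(self, states: np.ndarray, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Summed synthesis and degradation propensities for species ``i``
        (a_s,i and a_d,i) at each of the given states."""
        states = np.atleast_2d(np.asarray(states, dtype=float))
        code_s, code_d = self._step_codes(i)
        env = self._env(states)
        n = states.shape[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            a_s = (
                np.broadcast_to(eval(code_s, env), (n,)).astype(float)
                if code_s is not None
                else np.zeros(n)
            )
            a_d = (
                np.broadcast_to(eval(code_d, env), (n,)).astype(float)
                if code_d is not None
                else np.zeros(n)
            )
        return a_s, a_d


# ---------------------------------------------------------------------------
# state spaces and distributions


class StateSpace:
    """Rectangular truncated lattice ``[0, upper_i]`` with scale factor S.

    The enumerated points are multiples of S per species; with S=1 this is
    the full integer box.  State <-> linear index is a bijection in
    C (row-major) order over coarse indices.
    """

    def __init__(self, upper: Sequence[int], scale: int = 1):
        self.upper = np.asarray(upper, dtype=int)
        if np.any(self.upper < 0):
            raise ModelError("negative upper bound")
        self.scale = int(scale)
        if self.scale < 1:
            raise ModelError("scale factor S must be >= 1")
        self.shape = tuple(self.upper // self.scale + 1)
        self.n_states = int(np.prod(self.shape))

    @property
    def n_species(self) -> int:
        return len(self.upper)

    def states(self) -> np.ndarray:
        """(n_states, d) array of molecule-number states in index order."""
        grids = np.indices(self.shape).reshape(len(self.shape), -1).T
        return grids * self.scale

    def index_of(self, states: np.ndarray) -> np.ndarray:
        states = np.asarray(states, dtype=int)
        coarse = states // self.scale
        return np.ravel_multi_index(tuple(np.moveaxis(coarse, -1, 0)), self.shape)

    def state_of(self, index: np.ndarray) -> np.ndarray:
        coarse = np.stack(np.unravel_index(np.asarray(index), self.shape), axis=-1)
        return coarse * self.scale

    def contains(self, states: np.ndarray) -> np.ndarray:
        states = np.asarray(states, dtype=int)
        ok = np.all((states >= 0) & (states <= self.upper), axis=-1)
        return ok & np.all(states % self.scale == 0, axis=-1)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StateSpace)
            and np.array_equal(self.upper, other.upper)
            and self.scale == other.scale
        )


class DistributionGrid:
    """Probability mass over the lattice points of a StateSpace.

    ``mass`` holds the aggregated probability per enumerated lattice point
    and sums to 1.  For a coarse lattice (S>1) each point stands for the
    S^d underlying fine states; ``density`` divides the aggregated mass by
    S^d to give a per-fine-state probability density.
    """

    def __init__(self, space: StateSpace, mass: np.ndarray, normalize: bool = True):
        self.space = space
        mass = np.asarray(mass, dtype=float).reshape(-1)
        if mass.shape[0] != space.n_states:
            raise ModelError("mass vector length does not match state space")
        if np.any(mass < -1e-12):
            raise ModelError("negative probability mass")
        mass = np.clip(mass, 0.0, None)
        total = mass.sum()
        if normalize:
            if total <= 0:
                raise ModelError("all-zero mass vector")
            mass = mass / total
        self.mass = mass

    @property
    def density(self) -> np.ndarray:
        return self.mass / float(self.space.scale ** self.space.n_species)

    @property
    def grid(self) -> np.ndarray:
        """mass reshaped to the lattice shape (one axis per species)."""
        return self.mass.reshape(self.space.shape)

    def marginal(self, i: int) -> np.ndarray:
        axes = tuple(k for k in range(self.space.n_species) if k != i)
        return self.grid.sum(axis=axes) if axes else self.grid.copy()

    def marginal_values(self, i: int) -> np.ndarray:
        """Molecule numbers along species ``i``'s marginal axis."""
        return np.arange(self.space.shape[i]) * self.space.scale

    def mean(self) -> np.ndarray:
        return np.array(
            [float(self.marginal_values(i) @ self.marginal(i)) for i in range(self.space.n_species)]
        )

    def std(self) -> np.ndarray:
        out = []
        for i in range(self.space.n_species):
            v = self.marginal_values(i).astype(float)
            m = self.marginal(i)
            mu = float(v @ m)
            out.append(math.sqrt(max(float((v - mu) ** 2 @ m), 0.0)))
        return np.array(out)

    def sample_states(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw exact iid states from this distribution."""
        idx = rng.choice(self.space.n_states, size=n, p=self.mass)
        return self.space.state_of(idx)


# ---------------------------------------------------------------------------
# model-config documents (YAML dialect; documented in docs/methods.md)


def parse_model_config(text: str) -> tuple[ReactionNetwork, StateSpace]:
    """Parse a model-config document into a network and its state space.

    The dialect is YAML with top-level keys ``species`` (ordered list),
    ``parameters`` (name -> value), ``bounds`` (species -> upper bound),
    optional ``scale`` (integer >= 1), and ``reactions`` (list of mappings
    with ``name``, ``propensity`` and either ``change`` (species -> integer)
    or ``kernel`` (mapping with ``name`` plus kernel options)).
    """
    try:
        doc = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed model config{line}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("model config must be a mapping")
    for key in ("species", "reactions", "bounds"):
        if key not in doc:
            raise ConfigError(f"model config missing required key '{key}'")
    species = list(doc["species"])
    params = dict(doc.get("parameters") or {})
    bounds = doc["bounds"]
    missing = [s for s in species if s not in bounds]
    if missing:
        raise ConfigError(f"bounds missing for species {missing}")
    upper = [int(bounds[s]) for s in species]
    if any(u < 0 for u in upper):
        raise ConfigError("negative bound")
    scale = int(doc.get("scale", 1))
    if scale < 1:
        raise ConfigError("scale factor S must be >= 1")
    reactions = []
    for entry in doc["reactions"]:
        if "name" not in entry or "propensity" not in entry:
            raise ConfigError(f"reaction entry needs 'name' and 'propensity': {entry}")
        change = None
        kernel_name = None
        kernel_options: dict = {}
        if "change" in entry:
            ch = entry["change"]
            unknown = [s for s in ch if s not in species]
            if unknown:
                raise ConfigError(
                    f"reaction '{entry['name']}': change names undeclared species {unknown}"
                )
            change = np.array([int(ch.get(s, 0)) for s in species])
        elif "kernel" in entry:
            spec = dict(entry["kernel"])
            kernel_name = spec.pop("name", None)
            if kernel_name is None:
                raise ConfigError(f"reaction '{entry['name']}': kernel needs a 'name'")
            kernel_options = spec
        else:
            raise ConfigError(f"reaction '{entry['name']}': needs 'change' or 'kernel'")
        reactions.append(
            Reaction(
                name=str(entry["name"]),
                propensity=str(entry["propensity"]),
                change=change,
                kernel_name=kernel_name,
                kernel_options=kernel_options,
            )
        )
    try:
        network = ReactionNetwork(species, reactions, params)
    except ModelError as exc:
        raise ConfigError(str(exc)) from exc
    return network, StateSpace(upper, scale)


def serialize_model_config(network: ReactionNetwork, space: StateSpace) -> str:
    """Inverse of :func:`parse_model_config` (round-trippable)."""
    doc: dict = {
        "species": list(network.species),
        "parameters": {k: float(v) for k, v in network.parameters.items()},
        "bounds": {s: int(u) for s, u in zip(network.species, space.upper)},
    }
    if space.scale != 1:
        doc["scale"] = space.scale
    rxns = []
    for r in network.reactions:
        entry: dict = {"name": r.name, "propensity": r.propensity}
        if r.change is not None:
            entry["change"] = {
                s: int(c) for s, c in zip(network.species, r.change) if c != 0
            }
        else:
            entry["kernel"] = {"name": r.kernel_name, **r.kernel_options}
        rxns.append(entry)
    doc["reactions"] = rxns
    return yaml.safe_dump(doc, sort_keys=False)
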
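"""Constructors for the example gene circuits.

Three circuits are shipped:

* the constitutive birth-death process (synthesis ``k_s``, degradation
  ``k_d * n``), whose steady state is Poisson(k_s/k_d);
* the genetic toggle switch -- two mutually repressing proteins U and V
  with Hill synthesis ``r_u / (1 + (v/K_v)^beta)`` (resp.
  ``r_v / (1 + (u/K_u)^gamma)``) and linear degradation, optionally with
  antibiotic-enhanced degradation of V
  (``d_v0 + d_v1 * A / (A + k_A)``) modeling the SOS response to
  norfloxacin;
* the T7 RNA polymerase positive-feedback circuit with growth
  retardation: M promoters flip between an inactive state O_0 (m copies)
  and a T7-bound active state O_1, T7 RNAP is synthesized from both at
  rates k_0*m and k_1*(M-m), degraded at d_x0*n, and the cell divides
  with propensity mu/(1 + n/theta) -- fast growth at low T7 load.
  Division partitions the free T7 molecules binomially (p = 1/2) and
  resets every promoter to O_0.

The pseudo-steady state of the T7 circuit treats the effective growth
rate mu (the population growth rate scaled by the unused capacity) as a
constant of the log-phase window being modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.stats import binom

from .network import (
    Reaction,
    ReactionNetwork,
    StateSpace,
    parse_model_config,
    register_kernel,
)

__all__ = [
    "ToggleSwitchModel",
    "T7CircuitModel",
    "make_birth_death",
    "make_toggle",
    "make_t7",
    "builtin_model_names",
    "load_builtin_model",
]


# ---------------------------------------------------------------------------
# binomial division kernel (registered for model-config files)


def _binomial_division_factory(network: ReactionNetwork, options: dict):
    mol = options.get("molecules")
    prom = options.get("inactive_promoters")
    total = int(options.get("promoters", 0))
    if mol is None or prom is None:
        raise ValueError(
            "binomial_division kernel needs 'molecules' and 'inactive_promoters'"
        )
    i_mol = network.species_index(mol)
    i_prom = network.species_index(prom)
    p_half = float(options.get("p", 0.5))
    d = network.n_species

    def kernel(state: np.ndarray):
        n = int(state[i_mol])
        ks = np.arange(n + 1)
        probs = binom.pmf(ks, n, p_half)
        dests = np.tile(state, (n + 1, 1))
        dests[:, i_mol] = ks
        dests[:, i_prom] = total  # all promoters reset to the inactive state
        return dests, probs

    def sample(state: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        dest = np.asarray(state).copy()
        dest[i_mol] = rng.binomial(int(state[i_mol]), p_half)
        dest[i_prom] = total
        return dest

    kernel.sample = sample
    _ = d
    return kernel


register_kernel("binomial_division", _binomial_division_factory)


# ---------------------------------------------------------------------------
# parameterizations


@dataclass
class ToggleSwitchModel:
    """Toggle-switch parameters (molecule/time units).

    ``K_v`` gates repression of U by V and ``K_u`` repression of V by U;
    ``beta``/``gamma`` are the corresponding Hill exponents.  The optional
    antibiotic block (``d_v0``, ``d_v1``, ``k_A``, ``A``) replaces V's
    degradation constant with ``d_v0 + d_v1 * A / (A + k_A)``.
    """

    K_u: float = 1.0
    K_v: float = 1.0
    r_u: float = 10.0
    r_v: float = 9.0
    beta: float = 2.0
    gamma: float = 2.0
    d_u: float = 1.0
    d_v: float = 1.0
    d_v0: float | None = None
    d_v1: float | None = None
    k_A: float | None = None
    A: float = 0.0

    def __post_init__(self):
        for name in ("K_u", "K_v", "r_u", "r_v", "beta", "gamma", "d_u", "d_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.A < 0:
            raise ValueError("A must be nonnegative")

    @property
    def nfx(self) -> bool:
        return self.d_v0 is not None

    def effective_d_v(self) -> float:
        if not self.nfx:
            return self.d_v
        return self.d_v0 + self.d_v1 * self.A / (self.A + self.k_A)


@dataclass
class T7CircuitModel:
    """T7 RNAP circuit parameters (per-time units; theta in molecules)."""

    M: int = 10
    k_0: float = 0.0011
    k_1: float = 0.0087
    k_f: float = 0.01
    k_b: float = 0.11
    d_x0: float = 0.003
    mu: float = 0.007
    theta: float = 1.0

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        for name in ("k_0", "k_1", "k_f", "k_b", "d_x0", "theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")


# ---------------------------------------------------------------------------
# constructors


def make_birth_death(
    k_s: float, k_d: float, n_max: int
) -> tuple[ReactionNetwork, StateSpace]:
    """Birth-death network: synthesis at k_s, degradation at k_d * n."""
    if k_s <= 0 or k_d <= 0:
        raise ValueError("rates must be positive")
    network = ReactionNetwork(
        species=["n"],
        reactions=[
            Reaction("synthesis", "k_s", change=np.array([1])),
            Reaction("degradation", "k_d * n", change=np.array([-1])),
        ],
        parameters={"k_s": k_s, "k_d": k_d},
    )
    return network, StateSpace([n_max])


def make_toggle(
    params: ToggleSwitchModel, bounds: tuple[int, int] = (60, 60)
) -> tuple[ReactionNetwork, StateSpace]:
    """Toggle-switch network: Hill synthesis, linear degradation."""
    d_v = params.effective_d_v()
    network = ReactionNetwork(
        species=["u", "v"],
        reactions=[
            Reaction("synth_u", "r_u / (1 + (v / K_v)**beta)", change=np.array([1, 0])),
            Reaction("deg_u", "d_u * u", change=np.array([-1, 0])),
            Reaction("synth_v", "r_v / (1 + (u / K_u)**gamma)", change=np.array([0, 1])),
            Reaction("deg_v", "d_v * v", change=np.array([0, -1])),
        ],
        parameters={
            "K_u": params.K_u,
            "K_v": params.K_v,
            "r_u": params.r_u,
            "r_v": params.r_v,
            "beta": params.beta,
            "gamma": params.gamma,
            "d_u": params.d_u,
            "d_v": d_v,
        },
    )
    return network, StateSpace(list(bounds))


def make_t7(
    params: T7CircuitModel, n_max: int = 60
) -> tuple[ReactionNetwork, StateSpace]:
    """T7 positive-feedback circuit on the (free T7, inactive promoters)
    lattice; the sixth reaction is the binomial division jump."""
    network = ReactionNetwork(
        species=["t7", "o0"],
        reactions=[
            Reaction("synth_basal", "k_0 * o0", change=np.array([1, 0])),
            Reaction("synth_active", "k_1 * (M - o0)", change=np.array([1, 0])),
            Reaction("activation", "k_f * o0 * t7", change=np.array([-1, -1])),
            Reaction("deactivation", "k_b * (M - o0)", change=np.array([1, 1])),
            Reaction("degradation", "d_x0 * t7", change=np.array([-1, 0])),
            Reaction(
                "division",
                "mu / (1 + t7 / theta)",
                kernel_name="binomial_division",
                kernel_options={
                    "molecules": "t7",
                    "inactive_promoters": "o0",
                    "promoters": params.M,
                },
            ),
        ],
        parameters={
            "M": params.M,
            "k_0": params.k_0,
            "k_1": params.k_1,
            "k_f": params.k_f,
            "k_b": params.k_b,
            "d_x0": params.d_x0,
            "mu": params.mu,
            "theta": params.theta,
        },
    )
    return network, StateSpace([n_max, params.M])


# ---------------------------------------------------------------------------
# shipped model-config files

_BUILTIN = [
    "birth_death",
    "toggle_table1_set1",
    "toggle_table1_set2",
    "toggle_fig4b",
    "t7_base",
    "t7_mu013",
    "t7_iptg100",
]


def builtin_model_names() -> list[str]:
    return list(_BUILTIN)


def load_builtin_model(name: str) -> tuple[ReactionNetwork, StateSpace]:
    """Load one of the shipped model-config files by short name."""
    if name not in _BUILTIN:
        raise KeyError(f"unknown builtin model '{name}'; choose from {_BUILTIN}")
    text = (
        resources.files("cmenoise").joinpath("models").joinpath(f"{name}.model")
    ).read_text()
    return parse_model_config(text)
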
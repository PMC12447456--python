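"""DBN structure, linear-Gaussian conditionals, priors, and the joint density.

The network unrolls a first-order dynamic Bayesian network over daily time
slices.  Four endogenous nodes — perceived busyness B, perceived restedness
R, app page views PV, and steps per wear-time minute FS — each follow a
linear conditional Gaussian given their lagged/contemporaneous parents:

    B(k)  = wB·B(k−1) + bB + ε_B
    R(k)  = wR·R(k−1) + bR + ε_R
    PV(k) = wPV·PV(k−1) + wPVBU·B(k) + wPVR·R(k) + wPVW·W(k)
            + wPVMS·MS(k) [+ wPVT·T(k)] + bPV + ε_PV
    FS(k) = wFS·FS(k−1) + wFSPV·PV(k) [+ wFSPV1·PV(k−1)] + wFSBU·B(k)
            + wFSW·W(k) + wFSMS·MS(k) + wFST·T(k) + bFS + ε_FS

with ε_node ~ Normal(0, σ_node).  Messages MS, temperature T, and the
weekend indicator W are exogenous: conditioned on, never modeled.  Day 0 is
an initial condition.  The joint factorizes node-by-node, slice-by-slice,
as in any Bayesian network.

Weights and biases carry Normal priors, noise SDs Exponential priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

ENDOGENOUS = ("B", "R", "PV", "FS")
EXOGENOUS = ("MS", "T", "W")

LOG_2PI = math.log(2.0 * math.pi)


class ModelError(ValueError):
    """Invalid structure, parameters, or data for the DBN."""


@dataclass(frozen=True)
class NodeSpec:
    """One endogenous node: its parents (with lags) and parameter names."""

    name: str
    parents: tuple[tuple[str, int], ...]
    weight_names: tuple[str, ...]
    bias_name: str
    noise_sd_name: str

    def __post_init__(self) -> None:
        if len(self.weight_names) != len(self.parents):
            raise ModelError(f"{self.name}: weights not in bijection with parents")
        if len(set(self.weight_names)) != len(self.weight_names):
            raise ModelError(f"{self.name}: duplicate weight names")
        for p, lag in self.parents:
            if lag not in (0, 1):
                raise ModelError(f"{self.name}: lag must be 0 or 1")
            if p == self.name and lag == 0:
                raise ModelError(f"{self.name}: node cannot be its own lag-0 parent")


@dataclass
class DBNStructure:
    """Node specs for the endogenous variables plus the exogenous set.

    ``alias_map`` carries the short reporting labels for edges (e.g. ``t_m``
    for the messages→page-views effect) mapped to (node, (parent, lag)).
    """

    nodes: dict[str, NodeSpec]
    exogenous: tuple[str, ...] = EXOGENOUS
    alias_map: dict[str, tuple[str, tuple[str, int]]] = field(default_factory=dict)

    def node(self, name: str) -> NodeSpec:
        return self.nodes[name]

    def weight_for_edge(self, node: str, parent: str, lag: int) -> str:
        spec = self.nodes[node]
        for (p, l), w in zip(spec.parents, spec.weight_names):
            if p == parent and l == lag:
                return w
        raise ModelError(f"no edge {parent}[lag {lag}] -> {node}")

    def alias_for(self, node: str, parent: str, lag: int) -> str | None:
        for alias, (n, (p, l)) in self.alias_map.items():
            if (n, p, l) == (node, parent, lag):
                return alias
        return None

    def weight_names(self) -> list[str]:
        return [w for spec in self.nodes.values() for w in spec.weight_names]

    def bias_names(self) -> list[str]:
        return [spec.bias_name for spec in self.nodes.values()]

    def noise_sd_names(self) -> list[str]:
        return [spec.noise_sd_name for spec in self.nodes.values()]

    def parameter_names(self) -> list[str]:
        return self.weight_names() + self.bias_names() + self.noise_sd_names()

    # -- config round trip ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "exogenous": list(self.exogenous),
            "nodes": {
                name: {
                    "parents": [[p, lag] for p, lag in spec.parents],
                    "weights": list(spec.weight_names),
                    "bias": spec.bias_name,
                    "noise_sd": spec.noise_sd_name,
                }
                for name, spec in self.nodes.items()
            },
            "aliases": {a: [n, [p, l]] for a, (n, (p, l)) in self.alias_map.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DBNStructure":
        nodes = {
            name: NodeSpec(
                name=name,
                parents=tuple((p, int(lag)) for p, lag in nd["parents"]),
                weight_names=tuple(nd["weights"]),
                bias_name=nd["bias"],
                noise_sd_name=nd["noise_sd"],
            )
            for name, nd in d["nodes"].items()
        }
        aliases = {a: (n, (p, int(l))) for a, (n, (p, l)) in d.get("aliases", {}).items()}
        return cls(nodes=nodes, exogenous=tuple(d.get("exogenous", EXOGENOUS)), alias_map=aliases)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DBNStructure":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PriorConfig:
    """Normal priors on weights/biases, Exponential priors on noise SDs.

    Defaults Normal(0, 1) and Exponential(rate 1); per-parameter overrides by
    name.  The families are part of the model; the hyperparameters are a
    modeling choice kept weakly informative on the standardized scale.
    """

    weight_mean: float = 0.0
    weight_sd: float = 1.0
    noise_rate: float = 1.0
    normal_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    rate_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight_sd <= 0 or self.noise_rate <= 0:
            raise ModelError("prior SDs and rates must be positive")
        for _, sd in self.normal_overrides.values():
            if sd <= 0:
                raise ModelError("prior SDs must be positive")
        for rate in self.rate_overrides.values():
            if rate <= 0:
                raise ModelError("prior rates must be positive")

    def normal(self, name: str) -> tuple[float, float]:
        return self.normal_overrides.get(name, (self.weight_mean, self.weight_sd))

    def rate(self, name: str) -> float:
        return self.rate_overrides.get(name, self.noise_rate)

    def to_dict(self) -> dict:
        return {
            "weight_mean": self.weight_mean,
            "weight_sd": self.weight_sd,
            "noise_rate": self.noise_rate,
            "normal_overrides": {k: list(v) for k, v in self.normal_overrides.items()},
            "rate_overrides": dict(self.rate_overrides),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PriorConfig":
        return cls(
            weight_mean=float(d.get("weight_mean", 0.0)),
            weight_sd=float(d.get("weight_sd", 1.0)),
            noise_rate=float(d.get("noise_rate", 1.0)),
            normal_overrides={k: (float(m), float(s)) for k, (m, s) in d.get("normal_overrides", {}).items()},
            rate_overrides={k: float(r) for k, r in d.get("rate_overrides", {}).items()},
        )


def default_structure(
    include_temp_on_pv: bool = True, include_lagged_pv_on_fs: bool = True
) -> DBNStructure:
    """The study's DAG: self-lags for B and R; contextual drivers for PV, FS.

    With both flags on, PV gets a temperature parent and FS gets the
    previous day's page views (the reported ``t_pvfs`` edge), matching the
    full hypothesis set; with both off, the parent sets match the printed
    difference equations exactly.
    """
    pv_parents = [("PV", 1), ("B", 0), ("R", 0), ("W", 0), ("MS", 0)]
    pv_weights = ["wPV", "wPVBU", "wPVR", "wPVW", "wPVMS"]
    if include_temp_on_pv:
        pv_parents.append(("T", 0))
        pv_weights.append("wPVT")
    fs_parents = [("FS", 1), ("PV", 0), ("B", 0), ("W", 0), ("MS", 0), ("T", 0)]
    fs_weights = ["wFS", "wFSPV", "wFSBU", "wFSW", "wFSMS", "wFST"]
    if include_lagged_pv_on_fs:
        fs_parents.append(("PV", 1))
        fs_weights.append("wFSPV1")
    nodes = {
        "B": NodeSpec("B", (("B", 1),), ("wB",), "bB", "sigma_B"),
        "R": NodeSpec("R", (("R", 1),), ("wR",), "bR", "sigma_R"),
        "PV": NodeSpec("PV", tuple(pv_parents), tuple(pv_weights), "bPV", "sigma_PV"),
        "FS": NodeSpec("FS", tuple(fs_parents), tuple(fs_weights), "bFS", "sigma_FS"),
    }
    aliases = {
        "t_m": ("PV", ("MS", 0)),
        "t_ww": ("PV", ("W", 0)),
        "t_baa": ("PV", ("B", 0)),
        "t_fsaa": ("FS", ("PV", 0)),
        "t_baaa": ("FS", ("B", 0)),
        "t_www": ("FS", ("W", 0)),
        "t_msfs": ("FS", ("MS", 0)),
        "t_t": ("FS", ("T", 0)),
    }
    if include_lagged_pv_on_fs:
        aliases["t_pvfs"] = ("FS", ("PV", 1))
    return DBNStructure(nodes=nodes, alias_map=aliases)


def validate_structure(s: DBNStructure) -> list[str]:
    """Return a list of violations (empty list means the structure is valid)."""
    violations: list[str] = []
    known = set(s.nodes) | set(s.exogenous)
    all_weights: list[str] = []
    for name, spec in s.nodes.items():
        all_weights.extend(spec.weight_names)
        for p, lag in spec.parents:
            if p not in known:
                violations.append(f"{name}: unknown parent {p!r}")
        if len(set(spec.parents)) != len(spec.parents):
            violations.append(f"{name}: duplicate parents")
    if len(set(all_weights)) != len(all_weights):
        violations.append("duplicate weight names across nodes")
    # lag-0 cycle check among endogenous nodes (iterative DFS)
    edges = {
        name: [p for p, lag in spec.parents if lag == 0 and p in s.nodes]
        for name, spec in s.nodes.items()
    }
    color: dict[str, int] = {}
    for start in edges:
        if color.get(start):
            continue
        stack = [(start, iter(edges[start]))]
        color[start] = 1
        while stack:
            node, it = stack[-1]
            nxt = next(it, None)
            if nxt is None:
                color[node] = 2
                stack.pop()
            elif color.get(nxt, 0) == 1:
                violations.append(f"lag-0 cycle through {nxt}")
                color[node] = 2
                stack.pop()
            elif color.get(nxt, 0) == 0:
                color[nxt] = 1
                stack.append((nxt, iter(edges[nxt])))
    return violations


def zero_params(structure: DBNStructure) -> dict[str, float]:
    """Weights/biases 0, noise SDs 1 — the prior-typical starting point."""
    params = {name: 0.0 for name in structure.weight_names() + structure.bias_names()}
    params.update({name: 1.0 for name in structure.noise_sd_names()})
    return params


def conditional_mean(
    node: NodeSpec,
    params: Mapping[str, float],
    data: Mapping[str, np.ndarray],
    k: int,
) -> float:
    """bias + Σ weight × parent value at day ``k`` (k ≥ 1)."""
    if k < 1:
        raise ModelError("day 0 is an initial condition, not modeled")
    total = params[node.bias_name]
    for (p, lag), wname in zip(node.parents, node.weight_names):
        total += params[wname] * data[p][k - lag]
    return float(total)


def node_means(
    node: NodeSpec, params: Mapping[str, float], data: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Vectorized conditional means for k = 1..N−1."""
    n = len(data[node.name])
    mean = np.full(n - 1, params[node.bias_name])
    for (p, lag), wname in zip(node.parents, node.weight_names):
        arr = data[p]
        mean += params[wname] * (arr[1:] if lag == 0 else arr[:-1])
    return mean


def log_joint(
    structure: DBNStructure,
    priors: PriorConfig,
    data: Mapping[str, np.ndarray],
    params: Mapping[str, float],
    imputed: Mapping[tuple[str, int], float] | None = None,
) -> float:
    """Log joint density of parameters, imputed values, and data.

    ``data`` holds standardized arrays (NaN where missing); ``imputed``
    supplies a value for every missing entry.  The density is the parameter
    priors, a standard-normal prior for any imputed day-0 entry (whose value
    otherwise enters only as a lag-1 predictor), and the Gaussian transition
    terms for k = 1..N−1 of every endogenous node.
    """
    filled = {k: np.array(v, dtype=float) for k, v in data.items()}
    if imputed:
        for (var, k), val in imputed.items():
            if not np.isnan(filled[var][k]):
                raise ModelError(f"imputed value for observed entry ({var}, {k})")
            filled[var][k] = val

    total = 0.0
    for name in structure.weight_names() + structure.bias_names():
        mu, sd = priors.normal(name)
        z = (params[name] - mu) / sd
        total += -0.5 * (LOG_2PI + z * z) - math.log(sd)
    for name in structure.noise_sd_names():
        sd = params[name]
        if sd <= 0:
            raise ModelError(f"non-positive noise SD {name}")
        rate = priors.rate(name)
        total += math.log(rate) - rate * sd

    if imputed:
        for (var, k), val in imputed.items():
            if k == 0:
                total += -0.5 * (LOG_2PI + val * val)

    for name, spec in structure.nodes.items():
        arr = filled[name]
        if np.isnan(arr).any():
            raise ModelError(f"unimputed missing entry in {name}")
        if len(arr) < 2:
            continue  # no modeled transitions
        sd = params[spec.noise_sd_name]
        resid = arr[1:] - node_means(spec, params, filled)
        total += float(np.sum(-0.5 * (LOG_2PI + (resid / sd) ** 2) - math.log(sd)))
    return total
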
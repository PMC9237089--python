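"""Synthetic benchmark generator: planted-partition graphs under partial
observation with sampled (optionally corrupted) side information.

The generator emulates the benchmark protocol for community detection on
incompletely mapped interactomes: a stochastic block model (SBM) provides a
network with known ground-truth communities; an *observed* instance is the
induced subgraph on a uniformly sampled node subset (modeling partial
interactome capture); side information assigns a sampled fraction of observed
nodes their true community label; a corruption step can flip a fraction of
those labels to a uniformly chosen wrong community.

The default benchmark configuration is a 1000-node SBM with 10 planted
communities of sizes [150, 125, 125, 110, 100, 100, 90, 75, 75, 50]. The
edge probabilities default to p_in = 0.10 and p_out = 0.005 — a detectable
but nontrivial assortative regime; any quantitative claim should state them
explicitly, as they are a modeling choice, not a property of the block sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import floor
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .network import Network, Partition, SideInfo

__all__ = [
    "SBMConfig",
    "ObservedInstance",
    "ExperimentConfig",
    "DEFAULT_BLOCK_SIZES",
    "DEFAULT_P_IN",
    "DEFAULT_P_OUT",
    "benchmark_config",
    "generate_sbm",
    "observe",
    "sample_side_info",
    "corrupt_side_info",
    "make_instance",
    "round_half_up",
]

DEFAULT_BLOCK_SIZES: tuple[int, ...] = (150, 125, 125, 110, 100, 100, 90, 75, 75, 50)
DEFAULT_P_IN = 0.10
DEFAULT_P_OUT = 0.005


def round_half_up(x: float) -> int:
    """Deterministic sample-size rounding for percentage grids."""
    return int(floor(x + 0.5))


@dataclass(frozen=True)
class SBMConfig:
    """Stochastic block model parameters."""

    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES
    p_in: float = DEFAULT_P_IN
    p_out: float = DEFAULT_P_OUT
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.block_sizes or any(s < 1 for s in self.block_sizes):
            raise ConfigError("block_sizes must be non-empty positive integers")
        for name, p in (("p_in", self.p_in), ("p_out", self.p_out)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.p_out > self.p_in:
            warnings.warn(
                f"p_out={self.p_out} > p_in={self.p_in}: disassortative blocks",
                stacklevel=2,
            )

    @property
    def n_nodes(self) -> int:
        return int(sum(self.block_sizes))

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)


def benchmark_config(seed: int = 0) -> SBMConfig:
    """The default 1000-node, 10-community benchmark configuration."""
    return SBMConfig(seed=seed)


@dataclass(frozen=True)
class ObservedInstance:
    """One benchmark instance: observed graph, restricted truth, side info."""

    graph: Network
    truth: Partition
    observed_fraction: float
    si: SideInfo = field(default_factory=SideInfo)
    si_fraction: float = 0.0
    corrupt_fraction: float = 0.0
    seed: int = 0

    @property
    def n_observed(self) -> int:
        return self.graph.n_nodes


def _node_id(i: int, width: int) -> str:
    return f"n{i:0{width}d}"


def generate_sbm(cfg: SBMConfig) -> tuple[Network, Partition]:
    """Sample an SBM graph and its ground-truth partition.

    Node ids are zero-padded (`n000` ...) so lexicographic order equals
    numeric order; block ids are `b00`, `b01`, ... Every unordered node pair
    is an independent Bernoulli draw: p_in within a block, p_out across.
    Identical configs (including seed) yield identical networks.
    """
    n = cfg.n_nodes
    width = max(3, len(str(n - 1)))
    block_of = np.repeat(np.arange(cfg.n_blocks), cfg.block_sizes)
    starts = np.concatenate([[0], np.cumsum(cfg.block_sizes)])
    rng = np.random.default_rng(cfg.seed)
    edges: list[tuple[str, str]] = []
    bwidth = max(2, len(str(cfg.n_blocks - 1)))
    for a in range(cfg.n_blocks):
        ia, ja = int(starts[a]), int(starts[a + 1])
        # intra-block: strict upper triangle
        size = ja - ia
        draws = rng.random((size, size))
        iu, ju = np.nonzero(np.triu(draws < cfg.p_in, k=1))
        edges.extend(
            (_node_id(ia + i, width), _node_id(ia + j, width)) for i, j in zip(iu, ju)
        )
        for b in range(a + 1, cfg.n_blocks):
            ib, jb = int(starts[b]), int(starts[b + 1])
            draws = rng.random((size, jb - ib))
            iu, ju = np.nonzero(draws < cfg.p_out)
            edges.extend(
                (_node_id(ia + i, width), _node_id(ib + j, width))
                for i, j in zip(iu, ju)
            )
    nodes = [_node_id(i, width) for i in range(n)]
    truth = Partition(
        {nodes[i]: f"b{int(block_of[i]):0{bwidth}d}" for i in range(n)}
    )
    return Network.from_edges(edges, nodes=nodes), truth


def observe(
    net: Network, truth: Partition, fraction: float, seed: int = 0
) -> ObservedInstance:
    """Induced subgraph on a uniform sample of round(fraction * |V|) nodes."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigError(f"observed fraction must be in (0, 1], got {fraction}")
    nodes = sorted(net.nodes)
    k = round_half_up(fraction * len(nodes))
    rng = np.random.default_rng(seed)
    sample = rng.choice(len(nodes), size=k, replace=False)
    keep = [nodes[i] for i in sorted(sample)]
    return ObservedInstance(
        graph=net.subgraph(keep),
        truth=truth.restrict(keep),
        observed_fraction=fraction,
        seed=seed,
    )


def sample_side_info(
    inst: ObservedInstance, fraction: float, seed: int = 0
) -> SideInfo:
    """Label round(fraction * n_obs) observed nodes with their true community."""
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(f"side-information fraction must be in [0, 1], got {fraction}")
    nodes = sorted(inst.graph.nodes)
    k = round_half_up(fraction * len(nodes))
    rng = np.random.default_rng(seed)
    sample = rng.choice(len(nodes), size=k, replace=False)
    return SideInfo(
        {nodes[i]: frozenset({str(inst.truth[nodes[i]])}) for i in sorted(sample)}
    )


def corrupt_side_info(
    si: SideInfo, truth: Partition, fraction: float, seed: int = 0
) -> SideInfo:
    """Replace the labels of round(fraction * |si|) labeled nodes with a
    uniformly chosen *wrong* community id (guaranteed != the true one)."""
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(f"corrupt fraction must be in [0, 1], got {fraction}")
    community_ids = sorted(str(c) for c in truth.communities)
    if fraction > 0 and len(community_ids) < 2:
        raise ConfigError("cannot corrupt labels with a single-community truth")
    labeled = sorted(si.labels)
    k = round_half_up(fraction * len(labeled))
    rng = np.random.default_rng(seed)
    sample = rng.choice(len(labeled), size=k, replace=False) if labeled else []
    out = {n: si.labels[n] for n in labeled}
    for i in sorted(sample):
        node = labeled[i]
        true_id = str(truth[node])
        others = [c for c in community_ids if c != true_id]
        out[node] = frozenset({others[int(rng.integers(len(others)))]})
    return SideInfo(out)


def _sub_seeds(seed: int, n: int = 4) -> list[int]:
    """Independent sub-stream seeds so varying one grid axis leaves the
    other random streams untouched."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def make_instance(
    cfg: SBMConfig,
    observed_fraction: float = 1.0,
    si_fraction: float = 0.0,
    corrupt_fraction: float = 0.0,
    seed: int = 0,
) -> ObservedInstance:
    """Generate a fully populated benchmark instance from one master seed."""
    s_gen, s_obs, s_si, s_cor = _sub_seeds(seed)
    net, truth_full = generate_sbm(replace(cfg, seed=s_gen))
    inst = observe(net, truth_full, observed_fraction, seed=s_obs)
    si = sample_side_info(inst, si_fraction, seed=s_si)
    if corrupt_fraction > 0 and len(si) > 0:
        si = corrupt_side_info(si, inst.truth, corrupt_fraction, seed=s_cor)
    return replace(
        inst,
        si=si,
        si_fraction=si_fraction,
        corrupt_fraction=corrupt_fraction,
        seed=seed,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """A full observability x side-information grid experiment."""

    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES
    p_in: float = DEFAULT_P_IN
    p_out: float = DEFAULT_P_OUT
    observability: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.1, 2))
    side_info: tuple[float, ...] = tuple(np.round(np.arange(0, 11) * 0.1, 2))
    corrupt: tuple[float, ...] = (0.0,)
    repeats: int = 20
    seed: int = 0
    laziness: float = 0.0
    curvature_threshold: float = 0.0
    distance_mode: str = "original"

    def sbm_config(self, seed: int = 0) -> SBMConfig:
        return SBMConfig(
            block_sizes=tuple(self.block_sizes),
            p_in=self.p_in,
            p_out=self.p_out,
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown experiment config keys: {sorted(unknown)}")
        for key in ("block_sizes", "observability", "side_info", "corrupt"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
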
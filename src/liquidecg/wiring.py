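"""Sparse four-layer neural-circuit-policy (NCP) wiring.

Neurons are organized as sensory -> inter -> command -> motor, in the spirit
of the C. elegans-inspired circuit designs. Synapses are inserted
stochastically by three mechanisms:

1. every source neuron draws ``fanout_per_source`` distinct candidate targets
   in the next layer and keeps each with Bernoulli probability ``p2``;
2. any next-layer target left without afferents receives a Binomial(p3)
   number of synapses from the previous layer (redrawn until at least one
   lands), so no non-sensory neuron is orphaned;
3. command neurons form recurrent command->command synapses: each command
   source draws ``n_recurrent_draws`` distinct command targets and keeps each
   with probability ``p4``.

Each synapse carries a fixed polarity (excitatory +1 / inhibitory -1);
polarity is structural and never trained. Polarities are assigned per target
neuron by alternating excitatory/inhibitory over a seeded random ordering of
its afferents (excitatory first), so every neuron with two or more afferents
receives both signs — a neuron with only inhibitory inputs could never be
driven above its resting level, which would silence it as a readout. The
whole graph is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

LAYERS = ("sensory", "inter", "command", "motor")

#: (mechanism tag) feasible feed-forward pairs, in construction order
_FORWARD_PAIRS = (("sensory", "inter"), ("inter", "command"), ("command", "motor"))


@dataclass(frozen=True)
class WiringConfig:
    """Layer sizes and synapse-insertion probabilities.

    Defaults give 75 sensory, 14 inter+command (8+6) and 6 motor neurons —
    20 neurons outside the sensory layer.
    """

    n_sensory: int = 75
    n_inter: int = 8
    n_command: int = 6
    n_motor: int = 6
    fanout_per_source: int = 4
    p2: float = 0.5
    p3: float = 0.6
    p4: float = 0.3
    n_recurrent_draws: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sensory", "n_inter", "n_command", "n_motor"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fanout_per_source < 1 or self.n_recurrent_draws < 1:
            raise ValueError("draw counts must be >= 1")
        for name in ("p2", "p3", "p4"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")

    def replace(self, **kw) -> "WiringConfig":
        return replace(self, **kw)

    @property
    def layer_sizes(self) -> dict[str, int]:
        return {
            "sensory": self.n_sensory,
            "inter": self.n_inter,
            "command": self.n_command,
            "motor": self.n_motor,
        }


@dataclass
class WiringGraph:
    """Directed sparse synapse graph over the four neuron layers.

    ``edges`` maps (source_id, target_id) -> (polarity, mechanism) where
    mechanism is 1, 2 or 3. Node ids are contiguous: sensory first, then
    inter, command, motor.
    """

    config: WiringConfig
    edges: dict[tuple[int, int], tuple[int, int]]

    # -- node-id layout -------------------------------------------------------

    @property
    def layer_slices(self) -> dict[str, range]:
        sizes = self.config.layer_sizes
        out, start = {}, 0
        for name in LAYERS:
            out[name] = range(start, start + sizes[name])
            start += sizes[name]
        return out

    @property
    def n_nodes(self) -> int:
        return sum(self.config.layer_sizes.values())

    @property
    def n_hidden(self) -> int:
        """Neurons carrying state: inter + command + motor."""
        c = self.config
        return c.n_inter + c.n_command + c.n_motor

    def layer_of(self, node: int) -> str:
        for name, rng in self.layer_slices.items():
            if node in rng:
                return name
        raise KeyError(f"node {node} out of range")

    # -- dense masks for the cell implementations -----------------------------

    def source_target_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency and polarity as dense (n_sensory + n_hidden, n_hidden) arrays.

        Rows index presynaptic sources (sensory neurons then stateful
        neurons); columns index the stateful neurons in layer order.
        """
        n_src = self.config.n_sensory + self.n_hidden
        n_tgt = self.n_hidden
        adj = np.zeros((n_src, n_tgt))
        pol = np.zeros((n_src, n_tgt))
        offset = self.config.n_sensory  # targets are numbered after sensory
        for (s, t), (polarity, _mech) in self.edges.items():
            adj[s, t - offset] = 1.0
            pol[s, t - offset] = polarity
        return adj, pol

    def out_degrees(self, mechanism: int | None = None) -> dict[int, int]:
        deg: dict[int, int] = {n: 0 for n in range(self.n_nodes)}
        for (s, _t), (_pol, mech) in self.edges.items():
            if mechanism is None or mech == mechanism:
                deg[s] += 1
        return deg

    def in_degrees(self) -> dict[int, int]:
        deg: dict[int, int] = {n: 0 for n in range(self.n_nodes)}
        for (_s, t), _ in self.edges.items():
            deg[t] += 1
        return deg


def _insert(edges, rng, pairs: Iterable[tuple[int, int]], mech: int) -> None:
    for s, t in pairs:
        if (s, t) not in edges:  # duplicates collapse to a single synapse
            edges[(s, t)] = (0, mech)  # polarity assigned in a later pass


def _assign_polarities(edges: dict, rng) -> None:
    """Alternate +1/-1 over a shuffled ordering of each target's afferents."""
    by_target: dict[int, list[tuple[int, int]]] = {}
    for key in edges:
        by_target.setdefault(key[1], []).append(key)
    for t in sorted(by_target):
        keys = by_target[t]
        order = rng.permutation(len(keys))
        for rank, j in enumerate(order):
            pol = 1 if rank % 2 == 0 else -1
            key = keys[j]
            edges[key] = (pol, edges[key][1])


def build_wiring(cfg: WiringConfig | None = None, seed: int | None = None) -> WiringGraph:
    """Construct the sparse NCP graph from ``cfg`` (seed overrides cfg.seed)."""
    cfg = cfg or WiringConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sizes = cfg.layer_sizes
    ids, start = {}, 0
    for name in LAYERS:
        if sizes[name] < 1:
            raise ValueError(f"layer {name} has no eligible neurons")
        ids[name] = np.arange(start, start + sizes[name])
        start += sizes[name]

    edges: dict[tuple[int, int], tuple[int, int]] = {}

    # mechanism 1: Bernoulli(p2) over fanout_per_source distinct candidates
    for src_name, tgt_name in _FORWARD_PAIRS:
        tgt_ids = ids[tgt_name]
        k = min(cfg.fanout_per_source, len(tgt_ids))
        for s in ids[src_name]:
            candidates = rng.choice(tgt_ids, size=k, replace=False)
            kept = candidates[rng.random(k) < cfg.p2]
            _insert(edges, rng, ((int(s), int(t)) for t in kept), mech=1)

    # mechanism 2: top-up for orphan targets, guaranteeing >= 1 afferent
    for src_name, tgt_name in _FORWARD_PAIRS:
        src_ids = ids[src_name]
        have_in = {t for (_s, t) in edges}
        for t in ids[tgt_name]:
            if int(t) in have_in:
                continue
            if cfg.p3 > 0:
                m = 0
                while m == 0:  # redraw until at least one synapse lands
                    m = int(rng.binomial(cfg.fanout_per_source, cfg.p3))
            else:
                m = 1
            chosen = rng.choice(src_ids, size=min(m, len(src_ids)), replace=False)
            _insert(edges, rng, ((int(s), int(t)) for s in chosen), mech=2)

    # mechanism 3: recurrent command -> command synapses
    cmd = ids["command"]
    k = min(cfg.n_recurrent_draws, len(cmd))
    for s in cmd:
        candidates = rng.choice(cmd, size=k, replace=False)
        kept = candidates[rng.random(k) < cfg.p4]
        _insert(edges, rng, ((int(s), int(t)) for t in kept), mech=3)

    _assign_polarities(edges, rng)
    return WiringGraph(config=cfg, edges=edges)


def validate_wiring(g: WiringGraph) -> list[str]:
    """Return human-readable invariant violations (empty list = valid)."""
    violations: list[str] = []
    slices = g.layer_slices
    allowed = set(_FORWARD_PAIRS) | {("command", "command")}
    for (s, t), (pol, mech) in g.edges.items():
        try:
            ls, lt = g.layer_of(s), g.layer_of(t)
        except KeyError as err:
            violations.append(str(err))
            continue
        if (ls, lt) not in allowed:
            violations.append(f"edge {s}->{t} connects {ls}->{lt}, which is not allowed")
        if pol not in (-1, 1):
            violations.append(f"edge {s}->{t} has invalid polarity {pol}")
        if mech not in (1, 2, 3):
            violations.append(f"edge {s}->{t} has unknown mechanism {mech}")
    in_deg = g.in_degrees()
    for name in ("inter", "command", "motor"):
        for t in slices[name]:
            if in_deg[t] == 0:
                violations.append(f"{name} neuron {t} has no incoming synapse")
    return violations


def sparsity(g: WiringGraph) -> float:
    """Edges over feasible synapse slots (layer pairs + command recurrence)."""
    c = g.config
    feasible = (
        c.n_sensory * c.n_inter
        + c.n_inter * c.n_command
        + c.n_command * c.n_motor
        + c.n_command * c.n_command
    )
    return len(g.edges) / feasible
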
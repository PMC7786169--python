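"""Seeded synthetic workflow corpora with known next-tool ground truth.

Real workflow corpora are private server dumps, so every other module is
exercised against corpora drawn from a layered tool-compatibility
grammar: tools are partitioned into layers, each non-terminal tool is
wired to ``fanout`` successors in the next layer (clipped by the layer's
size), and a workflow is a random branching walk through that wiring. Because the
successor map is fixed and layered, every generated graph is acyclic by
construction and the exact set of valid next tools for any context is
known — which is what lets tests score the trained recommender against
ground truth. Monthly usage tables with constant, increasing,
decreasing-to-zero and bursty trends (Poisson noise) emulate the usage
input the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import UsageSeries, WorkflowGraph
from .errors import ValidationError

TREND_TYPES = ("constant", "increasing", "decreasing", "bursty")


@dataclass(frozen=True)
class GrammarSpec:
    """Parameters of the layered tool-compatibility grammar."""

    n_tools: int = 40
    n_layers: int = 5
    fanout: int = 2
    p_shared: float = 0.8
    n_workflows: int = 400
    seed: int = 0
    p_branch: float = 0.25
    start_weights: Mapping[str, float] | None = None
    tool_prefix: str = "tool"  # disambiguates tools of coexisting grammars

    def __post_init__(self) -> None:
        if not self.n_tools >= self.n_layers >= 2:
            raise ValidationError("need n_tools >= n_layers >= 2")
        if self.fanout < 1:
            raise ValidationError("fanout must be >= 1 (otherwise dead ends)")
        if not 0.0 <= self.p_shared <= 1.0:
            raise ValidationError("p_shared must lie in [0, 1]")
        if self.n_workflows < 1:
            raise ValidationError("n_workflows must be >= 1")


def _layers(spec: GrammarSpec) -> list[list[str]]:
    sizes = np.full(spec.n_layers, spec.n_tools // spec.n_layers)
    sizes[: spec.n_tools % spec.n_layers] += 1
    layers = []
    for layer, size in enumerate(sizes):
        layers.append(
            [f"{spec.tool_prefix}{layer:02d}_{i:03d}" for i in range(size)]
        )
    return layers


def _successor_map(
    spec: GrammarSpec, layers: list[list[str]], rng: np.random.Generator
) -> dict[str, tuple[str, ...]]:
    succ: dict[str, tuple[str, ...]] = {}
    for layer, tools in enumerate(layers[:-1]):
        nxt = layers[layer + 1]
        for tool in tools:
            k = min(spec.fanout, len(nxt))
            chosen = rng.choice(len(nxt), size=k, replace=False)
            succ[tool] = tuple(nxt[i] for i in sorted(chosen))
    return succ


def generate_corpus(
    spec: GrammarSpec,
) -> tuple[list[WorkflowGraph], dict[str, frozenset[str]]]:
    """Draw a corpus of workflows plus the grammar's ground-truth map.

    The returned ground truth maps each tool to its exact allowed
    successor set; every edge of every workflow respects it. Output is
    byte-identical for a fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    layers = _layers(spec)
    succ = _successor_map(spec, layers, rng)

    starts = layers[0]
    if spec.start_weights is not None:
        p = np.array([spec.start_weights.get(t, 1.0) for t in starts], dtype=float)
        if p.sum() <= 0:
            raise ValidationError("start_weights sum to zero")
        p = p / p.sum()
    else:
        p = None

    graphs: list[WorkflowGraph] = []
    for wf in range(spec.n_workflows):
        start = starts[int(rng.choice(len(starts), p=p))]
        edges: list[tuple[str, str]] = []
        frontier = [start]
        while frontier:
            node = frontier.pop()
            children = succ.get(node, ())
            if not children:
                continue
            n_take = 2 if len(children) > 1 and rng.random() < spec.p_branch else 1
            picks = rng.choice(len(children), size=n_take, replace=False)
            for i in sorted(picks):
                edge = (node, children[i])
                if edge not in edges:
                    edges.append(edge)
                    frontier.append(children[i])
        graphs.append(
            WorkflowGraph(
                workflow_id=f"{spec.tool_prefix}-wf{wf:05d}",
                edges=tuple(edges),
                is_shared=bool(rng.random() < spec.p_shared),
            )
        )
    ground_truth = {tool: frozenset(children) for tool, children in succ.items()}
    return graphs, ground_truth


def generate_usage(
    n_tools: int,
    months: int = 12,
    seed: int = 0,
    tools: Sequence[str] | None = None,
    end_month: tuple[int, int] = (2024, 12),
    return_trends: bool = False,
):
    """Synthetic monthly usage with mixed trends and Poisson noise.

    Each tool draws a trend type — constant, linearly increasing,
    linearly decreasing to exactly zero, or bursty (low base with spike
    months) — and monthly counts are Poisson around the trend line.
    """
    if months < 2:
        raise ValidationError("months must be >= 2")
    rng = np.random.default_rng(seed)
    if tools is None:
        tools = [f"tool_{i:03d}" for i in range(n_tools)]
    else:
        tools = list(tools)[:n_tools]

    end_ordinal = end_month[0] * 12 + (end_month[1] - 1)
    keys = tuple(
        (o // 12, o % 12 + 1)
        for o in range(end_ordinal - months + 1, end_ordinal + 1)
    )

    series: list[UsageSeries] = []
    trends: dict[str, str] = {}
    for tool in tools:
        trend = TREND_TYPES[int(rng.integers(0, len(TREND_TYPES)))]
        base = float(rng.uniform(20, 500))
        t = np.arange(months, dtype=float)
        if trend == "constant":
            mu = np.full(months, base)
        elif trend == "increasing":
            mu = base + (base * float(rng.uniform(0.5, 2.0))) * t / (months - 1)
        elif trend == "decreasing":
            mu = base * (1.0 - t / (months - 1))  # hits exactly 0 at the end
        else:  # bursty
            mu = np.full(months, base * 0.1)
            n_spikes = int(rng.integers(1, 3))
            spikes = rng.choice(months, size=n_spikes, replace=False)
            mu[spikes] = base * float(rng.uniform(3.0, 6.0))
        counts = rng.poisson(mu)
        if trend == "decreasing":
            counts[-1] = 0  # construction guarantee: ends at zero usage
        series.append(
            UsageSeries(tool=tool, months=keys, counts=tuple(int(c) for c in counts))
        )
        trends[tool] = trend
    if return_trends:
        return series, trends
    return series
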
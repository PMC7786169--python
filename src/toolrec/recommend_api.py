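"""Inference: ranked next-tool recommendations for a query sequence.

The network produces one score per vocabulary tool; candidates are split
into shared and non-shared sets using the persisted shared-capable map
(tools that ever occurred as shared labels during extraction), each set
is sorted by descending score, and the shared block is promoted ahead of
the non-shared block so high-quality tools surface first. Administrators
can replace the predictions for a given last tool (overrides) or append
newly added tools that the model has not seen yet (extra tools).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .encoding import encode_sequence
from .errors import ValidationError

OVERRIDE_SCORE = 1.0  # nominal score for administrator-supplied items


@dataclass(frozen=True)
class RecommendationItem:
    tool: str
    score: float
    category: str  # shared | nonshared | override


@dataclass(frozen=True)
class RecommendationResult:
    query: tuple[str, ...]
    items: tuple[RecommendationItem, ...]
    max_items: int

    def tools(self) -> list[str]:
        return [item.tool for item in self.items]

    def to_dict(self) -> dict:
        return {
            "query": list(self.query),
            "max_items": self.max_items,
            "items": [
                {"tool": i.tool, "score": i.score, "category": i.category}
                for i in self.items
            ],
        }


def score_query(model, query: Sequence[str]) -> np.ndarray:
    """Deterministic forward pass scoring all V tools for one query."""
    _validate_query(model, query)
    x = encode_sequence(list(query), model.vocabulary, model.config.max_len)
    return model.predict(x[None, :])[0]


def _validate_query(model, query: Sequence[str]) -> None:
    if model.vocabulary is None:
        raise ValidationError("model carries no vocabulary")
    if not query:
        raise ValidationError("empty query")
    if len(query) > model.config.max_len - 1:
        raise ValidationError(
            f"query of {len(query)} tools exceeds the maximum of "
            f"{model.config.max_len - 1}"
        )
    for tool in query:
        if tool not in model.vocabulary:
            raise LookupError(f"unknown tool {tool!r}")


def recommend_tools(
    model,
    query: Sequence[str],
    max_items: int = 5,
    overrides: Mapping[str, Sequence[str]] | None = None,
    extra_tools: Sequence[str] | None = None,
) -> RecommendationResult:
    """Ranked recommendations with shared labels promoted to the top.

    If ``overrides`` has an entry for the query's last tool, that list
    replaces the model's predictions entirely. ``extra_tools`` are
    appended after the ranked list, flagged as overrides.
    """
    _validate_query(model, query)
    if max_items < 1:
        raise ValidationError("max_items must be >= 1")

    items: list[RecommendationItem] = []
    if overrides and query[-1] in overrides:
        for tool in overrides[query[-1]]:
            if tool not in {i.tool for i in items}:
                items.append(RecommendationItem(tool, OVERRIDE_SCORE, "override"))
        items = items[:max_items]
    else:
        scores = score_query(model, query)
        shared_capable = model.shared_tools or frozenset()
        id_of = model.vocabulary.id_of
        blocks: dict[str, list[tuple[float, int, str]]] = {
            "shared": [],
            "nonshared": [],
        }
        for idx0 in range(scores.shape[0]):
            tool = id_of[idx0 + 1]
            category = "shared" if tool in shared_capable else "nonshared"
            blocks[category].append((float(scores[idx0]), idx0, tool))
        for category in ("shared", "nonshared"):
            # descending score, ascending tool index on ties
            for score, _, tool in sorted(
                blocks[category], key=lambda t: (-t[0], t[1])
            ):
                items.append(RecommendationItem(tool, score, category))
        items = items[:max_items]

    if extra_tools:
        present = {i.tool for i in items}
        for tool in extra_tools:
            if tool not in present:
                items.append(RecommendationItem(tool, OVERRIDE_SCORE, "override"))
                present.add(tool)

    return RecommendationResult(
        query=tuple(query), items=tuple(items), max_items=max_items
    )
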
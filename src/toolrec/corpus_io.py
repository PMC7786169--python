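"""Read, validate and write the two input tables of the recommender.

Two tab-separated tables drive the whole pipeline:

* a **workflow connection table** — one row per directed tool-to-tool edge,
  with the owning workflow id and the quality flags (``published``,
  ``deleted``, ``has_errors``) that decide whether a workflow counts as
  *shared* (high quality) or *non-shared*;
* a **tool usage table** — monthly usage counts per tool over the trailing
  year, later turned into per-tool class weights.

Tool identifiers are canonicalized on ingestion: repository-style ids such
as ``toolshed.../iuc/trimmomatic/trimmomatic/0.38.0`` collapse to the bare
tool name (``trimmomatic``), merging sequences produced by different tool
versions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

CONNECTION_COLUMNS = (
    "workflow_id",
    "parent_tool",
    "child_tool",
    "published",
    "deleted",
    "has_errors",
)
USAGE_COLUMNS = ("tool_id", "month", "count")

_MONTH_RE = re.compile(r"^(\d{4})-(0[1-9]|1[0-2])$")
_TRUE = {"true", "t", "1", "yes"}
_FALSE = {"false", "f", "0", "no"}


@dataclass(frozen=True)
class WorkflowGraph:
    """One workflow: an acyclic set of directed tool edges plus provenance.

    ``is_shared`` is true for published, non-deleted, non-erroneous
    workflows; labels harvested from them outrank labels from the rest.
    """

    workflow_id: str
    edges: tuple[tuple[str, str], ...]
    is_shared: bool

    def tools(self) -> set[str]:
        """All tool ids appearing in this workflow."""
        out: set[str] = set()
        for parent, child in self.edges:
            out.add(parent)
            out.add(child)
        return out


@dataclass(frozen=True)
class UsageSeries:
    """Monthly usage counts of one tool over a fixed trailing window."""

    tool: str
    months: tuple[tuple[int, int], ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.months) != len(self.counts):
            raise ValidationError("months and counts must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValidationError("usage counts must be non-negative")


def normalize_tool_id(raw_id: str) -> str:
    """Canonicalize a tool id by stripping repository path and version.

    Ids containing ``/`` keep only the second-to-last path component (the
    tool name, dropping the trailing version). Plain ids pass through.
    The rule is idempotent.
    """
    if not raw_id:
        raise ValidationError("tool id must be non-empty")
    if "/" in raw_id:
        parts = raw_id.split("/")
        name = parts[-2]
        if not name:
            raise ValidationError(f"cannot canonicalize tool id {raw_id!r}")
        return name
    return raw_id


def _parse_bool(value: object, column: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise FormatError(f"unparsable boolean {value!r} in column {column!r}")


def _month_key(text: str) -> tuple[int, int]:
    m = _MONTH_RE.match(str(text).strip())
    if m is None:
        raise FormatError(f"malformed month {text!r}; expected ISO YYYY-MM")
    return int(m.group(1)), int(m.group(2))


def _month_ordinal(key: tuple[int, int]) -> int:
    return key[0] * 12 + (key[1] - 1)


def _ordinal_month(ordinal: int) -> tuple[int, int]:
    return ordinal // 12, ordinal % 12 + 1


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_workflow_connections(path) -> list[WorkflowGraph]:
    """Parse a connection table into one :class:`WorkflowGraph` per workflow.

    Rows are grouped by ``workflow_id`` in order of first appearance and a
    workflow is shared iff every row marks it published and no row marks it
    deleted or erroneous. Workflows whose edge set contains a cycle (self
    edges included) are dropped with a logged warning: a workflow is a DAG
    by definition, so a cyclic record is corrupt.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, CONNECTION_COLUMNS, path)

    order: list[str] = []
    edges: dict[str, list[tuple[str, str]]] = {}
    flags: dict[str, list[bool]] = {}
    for row in df.itertuples(index=False):
        wf = str(row.workflow_id)
        try:
            parent = normalize_tool_id(str(row.parent_tool))
            child = normalize_tool_id(str(row.child_tool))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        shared = (
            _parse_bool(row.published, "published")
            and not _parse_bool(row.deleted, "deleted")
            and not _parse_bool(row.has_errors, "has_errors")
        )
        if wf not in edges:
            order.append(wf)
            edges[wf] = []
            flags[wf] = []
        if (parent, child) not in edges[wf]:
            edges[wf].append((parent, child))
        flags[wf].append(shared)

    graphs: list[WorkflowGraph] = []
    for wf in order:
        g = nx.DiGraph(edges[wf])
        if not nx.is_directed_acyclic_graph(g):
            logger.warning("workflow %r contains a cycle; dropped", wf)
            continue
        graphs.append(
            WorkflowGraph(
                workflow_id=wf,
                edges=tuple(edges[wf]),
                is_shared=all(flags[wf]),
            )
        )
    return graphs


def write_workflow_connections(graphs: list[WorkflowGraph], path) -> None:
    """Serialize workflows back to the connection-table dialect."""
    rows = [
        {
            "workflow_id": g.workflow_id,
            "parent_tool": parent,
            "child_tool": child,
            "published": str(g.is_shared).lower(),
            "deleted": "false",
            "has_errors": "false",
        }
        for g in graphs
        for parent, child in g.edges
    ]
    pd.DataFrame(rows, columns=list(CONNECTION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_tool_usage(path, horizon_months: int = 12) -> list[UsageSeries]:
    """Parse a usage table into gap-filled trailing monthly series.

    Counts of ids collapsing to the same canonical tool are summed per
    month. Each series covers exactly ``horizon_months`` consecutive months
    ending at the latest month present anywhere in the table; months with
    no row are filled with 0.
    """
    if horizon_months < 1:
        raise ValidationError("horizon_months must be >= 1")
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, USAGE_COLUMNS, path)
    if df.empty:
        return []

    totals: dict[str, dict[int, int]] = {}
    max_ordinal = None
    for row in df.itertuples(index=False):
        try:
            tool = normalize_tool_id(str(row.tool_id))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        ordinal = _month_ordinal(_month_key(row.month))
        try:
            count = int(str(row.count).strip())
        except ValueError as exc:
            raise FormatError(f"{path}: unparsable count {row.count!r}") from exc
        if count < 0:
            raise FormatError(f"{path}: negative count {count} for {tool!r}")
        totals.setdefault(tool, {})
        totals[tool][ordinal] = totals[tool].get(ordinal, 0) + count
        max_ordinal = ordinal if max_ordinal is None else max(max_ordinal, ordinal)

    window = range(max_ordinal - horizon_months + 1, max_ordinal + 1)
    months = tuple(_ordinal_month(o) for o in window)
    return [
        UsageSeries(
            tool=tool,
            months=months,
            counts=tuple(per_month.get(o, 0) for o in window),
        )
        for tool, per_month in sorted(totals.items())
    ]


def write_tool_usage(series: list[UsageSeries], path) -> None:
    """Serialize usage series back to the usage-table dialect."""
    rows = [
        {"tool_id": s.tool, "month": f"{y:04d}-{m:02d}", "count": c}
        for s in series
        for (y, m), c in zip(s.months, s.counts)
    ]
    pd.DataFrame(rows, columns=list(USAGE_COLUMNS)).to_csv(path, sep="\t", index=False)
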
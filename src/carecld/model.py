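"""Core data model for causal loop diagrams (CLDs).

A CLD is a signed directed graph: *elements* (system variables, each
assigned to one of six conceptual categories used in home-care systems
modelling) joined by *connections* carrying a polarity of +1 (an increase
in the source drives an increase in the target) or -1 (an increase drives
a decrease).  The model object is deliberately dumb — validation, loop
analysis, simulation and metrics all live in sibling modules and operate
on it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

#: The closed category scheme: the core work-stress model, home care staff,
#: home care users, the provider organization, the user's social support
#: network, and societal-level drivers external to the organization.
CATEGORIES: tuple[str, ...] = (
    "stress",
    "home_care_staff",
    "home_care_user",
    "organization",
    "social_support",
    "societal",
)

_SLUG_RE = re.compile(r"[^a-z0-9]+")
_ID_RE = re.compile(r"^[a-z0-9_]+$")


def slugify(label: str) -> str:
    """Derive a stable element id from a free-text label.

    Lowercases, maps every run of non-alphanumeric characters to a single
    underscore and strips leading/trailing underscores, so labels that
    differ only in punctuation map to the same id.
    """
    slug = _SLUG_RE.sub("_", label.lower()).strip("_")
    if not slug:
        raise ValueError(f"label {label!r} produces an empty id")
    return slug


@dataclass(frozen=True)
class ElementNode:
    """One system variable of a CLD."""

    id: str
    label: str
    category: str
    description: str = ""
    evidence_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "evidence_refs", tuple(self.evidence_refs))


@dataclass(frozen=True)
class SignedConnection:
    """A directed causal influence with polarity +1 or -1."""

    source: str
    target: str
    polarity: int
    evidence_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "evidence_refs", tuple(self.evidence_refs))

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class ValidationIssue:
    """A single validation finding; ``severity`` is ``error`` or ``warning``."""

    severity: str
    code: str
    message: str
    subject: str


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant.

    Carries the full list of error-severity :class:`ValidationIssue` so
    callers can report every problem at once.
    """

    def __init__(self, issues: Iterable[ValidationIssue]):
        self.issues = [i for i in issues if i.severity == "error"]
        msgs = "; ".join(f"[{i.code}] {i.message}" for i in self.issues)
        super().__init__(f"invalid CLD model: {msgs}")


class CLDModel:
    """A validated-on-demand signed digraph of categorized elements.

    Elements are stored in insertion order keyed by id; connections as a
    list.  Equality compares the element table and the signed edge set
    (name and metadata are presentation details and are ignored), which is
    what round-tripping through any of the serialization formats
    preserves.
    """

    def __init__(
        self,
        elements: Iterable[ElementNode] = (),
        connections: Iterable[SignedConnection] = (),
        name: str = "model",
        metadata: Mapping[str, str] | None = None,
    ):
        self.name = name
        self.metadata: dict[str, str] = dict(metadata or {})
        self.elements: dict[str, ElementNode] = {}
        for el in elements:
            if el.id in self.elements:
                raise ModelValidationError(
                    [ValidationIssue("error", "duplicate_id",
                                     f"duplicate element id {el.id!r}", el.id)]
                )
            self.elements[el.id] = el
        self.connections: list[SignedConnection] = list(connections)

    # -- basic accessors -------------------------------------------------

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_connections(self) -> int:
        return len(self.connections)

    @property
    def element_ids(self) -> tuple[str, ...]:
        return tuple(self.elements)

    def __contains__(self, element_id: str) -> bool:
        return element_id in self.elements

    def __iter__(self) -> Iterator[ElementNode]:
        return iter(self.elements.values())

    def connection(self, source: str, target: str) -> SignedConnection | None:
        for c in self.connections:
            if c.source == source and c.target == target:
                return c
        return None

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for el in self:
            counts[el.category] = counts.get(el.category, 0) + 1
        return counts

    def elements_in_category(self, category: str) -> list[ElementNode]:
        return [el for el in self if el.category == category]

    # -- graph views -----------------------------------------------------

    def to_digraph(self) -> nx.DiGraph:
        """Signed digraph view; edge attribute ``polarity`` carries the sign."""
        g = nx.DiGraph(name=self.name)
        for el in self:
            g.add_node(el.id, label=el.label, category=el.category)
        for c in self.connections:
            g.add_edge(c.source, c.target, polarity=c.polarity)
        return g

    # -- equality --------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CLDModel):
            return NotImplemented
        return (
            self.elements == other.elements
            and set(self.connections) == set(other.connections)
        )

    def __repr__(self) -> str:
        return (
            f"CLDModel(name={self.name!r}, elements={self.n_elements}, "
            f"connections={self.n_connections})"
        )


def validate_model(model: CLDModel) -> list[ValidationIssue]:
    """Check every structural invariant; report, never raise.

    Error codes: ``unknown_category``, ``bad_polarity``,
    ``dangling_endpoint``, ``self_loop``, ``duplicate_pair``, ``bad_id``.
    Warning codes: ``isolated_element`` (no incident connections).
    """
    issues: list[ValidationIssue] = []
    for el in model:
        if not _ID_RE.match(el.id):
            issues.append(ValidationIssue(
                "error", "bad_id",
                f"element id {el.id!r} is not a lowercase slug", el.id))
        if el.category not in CATEGORIES:
            issues.append(ValidationIssue(
                "error", "unknown_category",
                f"element {el.id!r} has unknown category {el.category!r}",
                el.id))

    seen_pairs: set[tuple[str, str]] = set()
    incident: set[str] = set()
    for c in model.connections:
        subject = f"{c.source}->{c.target}"
        if c.polarity not in (1, -1):
            issues.append(ValidationIssue(
                "error", "bad_polarity",
                f"connection {subject} has polarity {c.polarity!r}, "
                "expected +1 or -1", subject))
        missing = [e for e in (c.source, c.target) if e not in model]
        for e in missing:
            issues.append(ValidationIssue(
                "error", "dangling_endpoint",
                f"connection {subject} references unknown element {e!r}",
                subject))
        if c.source == c.target:
            issues.append(ValidationIssue(
                "error", "self_loop",
                f"self-loop on {c.source!r} is not allowed", subject))
        if c.key in seen_pairs:
            issues.append(ValidationIssue(
                "error", "duplicate_pair",
                f"more than one connection for pair {subject}", subject))
        seen_pairs.add(c.key)
        incident.update((c.source, c.target))

    for el in model:
        if el.id not in incident:
            issues.append(ValidationIssue(
                "warning", "isolated_element",
                f"element {el.id!r} has no incident connections", el.id))
    return issues


def assert_valid(model: CLDModel) -> CLDModel:
    """Raise :class:`ModelValidationError` on any error-severity issue."""
    errors = [i for i in validate_model(model) if i.severity == "error"]
    if errors:
        raise ModelValidationError(errors)
    return model
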
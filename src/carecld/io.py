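"""Readers and writers for CLD models.

Three interchange formats are supported:

``tables``
    A pair of UTF-8 comma-separated files with mandatory header rows:
    ``elements.csv`` (id,label,category,description,evidence_refs) and
    ``connections.csv`` (source,target,polarity,evidence_refs).  Column
    names are matched permissively (e.g. ``from``/``to``/``sign`` are
    accepted for connections), and polarity accepts ``+``, ``-``, ``+1``,
    ``-1`` and the unicode minus.
``json``
    A single document with ``elements`` and ``connections`` arrays in the
    style of Kumu blueprint exports (connection keys ``from``/``to``/
    ``sign``).
``dot``
    Graphviz output only: solid edges for positive connections, dashed
    for negative, mirroring the usual CLD drawing convention.

Loading always validates; any error-severity issue raises
:class:`~carecld.model.ModelValidationError`.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping

from .model import (
    CLDModel,
    ElementNode,
    ModelValidationError,
    SignedConnection,
    ValidationIssue,
    assert_valid,
)

FORMATS = ("tables", "json", "dot")

_ELEMENT_ALIASES = {
    "id": "id", "element": "id", "element_id": "id", "slug": "id",
    "label": "label", "name": "label", "title": "label",
    "category": "category", "type": "category", "group": "category",
    "description": "description", "notes": "description",
    "evidence_refs": "evidence_refs", "evidence": "evidence_refs",
    "references": "evidence_refs", "refs": "evidence_refs",
}
_CONNECTION_ALIASES = {
    "source": "source", "from": "source", "src": "source",
    "target": "target", "to": "target", "dst": "target",
    "polarity": "polarity", "sign": "polarity", "direction": "polarity",
    "evidence_refs": "evidence_refs", "evidence": "evidence_refs",
    "references": "evidence_refs", "refs": "evidence_refs",
}
_POLARITY_TOKENS = {
    "+": 1, "+1": 1, "1": 1, "positive": 1, "pos": 1,
    "-": -1, "-1": -1, "−": -1, "−1": -1,
    "negative": -1, "neg": -1,
}


def _split_refs(raw: str | None) -> tuple[str, ...]:
    if not raw:
        return ()
    return tuple(part.strip() for part in raw.split(";") if part.strip())


def _join_refs(refs: Iterable[str]) -> str:
    return "; ".join(refs)


def _remap(row: Mapping[str, str], aliases: Mapping[str, str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for key, value in row.items():
        if key is None:
            continue
        canon = aliases.get(key.strip().lower())
        if canon is not None and canon not in out:
            out[canon] = (value or "").strip()
    return out


def parse_polarity(token: str | int) -> int:
    """Parse a polarity cell; raises ``ValueError`` on anything unexpected."""
    if isinstance(token, int):
        if token in (1, -1):
            return token
        raise ValueError(f"unparseable polarity {token!r}")
    value = _POLARITY_TOKENS.get(str(token).strip().lower())
    if value is None:
        raise ValueError(f"unparseable polarity {token!r}")
    return value


def _read_rows(path: Path, aliases: Mapping[str, str],
               required: tuple[str, ...]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ModelValidationError([ValidationIssue(
                "error", "missing_header", f"{path} is empty", str(path))])
        rows = [_remap(row, aliases) for row in reader]
    header = {aliases.get(h.strip().lower()) for h in reader.fieldnames}
    missing = [col for col in required if col not in header]
    if missing:
        raise ModelValidationError([ValidationIssue(
            "error", "missing_header",
            f"{path} lacks required column(s) {missing}", str(path))])
    return rows


def load_model(elements_path: str | Path, connections_path: str | Path,
               name: str | None = None) -> CLDModel:
    """Load and validate a model from the two-table format."""
    elements_path = Path(elements_path)
    connections_path = Path(connections_path)
    el_rows = _read_rows(elements_path, _ELEMENT_ALIASES, ("id", "label", "category"))
    co_rows = _read_rows(connections_path, _CONNECTION_ALIASES,
                         ("source", "target", "polarity"))

    issues: list[ValidationIssue] = []
    elements: list[ElementNode] = []
    seen_ids: set[str] = set()
    for row in el_rows:
        eid = row.get("id", "")
        if eid in seen_ids:
            issues.append(ValidationIssue(
                "error", "duplicate_id", f"duplicate element id {eid!r}", eid))
            continue
        seen_ids.add(eid)
        elements.append(ElementNode(
            id=eid,
            label=row.get("label", eid),
            category=row.get("category", ""),
            description=row.get("description", ""),
            evidence_refs=_split_refs(row.get("evidence_refs")),
        ))

    connections: list[SignedConnection] = []
    for row in co_rows:
        subject = f"{row.get('source', '?')}->{row.get('target', '?')}"
        try:
            polarity = parse_polarity(row.get("polarity", ""))
        except ValueError as exc:
            issues.append(ValidationIssue("error", "bad_polarity", str(exc), subject))
            continue
        connections.append(SignedConnection(
            source=row.get("source", ""),
            target=row.get("target", ""),
            polarity=polarity,
            evidence_refs=_split_refs(row.get("evidence_refs")),
        ))

    if any(i.severity == "error" for i in issues):
        raise ModelValidationError(issues)
    model = CLDModel(elements, connections,
                     name=name or elements_path.stem.replace("elements", "").strip("_.") or "model")
    return assert_valid(model)


def model_to_dict(model: CLDModel) -> dict:
    """Kumu-blueprint-like JSON structure."""
    return {
        "name": model.name,
        "metadata": dict(model.metadata),
        "elements": [
            {
                "id": el.id,
                "label": el.label,
                "category": el.category,
                "description": el.description,
                "evidence_refs": list(el.evidence_refs),
            }
            for el in model
        ],
        "connections": [
            {
                "from": c.source,
                "to": c.target,
                "sign": "+" if c.polarity > 0 else "-",
                "evidence_refs": list(c.evidence_refs),
            }
            for c in model.connections
        ],
    }


def model_from_dict(doc: Mapping) -> CLDModel:
    issues: list[ValidationIssue] = []
    elements = [
        ElementNode(
            id=e.get("id") or e["label"],
            label=e.get("label", e.get("id", "")),
            category=e.get("category", ""),
            description=e.get("description", ""),
            evidence_refs=tuple(e.get("evidence_refs", ())),
        )
        for e in doc.get("elements", ())
    ]
    connections = []
    for c in doc.get("connections", ()):
        subject = f"{c.get('from', '?')}->{c.get('to', '?')}"
        try:
            polarity = parse_polarity(c.get("sign", c.get("polarity", "")))
        except ValueError as exc:
            issues.append(ValidationIssue("error", "bad_polarity", str(exc), subject))
            continue
        connections.append(SignedConnection(
            source=c.get("from", c.get("source", "")),
            target=c.get("to", c.get("target", "")),
            polarity=polarity,
            evidence_refs=tuple(c.get("evidence_refs", ())),
        ))
    if issues:
        raise ModelValidationError(issues)
    model = CLDModel(elements, connections,
                     name=doc.get("name", "model"),
                     metadata=doc.get("metadata", {}))
    return assert_valid(model)


def load_model_json(path: str | Path) -> CLDModel:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))


def load_model_dir(path: str | Path) -> CLDModel:
    """Load a model from a directory holding either the table pair or model.json."""
    path = Path(path)
    if (path / "elements.csv").exists() and (path / "connections.csv").exists():
        return load_model(path / "elements.csv", path / "connections.csv",
                          name=path.name)
    if (path / "model.json").exists():
        return load_model_json(path / "model.json")
    raise FileNotFoundError(
        f"{path} contains neither elements.csv/connections.csv nor model.json")


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def model_to_dot(model: CLDModel) -> str:
    """Graphviz digraph; solid edges for +, dashed for -."""
    lines = [f'digraph "{_dot_escape(model.name)}" {{']
    for el in model:
        lines.append(
            f'  "{el.id}" [label="{_dot_escape(el.label)}", '
            f'category="{el.category}"];'
        )
    for c in model.connections:
        style = "solid" if c.polarity > 0 else "dashed"
        sign = "+" if c.polarity > 0 else "−"
        lines.append(
            f'  "{c.source}" -> "{c.target}" [style={style}, label="{sign}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_model(model: CLDModel, out_dir: str | Path,
                format: str = "tables") -> list[Path]:
    """Write ``model`` to ``out_dir`` in the requested format; returns paths."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if format == "tables":
        el_path = out_dir / "elements.csv"
        co_path = out_dir / "connections.csv"
        with open(el_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
            writer.writerow(["id", "label", "category", "description",
                             "evidence_refs"])
            for el in model:
                writer.writerow([el.id, el.label, el.category, el.description,
                                 _join_refs(el.evidence_refs)])
        with open(co_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
            writer.writerow(["source", "target", "polarity", "evidence_refs"])
            for c in model.connections:
                writer.writerow([c.source, c.target,
                                 "+1" if c.polarity > 0 else "-1",
                                 _join_refs(c.evidence_refs)])
        return [el_path, co_path]

    if format == "json":
        path = out_dir / "model.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(model_to_dict(model), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return [path]

    path = out_dir / "model.dot"
    path.write_text(model_to_dot(model), encoding="utf-8")
    return [path]
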
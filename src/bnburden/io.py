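"""Reading and writing networks: package JSON dialect and XMLBIF 0.3.

The JSON dialect is the native format: it round-trips everything including
role tags, an optional disability-weight registry and elicitation metadata
(schema in ``docs/schemas/network.schema.json``).  XMLBIF 0.3 is supported
for interchange with other Bayesian-network tools; it has no notion of
clinical roles, so writing emits a warning and reading assigns the neutral
role ``derived``.  CPT values round-trip at full float precision in both
formats.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .burden import BurdenRegistry
from .errors import InputError, ParseError
from .network import CPT, Network, NodeSpec

JSON_FORMAT_NAME = "bnburden-network"
JSON_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# JSON dialect


def network_to_dict(net: Network, registry: BurdenRegistry | None = None) -> dict:
    doc = {
        "format": JSON_FORMAT_NAME,
        "version": JSON_FORMAT_VERSION,
        "metadata": dict(net.metadata),
        "nodes": [
            {
                "name": spec.name,
                "states": list(spec.states),
                "role": spec.role,
                "parents": list(spec.parents),
                "cpt": net.cpt(spec.name).tolist(),
            }
            for spec in net.nodes
        ],
    }
    if registry is not None:
        doc["burden_registry"] = registry.to_list()
    return doc


def network_from_dict(doc: dict) -> tuple[Network, BurdenRegistry | None]:
    if doc.get("format") != JSON_FORMAT_NAME:
        raise ParseError(
            f"not a {JSON_FORMAT_NAME} document (format={doc.get('format')!r})"
        )
    nodes, cpts = [], []
    for i, nd in enumerate(doc.get("nodes", [])):
        try:
            nodes.append(
                NodeSpec(
                    name=nd["name"],
                    states=tuple(nd["states"]),
                    role=nd.get("role", "derived"),
                    parents=tuple(nd.get("parents", ())),
                )
            )
            cpts.append(CPT(nd["name"], np.asarray(nd["cpt"], dtype=float)))
        except (KeyError, InputError, TypeError, ValueError) as exc:
            raise ParseError(f"nodes[{i}]: {exc}") from exc
    registry = None
    if "burden_registry" in doc:
        registry = BurdenRegistry.from_list(doc["burden_registry"])
    return Network(nodes, cpts, metadata=doc.get("metadata", {})), registry


def write_network_json(
    net: Network, path: str | Path, registry: BurdenRegistry | None = None
) -> None:
    doc = network_to_dict(net, registry)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False), encoding="utf-8")


def read_network_json(path: str | Path) -> tuple[Network, BurdenRegistry | None]:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
    return network_from_dict(doc)


# ---------------------------------------------------------------------------
# XMLBIF 0.3


def write_network_xmlbif(net: Network, path: str | Path, name: str = "network") -> None:
    if any(spec.role != "derived" for spec in net.nodes):
        warnings.warn(
            "XMLBIF cannot represent clinical role tags; roles are dropped "
            "(use the JSON dialect to preserve them)",
            UserWarning,
            stacklevel=2,
        )
    bif = ET.Element("BIF", VERSION="0.3")
    network = ET.SubElement(bif, "NETWORK")
    ET.SubElement(network, "NAME").text = name
    for spec in net.nodes:
        var = ET.SubElement(network, "VARIABLE", TYPE="nature")
        ET.SubElement(var, "NAME").text = spec.name
        for state in spec.states:
            ET.SubElement(var, "OUTCOME").text = state
    for spec in net.nodes:
        definition = ET.SubElement(network, "DEFINITION")
        ET.SubElement(definition, "FOR").text = spec.name
        for p in spec.parents:
            ET.SubElement(definition, "GIVEN").text = p
        # XMLBIF table order: parent combinations row-major (last GIVEN
        # fastest), the node's own states fastest of all — exactly the
        # flattened internal layout.
        flat = net.cpt(spec.name).ravel()
        ET.SubElement(definition, "TABLE").text = " ".join(repr(float(x)) for x in flat)
    tree = ET.ElementTree(bif)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def read_network_xmlbif(path: str | Path) -> Network:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "BIF":
        raise ParseError(f"{path}: root element is <{root.tag}>, expected <BIF>")
    network = root.find("NETWORK")
    if network is None:
        raise ParseError(f"{path}: missing <NETWORK> element")

    states: dict[str, tuple[str, ...]] = {}
    var_order: list[str] = []
    for var in network.findall("VARIABLE"):
        name_el = var.find("NAME")
        if name_el is None or not (name_el.text or "").strip():
            raise ParseError(f"{path}: <VARIABLE> without a <NAME>")
        vname = name_el.text.strip()
        outcomes = tuple((o.text or "").strip() for o in var.findall("OUTCOME"))
        if len(outcomes) < 2:
            raise ParseError(f"{path}: variable {vname!r} has fewer than 2 <OUTCOME>s")
        states[vname] = outcomes
        var_order.append(vname)

    specs: list[NodeSpec] = []
    cpts: list[CPT] = []
    seen: set[str] = set()
    for definition in network.findall("DEFINITION"):
        for_el = definition.find("FOR")
        if for_el is None or not (for_el.text or "").strip():
            raise ParseError(f"{path}: <DEFINITION> without a <FOR>")
        vname = for_el.text.strip()
        if vname not in states:
            raise ParseError(f"{path}: <DEFINITION> for undeclared variable {vname!r}")
        parents = tuple((g.text or "").strip() for g in definition.findall("GIVEN"))
        for p in parents:
            if p not in states:
                raise ParseError(f"{path}: variable {vname!r} conditioned on undeclared {p!r}")
        table_el = definition.find("TABLE")
        if table_el is None:
            raise ParseError(f"{path}: <DEFINITION> for {vname!r} missing <TABLE>")
        try:
            values = np.array([float(x) for x in (table_el.text or "").split()])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric entry in table for {vname!r}") from exc
        card = len(states[vname])
        n_rows = int(np.prod([len(states[p]) for p in parents])) if parents else 1
        if values.size != n_rows * card:
            raise ParseError(
                f"{path}: table for {vname!r} has {values.size} entries, "
                f"expected {n_rows * card} ({n_rows} rows x {card} states)"
            )
        specs.append(NodeSpec(name=vname, states=states[vname], role="derived", parents=parents))
        cpts.append(CPT(vname, values.reshape(n_rows, card)))
        seen.add(vname)

    undefined = [v for v in var_order if v not in seen]
    if undefined:
        raise ParseError(f"{path}: variables without <DEFINITION>: {undefined}")
    # keep declaration order of <VARIABLE>
    by_name = {s.name: s for s in specs}
    specs = [by_name[v] for v in var_order]
    return Network(specs, cpts, metadata={"source": "xmlbif"})


# ---------------------------------------------------------------------------
# format dispatch


def write_network(
    net: Network,
    path: str | Path,
    format: str | None = None,
    registry: BurdenRegistry | None = None,
) -> None:
    fmt = format or _infer_format(path)
    if fmt == "json":
        write_network_json(net, path, registry)
    elif fmt == "xmlbif":
        write_network_xmlbif(net, path)
    else:
        raise InputError(f"unknown format {fmt!r}; use 'json' or 'xmlbif'")


def read_network(path: str | Path, format: str | None = None) -> Network:
    fmt = format or _infer_format(path)
    if fmt == "json":
        return read_network_json(path)[0]
    if fmt == "xmlbif":
        return read_network_xmlbif(path)
    raise InputError(f"unknown format {fmt!r}; use 'json' or 'xmlbif'")


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".xmlbif", ".bif"):
        return "xmlbif"
    raise InputError(f"cannot infer format from {path}; pass format= explicitly")
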
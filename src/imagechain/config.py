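"""Chain configuration files.

One JSON document defines a full comparison experiment: the candidate
chains (extractors with parameters, optional selector cascade, one
classifier), the evaluation protocol and the input description.  Unknown
keys are rejected with their location so typos fail loudly.

Example::

    {
      "protocol": {"folds": 5, "repeats": 5, "seed": 1},
      "io": {"mode": "directory-tree", "channel": "all",
             "geometry": {"rx": 3, "ry": 3, "rz": 2}},
      "chains": [
        {"name": "haar+3nn",
         "extractors": [{"name": "haar2d", "levels": 2,
                         "pooling": "subband-stats"}],
         "selectors": [{"criterion": "fisher", "n_keep": 40}],
         "classifier": {"kind": "knn", "k": 3}}
      ]
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from .chains import AlgorithmChain, EvaluationProtocol
from .classifiers import ClassifierSpec
from .errors import ConfigurationError
from .registry import PluginRegistry, default_registry
from .selection import SelectorSpec
from .volume import PatchGeometry

_PROTOCOL_KEYS = {"folds", "repeats", "seed", "stratified", "mode"}
_IO_KEYS = {"mode", "channel", "geometry", "path", "target_file", "image"}
_CHAIN_KEYS = {"name", "extractors", "selectors", "classifier"}
_SELECTOR_KEYS = {"criterion", "n_keep"}
_CLASSIFIER_KEYS = {"kind", "k", "C", "n_trees", "max_depth", "seed",
                    "zscale"}
_TOP_KEYS = {"protocol", "io", "chains"}
_GEOMETRY_KEYS = {"rx", "ry", "rz"}


def _check_keys(obj: Dict, allowed: set, where: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise ConfigurationError(
            f"{where}: unknown key(s) {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")


@dataclass
class ExperimentConfig:
    chains: List[AlgorithmChain]
    protocol: EvaluationProtocol
    io: Dict = field(default_factory=dict)

    @property
    def geometry(self) -> Optional[PatchGeometry]:
        g = self.io.get("geometry")
        return None if g is None else PatchGeometry(**g)


def parse_config(doc: Dict,
                 registry: PluginRegistry | None = None
                 ) -> ExperimentConfig:
    registry = registry if registry is not None else default_registry
    if not isinstance(doc, dict):
        raise ConfigurationError("config root must be a JSON object")
    _check_keys(doc, _TOP_KEYS, "config")
    proto_doc = dict(doc.get("protocol", {}))
    _check_keys(proto_doc, _PROTOCOL_KEYS, "protocol")
    protocol = EvaluationProtocol(**proto_doc)
    io_doc = dict(doc.get("io", {}))
    _check_keys(io_doc, _IO_KEYS, "io")
    if "geometry" in io_doc and io_doc["geometry"] is not None:
        _check_keys(dict(io_doc["geometry"]), _GEOMETRY_KEYS, "io.geometry")
    chains_doc = doc.get("chains")
    if not chains_doc:
        raise ConfigurationError("config lists no chains")
    chains: List[AlgorithmChain] = []
    for i, cdoc in enumerate(chains_doc):
        where = f"chains[{i}]"
        _check_keys(cdoc, _CHAIN_KEYS, where)
        name = cdoc.get("name", f"chain-{i}")
        ext_docs = cdoc.get("extractors")
        if not ext_docs:
            raise ConfigurationError(f"{where}: needs >= 1 extractor")
        extractors = []
        for j, edoc in enumerate(ext_docs):
            edoc = dict(edoc)
            ename = edoc.pop("name", None)
            if ename is None:
                raise ConfigurationError(
                    f"{where}.extractors[{j}]: missing 'name'")
            if "scales" in edoc:  # JSON lists -> tuples for hashability
                edoc["scales"] = tuple(edoc["scales"])
            extractors.append(registry.make("extractor", ename, **edoc))
        selectors = []
        for j, sdoc in enumerate(cdoc.get("selectors", []) or []):
            _check_keys(sdoc, _SELECTOR_KEYS, f"{where}.selectors[{j}]")
            selectors.append(SelectorSpec(**sdoc))
        cls_doc = dict(cdoc.get("classifier", {}))
        _check_keys(cls_doc, _CLASSIFIER_KEYS, f"{where}.classifier")
        classifier = ClassifierSpec(**cls_doc)
        chains.append(AlgorithmChain(name=name, extractors=extractors,
                                     selectors=selectors,
                                     classifier=classifier))
    names = [c.name for c in chains]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate chain names: {names}")
    return ExperimentConfig(chains=chains, protocol=protocol, io=io_doc)


def load_config(path: str | Path,
                registry: PluginRegistry | None = None) -> ExperimentConfig:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}:{exc.lineno}: invalid JSON: "
                                 f"{exc.msg}")
    return parse_config(doc, registry)
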
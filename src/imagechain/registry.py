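"""Plugin registry for extractors, selectors and classifiers.

Built-ins are pre-registered; third-party algorithms are added under a new
name and become addressable from chain configurations.  An extractor is
contract-checked on first use: its output length must be a function of its
configuration only, never of image content.
"""

from __future__ import annotations

from typing import Callable, Dict

import numpy as np

from .classifiers import ClassifierSpec
from .errors import ConfigurationError, ContractError
from .extractors import BUILTIN_EXTRACTORS, Extractor
from .selection import SelectorSpec
from .volume import ImageVolume

KINDS = ("extractor", "selector", "classifier")


class PluginRegistry:
    def __init__(self) -> None:
        self._plugins: Dict[str, Dict[str, Callable]] = {
            k: {} for k in KINDS}
        self._checked: set = set()
        for name, ctor in BUILTIN_EXTRACTORS.items():
            self._plugins["extractor"][name] = ctor
        self._plugins["selector"]["fisher"] = SelectorSpec
        self._plugins["classifier"]["default"] = ClassifierSpec

    def register(self, kind: str, name: str,
                 constructor: Callable) -> None:
        if kind not in KINDS:
            raise ConfigurationError(f"unknown plugin kind {kind!r}")
        if name in self._plugins[kind]:
            raise ConfigurationError(
                f"{kind} plugin {name!r} is already registered")
        self._plugins[kind][name] = constructor

    def names(self, kind: str) -> list:
        return sorted(self._plugins[kind])

    def make(self, kind: str, name: str, **params):
        if name not in self._plugins[kind]:
            raise ConfigurationError(
                f"unknown {kind} {name!r}; registered: {self.names(kind)}")
        try:
            obj = self._plugins[kind][name](**params)
        except TypeError as exc:
            raise ConfigurationError(f"{kind} {name!r}: {exc}")
        if kind == "extractor":
            self._check_extractor(name, obj, params)
        return obj

    def _check_extractor(self, name: str, obj: Extractor,
                         params: dict) -> None:
        """Output length must not depend on image content."""
        key = (name, tuple(sorted(params.items())))
        if key in self._checked:
            return
        if not hasattr(obj, "extract"):
            raise ContractError(
                f"extractor {name!r} lacks an extract(volume) method")
        rng = np.random.default_rng(12345)
        lengths = set()
        for _ in range(2):
            probe = ImageVolume(rng.uniform(0, 1, (3, 16, 16)))
            lengths.add(len(obj.extract(probe).values))
        if len(lengths) != 1:
            raise ContractError(
                f"extractor {name!r} violates the output-length contract: "
                f"lengths {sorted(lengths)} on probe images")
        self._checked.add(key)


default_registry = PluginRegistry()


def register_plugin(kind: str, name: str, constructor: Callable,
                    registry: PluginRegistry | None = None) -> PluginRegistry:
    reg = registry if registry is not None else default_registry
    reg.register(kind, name, constructor)
    return reg
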
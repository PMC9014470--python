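"""Shared surface-string normalization used for all membership tests."""

from __future__ import annotations

import re
from dataclasses import dataclass

_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class NormalizationPolicy:
    """Normalization applied before comparing mention surfaces.

    Case-folding plus internal-whitespace collapsing by default; no stemming.
    The policy travels with every inventory/dictionary it built so results
    record how matching was done.
    """

    casefold: bool = True
    collapse_whitespace: bool = True

    def normalize(self, surface: str) -> str:
        s = surface.strip()
        if self.collapse_whitespace:
            s = _WS_RE.sub(" ", s)
        if self.casefold:
            s = s.casefold()
        return s

    def describe(self) -> str:
        parts = []
        if self.casefold:
            parts.append("casefold")
        if self.collapse_whitespace:
            parts.append("collapse-whitespace")
        return "+".join(parts) or "identity"


DEFAULT_POLICY = NormalizationPolicy()
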
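"""Built-in parameter presets used throughout the examples and tests."""

from __future__ import annotations

from dataclasses import dataclass

from .params import ModelParams

__all__ = ["Preset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class Preset:
    name: str
    params: ModelParams
    description: str


_BASE = dict(A=7.0, d=0.7, v=4.0, c=2.5, theta=0.1, b=1.0, q=0.22)

PRESETS: dict[str, Preset] = {
    "fig1": Preset(
        "fig1",
        ModelParams(beta=1.0, S_T=8.0, **_BASE),
        "baseline: R0 ~ 1.39, mu2 barely above 1 (semi-trivial orbit unstable)",
    ),
    "fig2a": Preset(
        "fig2a",
        ModelParams(beta=0.8, S_T=6.3, **_BASE),
        "low threshold: semi-trivial orbit globally attracting",
    ),
    "fig2b": Preset(
        "fig2b",
        ModelParams(beta=0.8, S_T=8.0, **_BASE),
        "bistable: stable semi-trivial orbit + stable endemic point, "
        "separated by an unstable order-1 periodic orbit",
    ),
}


def get_preset(name: str) -> ModelParams:
    """Return the parameter set of a named preset."""
    try:
        return PRESETS[name].params
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
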
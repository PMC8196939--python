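"""Model parameters for the impulsive SIS system with saturated treatment.

The continuous core is a planar SIS model with recruitment ``A``, natural
death ``d``, mass-action transmission ``beta``, spontaneous recovery ``v``,
vaccine waning ``theta`` and a saturating hospital-treatment term
``c*I/(b+I)``.  The control layer is a state-dependent pulse: whenever the
susceptible population grows to the threshold ``S_T``, a fraction ``q`` of
susceptibles is vaccinated instantaneously, resetting S to ``(1-q)*S_T``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

__all__ = ["ModelParams", "ParamError"]

#: ordered parameter names used by config files and CSV headers
PARAM_NAMES = ("A", "d", "beta", "v", "theta", "c", "b", "q", "S_T")


class ParamError(ValueError):
    """Raised when a parameter set violates the model invariants."""


@dataclass(frozen=True)
class ModelParams:
    """The nine constants of the pulsed SIS model.

    Units: ``A`` individuals/time; ``d``, ``v``, ``theta`` 1/time;
    ``beta`` 1/(individuals*time); ``c`` individuals/time; ``b``, ``S_T``
    individuals; ``q`` dimensionless.

    Invariants: all of ``A, d, beta, v, c, b`` positive, ``theta >= 0``,
    ``0 < q < 1`` and ``0 < S_T < A/d`` (the threshold must lie below the
    demographic carrying level ``A/d``, otherwise S never reaches it).
    """

    A: float
    d: float
    beta: float
    v: float
    theta: float
    c: float
    b: float
    q: float
    S_T: float

    def __post_init__(self) -> None:
        for name in ("A", "d", "beta", "v", "c", "b"):
            if not getattr(self, name) > 0:
                raise ParamError(f"parameter {name} must be positive, got {getattr(self, name)!r}")
        if not self.theta >= 0:
            raise ParamError(f"parameter theta must be nonnegative, got {self.theta!r}")
        if not 0 < self.q < 1:
            raise ParamError(f"parameter q must lie in (0, 1), got {self.q!r}")
        if not 0 < self.S_T < self.A / self.d:
            raise ParamError(
                f"parameter S_T must lie in (0, A/d) = (0, {self.A / self.d!r}), got {self.S_T!r}"
            )

    @property
    def carrying_level(self) -> float:
        """Demographic equilibrium A/d of the total population."""
        return self.A / self.d

    def replace(self, **changes: float) -> "ModelParams":
        """Return a validated copy with the given fields changed."""
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
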
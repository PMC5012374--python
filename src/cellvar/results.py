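"""Shared result containers for the statistical tests in the pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: allowed values of :attr:`EnrichmentResult.effect_direction`
DIRECTIONS = ("higher_cv", "lower_cv", "enriched", "depleted", "none")


@dataclass
class EnrichmentResult:
    """Outcome of one named two-group or set-overlap test.

    ``evaluated`` is False when a precondition (e.g. a minimum group size)
    failed; statistic and p-value are then NaN and must not be interpreted.
    """

    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    effect_direction: str
    evaluated: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.effect_direction not in DIRECTIONS:
            raise ValueError(f"unknown effect direction {self.effect_direction!r}")
        if self.evaluated and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @classmethod
    def not_evaluated(cls, test_name: str, n_a: int = 0, n_b: int = 0, reason: str = "") -> "EnrichmentResult":
        return cls(
            test_name=test_name,
            statistic=math.nan,
            p_value=math.nan,
            n_a=n_a,
            n_b=n_b,
            effect_direction="none",
            evaluated=False,
            extras={"reason": reason} if reason else {},
        )

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "effect_direction": self.effect_direction,
            "evaluated": self.evaluated,
        }
        for k in sorted(self.extras):
            d[k] = self.extras[k]
        return d
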
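"""Shared result containers for effectiveness estimates."""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class EffectEstimate:
    """One (method, outcome, subgroup) screening-effectiveness cell.

    ``relative_pct`` is the percentage reduction in cumulative lung-cancer
    mortality in the CT arm (100 x (1 - risk ratio) of standardized risks);
    ``abs_per_1000`` is deaths prevented per 1000 randomized participants.
    """

    method: str
    trial: str
    outcome: str
    subgroup: str
    relative_pct: float
    abs_per_1000: float
    rel_ci: tuple[float, float] = (math.nan, math.nan)
    abs_ci: tuple[float, float] = (math.nan, math.nan)
    n_events: int = 0
    n: int = 0
    flagged: str | None = None

    def __post_init__(self) -> None:
        if math.isfinite(self.relative_pct) and self.relative_pct > 100.0 + 1e-9:
            raise ValueError("relative effectiveness cannot exceed 100%")
        lo, hi = self.rel_ci
        if (math.isfinite(lo) and math.isfinite(hi)
                and math.isfinite(self.relative_pct)):
            if not (lo <= self.relative_pct + 1e-9 and self.relative_pct - 1e-9 <= hi):
                raise ValueError(
                    f"CI ({lo}, {hi}) does not contain estimate {self.relative_pct}")

    def to_row(self) -> dict:
        return {
            "method": self.method, "trial": self.trial, "outcome": self.outcome,
            "subgroup": self.subgroup, "estimate_pct": self.relative_pct,
            "ci_low": self.rel_ci[0], "ci_high": self.rel_ci[1],
            "abs_per_1000": self.abs_per_1000,
            "abs_ci_low": self.abs_ci[0], "abs_ci_high": self.abs_ci[1],
            "n_events": self.n_events, "n": self.n, "flagged": self.flagged,
        }
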
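"""Choosing the best similarity function for a dataset.

Given each candidate function's GOOD-curve summaries (dynamic range and
monotonicity), the four-step rule is:

1. drop candidates whose monotonicity is below ``mono_min`` (default 0.4) —
   they violate the assumption that performance tracks the threshold;
2. keep candidates whose dynamic range is within ``delta`` of the best
   (delta starts at ``delta0`` = 0.2 on the 0-1 scale, i.e. 20 percentage
   points);
3. if fewer than ``k`` (default 3) candidates survive, relax delta by
   ``eps`` (default 0.1) and repeat step 2, until k survive or every
   step-1 survivor is included;
4. of the survivors, pick the one with the highest monotonicity (ties:
   larger dynamic range, then name).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .good_curve import GoodCurve


@dataclass(frozen=True)
class CandidateSummary:
    """One similarity function's curve summaries."""

    name: str
    dynamic_range: float  # percentage points, [0, 100]
    monotonicity: float  # Spearman's rho, [-1, 1]
    monotonicity_sd: float = 0.0

    def __post_init__(self):
        if not 0 <= self.dynamic_range <= 100:
            raise ValueError("dynamic_range must lie in [0, 100]")
        if not -1 <= self.monotonicity <= 1:
            raise ValueError("monotonicity must lie in [-1, 1]")

    @classmethod
    def from_curve(cls, name: str, curve: GoodCurve) -> "CandidateSummary":
        return cls(name=name, dynamic_range=curve.dynamic_range,
                   monotonicity=curve.monotonicity_mean,
                   monotonicity_sd=curve.monotonicity_sd)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the four-step rule.

    ``delta0`` and ``eps`` are on the 0-1 scale of dynamic range / 100, so
    the defaults mean "within 20 percentage points, relaxed by 10".
    """

    mono_min: float = 0.4
    delta0: float = 0.2
    k: int = 3
    eps: float = 0.1
    recompute_max_after_filter: bool = True

    def __post_init__(self):
        if min(self.mono_min, self.delta0, self.eps) <= 0 or self.k < 1:
            raise ValueError("selection parameters must be positive")


@dataclass
class SelectionResult:
    """Chosen function with the per-delta survivor trace."""

    chosen: Optional[str]
    delta_final: float
    rounds: List[Dict] = field(default_factory=list)
    diagnostic: str = ""


def select_similarity_function(candidates: Sequence[CandidateSummary],
                               cfg: SelectionConfig = SelectionConfig()
                               ) -> SelectionResult:
    """Apply the four-step selection rule to a candidate table."""
    if not candidates:
        raise ValueError("no candidates")
    names = [c.name for c in candidates]
    if len(set(names)) != len(names):
        raise ValueError("duplicate candidate names")
    step1 = [c for c in candidates if c.monotonicity >= cfg.mono_min]
    if not step1:
        return SelectionResult(
            chosen=None, delta_final=cfg.delta0,
            diagnostic="no function satisfies the monotonicity assumption "
                       f"(all below {cfg.mono_min})")
    pool = step1 if cfg.recompute_max_after_filter else list(candidates)
    best_dr = max(c.dynamic_range for c in pool) / 100.0
    delta = cfg.delta0
    rounds: List[Dict] = []
    while True:
        survivors = [c for c in step1
                     if c.dynamic_range / 100.0 >= best_dr - delta - 1e-12]
        rounds.append({"delta": round(delta, 10),
                       "survivors": [c.name for c in survivors]})
        if len(survivors) >= cfg.k or len(survivors) == len(step1):
            break
        delta += cfg.eps
    winner = sorted(survivors,
                    key=lambda c: (-c.monotonicity, -c.dynamic_range, c.name))[0]
    return SelectionResult(chosen=winner.name, delta_final=round(delta, 10),
                           rounds=rounds)
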
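"""Secondary-structure composition comparison from circular dichroism.

Far-UV CD deconvolution software reports a protein's secondary-structure
content as percentages of alpha-helix, beta-turn and random coil.  This
module validates such compositions (the three classes must account for
~100% of the structure) and reports per-class changes between a native
(control) protein and the inhibitor-bound form.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidCompositionError, ValidationError

#: Allowed deviation of helix+turn+coil from 100%, absorbing deconvolution
#: rounding.
TAU_SUM = 2.0


@dataclass(frozen=True)
class SecondaryStructureComposition:
    """Helix/turn/coil percentages for one sample."""

    label: str
    helix_pct: float
    turn_pct: float
    coil_pct: float

    def __post_init__(self) -> None:
        for name in ("helix_pct", "turn_pct", "coil_pct"):
            val = getattr(self, name)
            if not 0.0 <= val <= 100.0:
                raise ValidationError(f"{name} must lie in [0, 100], got {val}")
        total = self.helix_pct + self.turn_pct + self.coil_pct
        if not (100.0 - TAU_SUM <= total <= 100.0 + TAU_SUM):
            raise InvalidCompositionError(
                f"{self.label}: composition sums to {total:.1f}%, "
                f"outside 100 +/- {TAU_SUM}%"
            )


@dataclass(frozen=True)
class CompositionDeltas:
    """Treated-minus-control changes per structure class, in percentage points."""

    helix_delta: float
    turn_delta: float
    coil_delta: float
    summary: str


def _direction(delta: float, name: str) -> str:
    if delta > 0:
        return f"{name} increased by {delta:.1f}"
    if delta < 0:
        return f"{name} decreased by {-delta:.1f}"
    return f"{name} unchanged"


def compare_composition(
    control: SecondaryStructureComposition,
    treated: SecondaryStructureComposition,
) -> CompositionDeltas:
    """Per-class composition change (treated - control), percentage points.

    Both compositions must individually satisfy the ~100% sum invariant
    (enforced at construction), so the three deltas sum to approximately
    zero.
    """
    dh = treated.helix_pct - control.helix_pct
    dt = treated.turn_pct - control.turn_pct
    dc = treated.coil_pct - control.coil_pct
    summary = "; ".join(
        (
            _direction(dh, "alpha-helix"),
            _direction(dt, "beta-turn"),
            _direction(dc, "random coil"),
        )
    )
    return CompositionDeltas(helix_delta=dh, turn_delta=dt, coil_delta=dc, summary=summary)
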
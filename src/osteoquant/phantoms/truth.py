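"""Ground-truth record attached to every synthetic phantom."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional


@dataclass
class PhantomTruth:
    """Continuous-geometry ground truth for phantom-recovery tests.

    Only the fields relevant to the generating modality are populated;
    the rest stay ``None``. Percentages live in [0, 100], lengths are
    strictly positive, and the seed of the generating RNG is always kept.
    """

    seed: int
    dr_true: Optional[float] = None  # mm/year
    bic_true: Optional[float] = None  # percent
    bvtv_true: Optional[float] = None  # percent
    capratio_profile_true: Optional[Callable[[float], float]] = None
    d_true: Optional[float] = None  # nm
    tau_true: Optional[float] = None  # nm
    T_true: Optional[float] = None  # nm
    ppm_true: Optional[Mapping[str, Mapping[str, float]]] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("bic_true", "bvtv_true"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        for name in ("d_true", "tau_true", "T_true"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name}={v} must be > 0")
        self.seed = int(self.seed)
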
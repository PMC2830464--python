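"""Common decoder output type."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InputError

__all__ = ["DecoderEstimate"]


@dataclass(frozen=True)
class DecoderEstimate:
    """Per-timestep (v_x, v_y) predictions of one decoder.

    ``velocities`` is aligned to the true-velocity timeline: row ``t`` is the
    estimate of the true velocity at timestep ``t``.
    """

    decoder_id: str
    velocities: np.ndarray  # (n, 2)

    def __post_init__(self):
        vel = np.asarray(self.velocities, dtype=float)
        if vel.ndim != 2 or vel.shape[1] != 2:
            raise InputError(f"velocities must have shape (n, 2), got {vel.shape}")
        if not np.all(np.isfinite(vel)):
            raise InputError(f"decoder {self.decoder_id!r} produced non-finite estimates")
        object.__setattr__(self, "velocities", vel)

    def __len__(self) -> int:
        return self.velocities.shape[0]
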
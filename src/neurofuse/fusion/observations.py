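"""Stacking individual decoder estimates into fusion observation vectors."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..decoders.base import DecoderEstimate
from ..decoders.kalman import KalmanModel, _train_statespace, kalman_filter
from ..errors import InputError
from ..synthetic import VelocitySeries

__all__ = [
    "FusionObservationSeries",
    "assemble_observations",
    "train_kalman_fusion",
    "decode_kalman_fusion",
]

#: canonical column ordering for the three standard decoders
_DECODER_PRIORITY = {"kalman": 0, "pva": 1, "linear": 2}


@dataclass(frozen=True)
class FusionObservationSeries:
    """Per-timestep stacked (v_x, v_y) predictions: k decoders -> 2k columns.

    For the three standard decoders the column order is fixed:
    (kalman v_x, kalman v_y, pva v_x, pva v_y, linear v_x, linear v_y).
    """

    observations: np.ndarray  # (n_steps, 2k)
    decoder_ids: tuple[str, ...]

    def __post_init__(self):
        obs = np.asarray(self.observations, dtype=float)
        if obs.ndim != 2 or obs.shape[1] != 2 * len(self.decoder_ids):
            raise InputError(
                f"observations shape {obs.shape} inconsistent with "
                f"{len(self.decoder_ids)} decoders")
        if not np.all(np.isfinite(obs)):
            raise InputError("fusion observations contain non-finite values")
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "decoder_ids", tuple(self.decoder_ids))

    def __len__(self) -> int:
        return self.observations.shape[0]

    @property
    def n_components(self) -> int:
        return self.observations.shape[1]


def assemble_observations(estimates: Sequence[DecoderEstimate]) -> FusionObservationSeries:
    """Interleave decoder estimates into one observation matrix.

    Known decoder ids are placed in canonical (kalman, pva, linear) order;
    any other ids follow in the given order.  All estimates must have the
    same length and distinct ids.
    """
    if not estimates:
        raise InputError("need at least one decoder estimate")
    ids = [e.decoder_id for e in estimates]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate decoder ids: {ids}")
    lengths = {len(e) for e in estimates}
    if len(lengths) != 1:
        raise InputError(f"decoder estimates have unequal lengths: {sorted(lengths)}")
    ordered = sorted(estimates,
                     key=lambda e: (_DECODER_PRIORITY.get(e.decoder_id, len(_DECODER_PRIORITY)),
                                    ids.index(e.decoder_id)))
    obs = np.hstack([e.velocities for e in ordered])
    return FusionObservationSeries(observations=obs,
                                   decoder_ids=tuple(e.decoder_id for e in ordered))


def train_kalman_fusion(
    obs: FusionObservationSeries, vel: VelocitySeries, *, center: bool = True
) -> KalmanModel:
    """Closed-form Kalman training with the 2-D velocity state and 2k-D observations."""
    model = _train_statespace(obs.observations, vel, state="velocity", center=center)
    model.meta["decoder_ids"] = list(obs.decoder_ids)
    return model


def decode_kalman_fusion(model: KalmanModel, obs: FusionObservationSeries) -> DecoderEstimate:
    """Filter stacked decoder estimates into one fused velocity estimate."""
    if obs.n_components != model.d_obs:
        raise InputError(
            f"observation dimension {obs.n_components} != model d_obs {model.d_obs}")
    states = kalman_filter(model, obs.observations)
    return DecoderEstimate(decoder_id="kalman_fusion", velocities=states[:, :2])
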
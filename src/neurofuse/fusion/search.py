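"""Grid search over ANN hidden-layer topologies.

The default grid spans 1..12 units in the first hidden layer and 0..11 in
the second (0 = single hidden layer), i.e. 144 candidate networks.  Each
cell trains with its own seed derived from (seed, h1, h2) so the resulting
E_rms matrix does not depend on the order in which cells are visited.  The
evaluation series is explicit: pass the validation series for honest model
selection, or a test series to reproduce reported E_rms matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..errors import NeurofuseError
from .ann import ANNModel, ANNTopology, decode_ann, train_ann
from .observations import FusionObservationSeries

__all__ = ["TopologySearchResult", "topology_search", "cell_seed"]

DEFAULT_H1_GRID = tuple(range(1, 13))
DEFAULT_H2_GRID = tuple(range(0, 12))


def cell_seed(seed: int, h1: int, h2: int) -> int:
    """Per-cell training seed, independent of grid iteration order."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(h1, h2))
    return int(ss.generate_state(2, dtype=np.uint32).view(np.uint64)[0])


@dataclass
class TopologySearchResult:
    """E_rms over the grid plus the winning network.

    ``e_rms_matrix[i, j]`` is the evaluation E_rms of topology
    (h1_grid[i], h2_grid[j]); failed cells are NaN and recorded in
    ``failures``.
    """

    e_rms_matrix: np.ndarray
    h1_grid: tuple[int, ...]
    h2_grid: tuple[int, ...]
    best_topology: ANNTopology
    best_model: ANNModel
    n_trained: int
    failures: dict = field(default_factory=dict)


def topology_search(
    train_obs: FusionObservationSeries,
    train_vel,
    val_obs: FusionObservationSeries,
    val_vel,
    eval_obs: FusionObservationSeries,
    eval_vel,
    seed: int = 0,
    h1_grid: Sequence[int] = DEFAULT_H1_GRID,
    h2_grid: Sequence[int] = DEFAULT_H2_GRID,
    max_epochs: int = 500,
    patience: int = 15,
) -> TopologySearchResult:
    """Train every grid topology and pick the one with minimal evaluation E_rms.

    Ties break toward fewer total hidden units, then fewer first-layer
    units.  A cell whose training fails is recorded as missing (NaN) and
    the search continues.
    """
    from ..evaluation import e_rms  # local import: evaluation orchestrates fusion

    h1_grid = tuple(h1_grid)
    h2_grid = tuple(h2_grid)
    matrix = np.full((len(h1_grid), len(h2_grid)), np.nan)
    failures: dict[tuple[int, int], str] = {}
    best_key = None
    best_model = None
    best_topology = None
    n_trained = 0

    for i, h1 in enumerate(h1_grid):
        for j, h2 in enumerate(h2_grid):
            topo = ANNTopology(h1=h1, h2=h2)
            try:
                model = train_ann(train_obs, train_vel, val_obs, val_vel, topo,
                                  seed=cell_seed(seed, h1, h2),
                                  max_epochs=max_epochs, patience=patience)
                score = e_rms(eval_vel, decode_ann(model, eval_obs)).e_rms
            except NeurofuseError as exc:
                failures[(h1, h2)] = str(exc)
                continue
            matrix[i, j] = score
            n_trained += 1
            key = (score, h1 + h2, h1)
            if best_key is None or key < best_key:
                best_key = key
                best_model = model
                best_topology = topo

    if best_model is None:
        raise NeurofuseError("every topology in the grid failed to train")
    return TopologySearchResult(
        e_rms_matrix=matrix, h1_grid=h1_grid, h2_grid=h2_grid,
        best_topology=best_topology, best_model=best_model,
        n_trained=n_trained, failures=failures,
    )
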
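"""Label-switching resolution and confidence thresholding.

An unsupervised HMM fit identifies three clusters of district-weeks
whose indices carry no meaning: the likelihood is invariant under any
permutation of hidden states.  The clusters are anchored to modalities
by majority vote — each hidden state takes the modality most commonly
*reported* (all four sources pooled, unweighted) among the
district-weeks whose MAP state it is — resolved to a proper permutation
greedily in descending count order.

Confidence filtering keeps district-weeks whose maximum posterior
probability clears a threshold (0.75 by default, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .hmm import DecodedPanel
from .panel_io import N_STATES, SOURCES, ObservationPanel


class LabelingError(RuntimeError):
    """A hidden state has no supporting observations; refit or map manually."""


@dataclass
class StateLabeling:
    """Permutation from hidden-state index to modality code.

    ``mapping[h]`` is the modality code (1..3) assigned to hidden state
    ``h+1``; ``support[h, m]`` the pooled count of reports of modality
    ``m+1`` among district-weeks whose MAP state is ``h+1``.
    """

    mapping: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=np.int64).reshape(N_STATES)
        if sorted(self.mapping.tolist()) != [1, 2, 3]:
            raise ValueError(f"mapping must be a permutation of (1,2,3), got {self.mapping}")

    @property
    def is_identity(self) -> bool:
        return bool((self.mapping == np.arange(1, N_STATES + 1)).all())


def identity_labeling() -> StateLabeling:
    return StateLabeling(np.arange(1, N_STATES + 1), np.zeros((N_STATES, N_STATES)))


def derive_labeling(panel: ObservationPanel, decoded: DecodedPanel) -> StateLabeling:
    """Majority-report mapping from hidden states to modalities.

    For each hidden state, pool every reported modality (all sources,
    unweighted) over the district-weeks whose MAP state is that state,
    then assign modalities greedily: visit (state, modality) count cells
    in descending order — ties broken by lowest modality code, then
    lowest state index — assigning each state the best still-free
    modality.
    """
    if decoded.map_state.shape != panel.obs.shape[:2]:
        raise ValueError("decoded panel does not cover the observation panel")
    support = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    for s in range(len(SOURCES)):
        o = panel.obs[:, :, s]
        present = (o != 0) & decoded.valid
        np.add.at(support, (decoded.map_state[present] - 1, o[present] - 1), 1)

    empty = np.flatnonzero(support.sum(axis=1) == 0)
    if empty.size:
        raise LabelingError(
            f"hidden state(s) {[int(h) + 1 for h in empty]} have no supporting "
            "observations; refit the model or supply a manual mapping"
        )

    cells = sorted(
        ((h, m) for h in range(N_STATES) for m in range(N_STATES)),
        key=lambda hm: (-support[hm], hm[1], hm[0]),
    )
    mapping = np.zeros(N_STATES, dtype=np.int64)
    taken_state = np.zeros(N_STATES, dtype=bool)
    taken_mod = np.zeros(N_STATES, dtype=bool)
    for h, m in cells:
        if not taken_state[h] and not taken_mod[m]:
            mapping[h] = m + 1
            taken_state[h] = taken_mod[m] = True
    return StateLabeling(mapping, support)


def apply_labeling(decoded: DecodedPanel, labeling: StateLabeling) -> DecodedPanel:
    """Permute a decoded panel so state indices mean modalities.

    Posterior column ``m-1`` of the result is the probability of
    modality ``m``; MAP and Viterbi states are relabelled through the
    mapping.  Applying the identity mapping is a no-op (apart from the
    ``labeled`` flag); applying an involution twice returns the input.
    """
    perm0 = labeling.mapping - 1  # hidden index -> modality index
    posterior = np.empty_like(decoded.posterior)
    posterior[:, :, perm0] = decoded.posterior
    relabel = np.concatenate([[0], labeling.mapping]).astype(np.int8)  # keep 0 for out-of-window
    return replace(
        decoded,
        posterior=posterior,
        map_state=relabel[decoded.map_state],
        viterbi_state=relabel[decoded.viterbi_state],
        labeled=True,
    )


@dataclass
class ConfidenceResult:
    """High-confidence subset of a decoded panel."""

    frame: pd.DataFrame
    n_total: int
    n_retained: int

    @property
    def fraction_retained(self) -> float:
        return self.n_retained / self.n_total if self.n_total else float("nan")


def confidence_filter(decoded: DecodedPanel, threshold: float = 0.75) -> ConfidenceResult:
    """District-weeks whose maximum posterior probability is ≥ ``threshold``.

    The comparison is inclusive; a threshold of 0 retains everything.
    The retained fraction is monotone non-increasing in the threshold.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    frame = decoded.to_frame(threshold=threshold)
    conf = frame[["p_remote", "p_hybrid", "p_in_person"]].max(axis=1)
    keep = conf >= threshold if threshold > 0 else np.ones(len(frame), dtype=bool)
    retained = frame[keep].reset_index(drop=True)
    return ConfidenceResult(frame=retained, n_total=len(frame), n_retained=len(retained))
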
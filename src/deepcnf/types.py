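"""Shared containers for per-residue features and order/disorder labels.

Label convention: state 0 = ordered, state 1 = disordered. Residues removed
from evaluation (e.g. "not available" in crystal-structure annotations) are
carried as masked positions so that sequence lengths stay aligned with the
original chain.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ORDER = 0
DISORDER = 1


@dataclass
class FeatureMatrix:
    """Per-residue input features: an L x input_dim real matrix.

    ``manifest`` records how the columns were assembled (feature classes and
    their widths) so a trained model can refuse incompatible inputs.
    """

    values: np.ndarray
    sequence_id: str = ""
    manifest: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError(
                f"feature matrix for {self.sequence_id!r} must be 2-D with L >= 1, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"feature matrix for {self.sequence_id!r} contains non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def input_dim(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelSequence:
    """Per-residue order/disorder states with an inclusion mask.

    ``states[i]`` is 0 (order) or 1 (disorder) where ``mask[i]`` is True and
    -1 at masked (excluded) positions.
    """

    states: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.mask is None:
            self.mask = np.ones(self.states.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.states.shape != self.mask.shape or self.states.ndim != 1:
            raise ValueError("states and mask must be 1-D arrays of equal length")
        obs = self.states[self.mask]
        if obs.size and (obs.min() < 0 or obs.max() > 1):
            raise ValueError("observed states must be 0 (order) or 1 (disorder)")

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def fully_observed(self) -> bool:
        return bool(self.mask.all())

    def compressed(self) -> tuple["LabelSequence", np.ndarray]:
        """Drop masked positions; return the dense labels and the original indices kept.

        The returned index array maps new position -> old position so that
        predictions on the compressed chain can be re-projected.
        """
        idx = np.flatnonzero(self.mask)
        return LabelSequence(self.states[idx]), idx

    @classmethod
    def from_states(cls, states) -> "LabelSequence":
        return cls(np.asarray(states, dtype=np.int8))
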
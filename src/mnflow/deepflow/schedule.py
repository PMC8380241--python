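"""Step learning-rate schedule: lr0 dropping by a fixed factor every period."""

from __future__ import annotations


def lr_at_epoch(epoch: int, lr0: float = 5e-3, drop_factor: float = 0.9,
                drop_period: int = 5) -> float:
    """Learning rate at a 1-based epoch: lr0 * factor^floor((epoch-1)/period).

    Defaults follow the published schedule: initial rate 5e-3 dropping by
    0.9 every five epochs.
    """
    if epoch < 1:
        raise ValueError(f"epoch must be >= 1, got {epoch}")
    if drop_period < 1:
        raise ValueError(f"drop_period must be >= 1, got {drop_period}")
    return lr0 * drop_factor ** ((int(epoch) - 1) // drop_period)
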
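"""Iterative groupwise training and the matching prediction pipeline.

One *iteration* feeds every frame of a sequence through the network against
the current template, warps the frames with the predicted fields, and — in
training — takes one Adam step on the total loss.  The template is then
recomputed as the pointwise average of the just-registered frames and the
next iteration starts.  With ``L`` template updates the pipeline runs
``L + 1`` iterations per sequence; the initial template (l = 0) is the
geodesic-medoid frame chosen by the template-selection module.  The template
is treated as a constant between iterations: no gradient flows through its
history.

Prediction (:func:`register`) runs exactly the same ``L + 1``-iteration loop
without parameter updates and returns the per-iteration templates and the
groupwise-SSD trace, which is the standard diagnostic for the benefit of
iterating (the SSD drops and stabilizes after about six iterations).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .data import CineSequence, DeformationSequence
from .losses import LossConfig, ssd_loss, total_loss_and_field_grad
from .network import Adam, GWNet, NetConfig, build_network, predict_fields
from .template import (
    TemplateImage,
    TemplateSelectConfig,
    select_template,
    update_template,
)
from .warp import warp_sequence

__all__ = [
    "GWConfig",
    "RegistrationResult",
    "TrainingDivergedError",
    "train",
    "register",
    "roll_sequence",
    "permute_sequence",
]


@dataclass
class GWConfig:
    """Configuration of the groupwise training / prediction pipeline.

    Defaults mirror the reference cardiac setup: L = 5 template updates
    (six iterations), 10 epochs, Adam with learning rate 1e-4, batch size =
    the number of frames of the sequence.
    """

    L: int = 5
    epochs: int = 10
    learning_rate: float = 1e-4
    loss: LossConfig = dc_field(default_factory=LossConfig)
    net: NetConfig = dc_field(default_factory=NetConfig)
    template: TemplateSelectConfig = dc_field(default_factory=TemplateSelectConfig)
    shuffle_sequences: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError("L must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class RegistrationResult:
    """Output of the L+1-iteration registration of one sequence."""

    registered: CineSequence
    fields: DeformationSequence
    templates: list[TemplateImage]
    ssd_trace: np.ndarray

    def __post_init__(self) -> None:
        self.ssd_trace = np.asarray(self.ssd_trace, dtype=np.float64)
        if len(self.templates) != len(self.ssd_trace):
            raise ValueError("templates and ssd_trace must have equal length")

    @property
    def final_template(self) -> TemplateImage:
        return self.templates[-1]


class TrainingDivergedError(RuntimeError):
    pass


def _sequence_pass(
    net: GWNet,
    seq: CineSequence,
    cfg: GWConfig,
    optimizer: Adam | None,
    seq_label: str = "",
) -> tuple[RegistrationResult, float]:
    """Run the L+1-iteration loop on one sequence.

    With an optimizer, takes one Adam step per iteration (training); without,
    performs pure prediction.  Returns the result and the mean loss over
    iterations (training diagnostics).
    """
    template, _ = select_template(seq, cfg.template)
    templates: list[TemplateImage] = []
    trace: list[float] = []
    losses: list[float] = []
    fields: DeformationSequence | None = None
    registered: CineSequence | None = None
    for l in range(cfg.L + 1):
        training = optimizer is not None
        fields = predict_fields(net, seq, template, train=training)
        registered = warp_sequence(seq, fields)
        if training:
            value, grad_fields = total_loss_and_field_grad(
                seq, template, fields, cfg.loss
            )
            if not np.isfinite(value):
                raise TrainingDivergedError(
                    f"non-finite loss at sequence {seq_label or seq.subject_id!r}, "
                    f"iteration l={l}"
                )
            net.zero_grad()
            net.backward(grad_fields)
            optimizer.step()
            losses.append(value)
        templates.append(template)
        trace.append(ssd_loss(registered, cfg.loss.region))
        template = update_template(registered, iteration=l + 1)
    result = RegistrationResult(registered, fields, templates, np.asarray(trace))
    mean_loss = float(np.mean(losses)) if losses else float("nan")
    return result, mean_loss


def train(
    dataset: list[CineSequence],
    cfg: GWConfig | None = None,
    validation: list[CineSequence] | None = None,
    log_path: str | Path | None = None,
) -> tuple[GWNet, list[dict]]:
    """Train the registration network on a set of cine sequences.

    Each epoch visits the sequences in a seeded random order; each sequence
    contributes L+1 Adam steps (one per iteration, batch = all N frames of
    the sequence).  Returns the trained network and a per-epoch log of mean
    training loss (and mean validation loss when a validation set is given).
    """
    cfg = cfg or GWConfig()
    if not dataset:
        raise ValueError("dataset must be non-empty")
    net = build_network(cfg.net)
    optimizer = Adam(net, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset)) if cfg.shuffle_sequences else np.arange(
            len(dataset)
        )
        epoch_losses = []
        for idx in order:
            _, mean_loss = _sequence_pass(
                net, dataset[idx], cfg, optimizer, seq_label=str(idx)
            )
            epoch_losses.append(mean_loss)
        record = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if validation:
            val_losses = []
            for seq in validation:
                result, _ = _sequence_pass(net, seq, cfg, optimizer=None)
                val_losses.append(result.ssd_trace[-1])
            record["val_ssd"] = float(np.mean(val_losses))
        log.append(record)
    if log_path is not None:
        _write_log(log, log_path)
    return net, log


def _write_log(log: list[dict], path: str | Path) -> None:
    keys = sorted({k for rec in log for k in rec})
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=keys)
        writer.writeheader()
        writer.writerows(log)


def register(net: GWNet, seq: CineSequence, cfg: GWConfig | None = None) -> RegistrationResult:
    """Predict: run the L+1-iteration pipeline without weight updates."""
    cfg = cfg or GWConfig()
    result, _ = _sequence_pass(net, seq, cfg, optimizer=None)
    return result


def roll_sequence(seq: CineSequence, start: int) -> CineSequence:
    """Cyclically roll so the sequence starts at ``start`` (periodic extension)."""
    n = seq.n_frames
    if not -n <= start < 2 * n:
        raise ValueError(f"start {start} out of range for N={n}")
    return seq.with_frames(np.roll(seq.frames, -start, axis=0))


def permute_sequence(seq: CineSequence, permutation) -> CineSequence:
    """Reorder frames by an arbitrary permutation (ordering experiments)."""
    perm = np.asarray(permutation)
    n = seq.n_frames
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError("not a valid permutation of frame indices")
    return seq.with_frames(seq.frames[perm])
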
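"""Generalisation of a trained model under edge-swap perturbation.

A model trained on unperturbed networks is presented with progressively
swapped variants; reconstruction quality is tracked as TP accuracy
(recall of the presented edges, in percent) and binary cross-entropy
loss, as functions of the swapped fraction, with and without out-degree
preservation.  Loss and TP accuracy are measured against the swapped
matrix itself — the reconstruction of what was presented — by default;
``target="original"`` instead compares against the unswapped matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError
from .netio import DirectedBinaryNetwork
from .nne import NNEModel, bce_loss, reconstruct, tp_accuracy
from .synthgen import DEFAULT_SWAP_FRACTIONS, SwapSpec, swap_edges

__all__ = ["DegradationCurve", "evaluate_swapped", "compare_modes"]


@dataclass
class DegradationCurve:
    """Mean/sd of TP accuracy and loss per swap fraction."""

    fractions: np.ndarray
    tp_accuracy_mean: np.ndarray
    tp_accuracy_sd: np.ndarray
    loss_mean: np.ndarray
    loss_sd: np.ndarray
    mode: str  # "degree-preserving" | "non-preserving"
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "tp_accuracy_mean": self.tp_accuracy_mean,
                "tp_accuracy_sd": self.tp_accuracy_sd,
                "loss_mean": self.loss_mean,
                "loss_sd": self.loss_sd,
                "mode": self.mode,
            }
        )


def evaluate_swapped(
    model: NNEModel,
    nets: Sequence[DirectedBinaryNetwork],
    fractions: Sequence[float] = DEFAULT_SWAP_FRACTIONS,
    preserve_degree: bool = True,
    n_reps: int = 5,
    seed: int = 0,
    target: str = "swapped",
) -> DegradationCurve:
    """Swap -> reconstruct -> score, aggregated across networks x replicates.

    At fraction 0 the evaluation is exactly the plain reconstruction of
    the original networks (one replicate, no perturbation).
    """
    if 0.0 not in [float(f) for f in fractions]:
        raise ConfigurationError("fractions must include 0 (the unswapped reference)")
    if target not in ("swapped", "original"):
        raise ConfigurationError(f"unknown target {target!r}")
    ss = np.random.SeedSequence(seed)
    tp_mean, tp_sd, l_mean, l_sd = [], [], [], []
    for f in fractions:
        tps, losses = [], []
        reps = 1 if f == 0 else n_reps
        for net in nets:
            for _ in range(reps):
                if f == 0:
                    presented = net
                else:
                    child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                    presented = swap_edges(net, SwapSpec(float(f), preserve_degree, child))
                recon, p = reconstruct(model, presented)
                ref = presented if target == "swapped" else net
                tps.append(tp_accuracy(recon.adjacency, ref.adjacency))
                losses.append(bce_loss(ref.adjacency.astype(float), p))
        tp_mean.append(np.mean(tps))
        tp_sd.append(np.std(tps))
        l_mean.append(np.mean(losses))
        l_sd.append(np.std(losses))
    return DegradationCurve(
        np.asarray(fractions, dtype=float),
        np.asarray(tp_mean),
        np.asarray(tp_sd),
        np.asarray(l_mean),
        np.asarray(l_sd),
        "degree-preserving" if preserve_degree else "non-preserving",
        n_reps,
    )


def compare_modes(
    curve_preserving: DegradationCurve,
    curve_nonpreserving: DegradationCurve,
) -> dict:
    """Contrast the two swap modes.

    Sign convention: positive values mean the *non-preserving* mode
    degrades faster (lower TP accuracy / higher loss).  ``tp_auc_gap`` is
    the trapezoidal area between the TP-accuracy curves
    (preserving minus non-preserving) over the fraction axis.
    """
    fa, fb = curve_preserving.fractions, curve_nonpreserving.fractions
    if len(fa) != len(fb) or not np.allclose(fa, fb):
        raise AlignmentError("curves were evaluated at different swap fractions")
    tp_delta = curve_preserving.tp_accuracy_mean - curve_nonpreserving.tp_accuracy_mean
    loss_delta = curve_nonpreserving.loss_mean - curve_preserving.loss_mean
    return {
        "fractions": fa,
        "tp_delta": tp_delta,
        "loss_delta": loss_delta,
        "tp_auc_gap": float(np.trapezoid(tp_delta, fa)),
        "loss_auc_gap": float(np.trapezoid(loss_delta, fa)),
    }
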
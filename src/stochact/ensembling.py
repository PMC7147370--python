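"""Ensembles of activation-replaced networks, fused by the sum rule.

Members are built by stochastic (or uniform) activation replacement of a
shared base network, fine-tuned independently, and fused by summing their
post-softmax score vectors; the decision is the argmax of the sum.  For
segmentation the same sum runs per pixel, which on hard one-hot masks
reduces to a per-pixel majority vote.  Argmax ties break toward the lower
class index, deterministically.

Named recipes mirror the standard ensemble compositions: ``FusAct`` fuses
the ten fixed-activation variants, ``FusRan`` fuses N independent
stochastic replacements, and ``FusAR`` concatenates both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

from .activations import ACTIVATION_NAMES, ActivationSpec
from .model import ModelGraph
from .surgery import ActivationAssignment, default_pool, replace_all, stochastic_replacement

__all__ = [
    "EnsembleModel",
    "fuse_sum",
    "fuse_masks",
    "create_ensemble",
    "fus_act_members",
    "fus_ran_members",
    "fus_ar_members",
]

#: trainer contract: callable(model, member_seed) -> trained model
Trainer = Callable[[ModelGraph, int], ModelGraph]


def _check_scores(predictions: Sequence[np.ndarray]) -> List[np.ndarray]:
    preds = [np.asarray(p, dtype=np.float64) for p in predictions]
    if not preds:
        raise ValueError("need at least one prediction to fuse")
    shape = preds[0].shape
    for p in preds[1:]:
        if p.shape != shape:
            raise ValueError(f"prediction shape mismatch: {p.shape} vs {shape}")
    return preds


def fuse_sum(predictions: Sequence[np.ndarray]) -> np.ndarray:
    """Sum-rule fusion of per-sample class scores, shape (N, K).

    Returns the summed scores; take ``argmax(axis=1)`` for decisions.
    Permutation-invariant in its arguments and invariant to any common
    positive rescaling of the inputs (argmax-wise).
    """
    preds = _check_scores(predictions)
    return np.sum(preds, axis=0)


def fuse_decisions(predictions: Sequence[np.ndarray]) -> np.ndarray:
    """Argmax decisions of the sum rule (ties -> lowest class index)."""
    return np.argmax(fuse_sum(predictions), axis=1)


def fuse_masks(mask_scores: Sequence[np.ndarray], hard: bool = False) -> np.ndarray:
    """Pixel-wise sum-rule fusion of segmentation scores.

    Each member contributes per-pixel class scores of shape (K, H, W) or
    (N, K, H, W); scores are summed and the per-pixel argmax taken (class
    axis = -3).  With ``hard=True`` each member's scores are first
    converted to one-hot votes, making the fusion a literal per-pixel
    majority vote.  On one-hot inputs both modes coincide.  Ties resolve
    to the lower class index.
    """
    preds = _check_scores(mask_scores)
    if preds[0].ndim not in (3, 4):
        raise ValueError("mask scores must be (K, H, W) or (N, K, H, W)")
    if hard:
        onehot = []
        for p in preds:
            lab = np.argmax(p, axis=-3)
            eye = np.eye(p.shape[-3])
            oh = np.moveaxis(eye[lab], -1, -3)
            onehot.append(oh)
        preds = onehot
    total = np.sum(preds, axis=0)
    return np.argmax(total, axis=-3)


@dataclass
class EnsembleModel:
    """N member networks plus sum-rule fusion."""

    members: List[ModelGraph]
    recipe: str = "FusRan"
    manifests: List[List[ActivationAssignment]] = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise ValueError("an ensemble needs at least one member")

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return fuse_sum([m.predict_proba(x) for m in self.members])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    def predict_mask(self, x: np.ndarray, hard: bool = False) -> np.ndarray:
        return fuse_masks([m.predict_proba(x) for m in self.members], hard=hard)


def create_ensemble(
    base: ModelGraph,
    pool: Optional[Sequence[ActivationSpec]] = None,
    n: int = 10,
    seed: int = 0,
    trainer: Optional[Trainer] = None,
) -> EnsembleModel:
    """Build an N-member stochastic-replacement ensemble.

    Each member is an independent stochastic replacement of ``base`` (child
    seeds spawned from ``seed``), then fine-tuned by ``trainer`` (a
    callable ``(model, member_seed) -> model``; None skips training).
    """
    if n < 1:
        raise ValueError("ensemble size n must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n)
    members, manifests = [], []
    for child in children:
        member_seed = int(child.generate_state(1)[0] % (2 ** 31))
        m, manifest = stochastic_replacement(base, pool, seed=member_seed)
        if trainer is not None:
            m = trainer(m, member_seed)
        members.append(m)
        manifests.append(manifest)
    return EnsembleModel(members, recipe="FusRan", manifests=manifests)


def fus_ran_members(base: ModelGraph, n: int, seed: int,
                    max_inputs: Sequence[float] = (1.0,),
                    trainer: Optional[Trainer] = None) -> EnsembleModel:
    """FusRan{n}: n stochastic models per max_input value, concatenated.

    ``max_inputs=(1, 255)`` with n=10 gives the FusRan20-style composition
    (10 members at max_input 1 plus 10 at 255).
    """
    members, manifests = [], []
    for i, m_in in enumerate(max_inputs):
        ens = create_ensemble(base, default_pool(m_in), n=n, seed=seed + i, trainer=trainer)
        members.extend(ens.members)
        manifests.extend(ens.manifests)
    return EnsembleModel(members, recipe="FusRan", manifests=manifests)


def fus_act_members(base: ModelGraph, max_input: float = 1.0,
                    names: Sequence[str] = ACTIVATION_NAMES,
                    seed: int = 0,
                    trainer: Optional[Trainer] = None) -> EnsembleModel:
    """FusAct: one uniformly replaced model per activation name."""
    members = []
    for i, name in enumerate(names):
        spec = ActivationSpec.create(name, max_input=max_input)
        m = replace_all(base, spec, seed=seed + i)
        if trainer is not None:
            m = trainer(m, seed + i)
        members.append(m)
    return EnsembleModel(members, recipe="FusAct")


def fus_ar_members(base: ModelGraph, n_random: int = 10, max_input: float = 1.0,
                   seed: int = 0, trainer: Optional[Trainer] = None) -> EnsembleModel:
    """FusAR: the FusAct members plus n stochastic members, all fused."""
    act = fus_act_members(base, max_input=max_input, seed=seed, trainer=trainer)
    ran = fus_ran_members(base, n=n_random, seed=seed + 1000,
                          max_inputs=(max_input,), trainer=trainer)
    return EnsembleModel(act.members + ran.members, recipe="FusAR",
                         manifests=ran.manifests)
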
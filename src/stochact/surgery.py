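"""Network surgery: enumerate and replace activation layers.

A trained (or freshly built) network is modified by swapping the function
held in each activation slot, either uniformly — every slot receives the
same activation — or stochastically, with every slot independently drawing
a function from a pool.  All non-activation weights are preserved
bit-identically, and because every dynamic activation initializes to an
exact copy of ReLU, a ReLU network keeps computing the same function right
after surgery; diversity appears only once the new learnable parameters
start training.

Seeding: a master seed spawns one child seed per slot (via
``numpy.random.SeedSequence``), so the assignment for a given
(model, seed) pair is reproducible and per-slot draws stay independent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .activations import DEFAULT_POOL_NAMES, ActivationSpec
from .model import ActivationLayer, ModelGraph

__all__ = [
    "ActivationAssignment",
    "default_pool",
    "list_activation_slots",
    "replace_all",
    "stochastic_replacement",
    "write_manifest",
    "read_manifest",
]


@dataclass(frozen=True)
class ActivationAssignment:
    """Record of one slot replacement: which spec went where, and its seed."""

    slot_index: int
    spec: ActivationSpec
    seed_used: int


def default_pool(max_input: float = 1.0, include_relu: bool = False) -> List[ActivationSpec]:
    """The standard replacement pool: the nine non-ReLU activations.

    All members share one ``max_input``; pass ``include_relu=True`` to add
    plain ReLU as a tenth candidate.
    """
    names = list(DEFAULT_POOL_NAMES)
    if include_relu:
        names = ["ReLU"] + names
    return [ActivationSpec.create(n, max_input=max_input) for n in names]


def list_activation_slots(model: ModelGraph) -> List[int]:
    """Indices of every activation layer, in graph order (may be empty)."""
    return model.activation_slots()


def _fresh_activation(model: ModelGraph, slot: int, spec: ActivationSpec,
                      rng: np.random.Generator) -> ActivationLayer:
    channels = model.slot_channels(slot)
    return ActivationLayer(spec, channels, rng=rng)


def replace_all(model: ModelGraph, spec: ActivationSpec, seed: int = 0) -> ModelGraph:
    """Replace every activation slot with a fresh instance of ``spec``.

    Returns a new model; the input model and all non-activation weights are
    untouched.  ``seed`` only matters for APLU, whose hinge positions are
    drawn at construction.
    """
    out = model.copy()
    rng = np.random.default_rng(seed)
    for slot in out.activation_slots():
        out.layers[slot] = _fresh_activation(out, slot, spec, rng)
    return out


def stochastic_replacement(
    model: ModelGraph,
    pool: Optional[Sequence[ActivationSpec]] = None,
    seed: int = 0,
) -> Tuple[ModelGraph, List[ActivationAssignment]]:
    """Independently replace each activation slot with a random pool member.

    Each slot draws uniformly (i.i.d., with replacement) from ``pool``
    using its own child seed, so the full assignment is a pure function of
    (model, pool, seed).  Returns the new model together with the
    assignment manifest.
    """
    if pool is None:
        pool = default_pool()
    pool = list(pool)
    if not pool:
        raise ValueError("activation pool must be non-empty")
    out = model.copy()
    slots = out.activation_slots()
    children = np.random.SeedSequence(seed).spawn(len(slots))
    assignments = []
    for slot, child in zip(slots, children):
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(child_seed)
        spec = pool[int(rng.integers(len(pool)))]
        out.layers[slot] = _fresh_activation(out, slot, spec, rng)
        assignments.append(ActivationAssignment(slot, spec, child_seed))
    return out, assignments


def write_manifest(assignments: Sequence[ActivationAssignment], path) -> None:
    """Write the assignment record as tab-separated text."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["slot_index", "activation", "max_input", "seed"])
        for a in assignments:
            w.writerow([a.slot_index, a.spec.name, a.spec.max_input, a.seed_used])


def read_manifest(path) -> List[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
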
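"""Sequence evolution along a proximity-parameterized tree.

Background positions evolve under Jukes-Cantor (uniform equilibrium) or,
with a non-uniform background vector, under Felsenstein's F81 model.
Positions inside an embedded motif site evolve under the same
copy-or-redraw kernel but with the equilibrium of each position set to
the corresponding weight-matrix column, so that motif columns stay
distributed according to the motif model as sequences diverge.

The per-branch kernel is the single-parameter matrix

    P(a -> b) = q * delta(a, b) + (1 - q) * pi_b

whose proximity parameter q composes multiplicatively along paths:
T(q1) T(q2) = T(q1 q2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motif import ALPHABET, WeightMatrix, _validate_probs, uniform_background
from .phylo import PhyloTree, TreeNode


@dataclass(frozen=True)
class TransitionModel:
    """Copy-or-redraw substitution kernel for one branch."""

    proximity: float
    equilibrium: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    @property
    def matrix(self) -> np.ndarray:
        return transition_matrix(self.proximity, np.asarray(self.equilibrium))


@dataclass(frozen=True)
class LossSpec:
    """Where motif sites have been lost.

    ``lost_species``: species labels whose sequences lack the site in
    every orthologous set (loss in the orthologous direction).
    ``lost_genes``: gene indices whose whole orthologous set lacks the
    site (loss in the coregulation direction).
    """

    lost_species: frozenset = frozenset()
    lost_genes: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "lost_species", frozenset(self.lost_species))
        object.__setattr__(self, "lost_genes", frozenset(self.lost_genes))


def transition_matrix(q: float, equilibrium: np.ndarray) -> np.ndarray:
    """4x4 stochastic matrix ``q*I + (1-q) * 1 pi^T``."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"proximity {q} outside [0, 1]")
    pi = _validate_probs(np.asarray(equilibrium, dtype=float), "equilibrium")
    return q * np.eye(4) + (1.0 - q) * np.tile(pi, (4, 1))


def encode(seq: str) -> np.ndarray:
    idx = {b: i for i, b in enumerate(ALPHABET)}
    try:
        return np.array([idx[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc} in sequence") from None


def decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in arr)


def _draw_categorical(probs: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(probs)
    return (rng.random((size, 1)) < cum).argmax(axis=1).astype(np.int8)


@dataclass
class EvolvedLeaf:
    """One leaf's evolved sequence and, if retained, its site start."""

    sequence: np.ndarray
    site_start: int | None


def _evolve_edge(
    parent: np.ndarray,
    q: float,
    site: tuple[int, WeightMatrix] | None,
    background: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    child = parent.copy()
    redraw = np.nonzero(rng.random(len(parent)) >= q)[0]
    if redraw.size == 0:
        return child
    if site is None:
        child[redraw] = _draw_categorical(background, redraw.size, rng)
        return child
    start, wm = site
    in_site = (redraw >= start) & (redraw < start + wm.width)
    bg_idx = redraw[~in_site]
    child[bg_idx] = _draw_categorical(background, bg_idx.size, rng)
    for pos in redraw[in_site]:
        child[pos] = _draw_categorical(wm.column(pos - start), 1, rng)[0]
    return child


def evolve_sequence(
    ancestor: str | np.ndarray,
    tree: PhyloTree,
    site: tuple[int, WeightMatrix] | None = None,
    loss: LossSpec | None = None,
    rng: np.random.Generator | None = None,
    background: np.ndarray | None = None,
) -> dict[str, EvolvedLeaf]:
    """Evolve an ancestral sequence down a tree; return per-leaf results.

    The recursion visits edges in deterministic pre-order, drawing per
    position whether the base is copied (probability q) or redrawn from
    its equilibrium: the background vector for background positions, the
    motif-column distribution for positions inside the annotated site.
    Sequence length is invariant (substitutions only, no indels).

    A leaf whose species appears in ``loss.lost_species`` has its site
    window replaced by fresh i.i.d. background and carries no
    ground-truth site.
    """
    if rng is None:
        rng = np.random.default_rng()
    if background is None:
        background = uniform_background()
    background = _validate_probs(background, "background")
    loss = loss or LossSpec()
    anc = encode(ancestor) if isinstance(ancestor, str) else np.asarray(ancestor, dtype=np.int8)
    if site is not None:
        start, wm = site
        if not (0 <= start and start + wm.width <= len(anc)):
            raise ValueError("site annotation outside sequence bounds")
    leaf_labels = set(tree.leaf_labels())
    unknown = set(loss.lost_species) - leaf_labels
    if unknown:
        raise ValueError(f"lost species not in tree: {sorted(unknown)}")

    out: dict[str, EvolvedLeaf] = {}

    def recurse(node: TreeNode, seq: np.ndarray) -> None:
        if node.proximity is not None:
            seq = _evolve_edge(seq, node.proximity, site, background, rng)
        if node.is_leaf:
            site_start = site[0] if site is not None else None
            if site is not None and node.label in loss.lost_species:
                start, wm = site
                seq = seq.copy()
                seq[start : start + wm.width] = _draw_categorical(background, wm.width, rng)
                site_start = None
            out[node.label] = EvolvedLeaf(seq, site_start)
        else:
            for child in node.children:
                recurse(child, seq)

    recurse(tree.root, anc)
    return out
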
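"""Labeled synthetic protein datasets with controllable signal.

Sequences are drawn as first-order Markov chains over the 20-residue
alphabet: the initial residue from a stationary composition, successors
from a row-stochastic transition kernel.  This lets tests plant a
di-peptide signal that is invisible to composition-based descriptors
(doubly stochastic kernels keep the stationary distribution uniform), or
a pure composition signal, without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import AA_INDEX, AMINO_ACIDS, LabeledDataset, ProteinRecord


@dataclass(frozen=True)
class ClassGenerator:
    """Stationary composition + transition kernel + length bounds."""

    weights: np.ndarray
    transition: np.ndarray
    length_range: tuple[int, int] = (50, 400)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        t = np.asarray(self.transition, dtype=float)
        if w.shape != (20,):
            raise ValueError(f"weights must have shape (20,), got {w.shape}")
        if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must be non-negative and sum to 1")
        if t.shape != (20, 20):
            raise ValueError(f"transition must be (20, 20), got {t.shape}")
        if (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must be non-negative and sum to 1")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"bad length range {self.length_range}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "transition", t)

    def with_lengths(self, lo: int, hi: int) -> "ClassGenerator":
        return ClassGenerator(self.weights, self.transition, (lo, hi))


def _uniform_generator(length_range=(50, 400)) -> ClassGenerator:
    w = np.full(20, 1.0 / 20)
    t = np.full((20, 20), 1.0 / 20)
    return ClassGenerator(w, t, length_range)


def generate_sequence(gen: ClassGenerator, rng: np.random.Generator) -> str:
    """One Markov-chain draw; length uniform over the closed bounds."""
    length = int(rng.integers(gen.length_range[0], gen.length_range[1] + 1))
    cum_rows = np.cumsum(gen.transition, axis=1)
    out = np.empty(length, dtype=np.intp)
    out[0] = rng.choice(20, p=gen.weights)
    draws = rng.random(length - 1)
    for i in range(1, length):
        out[i] = np.searchsorted(cum_rows[out[i - 1]], draws[i - 1], side="right")
    return "".join(AMINO_ACIDS[i] for i in out)


def generate_dataset(
    pos: ClassGenerator,
    neg: ClassGenerator,
    n_pos: int,
    n_neg: int,
    seed: int,
) -> LabeledDataset:
    """n_pos +1-labeled and n_neg -1-labeled Markov sequences, reproducibly."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    pos_records = [
        ProteinRecord(id=f"pos{i + 1}", sequence=generate_sequence(pos, rng))
        for i in range(n_pos)
    ]
    neg_records = [
        ProteinRecord(id=f"neg{i + 1}", sequence=generate_sequence(neg, rng))
        for i in range(n_neg)
    ]
    return LabeledDataset.from_classes(pos_records, neg_records)


def leucine_enriched_preset(
    length_range: tuple[int, int] = (50, 400),
) -> tuple[ClassGenerator, ClassGenerator]:
    """Composition-signal pair: positives rich in L, poor in C and W.

    Both classes are i.i.d. (transition rows equal the stationary
    weights), so the signal is fully visible to composition descriptors.
    """
    neg_w = np.full(20, 1.0 / 20)
    pos_w = np.full(20, 1.0 / 20)
    pos_w[AA_INDEX["L"]] += 0.06
    pos_w[AA_INDEX["C"]] -= 0.03
    pos_w[AA_INDEX["W"]] -= 0.03
    pos = ClassGenerator(pos_w, np.tile(pos_w, (20, 1)), length_range)
    neg = ClassGenerator(neg_w, np.tile(neg_w, (20, 1)), length_range)
    return pos, neg


def dipeptide_enriched_preset(
    delta: float = 0.05,
    pairs: tuple[tuple[str, str], ...] = (("L", "V"),),
    length_range: tuple[int, int] = (50, 400),
) -> tuple[ClassGenerator, ClassGenerator]:
    """Order-signal pair with identical (uniform) stationary composition.

    For each residue pair (a, b) the positive kernel gets
    P(a->a) += delta, P(b->b) += delta, P(a->b) -= delta, P(b->a) -= delta
    on a uniform base of 1/20.  The perturbed kernel stays doubly
    stochastic, so the stationary composition remains uniform and the
    signal is invisible to AAC in expectation while DPC sees it directly.
    The default delta doubles P(L->L).
    """
    u = 1.0 / 20
    if not 0 < delta <= u:
        raise ValueError(f"delta must be in (0, {u}], got {delta}")
    t = np.full((20, 20), u)
    for a, b in pairs:
        ia, ib = AA_INDEX[a], AA_INDEX[b]
        if ia == ib:
            raise ValueError("pair residues must differ")
        t[ia, ia] += delta
        t[ib, ib] += delta
        t[ia, ib] -= delta
        t[ib, ia] -= delta
    w = np.full(20, u)
    pos = ClassGenerator(w, t, length_range)
    neg = _uniform_generator(length_range)
    return pos, neg


def null_preset(
    length_range: tuple[int, int] = (50, 400),
) -> tuple[ClassGenerator, ClassGenerator]:
    """Identical generators: no signal by construction."""
    return _uniform_generator(length_range), _uniform_generator(length_range)
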
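"""Bout-aware call-type transition analysis.

Calls are ordered by onset per animal; an inter-call interval (next onset
minus current offset) of MORE than the gap threshold (default 2 s, strict)
ends a bout.  Within-bout consecutive call pairs are counted as bigram
transitions, self-transitions included, and never across bout boundaries.
Per-animal joint frequencies (count / total transitions) are averaged
unweighted within groups, and edges above the edge threshold (default 5%,
strict) form the transition graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CallRecord


@dataclass
class Bout:
    calls: list[tuple[str, int, float, float]]  # (call_id, type, onset_s, offset_s)


@dataclass
class BoutSequence:
    animal_id: str
    bouts: list[Bout]

    @property
    def n_calls(self) -> int:
        return sum(len(b.calls) for b in self.bouts)

    @property
    def n_transitions(self) -> int:
        return sum(max(0, len(b.calls) - 1) for b in self.bouts)


@dataclass
class TransitionMatrix:
    counts: np.ndarray          # n_types x n_types integer counts
    n_transitions: int

    @property
    def joint(self) -> np.ndarray:
        """Joint frequencies (counts / total); zeros if no transitions."""
        if self.n_transitions == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n_transitions

    @property
    def conditional(self) -> np.ndarray:
        """Row-conditional probabilities; NaN rows where a type never occurs
        as a transition source."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.counts / sums, np.nan)


def build_sequences(calls: list[CallRecord], gap_s: float = 2.0,
                    ) -> dict[str, BoutSequence]:
    """Per-animal bout sequences from typed, timed calls.

    A bout break occurs where onset(next) - offset(current) exceeds ``gap_s``
    strictly; an interval of exactly ``gap_s`` stays within the bout.
    """
    by_animal: dict[str, list[CallRecord]] = {}
    for c in calls:
        if c.call_type is None:
            raise ValueError(f"call {c.call_id!r} has no type")
        by_animal.setdefault(c.animal_id, []).append(c)
    out = {}
    for animal, rows in by_animal.items():
        rows = sorted(rows, key=lambda c: c.onset_s)
        for prev, nxt in zip(rows, rows[1:]):
            if nxt.onset_s < prev.offset_s:
                raise ValueError(
                    f"animal {animal}: calls {prev.call_id!r} and {nxt.call_id!r} "
                    "overlap (detector contract violation)")
        bouts, current = [], []
        for c in rows:
            if current and (c.onset_s - current[-1][3]) > gap_s:
                bouts.append(Bout(current))
                current = []
            current.append((c.call_id, int(c.call_type), c.onset_s, c.offset_s))
        if current:
            bouts.append(Bout(current))
        out[animal] = BoutSequence(animal_id=animal, bouts=bouts)
    return out


def transition_counts(seq: BoutSequence, n_types: int = 9) -> TransitionMatrix:
    """Within-bout bigram counts (from-type x to-type), self-transitions
    included; nothing is counted across a bout boundary."""
    counts = np.zeros((n_types, n_types), dtype=int)
    for bout in seq.bouts:
        for (_, a, _, _), (_, b, _, _) in zip(bout.calls, bout.calls[1:]):
            if not (1 <= a <= n_types and 1 <= b <= n_types):
                raise ValueError(f"call type {a if not 1 <= a <= n_types else b} "
                                 f"outside 1..{n_types}")
            counts[a - 1, b - 1] += 1
    return TransitionMatrix(counts=counts, n_transitions=int(counts.sum()))


def group_average(matrices: list[TransitionMatrix]) -> np.ndarray:
    """Unweighted mean of per-animal joint-frequency matrices.

    Each animal contributes equally regardless of call count; animals with
    zero transitions are excluded with a warning.
    """
    valid = [m for m in matrices if m.n_transitions > 0]
    if len(valid) < len(matrices):
        warnings.warn(f"excluded {len(matrices) - len(valid)} animal(s) with "
                      "no transitions from the group average", stacklevel=2)
    if not valid:
        raise ValueError("no animal has any transitions")
    return np.mean([m.joint for m in valid], axis=0)


def edge_list(group_matrix: np.ndarray, threshold: float = 0.05,
              ) -> list[tuple[int, int, float]]:
    """Edges (from_type, to_type, weight) with weight strictly above the
    threshold, sorted by descending weight; self-edges included."""
    M = np.asarray(group_matrix, dtype=float)
    edges = [(i + 1, j + 1, float(M[i, j]))
             for i in range(M.shape[0]) for j in range(M.shape[1])
             if M[i, j] > threshold]
    return sorted(edges, key=lambda e: (-e[2], e[0], e[1]))


def edges_frame(edges: list[tuple[int, int, float]]) -> pd.DataFrame:
    df = pd.DataFrame(edges, columns=["from_type", "to_type", "weight"])
    df["self_transition"] = df["from_type"] == df["to_type"]
    return df


def to_dot(edges: list[tuple[int, int, float]], title: str = "transitions") -> str:
    """Graphviz DOT export of a transition graph (edge width ~ weight)."""
    lines = [f'digraph "{title}" {{', "  rankdir=LR;"]
    nodes = sorted({n for e in edges for n in e[:2]})
    for n in nodes:
        lines.append(f'  {n} [shape=circle];')
    for a, b, w in edges:
        lines.append(f'  {a} -> {b} [penwidth={max(0.5, 20 * w):.2f}, '
                     f'label="{w:.3f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
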
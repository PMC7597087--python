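"""Naive reference implementation of the automaton, used as an oracle.

Deliberately written as explicit double loops over cells and neighbours
with no vectorisation and no shared code with the package engine beyond
the rule definition itself.  Remote neighbours are not drawn here: the
caller feeds in the recorded per-iteration samples, so both engines see
the exact same stochastic choices.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

Coord = Tuple[int, ...]


def _local_neighbours(p: Coord, shape, kind: str, r: int) -> List[Coord]:
    out = []
    ranges = [range(-r, r + 1)] * len(shape)
    import itertools

    for off in itertools.product(*ranges):
        if all(o == 0 for o in off):
            continue
        if kind == "von_neumann" and sum(abs(o) for o in off) > r:
            continue
        q = tuple(pi + oi for pi, oi in zip(p, off))
        if all(0 <= qi < si for qi, si in zip(q, shape)):
            out.append(q)
    return out


def naive_run(
    image: np.ndarray,
    seed_items: Sequence[Tuple[Coord, int]],
    kind: str = "moore",
    radius: int = 1,
    max_iterations: int = 2000,
    remote_samples: Optional[List[Dict[Coord, List[Coord]]]] = None,
) -> List[np.ndarray]:
    """Run the automaton and return the label grid after every iteration.

    ``remote_samples[t][p]`` lists the remote attackers of cell p at
    iteration t (0-based); omit for the classical automaton.
    """
    image = np.asarray(image, dtype=float)
    shape = image.shape
    labels = {p: 0 for p in np.ndindex(*shape)}
    sigma = {p: 0.0 for p in np.ndindex(*shape)}
    for coord, label in seed_items:
        labels[tuple(coord)] = int(label)
        sigma[tuple(coord)] = 1.0

    history: List[np.ndarray] = []
    for t in range(max_iterations):
        new_labels = dict(labels)
        new_sigma = dict(sigma)
        captures = 0
        for p in np.ndindex(*shape):
            # strongest successful local attacker, first-in-order on ties
            best_local = None
            best_local_lab = None
            for q in _local_neighbours(p, shape, kind, radius):
                att = (1.0 - abs(image[p] - image[q])) * sigma[q]
                if best_local is None or att > best_local:
                    best_local = att
                    best_local_lab = labels[q]
            local_ok = best_local is not None and best_local > sigma[p]

            best_remote = None
            best_remote_lab = None
            if remote_samples is not None and t < len(remote_samples):
                for q in remote_samples[t].get(p, []):
                    att = (1.0 - abs(image[p] - image[q])) * sigma[q]
                    if best_remote is None or att > best_remote:
                        best_remote = att
                        best_remote_lab = labels[q]
            # remote must beat the defence AND the best local attack
            remote_ok = (
                best_remote is not None
                and best_remote > sigma[p]
                and (best_local is None or best_remote > best_local)
            )

            if remote_ok:
                new_labels[p] = best_remote_lab
                new_sigma[p] = best_remote
                captures += 1
            elif local_ok:
                new_labels[p] = best_local_lab
                new_sigma[p] = best_local
                captures += 1
        labels, sigma = new_labels, new_sigma
        grid = np.zeros(shape, dtype=np.int32)
        for p, lab in labels.items():
            grid[p] = lab
        history.append(grid)
        if captures == 0:
            break
    return history
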
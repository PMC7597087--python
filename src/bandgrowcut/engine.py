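"""The GrowCut / Band-Based GrowCut cellular automaton.

Each cell of the automaton carries a triplet (label, strength, feature):
the label is the region the cell currently claims (0 = unlabelled), the
strength sigma in [0, 1] is the confidence in that label, and the feature C
is the normalised grey intensity in [0, 1].  At every synchronous step each
neighbour q "attacks" cell p with force

    g(|C(p) - C(q)|) * sigma(q),        g(x) = 1 - x,

and p is captured (inherits q's label, strength set to the attack force)
whenever the force strictly exceeds sigma(p).  Seeds start at strength 1;
because g <= 1 no attack can exceed 1, so strengths stay in [0, 1] and
seed cells are never overrun.

Band-Based GrowCut (BBG) augments the standard Moore/von Neumann
neighbourhood with k remote cells sampled uniformly, per cell and per
iteration, from a Chebyshev annulus at distance a..b.  A sampled remote
attacker wins only if it is strictly stronger than both the defence and the
best local attacker — local neighbours win ties.  Every capture is
classified by its source (local / remote / remote override) so the
propagation micro-dynamics can be inspected.

The public surface is the :class:`GrowCut` model class (construct from
data, call :meth:`GrowCut.fit`) plus the functional :func:`run`,
:func:`segment_3d` and :func:`step`.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .neighbourhoods import NeighbourhoodSpec, enumerate_moore, enumerate_von_neumann
from .seeding import SeedMap

__all__ = [
    "CellState",
    "AutomatonState",
    "EngineConfig",
    "WinStats",
    "SegmentationResult",
    "GrowCut",
    "g_default",
    "attack_strength",
    "attack_matrix",
    "classify_win",
    "step",
    "run",
    "segment_3d",
]


def g_default(x: float, max_diff: float = 1.0) -> float:
    """Attack attenuation ``g(x) = 1 - x / max_diff``.

    Non-increasing and bounded to [0, 1]: identical features transfer the
    attacker's full strength, maximally different features transfer nothing.
    """
    if max_diff <= 0:
        raise ValueError("max_diff must be positive")
    x = float(x)
    if x < 0 or x > max_diff:
        raise ValueError(f"feature difference {x} outside [0, {max_diff}]")
    return 1.0 - x / max_diff


@dataclass(frozen=True)
class CellState:
    """State triplet of one cell: label, strength sigma, feature C."""

    label: int
    strength: float
    feature: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("strength must lie in [0, 1]")


@dataclass
class AutomatonState:
    """Dense grids of labels / strengths / features plus the iteration clock."""

    labels: np.ndarray
    strength: np.ndarray
    features: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        if not (self.labels.shape == self.strength.shape == self.features.shape):
            raise ValueError("label/strength/feature grids must share a shape")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.labels.shape

    @classmethod
    def from_seeds(cls, image: np.ndarray, seeds: SeedMap) -> "AutomatonState":
        image = np.asarray(image, dtype=np.float64)
        if image.ndim not in (2, 3):
            raise ValueError("image must be 2D or 3D")
        if image.size and (image.min() < -1e-9 or image.max() > 1 + 1e-9):
            raise ValueError("features must be normalised to [0, 1]")
        labels = np.zeros(image.shape, dtype=np.int32)
        strength = np.zeros(image.shape, dtype=np.float64)
        if len(seeds):
            if seeds.coords.shape[1] != image.ndim:
                raise ValueError("seed dimensionality does not match image")
            if (seeds.coords < 0).any() or (
                seeds.coords >= np.asarray(image.shape)
            ).any():
                raise ValueError("seed coordinate outside image")
            idx = tuple(seeds.coords.T)
            labels[idx] = seeds.labels
            strength[idx] = 1.0
        return cls(labels, strength, np.clip(image, 0.0, 1.0))

    def cell(self, coord: Sequence[int]) -> CellState:
        c = tuple(coord)
        return CellState(
            int(self.labels[c]), float(self.strength[c]), float(self.features[c])
        )

    def copy(self) -> "AutomatonState":
        return AutomatonState(
            self.labels.copy(), self.strength.copy(), self.features, self.t
        )


@dataclass(frozen=True)
class EngineConfig:
    """Run parameters: neighbourhood system, iteration cap, RNG seed."""

    neighbourhood: NeighbourhoodSpec = field(default_factory=NeighbourhoodSpec)
    max_iterations: int = 2000
    seed: int = 0
    record_wins: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class WinStats:
    """Cumulative capture counts by source over a run."""

    local_wins: int = 0
    remote_wins: int = 0
    remote_overrides: int = 0

    @property
    def total_wins(self) -> int:
        return self.local_wins + self.remote_wins + self.remote_overrides

    @property
    def local_fraction(self) -> float:
        """Local captures as a fraction of all captures (1.0 if none)."""
        total = self.total_wins
        return self.local_wins / total if total else 1.0

    def __iadd__(self, other: "WinStats") -> "WinStats":
        self.local_wins += other.local_wins
        self.remote_wins += other.remote_wins
        self.remote_overrides += other.remote_overrides
        return self

    def as_dict(self) -> dict:
        return {
            "local_wins": self.local_wins,
            "remote_wins": self.remote_wins,
            "remote_overrides": self.remote_overrides,
            "total_wins": self.total_wins,
        }


@dataclass
class SegmentationResult:
    """Outcome of a run: final labels plus convergence and win diagnostics."""

    labels: np.ndarray
    converged: bool
    iterations_used: int
    win_stats: WinStats
    seconds: float
    config: Optional[EngineConfig] = None

    def foreground_mask(self, foreground_label: int = 2) -> np.ndarray:
        return self.labels == foreground_label

    def stats_json(self) -> str:
        doc = {
            "iterations": self.iterations_used,
            "converged": self.converged,
            **self.win_stats.as_dict(),
            "seconds": self.seconds,
        }
        return json.dumps(doc)

    def summary(self) -> str:
        w = self.win_stats
        total = max(w.total_wins, 1)
        lines = [
            "GrowCut segmentation result",
            "===========================",
            f"grid shape          {self.labels.shape}",
            f"neighbourhood       "
            f"{self.config.neighbourhood.describe() if self.config else 'n/a'}",
            f"converged           {self.converged}",
            f"iterations used     {self.iterations_used}",
            f"wall time (s)       {self.seconds:.3f}",
            f"total captures      {w.total_wins}",
            f"  local wins        {w.local_wins} ({100 * w.local_wins / total:.1f}%)",
            f"  remote wins       {w.remote_wins} ({100 * w.remote_wins / total:.1f}%)",
            f"  remote overrides  {w.remote_overrides} "
            f"({100 * w.remote_overrides / total:.1f}%)",
        ]
        return "\n".join(lines)


def attack_strength(
    attacker: Sequence[int], defender: Sequence[int], state: AutomatonState
) -> float:
    """Force of ``attacker`` on ``defender``: g(|C(p) - C(q)|) * sigma(q)."""
    q, p = tuple(attacker), tuple(defender)
    diff = abs(float(state.features[p]) - float(state.features[q]))
    return g_default(min(diff, 1.0)) * float(state.strength[q])


def attack_matrix(
    state: AutomatonState, neighbourhood: Optional[NeighbourhoodSpec] = None
) -> np.ndarray:
    """Dense matrix of attack forces, rows = defenders, columns = attackers.

    Entries for non-adjacent cell pairs are NaN.  Cells are indexed in
    row-major (flat) order.  Intended for inspecting small automata.
    """
    spec = neighbourhood or NeighbourhoodSpec()
    shape = state.shape
    n = int(np.prod(shape))
    if n > 4096:
        raise ValueError("attack_matrix is meant for small grids")
    mat = np.full((n, n), np.nan)
    enum = enumerate_moore if spec.standard_kind == "moore" else enumerate_von_neumann
    for flat_p, p in enumerate(np.ndindex(*shape)):
        for q in enum(p, spec.standard_radius, shape):
            flat_q = int(np.ravel_multi_index(q, shape))
            mat[flat_p, flat_q] = attack_strength(q, p, state)
    return mat


def classify_win(
    best_local: Optional[float], best_remote: Optional[float], defense: float
) -> str:
    """Classify a capture by its source.

    ``local``: the local attacker succeeded and no stronger remote success
    exists; ``remote``: only the remote attacker succeeded; ``override``:
    both succeeded and the remote one was strictly stronger (a local
    neighbour would have propagated in its absence); ``none``: no success.
    Ties between local and remote go to the local neighbour.
    """
    local_ok = best_local is not None and best_local > defense
    remote_ok = best_remote is not None and best_remote > defense
    if local_ok and remote_ok:
        return "override" if best_remote > best_local else "local"
    if local_ok:
        return "local"
    if remote_ok:
        return "remote"
    return "none"


class _Kernel:
    """Precomputed geometry for synchronous steps on a fixed grid."""

    def __init__(self, shape: Tuple[int, ...], spec: NeighbourhoodSpec):
        self.shape = shape
        self.d = len(shape)
        self.spec = spec
        self.r = spec.standard_radius
        self.local_offsets = spec.local_offsets(self.d)
        self.band = None
        if spec.remote_band is not None:
            offs = np.asarray(spec.remote_offsets(self.d), dtype=np.int64)
            self.band = offs
            coords = np.indices(shape).reshape(self.d, -1).T  # (n, d)
            self.coords = coords
            valid = np.ones((coords.shape[0], offs.shape[0]), dtype=bool)
            for ax in range(self.d):  # per-axis to avoid an (n, m, d) temporary
                q_ax = coords[:, ax : ax + 1] + offs[None, :, ax]
                valid &= (q_ax >= 0) & (q_ax < shape[ax])
            self.counts = valid.sum(axis=1)
            # Per-cell table of in-grid band offset indices, padded with -1:
            # sampling then reduces to drawing distinct ranks < counts[cell].
            n, m = valid.shape
            maxc = int(self.counts.max()) if n else 0
            table = np.full((n, maxc), -1, dtype=np.int32)
            rows, cols = np.nonzero(valid)
            starts = np.zeros(n + 1, dtype=np.int64)
            np.cumsum(self.counts, out=starts[1:])
            pos = np.arange(rows.size) - starts[rows]
            table[rows, pos] = cols
            self.table = table
            k = spec.k
            self.low_rows = np.nonzero(self.counts <= k)[0]
            self.hi_rows = np.nonzero(self.counts > k)[0]

    # -- remote sampling ---------------------------------------------------

    def draw_samples(self, rng: np.random.Generator) -> np.ndarray:
        """(n_cells, k) indices into the band offset table; -1 = no sample.

        Each row is a uniform without-replacement draw from that cell's
        in-grid band cells (all of them when fewer than k remain).  Draws
        are sequential per sample slot with rejection of duplicate ranks,
        which is exact sampling without replacement.
        """
        assert self.band is not None
        k = self.spec.k
        n = self.counts.size
        ranks = np.full((n, k), -1, dtype=np.int64)
        for row in self.low_rows:
            c = self.counts[row]
            if c:
                ranks[row, :c] = np.arange(c)
        idx = self.hi_rows
        if idx.size:
            cnt = self.counts[idx].astype(np.float64)
            for j in range(k):
                col = (rng.random(idx.size) * cnt).astype(np.int64)
                dup = np.zeros(idx.size, dtype=bool)
                for jj in range(j):
                    dup |= col == ranks[idx, jj]
                while dup.any():
                    where = np.nonzero(dup)[0]
                    col[where] = (
                        rng.random(where.size) * cnt[where]
                    ).astype(np.int64)
                    still = np.zeros(where.size, dtype=bool)
                    for jj in range(j):
                        still |= col[where] == ranks[idx[where], jj]
                    dup[where] = still
                ranks[idx, j] = col
        S = np.where(ranks >= 0, self.table[np.arange(n)[:, None], ranks], -1)
        return S.astype(np.int64)

    # -- one synchronous update --------------------------------------------

    def step(
        self,
        state: AutomatonState,
        remote_samples: Optional[np.ndarray],
    ) -> Tuple[AutomatonState, WinStats, int]:
        shape = self.shape
        r = self.r
        pad = [(r, r)] * self.d
        # out-of-grid sentinel: strength -1 makes every attack force negative
        sig_p = np.pad(state.strength, pad, constant_values=-1.0)
        feat_p = np.pad(state.features, pad, constant_values=0.0)
        lab_p = np.pad(state.labels, pad, constant_values=0)

        best_local = np.full(shape, -np.inf)
        best_local_lab = np.zeros(shape, dtype=state.labels.dtype)
        for off in self.local_offsets:
            sl = tuple(slice(r + o, r + o + s) for o, s in zip(off, shape))
            att = (1.0 - np.abs(state.features - feat_p[sl])) * sig_p[sl]
            better = att > best_local  # strict: first offset in order wins ties
            best_local[better] = att[better]
            best_local_lab[better] = lab_p[sl][better]

        sigma = state.strength
        local_ok = best_local > sigma

        if self.band is not None and remote_samples is not None:
            S = remote_samples
            n, k = S.shape
            flat_feat = state.features.ravel()
            flat_sig = state.strength.ravel()
            flat_lab = state.labels.ravel()
            safe = np.maximum(S, 0)
            qpos = self.coords[:, None, :] + self.band[safe]  # (n, k, d)
            qflat = np.ravel_multi_index(
                tuple(np.clip(qpos[..., i], 0, shape[i] - 1) for i in range(self.d)),
                shape,
            )
            att = (
                1.0 - np.abs(flat_feat[:, None] - flat_feat[qflat])
            ) * flat_sig[qflat]
            att[S < 0] = -np.inf
            j_best = np.argmax(att, axis=1)  # first maximum = first sampled
            rows = np.arange(n)
            best_remote = att[rows, j_best].reshape(shape)
            best_remote_lab = flat_lab[qflat[rows, j_best]].reshape(shape)
            # remote wins only if strictly stronger than defence AND the best
            # local attack — local neighbours win ties
            remote_ok = (best_remote > sigma) & (best_remote > best_local)
        else:
            best_remote = None
            remote_ok = np.zeros(shape, dtype=bool)

        captured = local_ok | remote_ok
        new_labels = state.labels.copy()
        new_sigma = state.strength.copy()
        local_cap = local_ok & ~remote_ok
        if local_cap.any():
            new_labels[local_cap] = best_local_lab[local_cap]
            new_sigma[local_cap] = best_local[local_cap]
        if remote_ok.any():
            new_labels[remote_ok] = best_remote_lab[remote_ok]
            new_sigma[remote_ok] = best_remote[remote_ok]

        stats = WinStats(
            local_wins=int(local_cap.sum()),
            remote_wins=int((remote_ok & ~local_ok).sum()),
            remote_overrides=int((remote_ok & local_ok).sum()),
        )
        new_state = AutomatonState(new_labels, new_sigma, state.features, state.t + 1)
        return new_state, stats, int(captured.sum())


from functools import lru_cache


@lru_cache(maxsize=8)
def _get_kernel(shape: Tuple[int, ...], spec: NeighbourhoodSpec) -> _Kernel:
    """Kernels hold only geometry, so they are cached per (shape, spec)."""
    return _Kernel(shape, spec)


def step(
    state: AutomatonState,
    config: EngineConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[AutomatonState, WinStats, int]:
    """One fully synchronous update; returns (new state, win delta, captures)."""
    kernel = _get_kernel(state.shape, config.neighbourhood)
    samples = None
    if kernel.band is not None:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        samples = kernel.draw_samples(rng)
    return kernel.step(state, samples)


def _validate_inputs(image: np.ndarray, seeds: SeedMap) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if len(seeds) and seeds.coords.shape[1] != image.ndim:
        raise ValueError("seed/image dimensionality mismatch")
    return image


def run(
    image: np.ndarray,
    seeds: SeedMap,
    config: Optional[EngineConfig] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    sample_log: Optional[list] = None,
    remote_sample_feed: Optional[Iterator[np.ndarray]] = None,
    label_log: Optional[list] = None,
) -> SegmentationResult:
    """Iterate the automaton until a capture-free iteration or the cap.

    Deterministic given ``config.seed``.  ``sample_log`` (a list) receives a
    copy of the per-iteration remote sample index arrays;
    ``remote_sample_feed`` replays such arrays instead of drawing fresh
    ones; ``label_log`` receives a copy of the label grid after every
    iteration.  These hooks exist so an independent reference
    implementation can be run against the exact same stochastic choices.
    """
    config = config or EngineConfig()
    image = _validate_inputs(image, seeds)
    state = AutomatonState.from_seeds(image, seeds)
    kernel = _get_kernel(state.shape, config.neighbourhood)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    stats = WinStats()
    converged = False
    t = 0
    start = time.perf_counter()
    for t in range(1, config.max_iterations + 1):
        samples = None
        if kernel.band is not None:
            if remote_sample_feed is not None:
                samples = next(remote_sample_feed)
            else:
                samples = kernel.draw_samples(rng)
            if sample_log is not None:
                sample_log.append(samples.copy())
        state, delta, captures = kernel.step(state, samples)
        stats += delta
        if label_log is not None:
            label_log.append(state.labels.copy())
        if captures == 0:
            converged = True
            break
    seconds = time.perf_counter() - start
    return SegmentationResult(
        labels=state.labels,
        converged=converged,
        iterations_used=t,
        win_stats=stats,
        seconds=seconds,
        config=config,
    )


def segment_3d(
    volume: np.ndarray,
    seeds: SeedMap,
    config: Optional[EngineConfig] = None,
    mode: str = "stitch",
) -> SegmentationResult:
    """Segment a 3D volume slice-wise ("stitch") or as one 3D automaton ("full").

    Stitch mode runs an independent 2D automaton per slice (axis 0) using
    that slice's seeds, stacks the label slices, sums win statistics, and
    reports the maximum per-slice iteration count.  Slices without seeds are
    returned fully unlabelled with a warning.  Full mode is a single run
    with the d=3 generalisation of the neighbourhoods.
    """
    config = config or EngineConfig()
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("segment_3d expects a 3D volume")
    if mode == "full":
        return run(volume, seeds, config)
    if mode != "stitch":
        raise ValueError(f"unknown 3D mode {mode!r}")
    if len(seeds) and seeds.coords.shape[1] != 3:
        raise ValueError("stitch mode expects 3D seed coordinates")

    n_slices = volume.shape[0]
    children = np.random.SeedSequence(config.seed).spawn(n_slices)
    labels = np.zeros(volume.shape, dtype=np.int32)
    stats = WinStats()
    iterations = 0
    converged = True
    seconds = 0.0
    for z in range(n_slices):
        in_slice = seeds.coords[:, 0] == z if len(seeds) else np.zeros(0, bool)
        if len(seeds) and in_slice.any():
            sub = SeedMap(seeds.coords[in_slice][:, 1:], seeds.labels[in_slice])
        else:
            warnings.warn(f"slice {z} has no seeds; returned unlabelled", stacklevel=2)
            continue
        res = run(
            volume[z], sub, config, rng=np.random.default_rng(children[z])
        )
        labels[z] = res.labels
        stats += res.win_stats
        iterations = max(iterations, res.iterations_used)
        converged = converged and res.converged
        seconds += res.seconds
    return SegmentationResult(
        labels=labels,
        converged=converged,
        iterations_used=iterations,
        win_stats=stats,
        seconds=seconds,
        config=config,
    )


class GrowCut:
    """Seeded cellular-automaton segmentation model.

    Construct from an image (2D or 3D, features in [0, 1]) and a
    :class:`~bandgrowcut.seeding.SeedMap`; :meth:`fit` evolves the automaton
    to convergence (or the iteration cap) and returns a
    :class:`SegmentationResult`.

    Parameters
    ----------
    image : ndarray
        Normalised grey intensities in [0, 1].
    seeds : SeedMap
        Initial labelled cells, strength 1.
    neighbourhood : NeighbourhoodSpec, optional
        Defaults to the classical Moore radius-1 neighbourhood; supply a
        ``remote_band=(a, b)`` for Band-Based GrowCut.
    max_iterations : int
        Iteration cap (default 2000); non-converged runs are returned as-is.
    seed : int
        RNG seed for remote-band sampling.
    mode : {"stitch", "full"}
        3D handling; ignored for 2D images.

    Examples
    --------
    >>> from bandgrowcut import GrowCut, NeighbourhoodSpec
    >>> from bandgrowcut.fixtures import worked_example
    >>> ex = worked_example()
    >>> res = GrowCut(ex.image, ex.seeds).fit()
    >>> res.converged, res.iterations_used
    (True, 2)
    """

    def __init__(
        self,
        image: np.ndarray,
        seeds: SeedMap,
        neighbourhood: Optional[NeighbourhoodSpec] = None,
        *,
        max_iterations: int = 2000,
        seed: int = 0,
        mode: str = "stitch",
    ):
        self.image = np.asarray(image, dtype=np.float64)
        self.seeds = seeds
        self.config = EngineConfig(
            neighbourhood=neighbourhood or NeighbourhoodSpec(),
            max_iterations=max_iterations,
            seed=seed,
        )
        if mode not in ("stitch", "full"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode

    def fit(self, **run_kwargs) -> SegmentationResult:
        if self.image.ndim == 3:
            if run_kwargs:
                raise TypeError("run hooks are only supported for 2D fits")
            return segment_3d(self.image, self.seeds, self.config, self.mode)
        return run(self.image, self.seeds, self.config, **run_kwargs)
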
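"""Spatial primitives: diffusion proposals, tethers, voxel neighbor search.

The production integrator lives in :mod:`heterosim._kernel` (numba) and
operates on the flat arrays assembled by :mod:`heterosim.system`; the
functions here define the *semantics* of a single move — they are the
reference implementation the kernel mirrors, and the surface the unit
tests exercise directly.

Monte Carlo move scheme
-----------------------
Each particle, in randomized order, receives an isotropic Gaussian
displacement with per-axis variance 2·D·Δt (resampled while its magnitude
exceeds the resolution cap).  The move is rejected outright if it creates
a hard-core overlap with any non-tethered particle, and otherwise accepted
with probability ∏ w(d) over the particle's tethers, where

    w(d) = 0                      d < min_len   (overlap)
    w(d) = 1                      min_len ≤ d ≤ free_len
    w(d) = exp(-k·(d - free_len)) d > free_len  (exponential damping)

Accepting with probability w makes the stationary pair-distance density
proportional to r²·w(r) — the "random polymer" distribution of a tethered
pair.  The box is periodic; all distances are minimum-image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TetherSpec",
    "ParticleState",
    "VoxelGrid",
    "tether_acceptance",
    "propose_move",
    "minimum_image",
]


@dataclass(frozen=True)
class TetherSpec:
    """A pair tether: hard floor, free range, exponential damping beyond.

    ``min_len`` is the sum of partner radii (hard contact), ``free_len``
    the standard distance maintained by the disordered linker, and
    ``damping_k`` the multiplier in exp(-k·Δd) beyond it.
    """

    min_len: float
    free_len: float
    damping_k: float = 0.3

    def __post_init__(self) -> None:
        if not self.min_len < self.free_len:
            raise ValueError(
                f"tether min_len={self.min_len} must be < free_len={self.free_len}"
            )
        if self.damping_k < 0:
            raise ValueError(f"damping_k={self.damping_k} must be ≥ 0")


def tether_acceptance(new_dist: float, spec: TetherSpec) -> float:
    """Acceptance weight w(d) of a proposed tethered-pair distance."""
    if new_dist < 0:
        raise ValueError("distance must be ≥ 0")
    if new_dist < spec.min_len:
        return 0.0
    if new_dist <= spec.free_len:
        return 1.0
    return math.exp(-spec.damping_k * (new_dist - spec.free_len))


@dataclass
class ParticleState:
    """One particle: position, kind, size, mobility, attachments."""

    id: int
    kind: str
    position: np.ndarray
    radius: float
    diffusivity: float
    enzyme_label: str | None = None
    tethered_to: list = field(default_factory=list)  # (partner id, TetherSpec)
    bonds: list = field(default_factory=list)
    active: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.radius > 0:
            raise ValueError(f"radius={self.radius} must be > 0")
        if self.diffusivity < 0:
            raise ValueError(f"diffusivity={self.diffusivity} must be ≥ 0")


def propose_move(
    p: ParticleState,
    dt: float,
    rng: np.random.Generator,
    max_step: float = 6.0,
) -> np.ndarray:
    """Isotropic Gaussian displacement, per-axis variance 2·D·Δt.

    The magnitude is capped at ``max_step`` by rejection-resampling, which
    renormalizes the proposal density on the truncated support; with the
    default cap the truncated mass is <0.1% for every species.
    """
    sigma = math.sqrt(2.0 * p.diffusivity * dt)
    if sigma == 0.0:
        return np.zeros(3)
    cap2 = max_step * max_step
    while True:
        d = rng.normal(0.0, sigma, 3)
        if d @ d <= cap2:
            return d


def minimum_image(delta: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image convention displacement for a periodic cubic box."""
    return delta - box_edge * np.round(delta / box_edge)


class VoxelGrid:
    """Uniform cell list over a periodic cubic box.

    Guarantees that a 27-cell stencil query finds every particle within
    ``cutoff ≤ edge``; with fewer than 3 cells per dimension it degrades
    to an exhaustive scan, which remains exact.
    """

    def __init__(self, box_edge: float, edge: float):
        if edge <= 0 or box_edge <= 0:
            raise ValueError("box_edge and edge must be > 0")
        self.box_edge = float(box_edge)
        self.ncell = max(1, int(box_edge / edge))
        self.cell_edge = self.box_edge / self.ncell
        self._cells: dict[tuple, list[int]] = {}
        self._positions: dict[int, np.ndarray] = {}

    def _cell_of(self, pos: np.ndarray) -> tuple:
        idx = np.floor(np.asarray(pos) / self.cell_edge).astype(int) % self.ncell
        return tuple(idx)

    def insert(self, pid: int, pos: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=float) % self.box_edge
        self._positions[pid] = pos
        self._cells.setdefault(self._cell_of(pos), []).append(pid)

    def remove(self, pid: int) -> None:
        pos = self._positions.pop(pid)
        self._cells[self._cell_of(pos)].remove(pid)

    def move(self, pid: int, new_pos: np.ndarray) -> None:
        self.remove(pid)
        self.insert(pid, new_pos)

    def __contains__(self, pid: int) -> bool:
        return pid in self._positions

    def __len__(self) -> int:
        return len(self._positions)

    def neighbor_query(self, pos: np.ndarray, cutoff: float) -> list[int]:
        """All particle ids within ``cutoff`` of ``pos`` (closed ball)."""
        if cutoff > self.cell_edge and self.ncell >= 3:
            raise ValueError(
                f"cutoff={cutoff} exceeds voxel edge {self.cell_edge:.3g}; "
                "neighbor search would not be exhaustive"
            )
        pos = np.asarray(pos, dtype=float) % self.box_edge
        found = []
        if self.ncell < 3:
            candidates = self._positions.items()
            for pid, q in candidates:
                d = minimum_image(q - pos, self.box_edge)
                if d @ d <= cutoff * cutoff:
                    found.append(pid)
            return sorted(found)
        base = np.floor(pos / self.cell_edge).astype(int)
        seen_cells = set()
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    cell = tuple((base + (ox, oy, oz)) % self.ncell)
                    if cell in seen_cells:
                        continue
                    seen_cells.add(cell)
                    for pid in self._cells.get(cell, ()):
                        d = minimum_image(self._positions[pid] - pos, self.box_edge)
                        if d @ d <= cutoff * cutoff:
                            found.append(pid)
        return sorted(found)
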
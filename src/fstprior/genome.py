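"""Simulated genome map: chromosomes, marker and QTL positions.

Positions are genetic (centimorgan). Loci of both kinds live on one global,
position-sorted axis so that haplotypes are plain arrays; ``marker_index``
and ``qtl_index`` map back into that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenomeSpec:
    """Chromosome layout plus marker/QTL genetic positions.

    Parameters
    ----------
    n_chromosomes:
        Number of chromosomes (autosomes only).
    chrom_length_cM:
        Map length of every chromosome, in centimorgan.
    marker_positions, qtl_positions:
        Per-chromosome, strictly increasing positions in cM. Marker and QTL
        position sets must be disjoint within a chromosome.
    """

    n_chromosomes: int
    chrom_length_cM: float
    marker_positions: list[np.ndarray]
    qtl_positions: list[np.ndarray]

    # derived global arrays, filled in __post_init__
    chrom: np.ndarray = field(init=False, repr=False)
    pos: np.ndarray = field(init=False, repr=False)
    is_qtl: np.ndarray = field(init=False, repr=False)
    marker_index: np.ndarray = field(init=False, repr=False)
    qtl_index: np.ndarray = field(init=False, repr=False)
    chrom_bounds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        if len(self.marker_positions) != self.n_chromosomes:
            raise ValueError("marker_positions must have one array per chromosome")
        if len(self.qtl_positions) != self.n_chromosomes:
            raise ValueError("qtl_positions must have one array per chromosome")
        chroms, pos, is_qtl = [], [], []
        for c in range(self.n_chromosomes):
            m = np.asarray(self.marker_positions[c], dtype=float)
            q = np.asarray(self.qtl_positions[c], dtype=float)
            for name, arr in (("marker", m), ("qtl", q)):
                if arr.size and (np.any(arr < 0) or np.any(arr > self.chrom_length_cM)):
                    raise ValueError(f"{name} positions outside [0, chrom_length] on chrom {c}")
                if arr.size > 1 and np.any(np.diff(arr) <= 0):
                    raise ValueError(f"{name} positions not strictly increasing on chrom {c}")
            if np.intersect1d(m, q).size:
                raise ValueError(f"marker and QTL positions overlap on chrom {c}")
            allpos = np.concatenate([m, q])
            flags = np.concatenate([np.zeros(m.size, bool), np.ones(q.size, bool)])
            order = np.argsort(allpos, kind="stable")
            chroms.append(np.full(allpos.size, c, dtype=np.int32))
            pos.append(allpos[order])
            is_qtl.append(flags[order])
        self.chrom = np.concatenate(chroms)
        self.pos = np.concatenate(pos)
        self.is_qtl = np.concatenate(is_qtl)
        self.marker_index = np.flatnonzero(~self.is_qtl)
        self.qtl_index = np.flatnonzero(self.is_qtl)
        sizes = np.bincount(self.chrom, minlength=self.n_chromosomes)
        self.chrom_bounds = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)

    @property
    def n_loci(self) -> int:
        return int(self.pos.size)

    @property
    def n_markers(self) -> int:
        return int(self.marker_index.size)

    @property
    def n_qtl(self) -> int:
        return int(self.qtl_index.size)

    def locus_names(self) -> list[str]:
        """Stable locus identifiers, e.g. ``chr1_12.3450`` for markers, ``qtl`` prefix for QTL."""
        out = []
        for i in range(self.n_loci):
            kind = "qtl" if self.is_qtl[i] else "snp"
            out.append(f"{kind}_chr{self.chrom[i] + 1}_{self.pos[i]:.4f}")
        return out


def build_genome(
    n_chromosomes: int,
    chrom_length_cM: float,
    n_markers: int,
    n_qtl_candidates: int,
    rng: np.random.Generator,
) -> GenomeSpec:
    """Lay out evenly spaced markers and uniform-random QTL candidate positions.

    Markers are placed on a regular grid (offset half a step from the
    chromosome ends). QTL candidates are dropped uniformly at random and
    nudged off marker positions so the two sets never coincide.
    """
    if n_markers <= 0 or n_chromosomes <= 0:
        raise ValueError("marker and chromosome counts must be positive")
    per_chrom = np.full(n_chromosomes, n_markers // n_chromosomes, dtype=int)
    per_chrom[: n_markers % n_chromosomes] += 1
    qtl_per_chrom = rng.multinomial(n_qtl_candidates, np.ones(n_chromosomes) / n_chromosomes)
    marker_positions, qtl_positions = [], []
    for c in range(n_chromosomes):
        k = per_chrom[c]
        step = chrom_length_cM / k
        m = (np.arange(k) + 0.5) * step
        q = np.sort(rng.uniform(0.0, chrom_length_cM, size=qtl_per_chrom[c]))
        # nudge QTL off markers and off each other (exact collisions only)
        eps = step * 1e-3
        for _ in range(10):
            clash = np.isin(q, m) | np.concatenate([[False], np.diff(q) == 0])
            if not clash.any():
                break
            q[clash] += eps
            q = np.sort(np.clip(q, 0.0, chrom_length_cM))
        marker_positions.append(m)
        qtl_positions.append(q)
    return GenomeSpec(n_chromosomes, chrom_length_cM, marker_positions, qtl_positions)
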
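import numpy as np
import pytest

from breakscape.intervals import GenomicInterval
from breakscape.simulate import SimulationConfig


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """Desk-scale config for fast end-to-end runs."""
    cfg = SimulationConfig()
    cfg.amplicon.n_sites = 4
    cfg.mutation.templates_per_site = 60
    cfg.mutation.n_animals_per_group = 3
    cfg.n_elements = 40
    cfg.expression.n_genes = 400
    cfg.expression.n_cre = 60
    cfg.expression.n_dcre = 60
    cfg.expression.n_uninfected = 30
    cfg.expression.n_targets = 10
    return cfg


def random_intervals(rng: np.random.Generator, n: int, chrom_len: int = 10_000,
                     chrom: str = "c1") -> list[GenomicInterval]:
    starts = rng.integers(0, chrom_len - 2, size=n)
    widths = rng.integers(1, chrom_len // 10, size=n)
    return [GenomicInterval(chrom, int(s), int(min(s + w, chrom_len)))
            for s, w in zip(starts, widths)]


def brute_force_depth(sets, chrom_len: int = 10_000) -> np.ndarray:
    """Per-base replicate-depth profile of binarised peak sets (oracle)."""
    depth = np.zeros(chrom_len, dtype=int)
    for peaks in sets:
        cov = np.zeros(chrom_len, dtype=bool)
        for iv in peaks:
            cov[iv.start:iv.end] = True
        depth += cov
    return depth


def segments_from_mask(mask: np.ndarray, chrom: str = "c1"):
    """Maximal True runs of a per-base mask as intervals (oracle)."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [GenomicInterval(chrom, int(s), int(e))
            for s, e in zip(edges[::2], edges[1::2])]
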
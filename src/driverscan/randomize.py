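"""Trinucleotide- and locality-preserving randomization of mutation datasets.

Each mutation is independently moved to a uniformly chosen position within
±``window_bp`` on its own chromosome whose reference trinucleotide matches
the mutation's context, excluding the original position when an alternative
exists.  Repeating a cohort analysis on such a randomized dataset provides
an empirical estimate of the false discovery rate: hits surviving the
randomization can only be artefacts of the statistical model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .mutations import MutationRecord
from .regions import GenomeSequence, TRINUCLEOTIDES

log = logging.getLogger(__name__)

__all__ = ["RandomizationConfig", "randomize_dataset", "empirical_fdr"]

_CODE = {t: i for i, t in enumerate(TRINUCLEOTIDES)}


@dataclass
class RandomizationConfig:
    """Half-width of the repositioning window (bp) and RNG seed."""

    window_bp: int = 50_000
    seed: int = 1

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")


def _positions_by_code(genome: GenomeSequence, chrom: str) -> list[np.ndarray]:
    tcodes = genome.context_codes(chrom)
    order = np.argsort(tcodes, kind="stable")
    codes = tcodes[order]
    lo = np.searchsorted(codes, np.arange(64), side="left")
    hi = np.searchsorted(codes, np.arange(64), side="right")
    return [order[l:h].astype(np.int64) for l, h in zip(lo, hi)]


def randomize_dataset(
    muts: list[MutationRecord],
    genome: GenomeSequence,
    cfg: RandomizationConfig | None = None,
) -> list[MutationRecord]:
    """Reposition every mutation within its context-matched 50-kb neighbourhood.

    Sample, alleles, chromosome and trinucleotide context are preserved; a
    mutation whose context occurs nowhere else in the window (or contains N)
    keeps its position.
    """
    cfg = cfg or RandomizationConfig()
    rng = np.random.default_rng(cfg.seed)
    by_chrom: dict[str, list[np.ndarray]] = {}
    out: list[MutationRecord] = []
    n_unmoved = 0
    for m in muts:
        if "N" in m.context or m.chrom not in genome:
            out.append(m)
            n_unmoved += 1
            continue
        if m.chrom not in by_chrom:
            by_chrom[m.chrom] = _positions_by_code(genome, m.chrom)
        arr = by_chrom[m.chrom][_CODE[m.context]]
        lo = int(np.searchsorted(arr, m.pos - cfg.window_bp, side="left"))
        hi = int(np.searchsorted(arr, m.pos + cfg.window_bp, side="right"))
        n_window = hi - lo
        if n_window <= 1:
            out.append(m)
            n_unmoved += 1
            continue
        orig = int(np.searchsorted(arr, m.pos))
        j = lo + int(rng.integers(0, n_window - 1))
        if j >= orig:
            j += 1  # skip the original position
        out.append(replace(m, pos=int(arr[j])))
    if n_unmoved:
        log.info("randomize: %d mutation(s) had no alternative position", n_unmoved)
    return out


def empirical_fdr(n_hits_randomized: int, n_hits_real: int) -> float:
    """Hits on the randomized dataset over hits on the real one; NaN when
    the real analysis produced no hits."""
    if n_hits_randomized < 0 or n_hits_real < 0:
        raise ValueError("hit counts must be non-negative")
    if n_hits_real == 0:
        return math.nan
    return n_hits_randomized / n_hits_real
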
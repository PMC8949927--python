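"""Strain-vs-strain haplotype map over a critical interval.

Tiles the interval into fixed-size windows anchored at the interval
start, counts strain-discordant SNPs per window, flags windows whose
discordant count exceeds a threshold, merges runs of flagged windows
into haplotype blocks, and filters a gene annotation down to genes
overlapping at least one flagged window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import GenomicInterval

DEFAULT_WINDOW_BP = 250_000
DEFAULT_SNP_THRESHOLD = 100


@dataclass
class SnpWindowProfile:
    """One tiling window with its SNP tallies.

    Windows are half-open ``[start, end)`` in bp; a SNP at a boundary
    belongs to the right-hand window.
    """

    index: int
    start: int
    end: int
    total: int
    discordant: int
    polymorphic: bool = False

    def __post_init__(self):
        if self.discordant > self.total:
            raise ValueError("discordant count cannot exceed total")
        if self.end <= self.start:
            raise ValueError("empty window")


@dataclass
class HaplotypeBlock:
    """Maximal run of consecutive polymorphic windows."""

    start: int
    end: int
    window_indices: tuple
    discordant_total: int


def window_counts(
    catalog,
    interval: GenomicInterval,
    window_size: int = DEFAULT_WINDOW_BP,
) -> list:
    """Tile ``interval`` and tally total / strain-discordant SNPs per window.

    The final window may be shorter than ``window_size`` if the interval
    length is not a multiple of it; it is kept and tallied like the rest.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if catalog.chromosome != interval.chromosome:
        raise ValueError(
            f"catalog chromosome {catalog.chromosome!r} does not match "
            f"interval {interval.chromosome!r}"
        )
    n_windows = int(np.ceil(interval.length_bp / window_size))
    starts = interval.start + window_size * np.arange(n_windows, dtype=np.int64)
    ends = np.minimum(starts + window_size, interval.end)

    pos = np.asarray(catalog.positions, dtype=np.int64)
    disc = np.asarray(catalog.discordant, dtype=bool)
    inside = (pos >= interval.start) & (pos < interval.end)
    widx = (pos[inside] - interval.start) // window_size
    total = np.bincount(widx, minlength=n_windows)
    discordant = np.bincount(widx, weights=disc[inside].astype(float),
                             minlength=n_windows).astype(np.int64)
    return [
        SnpWindowProfile(
            index=k,
            start=int(starts[k]),
            end=int(ends[k]),
            total=int(total[k]),
            discordant=int(discordant[k]),
        )
        for k in range(n_windows)
    ]


def call_polymorphic(
    profiles,
    threshold: int = DEFAULT_SNP_THRESHOLD,
    inclusive: bool = False,
):
    """Flag windows whose discordant count exceeds ``threshold``.

    "Exceeding" is read strictly (``>``) by default; pass
    ``inclusive=True`` for ``>=``.  Returns the flagged profiles and the
    maximal runs of consecutive flagged windows merged into
    :class:`HaplotypeBlock` records.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    flagged = []
    for p in profiles:
        flag = p.discordant >= threshold if inclusive else p.discordant > threshold
        flagged.append(
            SnpWindowProfile(p.index, p.start, p.end, p.total, p.discordant, flag)
        )
    blocks = []
    run = []
    for p in flagged + [None]:
        if p is not None and p.polymorphic:
            run.append(p)
            continue
        if run:
            blocks.append(
                HaplotypeBlock(
                    start=run[0].start,
                    end=run[-1].end,
                    window_indices=tuple(w.index for w in run),
                    discordant_total=sum(w.discordant for w in run),
                )
            )
            run = []
    return flagged, blocks


def filter_genes(annotation, profiles) -> list:
    """Genes whose closed span overlaps >= 1 bp of any polymorphic window.

    ``annotation`` is a GeneAnnotation (1-based inclusive gene spans);
    ``profiles`` are flagged windows from :func:`call_polymorphic`.
    Returns retained gene ids in annotation order.
    """
    poly = [(p.start, p.end) for p in profiles if p.polymorphic]
    if not poly:
        return []
    wstart = np.array([s for s, _ in poly], dtype=np.int64)
    wend = np.array([e for _, e in poly], dtype=np.int64)
    kept = []
    gstart = np.asarray(annotation.start, dtype=np.int64)
    gend = np.asarray(annotation.end, dtype=np.int64)
    for gid, gs, ge in zip(annotation.gene_ids, gstart, gend):
        # closed gene [gs, ge] vs half-open window [ws, we)
        if np.any((ge >= wstart) & (gs < wend)):
            kept.append(gid)
    return kept


def profiles_to_frame(profiles) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "window": p.index,
                "start": p.start,
                "end": p.end,
                "total": p.total,
                "discordant": p.discordant,
                "polymorphic": p.polymorphic,
            }
            for p in profiles
        ]
    )


def blocks_to_frame(blocks) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start": b.start,
                "end": b.end,
                "n_windows": len(b.window_indices),
                "discordant_total": b.discordant_total,
            }
            for b in blocks
        ],
        columns=["start", "end", "n_windows", "discordant_total"],
    )
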
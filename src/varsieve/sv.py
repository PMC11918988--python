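"""Dual-caller structural-variant concordance.

Large deletions/duplications are accepted only when a read-pair-based
caller and a read-depth-based caller agree on the event: same chromosome
and type, at most a twofold size difference, and both breakpoints within
10 kb of each other.  Matched events seen in a parent (by the pair-based
caller) are removed, and the survivors are restricted to events touching
at least one exon of a loss-of-function-intolerant gene (pLI above the
pLoF threshold).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Caller",
    "SVType",
    "SVCall",
    "SVPair",
    "SVCandidate",
    "ExonInterval",
    "match_calls",
    "parental_exclusion",
    "exon_overlap_filter",
    "read_sv_calls",
    "write_sv_calls",
    "read_exons",
    "sv_consensus",
]


class Caller(str, enum.Enum):
    pair_based = "pair_based"    # read-pair signatures (BreakDancer-style)
    depth_based = "depth_based"  # read-depth comparison (BIC-seq-style)


class SVType(str, enum.Enum):
    deletion = "deletion"
    duplication = "duplication"
    other = "other"


@dataclass(frozen=True)
class SVCall:
    """One caller-attributed interval call (1-based inclusive coordinates)."""

    caller: Caller
    sv_type: SVType
    chrom: str
    start: int
    end: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SVPair:
    """A concordant pair: one pair-based and one depth-based call."""

    pair_call: SVCall
    depth_call: SVCall

    @property
    def chrom(self) -> str:
        return self.pair_call.chrom

    @property
    def sv_type(self) -> SVType:
        return self.pair_call.sv_type

    @property
    def consensus_start(self) -> int:
        return min(self.pair_call.start, self.depth_call.start)

    @property
    def consensus_end(self) -> int:
        return max(self.pair_call.end, self.depth_call.end)


@dataclass(frozen=True)
class SVCandidate:
    """A concordant, non-parental SV overlapping exons of intolerant genes."""

    pair: SVPair
    genes: tuple[str, ...]


@dataclass(frozen=True)
class ExonInterval:
    gene: str
    chrom: str
    start: int
    end: int
    pli: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")


def _concordant(a: SVCall, b: SVCall, max_size_ratio: float,
                max_breakpoint_dist: int) -> bool:
    if a.chrom != b.chrom or a.sv_type != b.sv_type:
        return False
    if max(a.size, b.size) / min(a.size, b.size) > max_size_ratio:
        return False
    return (
        abs(a.start - b.start) <= max_breakpoint_dist
        and abs(a.end - b.end) <= max_breakpoint_dist
    )


def match_calls(
    calls_a: Sequence[SVCall],
    calls_b: Sequence[SVCall],
    max_size_ratio: float = 2.0,
    max_breakpoint_dist: int = 10_000,
) -> list[SVPair]:
    """One-to-one concordance matching between two callers' call sets.

    A pair matches iff same chromosome and SV type, size ratio at most
    ``max_size_ratio`` and both breakpoints within ``max_breakpoint_dist``.
    Each call joins at most one pair; candidate pairs are resolved greedily
    by smallest combined breakpoint distance, ties broken by leftmost
    start.  Symmetric in its two arguments (up to pair orientation).
    """
    calls_a, calls_b = list(calls_a), list(calls_b)
    samples = {c.sample_id for c in calls_a} | {c.sample_id for c in calls_b}
    if len(samples) > 1:
        raise ValueError(f"match_calls requires a single sample, got {sorted(samples)}")

    candidates = []
    for i, a in enumerate(calls_a):
        for j, b in enumerate(calls_b):
            if _concordant(a, b, max_size_ratio, max_breakpoint_dist):
                dist = abs(a.start - b.start) + abs(a.end - b.end)
                candidates.append(
                    (dist, min(a.start, b.start), max(a.start, b.start),
                     min(a.end, b.end), max(a.end, b.end), i, j)
                )
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[SVPair] = []
    for _, _, _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = calls_a[i], calls_b[j]
        if a.caller is Caller.depth_based and b.caller is Caller.pair_based:
            a, b = b, a
        pairs.append(SVPair(pair_call=a, depth_call=b))
    pairs.sort(key=lambda p: (p.chrom, p.consensus_start, p.consensus_end))
    return pairs


def parental_exclusion(
    matched: Iterable[SVPair],
    parental_calls: Sequence[SVCall],
    max_size_ratio: float = 2.0,
    max_breakpoint_dist: int = 10_000,
) -> list[SVPair]:
    """Drop pairs whose pair-based member matches any parental pair-based call.

    Only the pair-based caller's parental calls are consulted (it is the
    caller run jointly across the pedigree); the concordance criteria are
    the same as for inter-caller matching.
    """
    kept = []
    for pair in matched:
        inherited = any(
            _concordant(pair.pair_call, parental, max_size_ratio, max_breakpoint_dist)
            # parental calls come from different samples by construction
            and parental.sample_id != pair.pair_call.sample_id
            for parental in parental_calls
        )
        if not inherited:
            kept.append(pair)
    return kept


def exon_overlap_filter(
    pairs: Iterable[SVPair],
    exons: Sequence[ExonInterval],
    pli_min: float = 0.9,
) -> list[SVCandidate]:
    """Keep pairs whose consensus interval touches an intolerant gene's exon.

    The consensus interval is the union span of the two member calls; an
    overlap of at least 1 bp with at least one exon of a gene with
    pLI > ``pli_min`` qualifies.  Overlapped genes are reported.
    """
    trees: dict[str, IntervalTree] = {}
    for exon in exons:
        if exon.pli > pli_min:
            # IntervalTree uses half-open intervals; inclusive end -> end + 1
            trees.setdefault(exon.chrom, IntervalTree()).addi(
                exon.start, exon.end + 1, exon.gene
            )
    candidates = []
    for pair in pairs:
        tree = trees.get(pair.chrom)
        if tree is None:
            continue
        hits = tree.overlap(pair.consensus_start, pair.consensus_end + 1)
        genes = tuple(sorted({iv.data for iv in hits}))
        if genes:
            candidates.append(SVCandidate(pair=pair, genes=genes))
    return candidates


# ---------------------------------------------------------------------------
# table I/O (BED-like TSV, but 1-based inclusive like the in-memory model)

SV_COLUMNS = ["chrom", "start", "end", "sv_type", "caller", "sample_id"]
EXON_COLUMNS = ["chrom", "start", "end", "gene", "pli"]


def read_sv_calls(path: str | Path) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in SV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing SV columns {missing}")
    return [
        SVCall(
            caller=Caller(row["caller"]),
            sv_type=SVType(row["sv_type"]),
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            sample_id=str(row["sample_id"]),
        )
        for row in df.to_dict(orient="records")
    ]


def write_sv_calls(calls: Iterable[SVCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": c.chrom, "start": c.start, "end": c.end,
                "sv_type": c.sv_type.value, "caller": c.caller.value,
                "sample_id": c.sample_id,
            }
            for c in calls
        ],
        columns=SV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_exons(path: str | Path) -> list[ExonInterval]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in EXON_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing exon columns {missing}")
    return [
        ExonInterval(
            gene=str(row["gene"]), chrom=str(row["chrom"]),
            start=int(row["start"]), end=int(row["end"]), pli=float(row["pli"]),
        )
        for row in df.to_dict(orient="records")
    ]


def sv_consensus(
    pair_based_calls: Sequence[SVCall],
    depth_based_calls: Sequence[SVCall],
    parental_calls: Sequence[SVCall],
    exons: Sequence[ExonInterval],
    *,
    max_size_ratio: float = 2.0,
    max_breakpoint_dist: int = 10_000,
    pli_min: float = 0.9,
) -> dict[str, list[SVCandidate]]:
    """Full per-sample consensus: match, exclude parental, filter by exons."""
    by_sample: dict[str, list[SVCandidate]] = {}
    samples = sorted(
        {c.sample_id for c in pair_based_calls}
        | {c.sample_id for c in depth_based_calls}
    )
    for sample in samples:
        a = [c for c in pair_based_calls if c.sample_id == sample]
        b = [c for c in depth_based_calls if c.sample_id == sample]
        pairs = match_calls(a, b, max_size_ratio, max_breakpoint_dist)
        pairs = parental_exclusion(pairs, parental_calls, max_size_ratio,
                                   max_breakpoint_dist)
        by_sample[sample] = exon_overlap_filter(pairs, exons, pli_min)
    return by_sample
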
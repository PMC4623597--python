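"""UCSC chain files and liftOver-style interval mapping.

A chain describes a gapped pairwise alignment between a *source* assembly
(UCSC "target"/t side, always plus strand) and a *target* assembly (UCSC
"query"/q side, either strand). ``map_interval`` projects a source-assembly
interval through the aligned blocks of a single chain, mirroring how the
UCSC liftOver tool maps features, and reports the mapped interval on the
plus strand of the target assembly.

A deliberately naive per-base reference mapper (``map_interval_per_base``)
is provided for cross-checking the block-arithmetic path.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .intervals import GenomicInterval

DEFAULT_MIN_MAPPED_FRACTION = 0.95  # UCSC liftOver -minMatch default


class ChainParseError(ValueError):
    """Malformed chain file; message carries the offending line number."""


@dataclass(frozen=True)
class ChainBlock:
    """One aligned block: ``size`` aligned bases then gaps ``dt`` (source) / ``dq`` (target)."""

    size: int
    dt: int = 0
    dq: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("block size must be > 0")
        if self.dt < 0 or self.dq < 0:
            raise ValueError("gap lengths must be >= 0")


@dataclass
class Chain:
    """A single pairwise-alignment chain.

    ``t_*`` fields are the source assembly (plus strand by construction);
    ``q_*`` fields are the target assembly. For ``q_strand == '-'`` the
    ``q_start``/``q_end`` coordinates are on the *minus* strand of the
    target, as in the UCSC format.
    """

    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[ChainBlock]
    chain_id: int = 0

    def __post_init__(self) -> None:
        if self.q_strand not in ("+", "-"):
            raise ValueError(f"bad target strand {self.q_strand!r}")
        if self.blocks:
            last = self.blocks[-1]
            if last.dt != 0 or last.dq != 0:
                raise ValueError("final block must have dt = dq = 0")
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ValueError(
                f"block sums ({t_span}) != source span ({self.t_end - self.t_start})"
            )
        if q_span != self.q_end - self.q_start:
            raise ValueError(
                f"block sums ({q_span}) != target span ({self.q_end - self.q_start})"
            )
        # Cumulative block starts for O(log n) lookups.
        sizes = np.array([b.size for b in self.blocks], dtype=np.int64)
        dts = np.array([b.dt for b in self.blocks], dtype=np.int64)
        dqs = np.array([b.dq for b in self.blocks], dtype=np.int64)
        self._src_starts = self.t_start + np.concatenate(
            ([0], np.cumsum(sizes + dts)[:-1])
        )
        self._tgt_starts = self.q_start + np.concatenate(
            ([0], np.cumsum(sizes + dqs)[:-1])
        )
        self._sizes = sizes

    # -- block coordinate helpers -------------------------------------------------

    def mapped_bases(self, start: int, end: int) -> int:
        """Number of bases of source ``[start, end)`` inside aligned blocks."""
        i0 = max(0, int(np.searchsorted(self._src_starts, start, side="right")) - 1)
        i1 = int(np.searchsorted(self._src_starts, end, side="left"))
        s = self._src_starts[i0:i1]
        lo = np.maximum(s, start)
        hi = np.minimum(s + self._sizes[i0:i1], end)
        return int(np.maximum(hi - lo, 0).sum())

    def map_base(self, pos: int) -> Optional[int]:
        """Map one source base to a plus-strand target coordinate (None in a gap)."""
        i = int(np.searchsorted(self._src_starts, pos, side="right")) - 1
        if i < 0:
            return None
        off = pos - int(self._src_starts[i])
        if off >= int(self._sizes[i]):
            return None
        q = int(self._tgt_starts[i]) + off
        if self.q_strand == "-":
            q = self.q_size - 1 - q
        return q


ChainsLike = Union[Sequence[Chain], "ChainSet"]


class ChainSet:
    """Chains indexed by source chromosome."""

    def __init__(self, chains: Iterable[Chain]):
        self.chains = list(chains)
        self.by_chrom: dict[str, list[Chain]] = {}
        for c in self.chains:
            self.by_chrom.setdefault(c.t_name, []).append(c)

    def __iter__(self):
        return iter(self.chains)

    def __len__(self) -> int:
        return len(self.chains)

    def for_chrom(self, chrom: str) -> list[Chain]:
        return self.by_chrom.get(chrom, [])


def _as_chainset(chains: ChainsLike) -> ChainSet:
    return chains if isinstance(chains, ChainSet) else ChainSet(chains)


# -- parsing / writing ------------------------------------------------------------


def parse_chain_file(path) -> list[Chain]:
    """Parse a UCSC chain-format file.

    Raises :class:`ChainParseError` naming the line number on malformed
    headers, negative fields, or block sums that contradict the declared
    spans.
    """
    chains: list[Chain] = []
    header: Optional[dict] = None
    blocks: list[ChainBlock] = []
    header_line = 0

    def finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        try:
            chains.append(Chain(blocks=blocks, **header))
        except ValueError as exc:
            raise ChainParseError(
                f"line {header_line}: invalid chain: {exc}"
            ) from exc
        header, blocks = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish()
                fields = line.split()
                if len(fields) not in (12, 13):
                    raise ChainParseError(
                        f"line {lineno}: chain header has {len(fields)} fields"
                    )
                try:
                    header = dict(
                        score=float(fields[1]),
                        t_name=fields[2],
                        t_size=int(fields[3]),
                        t_start=int(fields[5]),
                        t_end=int(fields[6]),
                        q_name=fields[7],
                        q_size=int(fields[8]),
                        q_strand=fields[9],
                        q_start=int(fields[10]),
                        q_end=int(fields[11]),
                        chain_id=int(fields[12]) if len(fields) == 13 else 0,
                    )
                except ValueError as exc:
                    raise ChainParseError(
                        f"line {lineno}: unparsable chain header"
                    ) from exc
                if fields[4] != "+":
                    raise ChainParseError(
                        f"line {lineno}: source strand must be '+', got {fields[4]!r}"
                    )
                if min(
                    header["t_size"], header["t_start"], header["t_end"],
                    header["q_size"], header["q_start"], header["q_end"],
                ) < 0:
                    raise ChainParseError(f"line {lineno}: negative coordinate field")
                header_line = lineno
                blocks = []
            else:
                if header is None:
                    raise ChainParseError(
                        f"line {lineno}: alignment line outside a chain"
                    )
                parts = line.split()
                try:
                    nums = list(map(int, parts))
                except ValueError as exc:
                    raise ChainParseError(
                        f"line {lineno}: non-integer alignment field"
                    ) from exc
                if len(nums) == 3:
                    blocks.append(ChainBlock(nums[0], nums[1], nums[2]))
                elif len(nums) == 1:
                    blocks.append(ChainBlock(nums[0], 0, 0))
                else:
                    raise ChainParseError(
                        f"line {lineno}: expected 1 or 3 alignment fields, got {len(nums)}"
                    )
        finish()
    return chains


def write_chain_file(chains: Iterable[Chain], path) -> None:
    """Write chains in UCSC chain format (round-trips through :func:`parse_chain_file`)."""
    with open(path, "w") as fh:
        for c in chains:
            score = int(c.score) if float(c.score).is_integer() else c.score
            fh.write(
                f"chain {score} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.dt} {b.dq}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


def invert_chain(chain: Chain) -> Chain:
    """Swap source and target assemblies of a chain.

    For a minus-strand chain the block order reverses and both coordinate
    systems flip strand so the new source is, as required, on the plus
    strand (the new target then carries the minus strand).
    """
    if chain.q_strand == "+":
        blocks = [ChainBlock(b.size, b.dq, b.dt) for b in chain.blocks]
        return Chain(
            score=chain.score,
            t_name=chain.q_name, t_size=chain.q_size,
            t_start=chain.q_start, t_end=chain.q_end,
            q_name=chain.t_name, q_size=chain.t_size, q_strand="+",
            q_start=chain.t_start, q_end=chain.t_end,
            blocks=blocks, chain_id=chain.chain_id,
        )
    old = chain.blocks
    n = len(old)
    blocks = []
    for j in range(n):
        size = old[n - 1 - j].size
        if j < n - 1:
            g = old[n - 2 - j]
            blocks.append(ChainBlock(size, g.dq, g.dt))
        else:
            blocks.append(ChainBlock(size))
    return Chain(
        score=chain.score,
        t_name=chain.q_name, t_size=chain.q_size,
        t_start=chain.q_size - chain.q_end,
        t_end=chain.q_size - chain.q_start,
        q_name=chain.t_name, q_size=chain.t_size, q_strand="-",
        q_start=chain.t_size - chain.t_end,
        q_end=chain.t_size - chain.t_start,
        blocks=blocks, chain_id=chain.chain_id,
    )


# -- mapping ----------------------------------------------------------------------


@dataclass(frozen=True)
class OrthologyResult:
    """Outcome of mapping a locus across assemblies.

    ``status`` is ``'full'`` (whole interval mapped), ``'subinterval'``
    (only a scanned sub-window mapped; ``offset`` is the signed distance of
    that window's center from the locus center) or ``'unmapped'``.
    """

    status: str
    mapped: Optional[GenomicInterval] = None
    offset: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("full", "subinterval", "unmapped"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "unmapped") != (self.mapped is None):
            raise ValueError("mapped interval present iff status != unmapped")


def map_interval(
    q: GenomicInterval,
    chains: ChainsLike,
    min_mapped_fraction: float = DEFAULT_MIN_MAPPED_FRACTION,
) -> OrthologyResult:
    """Project ``q`` through the best single chain covering it.

    The interval maps iff the fraction of its bases falling inside aligned
    blocks of one chain is at least ``min_mapped_fraction``; the result
    spans the first through last mapped base, reported on the plus strand
    of the target assembly. A chromosome absent from the chains yields
    status ``'unmapped'``, not an error.
    """
    cs = _as_chainset(chains)
    best: Optional[Chain] = None
    best_frac = 0.0
    for chain in cs.for_chrom(q.chrom):
        n = chain.mapped_bases(q.start, q.end)
        frac = n / len(q)
        if frac > best_frac or (
            frac == best_frac and best is not None and chain.score > best.score
        ):
            best, best_frac = chain, frac
    if best is None or best_frac < min_mapped_fraction or best_frac == 0.0:
        return OrthologyResult("unmapped")

    starts = best._src_starts
    ends = starts + best._sizes
    # First and last mapped source base.
    i0 = int(np.searchsorted(ends, q.start, side="right"))
    first = max(q.start, int(starts[i0]))
    i1 = int(np.searchsorted(starts, q.end, side="left")) - 1
    last = min(q.end - 1, int(ends[i1]) - 1)
    t_first = best.map_base(first)
    t_last = best.map_base(last)
    assert t_first is not None and t_last is not None
    lo, hi = min(t_first, t_last), max(t_first, t_last)
    return OrthologyResult(
        "full", GenomicInterval(best.q_name, lo, hi + 1, "+"), offset=0
    )


def map_interval_per_base(
    q: GenomicInterval,
    chains: ChainsLike,
    min_mapped_fraction: float = DEFAULT_MIN_MAPPED_FRACTION,
) -> OrthologyResult:
    """Reference implementation: walk every base of ``q`` through each chain.

    Semantically identical to :func:`map_interval` but O(length); used to
    cross-validate the block-arithmetic mapper.
    """
    cs = _as_chainset(chains)
    best = None
    best_frac = 0.0
    best_positions: list[int] = []
    for chain in cs.for_chrom(q.chrom):
        positions = [
            p for p in (chain.map_base(b) for b in range(q.start, q.end)) if p is not None
        ]
        frac = len(positions) / len(q)
        if frac > best_frac or (
            frac == best_frac and best is not None and chain.score > best.score
        ):
            best, best_frac, best_positions = chain, frac, positions
    if best is None or best_frac < min_mapped_fraction or best_frac == 0.0:
        return OrthologyResult("unmapped")
    lo, hi = min(best_positions), max(best_positions)
    return OrthologyResult("full", GenomicInterval(best.q_name, lo, hi + 1, "+"))
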
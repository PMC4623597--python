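"""Synthetic assembly pairs related by indels, inversions and breaks.

Two generators are provided. ``simulate_genome_pair`` samples
rearrangement events at configured per-bp rates along assembly A and
derives assembly B plus a chain file that exactly encodes the relation —
the input for chain-mapping correctness checks. ``anchored_genome_pair``
(used by the epigenome simulator) instead lays out one alignment segment
per planted locus so conservation truth is exact by construction.

Both return the ground-truth alignment as a segment table
(a_chrom, a_start, a_end, b_chrom, b_start, b_end, strand) from which
chains are built; segment and chain views are therefore consistent by
construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ..chains import Chain, ChainBlock, invert_chain
from .config import SimulationConfig

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GenomePair:
    """A source assembly, a derived assembly, and their exact alignment."""

    sizes_a: dict[str, int]
    sizes_b: dict[str, int]
    chains: list[Chain]
    segments: pd.DataFrame
    seqs_a: Optional[dict[str, str]] = None
    seqs_b: Optional[dict[str, str]] = None

    @property
    def chains_b2a(self) -> list[Chain]:
        """Chains for the reverse (B -> A) direction."""
        return [invert_chain(c) for c in self.chains]

    def map_base(self, chrom: str, pos: int):
        """Ground-truth per-base map A -> B (None when unaligned)."""
        sub = self.segments[
            (self.segments["a_chrom"] == chrom)
            & (self.segments["a_start"] <= pos)
            & (self.segments["a_end"] > pos)
        ]
        if len(sub) == 0:
            return None
        seg = sub.iloc[0]
        off = pos - seg["a_start"]
        if seg["strand"] == "+":
            return seg["b_chrom"], int(seg["b_start"] + off)
        return seg["b_chrom"], int(seg["b_end"] - 1 - off)


def _segments_to_chains(segments: pd.DataFrame, sizes_a, sizes_b) -> list[Chain]:
    """Group colinear plus-strand segments into gapped chains.

    Consecutive segments on the same (a_chrom, b_chrom) pair with "+"
    strand and increasing coordinates merge into a single chain with
    dt/dq gaps; every minus-strand (inversion) segment becomes its own
    single-block chain with target coordinates expressed on the minus
    strand, as the UCSC format requires.
    """
    chains: list[Chain] = []
    next_id = [1]

    def emit(seg_run: list) -> None:
        if not seg_run:
            return
        first, last = seg_run[0], seg_run[-1]
        blocks = []
        for i, s in enumerate(seg_run):
            size = s["a_end"] - s["a_start"]
            if i + 1 < len(seg_run):
                nxt = seg_run[i + 1]
                dt = nxt["a_start"] - s["a_end"]
                dq = nxt["b_start"] - s["b_end"]
            else:
                dt = dq = 0
            blocks.append(ChainBlock(size, dt, dq))
        chains.append(
            Chain(
                score=float(sum(b.size for b in blocks)),
                t_name=first["a_chrom"],
                t_size=sizes_a[first["a_chrom"]],
                t_start=first["a_start"],
                t_end=last["a_end"],
                q_name=first["b_chrom"],
                q_size=sizes_b[first["b_chrom"]],
                q_strand="+",
                q_start=first["b_start"],
                q_end=last["b_end"],
                blocks=blocks,
                chain_id=next_id[0],
            )
        )
        next_id[0] += 1

    for a_chrom, sub in segments.groupby("a_chrom", sort=True):
        run: list = []
        for seg in sub.sort_values("a_start").to_dict("records"):
            if seg["strand"] == "-":
                emit(run)
                run = []
                qsize = sizes_b[seg["b_chrom"]]
                size = seg["a_end"] - seg["a_start"]
                chains.append(
                    Chain(
                        score=float(size),
                        t_name=a_chrom,
                        t_size=sizes_a[a_chrom],
                        t_start=seg["a_start"],
                        t_end=seg["a_end"],
                        q_name=seg["b_chrom"],
                        q_size=qsize,
                        q_strand="-",
                        q_start=qsize - seg["b_end"],
                        q_end=qsize - seg["b_start"],
                        blocks=[ChainBlock(size)],
                        chain_id=next_id[0],
                    )
                )
                next_id[0] += 1
                continue
            if run and (
                seg["b_chrom"] != run[-1]["b_chrom"]
                or seg["b_start"] < run[-1]["b_end"]
            ):
                emit(run)
                run = []
            run.append(seg)
        emit(run)
    return chains


def simulate_genome_pair(
    config: SimulationConfig, with_sequence: bool = False
) -> GenomePair:
    """Derive assembly B from A by sampled deletions, insertions,
    inversions and chromosome breaks; the returned chains encode the
    relation exactly.

    With zero perturbation rates the chain is the identity and every
    interval maps to itself.
    """
    rng = np.random.default_rng(config.seed)
    seg_rows = []
    sizes_b: dict[str, int] = {}
    seqs_a: dict[str, str] = {}
    seqs_b: dict[str, str] = {}

    for a_chrom, a_len in config.chrom_sizes.items():
        if a_len <= 0:
            raise ValueError(f"degenerate chromosome {a_chrom!r}")
        rates = {
            "del": config.deletion_rate,
            "ins": config.insertion_rate,
            "inv": config.inversion_rate,
            "brk": config.break_rate,
        }
        events = []
        for kind, rate in rates.items():
            n = rng.poisson(rate * a_len)
            for pos in sorted(rng.integers(0, a_len, size=n)):
                if kind in ("del", "inv"):
                    size = int(rng.geometric(1.0 / config.event_size_mean))
                    events.append((int(pos), kind, size))
                elif kind == "ins":
                    size = int(rng.geometric(1.0 / config.event_size_mean))
                    events.append((int(pos), kind, size))
                else:
                    events.append((int(pos), kind, 0))
        events.sort()
        # Drop events overlapping a previous one.
        cleaned = []
        cursor = 0
        for pos, kind, size in events:
            if pos < cursor:
                continue
            cleaned.append((pos, kind, size))
            cursor = pos + (size if kind in ("del", "inv") else 1)

        b_chrom = a_chrom.replace("chrA", "chrB") if "chrA" in a_chrom else (
            a_chrom + "_b"
        )
        part = 0
        b_cursor = 0
        a_cursor = 0
        cur_b = b_chrom
        b_parts: dict[str, list] = {cur_b: []}

        def push_aligned(a_s, a_e, strand):
            nonlocal b_cursor
            if a_e <= a_s:
                return
            seg_rows.append(
                dict(
                    a_chrom=a_chrom, a_start=a_s, a_end=a_e,
                    b_chrom=cur_b, b_start=b_cursor,
                    b_end=b_cursor + (a_e - a_s), strand=strand,
                )
            )
            b_parts[cur_b].append(("copy", a_s, a_e, strand))
            b_cursor += a_e - a_s

        for pos, kind, size in cleaned:
            push_aligned(a_cursor, min(pos, a_len), "+")
            a_cursor = min(pos, a_len)
            if a_cursor >= a_len:
                break
            if kind == "del":
                a_cursor = min(a_cursor + size, a_len)
            elif kind == "ins":
                b_parts[cur_b].append(("random", size))
                b_cursor += size
            elif kind == "inv":
                end = min(pos + size, a_len)
                push_aligned(pos, end, "-")
                a_cursor = end
            elif kind == "brk":
                part += 1
                cur_b = f"{b_chrom}_part{part}"
                b_parts[cur_b] = []
                b_cursor = 0
        push_aligned(a_cursor, a_len, "+")

        for name, parts in b_parts.items():
            sizes_b[name] = sum(
                (p[2] - p[1]) if p[0] == "copy" else p[1] for p in parts
            )
        if with_sequence:
            seq_a = rng.integers(0, 4, size=a_len)
            seqs_a[a_chrom] = BASES[seq_a].tobytes().decode()
            comp = np.array([3, 2, 1, 0])
            for name, parts in b_parts.items():
                chunks = []
                for p in parts:
                    if p[0] == "copy":
                        _, s, e, strand = p
                        chunk = seq_a[s:e]
                        if strand == "-":
                            chunk = comp[chunk[::-1]]
                        chunks.append(chunk)
                    else:
                        chunks.append(rng.integers(0, 4, size=p[1]))
                full = (
                    np.concatenate(chunks) if chunks else np.empty(0, dtype=int)
                )
                seqs_b[name] = BASES[full].tobytes().decode()

    segments = pd.DataFrame(
        seg_rows,
        columns=["a_chrom", "a_start", "a_end", "b_chrom", "b_start", "b_end",
                 "strand"],
    )
    sizes_b = {k: v for k, v in sizes_b.items() if v > 0}
    chains = _segments_to_chains(segments, dict(config.chrom_sizes), sizes_b)
    return GenomePair(
        sizes_a=dict(config.chrom_sizes),
        sizes_b=sizes_b,
        chains=chains,
        segments=segments,
        seqs_a=seqs_a if with_sequence else None,
        seqs_b=seqs_b if with_sequence else None,
    )


def anchored_genome_pair(
    n_loci: int,
    locus_length: int,
    spacing: int,
    conserved: np.ndarray,
    human_extra: np.ndarray,
    mouse_extra: np.ndarray,
) -> GenomePair:
    """Locus-anchored assembly pair for the epigenome simulator.

    Slot i of assembly A holds locus i. ``conserved[i]`` slots are aligned
    A<->B; ``human_extra[i]`` slots exist only in A (a dq... dt gap in the
    chain: sequence deleted from B); ``mouse_extra[i]`` slots exist only
    in B (insertion). Exactly one of the three flags is set per locus.
    """
    flags = conserved.astype(int) + human_extra.astype(int) + mouse_extra.astype(int)
    if not np.all(flags == 1):
        raise ValueError("each locus needs exactly one placement flag")
    slot = locus_length + spacing
    seg_rows = []
    a_cursor = b_cursor = 0
    starts_a = np.full(n_loci, -1, dtype=np.int64)
    starts_b = np.full(n_loci, -1, dtype=np.int64)
    for i in range(n_loci):
        if conserved[i]:
            seg_rows.append(
                dict(a_chrom="chrA1", a_start=a_cursor, a_end=a_cursor + slot,
                     b_chrom="chrB1", b_start=b_cursor, b_end=b_cursor + slot,
                     strand="+")
            )
            starts_a[i] = a_cursor + spacing // 2
            starts_b[i] = b_cursor + spacing // 2
            a_cursor += slot
            b_cursor += slot
        elif human_extra[i]:
            starts_a[i] = a_cursor + spacing // 2
            a_cursor += slot
        else:
            starts_b[i] = b_cursor + spacing // 2
            b_cursor += slot
    sizes_a = {"chrA1": a_cursor + spacing}
    sizes_b = {"chrB1": b_cursor + spacing}
    segments = pd.DataFrame(seg_rows)
    chains = _segments_to_chains(segments, sizes_a, sizes_b)
    pair = GenomePair(sizes_a=sizes_a, sizes_b=sizes_b, chains=chains,
                      segments=segments)
    pair.locus_starts_a = starts_a  # type: ignore[attr-defined]
    pair.locus_starts_b = starts_b  # type: ignore[attr-defined]
    return pair
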
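"""Mismatch-tolerant spaced 16-mer hashing over 32-mer windows.

Six patterns each select 16 of the 32 positions so that any pair of
positions is jointly avoided by at least one pattern; a 32-mer carrying at
most two mismatches therefore still matches at least one table exactly.
Reads are screened by probing the three non-overlapping 32-mers of their
first 96 bases (18 probes) against the tables and counting hits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import ceil, comb
from typing import Iterable, Sequence

import numpy as np

from ._dna import encode, revcomp

WINDOW = 32          # spaced-seed window length
KMER = 16            # selected positions per pattern
N_PATTERNS = 6
SCREEN_SPAN = 96     # only the first 96 bases of a read are screened
N_WINDOWS = 3        # 96 / 32
N_PROBES = N_WINDOWS * N_PATTERNS
DEFAULT_MIN_HITS = 3

_N_BLOCKS = 4
_BLOCK = WINDOW // _N_BLOCKS  # 8


@dataclass(frozen=True)
class SpacedPattern:
    """One 16-of-32 position pattern."""

    id: int
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != KMER:
            raise ValueError("pattern must select exactly 16 positions")


def build_patterns() -> list[SpacedPattern]:
    """The six block-pair patterns.

    [0,32) is split into four contiguous 8-base blocks; each pattern is the
    union of one of the C(4,2)=6 block pairs.  Every position lands in
    exactly 3 patterns, and for any two positions some pattern avoids both
    (the pattern built from the two blocks containing neither).
    """
    blocks = [tuple(range(_BLOCK * b, _BLOCK * (b + 1))) for b in range(_N_BLOCKS)]
    return [
        SpacedPattern(i, blocks[a] + blocks[b])
        for i, (a, b) in enumerate(combinations(range(_N_BLOCKS), 2))
    ]


# ---------------------------------------------------------------------------
# key computation


def _window_keys(codes: np.ndarray, starts: np.ndarray, positions: Sequence[int]) -> np.ndarray:
    """Packed 2-bit keys for the given window starts under one pattern.

    ``codes`` may contain code 4 (ambiguous); callers must mask such
    windows out themselves.
    """
    key = np.zeros(len(starts), dtype=np.uint64)
    for j, p in enumerate(positions):
        key |= codes[starts + p].astype(np.uint64) << np.uint64(2 * j)
    return key


def _valid_window_mask(codes: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """True where the 32-mer window holds no ambiguous base."""
    bad = np.concatenate(([0], np.cumsum(codes == 4)))
    return (bad[starts + WINDOW] - bad[starts]) == 0


@dataclass
class _PatternTable:
    """Sorted-key location table for one pattern (forward strand)."""

    unique_keys: np.ndarray          # sorted uint64
    group_start: np.ndarray          # len(unique_keys)+1 offsets into loc_*
    loc_contig: np.ndarray           # int32, grouped by key
    loc_offset: np.ndarray           # int32 window start, grouped by key

    def contains(self, keys: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.unique_keys, keys)
        idx_c = np.minimum(idx, len(self.unique_keys) - 1)
        if len(self.unique_keys) == 0:
            return np.zeros(len(keys), dtype=bool)
        return self.unique_keys[idx_c] == keys

    def lookup(self, key: int) -> tuple[np.ndarray, np.ndarray]:
        i = int(np.searchsorted(self.unique_keys, np.uint64(key)))
        if i >= len(self.unique_keys) or self.unique_keys[i] != np.uint64(key):
            return np.empty(0, np.int32), np.empty(0, np.int32)
        lo, hi = self.group_start[i], self.group_start[i + 1]
        return self.loc_contig[lo:hi], self.loc_offset[lo:hi]


@dataclass
class SpacedHashIndex:
    """Per-pattern key→location tables over a set of contig sequences.

    Only the forward strand is indexed; reads are probed in both
    orientations, which is equivalent at half the memory.
    """

    patterns: list[SpacedPattern]
    tables: list[_PatternTable]
    contig_names: list[str]
    contig_lengths: np.ndarray
    step: int = 1
    _pattern_pos: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self._pattern_pos:
            self._pattern_pos = [np.asarray(p.positions) for p in self.patterns]

    @property
    def n_windows_indexed(self) -> int:
        return int(self.tables[0].loc_contig.shape[0])

    def save(self, path: str) -> None:
        arrays: dict[str, np.ndarray] = {}
        for i, t in enumerate(self.tables):
            arrays[f"uk{i}"] = t.unique_keys
            arrays[f"gs{i}"] = t.group_start
            arrays[f"lc{i}"] = t.loc_contig
            arrays[f"lo{i}"] = t.loc_offset
        meta = json.dumps(
            {"magic": "seqsentry-hashidx", "version": 1, "step": self.step,
             "contigs": self.contig_names,
             "lengths": [int(x) for x in self.contig_lengths]}
        )
        arrays["meta"] = np.frombuffer(meta.encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "SpacedHashIndex":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            if meta.get("magic") != "seqsentry-hashidx":
                raise ValueError(f"{path}: not a seqsentry hash index")
            tables = [
                _PatternTable(z[f"uk{i}"], z[f"gs{i}"], z[f"lc{i}"], z[f"lo{i}"])
                for i in range(N_PATTERNS)
            ]
        return cls(build_patterns(), tables, meta["contigs"],
                   np.asarray(meta["lengths"], dtype=np.int64), meta["step"])


def index_reference(seqs: Iterable[tuple[str, str]], step: int = 1) -> SpacedHashIndex:
    """Index every 32-mer window (stride ``step``) of every contig.

    ``seqs`` yields (name, sequence) pairs.  Windows containing ambiguous
    bases are skipped.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    patterns = build_patterns()
    names: list[str] = []
    lengths: list[int] = []
    per_pat_keys: list[list[np.ndarray]] = [[] for _ in range(N_PATTERNS)]
    per_pat_contig: list[list[np.ndarray]] = [[] for _ in range(N_PATTERNS)]
    per_pat_offset: list[list[np.ndarray]] = [[] for _ in range(N_PATTERNS)]

    for ci, (name, seq) in enumerate(seqs):
        names.append(name)
        lengths.append(len(seq))
        if len(seq) < WINDOW:
            continue
        codes = encode(seq)
        starts = np.arange(0, len(seq) - WINDOW + 1, step)
        ok = _valid_window_mask(codes, starts)
        starts = starts[ok]
        if len(starts) == 0:
            continue
        for pi, pat in enumerate(patterns):
            per_pat_keys[pi].append(_window_keys(codes, starts, pat.positions))
            per_pat_contig[pi].append(np.full(len(starts), ci, dtype=np.int32))
            per_pat_offset[pi].append(starts.astype(np.int32))

    if not names:
        raise ValueError("empty reference: nothing to index")

    tables = []
    for pi in range(N_PATTERNS):
        if per_pat_keys[pi]:
            keys = np.concatenate(per_pat_keys[pi])
            contig = np.concatenate(per_pat_contig[pi])
            offset = np.concatenate(per_pat_offset[pi])
        else:
            keys = np.empty(0, np.uint64)
            contig = offset = np.empty(0, np.int32)
        order = np.argsort(keys, kind="stable")
        keys, contig, offset = keys[order], contig[order], offset[order]
        uk, first = np.unique(keys, return_index=True)
        group_start = np.concatenate([first, [len(keys)]]).astype(np.int64)
        tables.append(_PatternTable(uk, group_start, contig, offset))

    return SpacedHashIndex(patterns, tables, names,
                           np.asarray(lengths, dtype=np.int64), step)


# ---------------------------------------------------------------------------
# probing & screening


def extract_probe_keys(read_seq: str) -> list[tuple[int, int, int | None]]:
    """(window, pattern, key) probes from the first 96 bases of a read.

    Reads of 96 bp or longer yield exactly 18 probes.  Shorter reads yield
    6 probes per complete 32-mer that fits; reads under 32 bp yield none
    (unscreenable).  A probe over an ambiguous base gets key ``None``,
    which can never match a table.
    """
    n_win = min(N_WINDOWS, len(read_seq) // WINDOW)
    if n_win == 0:
        return []
    span = read_seq[: n_win * WINDOW]
    codes = encode(span)
    starts = np.arange(n_win) * WINDOW
    valid = _valid_window_mask(codes, starts)
    probes: list[tuple[int, int, int | None]] = []
    patterns = build_patterns()
    for w in range(n_win):
        for pat in patterns:
            if not valid[w]:
                # a window-level N only poisons patterns covering its position
                sel = codes[starts[w] + np.asarray(pat.positions)]
                key = None if (sel == 4).any() else int(
                    _window_keys(codes, starts[w : w + 1], pat.positions)[0]
                )
            else:
                key = int(_window_keys(codes, starts[w : w + 1], pat.positions)[0])
            probes.append((w, pat.id, key))
    return probes


@dataclass(frozen=True)
class ScreenResult:
    hit_count: int
    passed: bool
    window_hits: tuple[int, ...]
    unscreenable: bool = False


def _orientation_hits(read_seq: str, index: SpacedHashIndex) -> tuple[int, tuple[int, ...]]:
    probes = extract_probe_keys(read_seq)
    if not probes:
        return -1, ()
    n_win = probes[-1][0] + 1
    window_hits = [0] * n_win
    for w, pi, key in probes:
        if key is None:
            continue
        if index.tables[pi].contains(np.asarray([key], dtype=np.uint64))[0]:
            window_hits[w] += 1
    return sum(window_hits), tuple(window_hits)


def screen_read(read_seq: str, index: SpacedHashIndex,
                k_min: int = DEFAULT_MIN_HITS) -> ScreenResult:
    """Count probe hits in both orientations (max) and threshold.

    For reads shorter than 96 bp the threshold is scaled to the number of
    usable windows: ceil(k_min * windows / 3).
    """
    if not 1 <= k_min <= N_PROBES:
        raise ValueError("k_min must be in [1, 18]")
    fwd_hits, fwd_win = _orientation_hits(read_seq, index)
    if fwd_hits < 0:
        return ScreenResult(0, False, (), unscreenable=True)
    rev_hits, rev_win = _orientation_hits(revcomp(read_seq), index)
    if rev_hits >= fwd_hits:
        hits, win = rev_hits, rev_win
    else:
        hits, win = fwd_hits, fwd_win
    n_win = len(win)
    k_eff = k_min if n_win == N_WINDOWS else ceil(k_min * n_win / N_WINDOWS)
    return ScreenResult(hits, hits >= k_eff, win)


def screen_reads_batch(seqs: Sequence[str], index: SpacedHashIndex,
                       k_min: int = DEFAULT_MIN_HITS) -> np.ndarray:
    """Vectorized hit counts for many reads.

    Reads of >= 96 unambiguous bases take the fast path and report the
    exact per-read max-over-orientation hit count, reusable at any
    threshold.  Other reads fall back to :func:`screen_read` at ``k_min``
    and report 18 if passed, 0 otherwise.
    """
    counts = np.zeros(len(seqs), dtype=np.int16)
    long_idx = [i for i, s in enumerate(seqs)
                if len(s) >= SCREEN_SPAN and "N" not in s[:SCREEN_SPAN].upper()]
    long_set = set(long_idx)
    other_idx = [i for i in range(len(seqs)) if i not in long_set]
    if long_idx:
        mat = np.empty((len(long_idx), SCREEN_SPAN), dtype=np.uint8)
        for r, i in enumerate(long_idx):
            mat[r] = encode(seqs[i][:SCREEN_SPAN])
        hits = np.zeros(len(long_idx), dtype=np.int16)
        for orient in range(2):
            codes = mat if orient == 0 else (3 - mat)[:, ::-1]
            ohits = np.zeros(len(long_idx), dtype=np.int16)
            for w in range(N_WINDOWS):
                block = codes[:, w * WINDOW : (w + 1) * WINDOW]
                for pi, pat in enumerate(index.patterns):
                    sel = block[:, np.asarray(pat.positions)].astype(np.uint64)
                    key = np.zeros(len(long_idx), dtype=np.uint64)
                    for j in range(KMER):
                        key |= sel[:, j] << np.uint64(2 * j)
                    ohits += index.tables[pi].contains(key)
            hits = np.maximum(hits, ohits)
        counts[long_idx] = hits
    for i in other_idx:
        res = screen_read(seqs[i], index, k_min)
        counts[i] = N_PROBES if res.passed else 0
    return counts


# ---------------------------------------------------------------------------
# worst-case analysis


def _min_hits_one_window(mismatches: int) -> int:
    """Minimum surviving tables for one 32-mer with this many mismatches.

    Hits = C(4-b, 2) where b is the number of distinct 8-base blocks hit;
    an adversary occupies as many distinct blocks as it has mismatches.
    """
    b = min(mismatches, _N_BLOCKS)
    return comb(_N_BLOCKS - b, 2)


def worst_case_min_hits(m: int) -> int:
    """Exact minimum hit count over all placements of m mismatches in 96 bp.

    Exhaustive over per-window mismatch counts; within a window only the
    block-occupancy class matters (verified against positional brute force
    in the test suite).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    best = N_PROBES
    cap = WINDOW
    for m1 in range(min(m, cap) + 1):
        for m2 in range(min(m - m1, cap) + 1):
            m3 = min(m - m1 - m2, cap)
            total = (_min_hits_one_window(m1) + _min_hits_one_window(m2)
                     + _min_hits_one_window(m3))
            best = min(best, total)
    return best


def worst_case_min_hits_bruteforce(m: int, span: int = SCREEN_SPAN) -> int:
    """Positional brute force over all C(span, m) mismatch placements.

    Test oracle only — exponential in m.
    """
    patterns = build_patterns()
    pat_sets = [frozenset(p.positions) for p in patterns]
    best = N_PROBES
    n_win = span // WINDOW
    for combo in combinations(range(span), m):
        hits = 0
        for w in range(n_win):
            in_win = [p - w * WINDOW for p in combo if w * WINDOW <= p < (w + 1) * WINDOW]
            for ps in pat_sets:
                if not any(p in ps for p in in_win):
                    hits += 1
        best = min(best, hits)
        if best == 0 and m >= 12:
            break
    return best
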
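"""Approximate (edit-distance) keyword search over OCR text.

OCR mis-translates characters at a low but persistent rate, so every
keyword filter in the pipeline tolerates a per-keyword Levenshtein
allowance. ``fuzzy_find`` returns all non-overlapping approximate
occurrences of a phrase in a haystack.

The search is case-insensitive. For a phrase of length m with allowance k
it uses the classic pigeonhole filter -- any substring within distance k of
the phrase must contain one of k+1 contiguous phrase pieces verbatim -- to
locate candidate windows with plain ``str.find``, then verifies each window
with the Sellers semi-global dynamic program (edit distance of the phrase
against the best substring ending at each window position, with start
tracking). This keeps scanning cost near exact-substring speed on the vast
majority of lines, which contain no keyword at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class KeywordSpec:
    """A search phrase with its fuzzy allowance.

    ``max_edit_distance=None`` defaults to ``ceil(0.15 * len(phrase))``:
    longer phrases accumulate more OCR noise, so the allowance scales with
    length unless the configuration pins it (per-keyword allowances are
    normally tuned to the observed mis-translation rate of each keyword).
    """

    phrase: str
    max_edit_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.phrase:
            raise ValueError("KeywordSpec.phrase must be non-empty")
        if self.max_edit_distance is not None and self.max_edit_distance < 0:
            raise ValueError("max_edit_distance must be >= 0")

    @property
    def allowance(self) -> int:
        if self.max_edit_distance is not None:
            return self.max_edit_distance
        return math.ceil(0.15 * len(self.phrase))


@dataclass(frozen=True)
class FuzzyMatch:
    """One approximate occurrence: haystack[start:end] at the given distance."""

    start: int
    end: int
    distance: int

    @property
    def span(self) -> int:
        return self.end - self.start


def _exact_matches(hay: str, pat: str) -> list[FuzzyMatch]:
    out = []
    i = hay.find(pat)
    while i != -1:
        out.append(FuzzyMatch(i, i + len(pat), 0))
        i = hay.find(pat, i + len(pat))
    return out


def _candidate_windows(hay: str, pat: str, k: int) -> list[tuple[int, int]]:
    """Merged haystack windows that could contain a match, via pigeonhole."""
    m = len(pat)
    n_pieces = k + 1
    # contiguous pieces of near-equal length
    bounds = [round(i * m / n_pieces) for i in range(n_pieces + 1)]
    intervals: list[tuple[int, int]] = []
    for p in range(n_pieces):
        lo, hi = bounds[p], bounds[p + 1]
        piece = pat[lo:hi]
        if not piece:
            continue
        i = hay.find(piece)
        while i != -1:
            start = max(0, i - lo - k)
            end = min(len(hay), i - lo + m + 2 * k)
            intervals.append((start, end))
            i = hay.find(piece, i + 1)
    if not intervals:
        return []
    intervals.sort()
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _sellers_candidates(
    window: str, offset: int, pat: str, k: int
) -> list[FuzzyMatch]:
    """All (start, end, distance<=k) substring matches within one window.

    Semi-global DP: row 0 is all zeros so a match may start anywhere.
    ``starts`` carries the start index of the aligned substring; on ties
    the earlier start is preferred (degenerate empty spans are dropped,
    and span-length preference is applied during final selection).
    """
    m, n = len(pat), len(window)
    dist = [0] * (n + 1)
    starts = list(range(n + 1))
    out: list[FuzzyMatch] = []
    for i in range(1, m + 1):
        pc = pat[i - 1]
        prev_diag_d, prev_diag_s = dist[0], starts[0]
        dist[0] = i
        starts[0] = 0
        for j in range(1, n + 1):
            sub_cost = prev_diag_d + (0 if window[j - 1] == pc else 1)
            del_cost = dist[j] + 1  # skip a phrase char
            ins_cost = dist[j - 1] + 1  # absorb a haystack char
            best = sub_cost
            best_start = prev_diag_s
            if del_cost < best or (del_cost == best and starts[j] < best_start):
                best, best_start = del_cost, starts[j]
            if ins_cost < best or (ins_cost == best and starts[j - 1] < best_start):
                best, best_start = ins_cost, starts[j - 1]
            prev_diag_d, prev_diag_s = dist[j], starts[j]
            dist[j] = best
            starts[j] = best_start
        if i == m:
            for j in range(1, n + 1):
                if dist[j] <= k:
                    s, e = starts[j] + offset, j + offset
                    if e > s:
                        out.append(FuzzyMatch(s, e, dist[j]))
    return out


def _select_non_overlapping(candidates: list[FuzzyMatch]) -> list[FuzzyMatch]:
    """Greedy selection: lowest distance first, then leftmost, then shortest.

    A distance-0 occurrence therefore always wins over the distance-1
    shadows that flank it; surviving matches never overlap and are
    returned in haystack order.
    """
    chosen: list[FuzzyMatch] = []
    for cand in sorted(candidates, key=lambda c: (c.distance, c.start, c.span)):
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c.start)
    return chosen


def fuzzy_find(haystack: str, spec: KeywordSpec) -> list[FuzzyMatch]:
    """All non-overlapping case-insensitive approximate matches of a phrase.

    With allowance 0 this is exactly case-insensitive substring search.
    Matches are reported in haystack order; overlapping candidates are
    resolved in favor of the lowest edit distance, then the leftmost start,
    then the shortest span.
    """
    if not haystack:
        return []
    hay = haystack.casefold()
    pat = spec.phrase.casefold()
    k = spec.allowance
    if k == 0:
        return _exact_matches(hay, pat)
    if k + 1 > len(pat):
        # pigeonhole pieces would be empty; verify the whole haystack
        windows = [(0, len(hay))]
    else:
        windows = _candidate_windows(hay, pat, k)
    candidates: list[FuzzyMatch] = []
    for start, end in windows:
        candidates.extend(_sellers_candidates(hay[start:end], start, pat, k))
    return _select_non_overlapping(candidates)


def contains_phrase(haystack: str, spec: KeywordSpec) -> bool:
    """True if the phrase occurs at least once within the allowance."""
    return bool(fuzzy_find(haystack, spec))
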
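"""Template-switch derivation of ZF-array alleles.

New alleles of repeat arrays arise when copying jumps between two
templates (replication slippage, gene conversion or recombination —
the model is agnostic). A child allele is *derivable* from a pair of
parental alleles if its DNA can be written as alternating exact
fragments of the two parents, where the first fragment starts at a
parent's 5' end, the last fragment ends at a parent's 3' end, and
every fragment is longer than ``min_match`` nucleotides (default 15,
i.e. 16 nt or more). The number of switches is the number of
fragments minus one. A self-pair (parent1 = parent2) models derivation
within a homozygote or from a single allele.

Two solvers are provided: the greedy procedure (at each step take the
longest match of the child's current 5' remainder in the other parent,
run from both starting parents, keep the better) and an exact dynamic
program over (child position, active parent) used as its oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

DEFAULT_MIN_MATCH = 15  # matches must be strictly longer than this
DEFAULT_MAX_SWITCHES = 50  # runtime safety cap; derivations are unbounded in principle


@dataclass(frozen=True)
class Segment:
    parent: int  # 1 or 2
    start: int  # 0-based, half-open on the parent
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SwitchPath:
    """A segmentation of the child into alternating parental fragments."""

    child: str
    parents: tuple[str, str]
    segments: tuple[Segment, ...]

    @property
    def n_switches(self) -> int:
        return len(self.segments) - 1

    def reconstruct(self) -> str:
        return "".join(
            self.parents[s.parent - 1][s.start : s.end] for s in self.segments
        )

    def validate(self, min_match: int = DEFAULT_MIN_MATCH) -> None:
        assert self.reconstruct() == self.child, "segments do not rebuild the child"
        assert self.segments[0].start == 0, "first segment must start at parent 5' end"
        last = self.segments[-1]
        assert last.end == len(self.parents[last.parent - 1]), (
            "last segment must end at parent 3' end"
        )
        for a, b in zip(self.segments, self.segments[1:]):
            assert a.parent != b.parent, "segments must alternate parents"
        assert all(s.length > min_match for s in self.segments), "segment too short"


# -- exact string helpers ----------------------------------------------

def _z_array(s: str) -> np.ndarray:
    """Z-algorithm: z[i] = length of the longest common prefix of s and s[i:]."""
    n = len(s)
    z = np.zeros(n, dtype=np.int64)
    z[0] = n
    l = r = 0
    for i in range(1, n):
        if i < r:
            z[i] = min(r - i, z[i - l])
        while i + z[i] < n and s[z[i]] == s[i + z[i]]:
            z[i] += 1
        if i + z[i] > r:
            l, r = i, i + z[i]
    return z

def _longest_prefix_match(rem: str, parent: str) -> tuple[int, int]:
    """(length, leftmost start) of the longest prefix of ``rem`` occurring
    anywhere in ``parent``; (0, -1) if none."""
    if not rem or not parent:
        return 0, -1
    z = _z_array(rem + "\x00" + parent)[len(rem) + 1 :]
    if z.size == 0:
        return 0, -1
    best = int(z.max())
    if best == 0:
        return 0, -1
    return best, int(np.argmax(z))


# -- greedy solver ------------------------------------------------------

def _greedy_from(
    child: str,
    parents: tuple[str, str],
    start_parent: int,
    min_match: int,
    max_switches: int,
) -> list[Segment] | None:
    active = start_parent
    p = parents[active]
    # step 1: anchored at the parent 5' end
    l = 0
    for a, b in zip(child, p):
        if a != b:
            break
        l += 1
    if l == len(child) and l == len(p) and l > min_match:
        return [Segment(active + 1, 0, l)]
    if l <= min_match or l >= len(child):
        return None
    segments = [Segment(active + 1, 0, l)]
    pos = l
    while len(segments) <= max_switches:
        active = 1 - active
        p = parents[active]
        rem = child[pos:]
        # termination: remainder is the 3' end of the active parent
        if len(rem) > min_match and len(rem) <= len(p) and p.endswith(rem):
            segments.append(Segment(active + 1, len(p) - len(rem), len(p)))
            return segments
        l, start = _longest_prefix_match(rem, p)
        if l <= min_match or l >= len(rem):
            return None  # dead end: too short, or full match not at parent 3' end
        segments.append(Segment(active + 1, start, start + l))
        pos += l
    return None


def greedy_switch_path(
    child: str,
    p1: str,
    p2: str,
    min_match: int = DEFAULT_MIN_MATCH,
    max_switches: int = DEFAULT_MAX_SWITCHES,
) -> SwitchPath | None:
    """Greedy alternating segmentation of ``child`` over (p1, p2).

    Run from both starting parents; the successful path with fewer
    switches wins (ties favour starting from p1). ``None`` = unreachable.
    """
    if not child or not p1 or not p2:
        raise ValueError("sequences must be non-empty")
    best: list[Segment] | None = None
    for start in (0, 1):
        segs = _greedy_from(child, (p1, p2), start, min_match, max_switches)
        if segs is not None and (best is None or len(segs) < len(best)):
            best = segs
    if best is None:
        return None
    path = SwitchPath(child=child, parents=(p1, p2), segments=tuple(best))
    path.validate(min_match)
    return path


# -- exact dynamic program ---------------------------------------------

def _lce_table(child: str, parent: str) -> np.ndarray:
    """lce[i, j] = longest common extension of child[i:] and parent[j:]."""
    c = np.frombuffer(child.encode(), dtype=np.uint8)
    p = np.frombuffer(parent.encode(), dtype=np.uint8)
    L, P = len(c), len(p)
    lce = np.zeros((L + 1, P + 1), dtype=np.int32)
    eq = c[:, None] == p[None, :]
    for i in range(L - 1, -1, -1):
        lce[i, :P] = np.where(eq[i], lce[i + 1, 1 : P + 1] + 1, 0)
    return lce[:L, :P] if L and P else lce


def min_switches_dp(
    child: str,
    p1: str,
    p2: str,
    min_match: int = DEFAULT_MIN_MATCH,
    max_switches: int = DEFAULT_MAX_SWITCHES,
) -> int | None:
    """Exact minimum number of switches, or ``None`` if unreachable.

    Dynamic program over (child position, active parent) under the same
    constraints as the greedy solver; always <= the greedy count.
    """
    if not child or not p1 or not p2:
        raise ValueError("sequences must be non-empty")
    parents = (p1, p2)
    L = len(child)
    lce = [_lce_table(child, p) for p in parents]
    maxl = [t.max(axis=1) if t.size else np.zeros(L, dtype=np.int32) for t in lce]

    def suffix_ok(cp: int, a: int) -> bool:
        rem = L - cp
        j = len(parents[a]) - rem
        return rem > min_match and j >= 0 and lce[a][cp, j] >= rem

    INF = math.inf
    # g[a][cp]: min switches to finish child[cp:], next unanchored segment from parent a
    g = [np.full(L + 1, INF), np.full(L + 1, INF)]
    for cp in range(L - 1, 0, -1):
        for a in (0, 1):
            if suffix_ok(cp, a):
                g[a][cp] = 0.0
                continue
            hi = min(int(maxl[a][cp]), L - cp - 1)
            lo = min_match + 1
            if hi >= lo:
                window = g[1 - a][cp + lo : cp + hi + 1]
                m = window.min()
                if m < INF:
                    g[a][cp] = 1.0 + m
    best = INF
    for a in (0, 1):
        if L == len(parents[a]) and child == parents[a]:
            best = 0.0
            break
        anchored = int(lce[a][0, 0]) if lce[a].size else 0
        hi = min(anchored, L - 1)
        lo = min_match + 1
        if hi >= lo:
            window = g[1 - a][lo : hi + 1]
            m = window.min() if window.size else INF
            if m < INF:
                best = min(best, 1.0 + m)
    if best is INF or best > max_switches:
        return None
    return int(best)


# -- catalog scans ------------------------------------------------------

@dataclass(frozen=True)
class ParentScanResult:
    child: str  # allele name
    table: dict  # (p1 name, p2 name) unordered -> n_switches or None
    origin_class: str  # "uni" | "bi" | "uni_or_bi" | "unreachable"
    best: int | None


def scan_parents(
    child_name: str,
    child_dna: str,
    catalog_dnas: Mapping[str, str],
    min_match: int = DEFAULT_MIN_MATCH,
    max_switches: int = DEFAULT_MAX_SWITCHES,
    exclude_self: bool = False,
) -> ParentScanResult:
    """Greedy-derive a child from every unordered parental pair
    (self-pairs included) of a catalog.

    Origin classes: *uni* — the minimum is achieved by a single-parent
    derivation only; *bi* — every minimal derivation uses two distinct
    parents; *uni_or_bi* — both kinds achieve the minimum;
    *unreachable* — no pair derives the child. With ``exclude_self``
    the child's own sequence is removed from the parental pool
    (derivability from *other* alleles).
    """
    names = [
        n for n, d in catalog_dnas.items() if not (exclude_self and d == child_dna)
    ]
    table: dict[tuple[str, str], int | None] = {}
    for n1, n2 in itertools.combinations_with_replacement(sorted(names), 2):
        path = greedy_switch_path(
            child_dna, catalog_dnas[n1], catalog_dnas[n2], min_match, max_switches
        )
        table[(n1, n2)] = path.n_switches if path is not None else None
    reachable = [v for v in table.values() if v is not None]
    if not reachable:
        return ParentScanResult(child_name, table, "unreachable", None)
    best = min(reachable)
    uni = any(
        v == best
        for (n1, n2), v in table.items()
        if v is not None and (n1 == n2 or v == 0)
    )
    bi = any(
        v == best
        for (n1, n2), v in table.items()
        if v is not None and n1 != n2 and v > 0
    )
    if uni and bi:
        cls = "uni_or_bi"
    elif uni:
        cls = "uni"
    elif bi:
        cls = "bi"
    else:  # pragma: no cover - exhaustive above
        cls = "unreachable"
    return ParentScanResult(child_name, table, cls, best)


def cohort_switch_summary(
    children: Mapping[str, str],
    catalog_dnas: Mapping[str, str],
    type_labels: Mapping[str, str],
    min_match: int = DEFAULT_MIN_MATCH,
    max_switches: int = DEFAULT_MAX_SWITCHES,
) -> "pd.DataFrame":
    """Minimal switch counts per child and parental-type class.

    For each child allele the parental pool is the catalog minus the
    child itself. Pairs are grouped into classes by the parents' type
    labels (AxA, AxC, CxC; pairs with an untyped parent are dropped).
    Returns one row per (child, class): the minimal switch count over
    pairs of that class and the number of pairs achieving it.
    """
    import pandas as pd

    label_key = {"A-type": "A", "C-type": "C"}
    rows = []
    for child_name, child_dna in children.items():
        scan = scan_parents(
            child_name,
            child_dna,
            catalog_dnas,
            min_match,
            max_switches,
            exclude_self=True,
        )
        per_class: dict[str, list[int]] = {}
        for (n1, n2), v in scan.table.items():
            if v is None:
                continue
            t1, t2 = label_key.get(type_labels.get(n1, "")), label_key.get(
                type_labels.get(n2, "")
            )
            if t1 is None or t2 is None:
                continue
            cls = "x".join(sorted((t1, t2)))
            per_class.setdefault(cls, []).append(v)
        for cls, vals in sorted(per_class.items()):
            m = min(vals)
            rows.append(
                {
                    "child": child_name,
                    "child_type": type_labels.get(child_name, "untyped"),
                    "parent_class": cls,
                    "min_switches": m,
                    "n_pairs_at_min": sum(1 for v in vals if v == m),
                    "n_pairs_reachable": len(vals),
                }
            )
        if not per_class:
            rows.append(
                {
                    "child": child_name,
                    "child_type": type_labels.get(child_name, "untyped"),
                    "parent_class": None,
                    "min_switches": None,
                    "n_pairs_at_min": 0,
                    "n_pairs_reachable": 0,
                }
            )
    return pd.DataFrame(rows)


def class_average_switches(summary: "pd.DataFrame") -> dict[str, float]:
    """Mean (over children) of the per-child minimal switch count, per
    parental class, counting only children reachable in that class."""
    out: dict[str, float] = {}
    ok = summary.dropna(subset=["min_switches"])
    for cls, grp in ok.groupby("parent_class"):
        out[str(cls)] = float(grp["min_switches"].mean())
    return out
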